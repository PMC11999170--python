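"""Clinical glucose-variability (GV) metrics and GV-based personalization.

Eight standard metrics summarize a subject's glucose dispersion: interday
SD and CV, mean intraday CV, time in range (TIR), J-index, the low/high
blood-glucose risk indices (LBGI/HBGI) from Kovatchev's symmetrizing
transform, and the glucose management indicator (GMI).  Subjects are split
into high vs low GV at the clinical threshold of 36% interday CV; high-GV
subjects need a longer initial training window before incremental
retraining starts paying off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import OBSERVED, EmptyInputError, GlucoseTrace

logger = logging.getLogger(__name__)

#: clinical high/low GV threshold on interday CV (%)
CV_THRESHOLD = 36.0
#: consensus time-in-range bounds, mg/dL
TIR_RANGE = (70.0, 180.0)

#: initial-window recommendations (days) per GV group
INITIAL_DAYS_HIGH = 7
INITIAL_DAYS_LOW = 2
ALLOWED_INITIAL_DAYS = (2, 3, 4, 5, 7, 8, 10)


@dataclass
class GVProfile:
    interday_sd: float
    interday_cv: float
    mean_intraday_cv: float
    tir_percent: float
    j_index: float
    hbgi: float
    lbgi: float
    gmi: float
    group: str  # "high" | "low"

    def as_dict(self) -> dict:
        return {
            "interday_sd": self.interday_sd,
            "interday_cv": self.interday_cv,
            "mean_intraday_cv": self.mean_intraday_cv,
            "tir_percent": self.tir_percent,
            "j_index": self.j_index,
            "hbgi": self.hbgi,
            "lbgi": self.lbgi,
            "gmi": self.gmi,
            "group": self.group,
        }


def risk_transform(g: np.ndarray) -> np.ndarray:
    """Kovatchev symmetrizing transform f(g) = 1.509((ln g)^1.084 - 5.381)."""
    g = np.asarray(g, dtype=float)
    return 1.509 * (np.log(g) ** 1.084 - 5.381)


def compute_gv(
    trace: GlucoseTrace,
    tir_range: tuple[float, float] = TIR_RANGE,
    cv_threshold: float = CV_THRESHOLD,
) -> GVProfile:
    """Compute the 8 GV metrics on observed (never imputed) samples.

    Definitions: interday CV = 100*SD/mean over all samples (sample SD,
    ddof=1); mean intraday CV = mean over calendar days of the per-day CV;
    TIR = % of samples inside ``tir_range``; J-index = 0.001*(mean+SD)^2;
    GMI = 3.31 + 0.02392*mean; LBGI (HBGI) = average over all samples of
    10*f(g)^2 restricted to f<0 (f>0), zero elsewhere.
    """
    mask = ~trace.missing & (trace.flags == OBSERVED)
    g = trace.values[mask]
    if g.size == 0:
        raise EmptyInputError("no observed glucose values")

    mean = float(np.mean(g))
    sd = float(np.std(g, ddof=1)) if g.size > 1 else 0.0
    cv = 100.0 * sd / mean

    # per-calendar-day CV, averaged over days with >= 2 samples
    days = trace.day_index()[mask]
    intraday = []
    for d in np.unique(days):
        gd = g[days == d]
        if gd.size >= 2:
            intraday.append(100.0 * np.std(gd, ddof=1) / np.mean(gd))
    mean_intraday_cv = float(np.mean(intraday)) if intraday else 0.0

    lo, hi = tir_range
    tir = 100.0 * float(np.mean((g >= lo) & (g <= hi)))
    j_index = 0.001 * (mean + sd) ** 2
    gmi = 3.31 + 0.02392 * mean

    f = risk_transform(g)
    risk = 10.0 * f ** 2
    lbgi = float(np.mean(np.where(f < 0, risk, 0.0)))
    hbgi = float(np.mean(np.where(f > 0, risk, 0.0)))

    group = "high" if cv > cv_threshold else "low"
    return GVProfile(
        interday_sd=sd,
        interday_cv=cv,
        mean_intraday_cv=mean_intraday_cv,
        tir_percent=tir,
        j_index=j_index,
        hbgi=hbgi,
        lbgi=lbgi,
        gmi=gmi,
        group=group,
    )


def classify_gv(profile: GVProfile, cv_threshold: float = CV_THRESHOLD) -> str:
    """High GV iff interday CV strictly exceeds the 36% threshold."""
    return "high" if profile.interday_cv > cv_threshold else "low"


def recommend_initial_days(group: str, override: int | None = None) -> int:
    """Initial-window length (days) for the first training subset.

    High-GV subjects start with 7 days, low-GV with 2; an explicit override
    (any of the supported window lengths) wins, with a logged warning.
    """
    if override is not None:
        if override not in ALLOWED_INITIAL_DAYS:
            raise ValueError(
                f"initial_days={override} not in supported set {ALLOWED_INITIAL_DAYS}"
            )
        default = INITIAL_DAYS_HIGH if group == "high" else INITIAL_DAYS_LOW
        if override != default:
            logger.warning(
                "initial_days override %d replaces the %s-GV recommendation %d",
                override, group, default,
            )
        return override
    if group == "high":
        return INITIAL_DAYS_HIGH
    if group == "low":
        return INITIAL_DAYS_LOW
    raise ValueError(f"unknown GV group {group!r}")
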