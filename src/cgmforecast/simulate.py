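"""Synthetic multi-week CGM subjects with controllable glucose variability.

A transparent kernel-sum generator (not a physiologic ODE model): glucose
is a circadian baseline plus additive meal-excursion kernels, subtractive
insulin-action kernels, an AR(1) sensor-noise process and optional
persistent regime (mean) shifts, sampled on the 5-minute grid, clipped to
the physiologic range [40, 400] mg/dL, and punctured by a missing-data gap
process.  Meals follow a regular daily schedule with small time/size
jitter, emulating a subject with a stable routine; insulin boluses are
dosed from carbohydrates by a fixed carb ratio.  The interday coefficient
of variation is controllable by a one-dimensional calibration search on
the stochastic amplitude.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import SLOTS_PER_DAY, STEP_MINUTES, EventSeries, GlucoseTrace, SubjectRecord
from .gv import CV_THRESHOLD

PHYSIOLOGIC_RANGE = (40.0, 400.0)


@dataclass(frozen=True)
class MealModel:
    """Daily meal schedule and glucose-excursion kernel."""

    times_minutes: tuple = (8 * 60, 13 * 60, 19 * 60)  # 08:00, 13:00, 19:00
    carbs_g: tuple = (45.0, 60.0, 70.0)
    time_jitter_min: float = 15.0
    size_jitter_frac: float = 0.10
    peak_per_gram: float = 2.6    # mg/dL rise per gram at the kernel peak
    rise_tau_min: float = 25.0
    decay_tau_min: float = 70.0
    kernel_span_min: float = 360.0


@dataclass(frozen=True)
class InsulinModel:
    """Bolus dosing from carbs and the insulin-action kernel."""

    carb_ratio_g_per_u: float = 12.0
    drop_per_unit: float = 12.0   # mg/dL drop per unit at the action peak
    rise_tau_min: float = 40.0
    decay_tau_min: float = 180.0
    kernel_span_min: float = 480.0
    basal_rate_uh: float = 0.9


@dataclass(frozen=True)
class GapModel:
    """Missing-run (sensor dropout) process."""

    rate_per_day: float = 0.5
    mean_slots: float = 3.0  # geometric; some runs exceed 6 slots (long gaps)


@dataclass(frozen=True)
class SimConfig:
    n_days: int = 70
    baseline_mean: float = 130.0
    circadian_amplitude: float = 28.0
    meal: MealModel = field(default_factory=MealModel)
    insulin: InsulinModel = field(default_factory=InsulinModel)
    noise_phi: float = 0.6        # AR(1) coefficient of sensor noise
    noise_sd: float = 9.0         # innovation SD, mg/dL
    target_cv: float | None = None  # desired interday CV %, calibrated if set
    gap: GapModel = field(default_factory=GapModel)
    regime_shifts: tuple = ()     # ((week_index, shift_mgdl), ...), persistent
    start_time: str = "2021-01-04T00:00:00"
    subject_id: str = "sim"
    seed: int = 0


def _kernel(tau_rise: float, tau_decay: float, span_min: float) -> np.ndarray:
    """Difference-of-exponentials kernel on the 5-min grid, peak scaled to 1."""
    t = np.arange(0, span_min, STEP_MINUTES, dtype=float)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = k.max()
    return k / peak if peak > 0 else k


def _generate(config: SimConfig, scale: float) -> tuple[np.ndarray, EventSeries]:
    """One deterministic draw of (glucose values, events) at a given
    stochastic amplitude ``scale`` (multiplies circadian, excursions, noise)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_days * SLOTS_PER_DAY
    tod_min = (np.arange(n) % SLOTS_PER_DAY) * STEP_MINUTES

    signal = np.zeros(n)
    # circadian rhythm: dawn trough, evening crest
    signal += config.circadian_amplitude * np.sin(
        2 * np.pi * (tod_min - 10 * 60) / (24 * 60)
    )

    meal_k = _kernel(config.meal.rise_tau_min, config.meal.decay_tau_min,
                     config.meal.kernel_span_min)
    ins_k = _kernel(config.insulin.rise_tau_min, config.insulin.decay_tau_min,
                    config.insulin.kernel_span_min)

    bolus = np.zeros(n)
    carbs = np.zeros(n)
    for day in range(config.n_days):
        for t_sched, grams0 in zip(config.meal.times_minutes, config.meal.carbs_g):
            jitter = rng.uniform(-config.meal.time_jitter_min, config.meal.time_jitter_min)
            grams = grams0 * (1.0 + config.meal.size_jitter_frac * rng.standard_normal())
            grams = max(grams, 5.0)
            slot = day * SLOTS_PER_DAY + int(round((t_sched + jitter) / STEP_MINUTES))
            if not 0 <= slot < n:
                continue
            hi = min(n, slot + meal_k.size)
            signal[slot:hi] += grams * config.meal.peak_per_gram * meal_k[: hi - slot]
            units = grams / config.insulin.carb_ratio_g_per_u
            hi = min(n, slot + ins_k.size)
            signal[slot:hi] -= units * config.insulin.drop_per_unit * ins_k[: hi - slot]
            carbs[slot] += grams
            bolus[slot] += units

    # AR(1) sensor noise
    noise = np.zeros(n)
    innov = rng.normal(0.0, config.noise_sd, size=n)
    for t in range(1, n):
        noise[t] = config.noise_phi * noise[t - 1] + innov[t]
    signal += noise

    values = config.baseline_mean + scale * signal

    for week, shift in config.regime_shifts:
        values[int(week) * 7 * SLOTS_PER_DAY:] += float(shift)

    values = np.clip(values, *PHYSIOLOGIC_RANGE)

    # sensor dropout gaps
    n_gaps = rng.poisson(config.gap.rate_per_day * config.n_days)
    p = min(1.0, 1.0 / config.gap.mean_slots)
    for _ in range(n_gaps):
        start = rng.integers(0, n)
        length = rng.geometric(p)
        values[start:start + length] = np.nan

    events = EventSeries(
        basal=np.full(n, config.insulin.basal_rate_uh), bolus=bolus, carbs=carbs
    )
    return values, events


def _measured_cv(values: np.ndarray) -> float:
    g = values[~np.isnan(values)]
    return 100.0 * float(np.std(g, ddof=1) / np.mean(g))


def simulate_subject(config: SimConfig) -> SubjectRecord:
    """Generate one subject.

    With ``target_cv`` set, a bisection search (max 20 iterations) on the
    stochastic amplitude matches the measured interday CV to the target
    within 2 percentage points; failure raises with the achieved CV.
    """
    if config.n_days < 1:
        raise ValueError("n_days must be >= 1")
    scale = 1.0
    if config.target_cv is not None:
        lo, hi = 0.02, 12.0
        achieved = None
        for _ in range(20):
            scale = 0.5 * (lo + hi)
            values, _ev = _generate(config, scale)
            achieved = _measured_cv(values)
            if abs(achieved - config.target_cv) < 0.5:
                break
            if achieved < config.target_cv:
                lo = scale
            else:
                hi = scale
        if achieved is None or abs(achieved - config.target_cv) > 2.0:
            raise ValueError(
                f"CV calibration failed: target {config.target_cv}%, "
                f"achieved {achieved:.2f}%"
            )
    values, events = _generate(config, scale)
    trace = GlucoseTrace(
        subject_id=config.subject_id,
        start_time=pd.Timestamp(config.start_time),
        values=values,
    )
    return SubjectRecord(trace=trace, events=events,
                         meta={"sim_scale": scale, "seed": config.seed})


def simulate_cohort(
    n_subjects: int,
    high_gv_fraction: float,
    base_config: SimConfig | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Cohort with a controlled high/low GV mixture at the 36% CV threshold.

    High-GV subjects get target CVs in [40, 48]%, low-GV in [24, 32]%;
    per-subject seeds derive deterministically from the cohort seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 <= high_gv_fraction <= 1.0:
        raise ValueError("high_gv_fraction must be in [0, 1]")
    base = base_config or SimConfig()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n_subjects)
    n_high = int(round(high_gv_fraction * n_subjects))
    records = []
    for k in range(n_subjects):
        high = k < n_high
        target = rng.uniform(40.0, 48.0) if high else rng.uniform(24.0, 32.0)
        cfg = replace(
            base,
            target_cv=float(target),
            seed=int(child_seeds[k]),
            subject_id=f"{base.subject_id}-{k:03d}",
        )
        records.append(simulate_subject(cfg))
    return records
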