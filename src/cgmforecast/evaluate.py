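"""Clinical evaluation of glucose forecasts.

RMSE is scored at the prediction horizon: for each forecast origin the
model's final output step (the 30- or 60-minute-ahead value) is compared
against the measured glucose.  Clarke error-grid analysis maps each
(reference, predicted) pair into clinical-risk zones A-E; zones A and B
are considered clinically safe.  Postprandial accuracy restricts RMSE to
the two hours following self-reported meals, where excursions make
forecasting hardest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PredictionSet:
    """Paired reference/predicted glucose at one horizon."""

    reference: np.ndarray       # measured glucose, mg/dL (never imputed)
    predicted: np.ndarray       # model output at the horizon, mg/dL
    origin_times: pd.DatetimeIndex
    horizon_minutes: int

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.reference.shape != self.predicted.shape:
            raise ValueError("reference/predicted length mismatch")

    @property
    def n(self) -> int:
        return self.reference.size


@dataclass
class EGAResult:
    zone_fractions: dict  # {"A": %, ..., "E": %}
    n_points: int

    @property
    def ab_percent(self) -> float:
        return self.zone_fractions["A"] + self.zone_fractions["B"]


def rmse(reference, predicted) -> float:
    """Root mean squared error, mg/dL."""
    reference = np.asarray(reference, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if reference.size == 0:
        raise ValueError("RMSE of an empty set is undefined")
    return float(np.sqrt(np.mean((reference - predicted) ** 2)))


def rmse_pairs(pairs: PredictionSet) -> float:
    return rmse(pairs.reference, pairs.predicted)


def clarke_zones(reference, predicted) -> np.ndarray:
    """Clarke error-grid zone ('A'..'E') for each pair.

    Implements the original error-grid boundary inequalities; the ordered
    evaluation assigns boundary points to the safer zone, and every
    admissible pair lands in exactly one zone.
    """
    r = np.asarray(reference, dtype=float)
    p = np.asarray(predicted, dtype=float)
    zone_a = (np.abs(p - r) <= 0.2 * r) | ((r < 70) & (p < 70))
    zone_e = ((r >= 180) & (p <= 70)) | ((r <= 70) & (p >= 180))
    zone_c = (((r >= 70) & (r <= 290)) & (p >= r + 110)) | (
        ((r >= 130) & (r <= 180)) & (p <= (7.0 / 5.0) * r - 182)
    )
    zone_d = ((r >= 240) & (p >= 70) & (p <= 180)) | (
        (r <= 175.0 / 3.0) & (p >= 70) & (p <= 180)
    ) | (((r >= 175.0 / 3.0) & (r < 70)) & (p >= (6.0 / 5.0) * r))
    return np.select([zone_a, zone_e, zone_c, zone_d], ["A", "E", "C", "D"], default="B")


def clarke_ega(pairs: PredictionSet) -> EGAResult:
    """Clarke error-grid analysis: fraction of pairs per zone (percent).

    Reference values must lie in (0, 600] mg/dL (they are measured CGM
    readings).  Predicted values outside that range are clipped to the
    grid boundary: the zones extend to the edges of the grid, so an absurd
    prediction lands in whatever (dangerous) zone owns that edge.
    """
    r, p = pairs.reference, pairs.predicted
    if r.size == 0:
        raise ValueError("EGA of an empty set is undefined")
    if (r <= 0).any() or (r > 600).any():
        raise ValueError("reference glucose must lie in (0, 600] mg/dL")
    p = np.clip(p, 1.0, 600.0)
    zones = clarke_zones(r, p)
    fractions = {z: 100.0 * float(np.mean(zones == z)) for z in "ABCDE"}
    return EGAResult(zone_fractions=fractions, n_points=r.size)


def postprandial_rmse(
    pairs: PredictionSet, meal_times, window_minutes: int = 120
) -> float:
    """RMSE restricted to the two hours following self-reported meals.

    A pair participates if its forecast origin falls in
    (meal_start, meal_start + window] for *any* meal; overlapping meal
    windows are a union, so no pair is double-counted.
    """
    meal_times = pd.DatetimeIndex(meal_times)
    if len(meal_times) == 0:
        raise ValueError("no meal times given")
    origins = pairs.origin_times
    mask = np.zeros(pairs.n, dtype=bool)
    for m in meal_times:
        dt = (origins - m).total_seconds() / 60.0
        mask |= (dt > 0) & (dt <= window_minutes)
    if not mask.any():
        raise ValueError("no forecast origins fall inside any meal window")
    return rmse(pairs.reference[mask], pairs.predicted[mask])


def compare_methods(rmse_a, rmse_b) -> tuple[float, float]:
    """Paired t-test between two methods' per-subject (or per-replicate) RMSEs.

    Returns (p_value, mean difference a - b).  Identical lists give
    (1.0, 0.0) by convention (zero variance).
    """
    a = np.asarray(rmse_a, dtype=float)
    b = np.asarray(rmse_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if a.size < 2:
        raise ValueError("need at least two paired values")
    diff = a - b
    mean_diff = float(np.mean(diff))
    if np.allclose(diff, diff[0]):
        if diff[0] == 0:
            return 1.0, 0.0
        return 0.0, mean_diff
    t = stats.ttest_rel(a, b)
    return float(t.pvalue), mean_diff


def plot_ega(pairs: PredictionSet, ax=None):
    """Clarke error-grid scatter (optional utility; needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 5))
    zones = clarke_zones(pairs.reference, np.clip(pairs.predicted, 1, 600))
    colors = {"A": "tab:green", "B": "tab:olive", "C": "tab:orange",
              "D": "tab:red", "E": "darkred"}
    for z in "ABCDE":
        m = zones == z
        if m.any():
            ax.scatter(pairs.reference[m], pairs.predicted[m], s=4,
                       c=colors[z], label=f"zone {z}")
    ax.plot([0, 400], [0, 400], "k--", lw=0.8)
    ax.set_xlim(0, 400)
    ax.set_ylim(0, 400)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("predicted glucose (mg/dL)")
    ax.legend(fontsize=8)
    return ax


def plot_rmse_density(per_subject_rmse, label=None, ax=None):
    """Probability density of per-subject RMSE (optional utility)."""
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    if ax is None:
        _fig, ax = plt.subplots()
    values = np.asarray(per_subject_rmse, dtype=float)
    grid = np.linspace(values.min() - 2, values.max() + 2, 200)
    ax.plot(grid, gaussian_kde(values)(grid), label=label)
    ax.set_xlabel("RMSE (mg/dL)")
    ax.set_ylabel("density")
    if label:
        ax.legend()
    return ax


def evaluation_report(pairs: PredictionSet, meal_times=None) -> dict:
    """Bundle RMSE, EGA fractions and (if meals known) postprandial RMSE."""
    report = {
        "n_pairs": int(pairs.n),
        "horizon_minutes": pairs.horizon_minutes,
        "rmse_mgdl": rmse_pairs(pairs),
        "ega_zone_percent": clarke_ega(pairs).zone_fractions,
    }
    if meal_times is not None and len(meal_times) > 0:
        try:
            report["postprandial_rmse_mgdl"] = postprandial_rmse(pairs, meal_times)
        except ValueError:
            report["postprandial_rmse_mgdl"] = None
    return report
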