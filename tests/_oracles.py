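"""Independent brute-force re-implementations used as test oracles.

Deliberately written with plain Python loops and no shared code with the
package, so agreement is a genuine cross-check rather than a tautology.
"""

import math

import numpy as np


def gv_metrics_bruteforce(values, day_indices):
    """All 8 glucose-variability metrics, loop-by-loop."""
    g = [float(v) for v in values if not math.isnan(v)]
    n = len(g)
    mean = sum(g) / n
    var = sum((x - mean) ** 2 for x in g) / (n - 1) if n > 1 else 0.0
    sd = math.sqrt(var)
    cv = 100.0 * sd / mean

    days = [d for v, d in zip(values, day_indices) if not math.isnan(v)]
    per_day_cv = []
    for d in sorted(set(days)):
        gd = [x for x, dd in zip(g, days) if dd == d]
        if len(gd) >= 2:
            m = sum(gd) / len(gd)
            s = math.sqrt(sum((x - m) ** 2 for x in gd) / (len(gd) - 1))
            per_day_cv.append(100.0 * s / m)
    intraday = sum(per_day_cv) / len(per_day_cv) if per_day_cv else 0.0

    tir = 100.0 * sum(1 for x in g if 70.0 <= x <= 180.0) / n
    j_index = 0.001 * (mean + sd) ** 2
    gmi = 3.31 + 0.02392 * mean

    lbgi_sum = 0.0
    hbgi_sum = 0.0
    for x in g:
        f = 1.509 * (math.log(x) ** 1.084 - 5.381)
        if f < 0:
            lbgi_sum += 10.0 * f * f
        elif f > 0:
            hbgi_sum += 10.0 * f * f
    return {
        "interday_sd": sd,
        "interday_cv": cv,
        "mean_intraday_cv": intraday,
        "tir_percent": tir,
        "j_index": j_index,
        "gmi": gmi,
        "lbgi": lbgi_sum / n,
        "hbgi": hbgi_sum / n,
    }


def count_windows_bruteforce(segment_length, history=24, horizon=6):
    """Exhaustively enumerate valid window start positions."""
    count = 0
    for s in range(segment_length):
        if s + history + horizon <= segment_length:
            count += 1
    return count


def risk_transform_root():
    """Numerically locate the glucose value where the Kovatchev transform is 0."""
    lo, hi = 50.0, 300.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = 1.509 * (math.log(mid) ** 1.084 - 5.381)
        if f < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def postprandial_mask_bruteforce(origin_times, meal_times, window_minutes=120):
    """Union-of-windows membership computed pair by pair."""
    mask = []
    for t in origin_times:
        inside = False
        for m in meal_times:
            dt = (t - m).total_seconds() / 60.0
            if 0 < dt <= window_minutes:
                inside = True
        mask.append(inside)
    return np.array(mask)
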