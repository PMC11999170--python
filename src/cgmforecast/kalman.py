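"""Kalman smoothing of training-split glucose values.

CGM readings carry sensor noise; smoothing the *training* data (never the
validation or test data) with a linear-Gaussian state-space filter gives
the recurrent network a cleaner target signal.  Two state models are
offered: a local level (random walk) and a local trend (constant-velocity)
model.  The filter runs forward (causal) by default; an optional
Rauch-Tung-Striebel backward pass is available since the transform is
confined to training data where lookahead is admissible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import OBSERVED, SMOOTHED, GlucoseTrace


@dataclass
class KalmanConfig:
    """Filter settings.

    ``process_noise_var`` is the random-acceleration (local-trend) or
    level-innovation (local-level) variance in (mg/dL)^2 per 5-min step;
    ``measurement_noise_var`` is the CGM sensor error variance, default
    100 (mg/dL)^2, i.e. a 10 mg/dL sensor SD.
    """

    state_model: str = "local-trend"  # or "local-level"
    process_noise_var: float = 1.0
    measurement_noise_var: float = 100.0
    initial_state_var: float = 1e4
    use_rts: bool = False

    def __post_init__(self):
        if self.state_model not in ("local-trend", "local-level"):
            raise ValueError(f"unknown state model {self.state_model!r}")
        for name in ("process_noise_var", "measurement_noise_var", "initial_state_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def matrices(self):
        q, r = self.process_noise_var, self.measurement_noise_var
        if self.state_model == "local-level":
            F = np.array([[1.0]])
            Q = np.array([[q]])
            H = np.array([[1.0]])
        else:
            F = np.array([[1.0, 1.0], [0.0, 1.0]])
            # discrete white-noise acceleration with unit step
            Q = q * np.array([[0.25, 0.5], [0.5, 1.0]])
            H = np.array([[1.0, 0.0]])
        return F, Q, H, np.array([[r]])


def _filter_segment(y: np.ndarray, config: KalmanConfig) -> np.ndarray:
    """Predict/update recursion on one contiguous segment.

    ``y`` may contain NaN (short interior gaps): those steps are
    prediction-only and the output stays NaN there.
    """
    F, Q, H, R = config.matrices()
    dim = F.shape[0]
    first = int(np.nonzero(~np.isnan(y))[0][0])
    x = np.zeros((dim, 1))
    x[0, 0] = y[first]
    P = np.eye(dim) * config.initial_state_var

    n = y.size
    out = np.full(n, np.nan)
    if config.use_rts:
        xs_pred = np.zeros((n, dim, 1))
        Ps_pred = np.zeros((n, dim, dim))
        xs_filt = np.zeros((n, dim, 1))
        Ps_filt = np.zeros((n, dim, dim))

    for t in range(n):
        if t > first:
            x = F @ x
            P = F @ P @ F.T + Q
        if config.use_rts:
            xs_pred[t], Ps_pred[t] = x, P
        if not np.isnan(y[t]):
            innov = y[t] - (H @ x)[0, 0]
            S = (H @ P @ H.T + R)[0, 0]
            K = (P @ H.T) / S
            x = x + K * innov
            P = (np.eye(dim) - K @ H) @ P
            out[t] = x[0, 0]
        if config.use_rts:
            xs_filt[t], Ps_filt[t] = x, P

    if config.use_rts:
        xs = xs_filt.copy()
        Ps = Ps_filt.copy()
        for t in range(n - 2, first - 1, -1):
            G = Ps_filt[t] @ F.T @ np.linalg.pinv(Ps_pred[t + 1])
            xs[t] = xs_filt[t] + G @ (xs[t + 1] - xs_pred[t + 1])
            Ps[t] = Ps_filt[t] + G @ (Ps[t + 1] - Ps_pred[t + 1]) @ G.T
        for t in range(n):
            if not np.isnan(y[t]):
                out[t] = xs[t][0, 0]
    return out


def smooth(trace: GlucoseTrace, config: KalmanConfig | None = None) -> GlucoseTrace:
    """Smooth a cleaned/interpolated trace, per contiguous segment.

    Gaps of >= 30 minutes reset the filter state (segments are independent).
    Output grid, length and missing pattern are identical to the input.
    Slots previously flagged ``observed`` become ``smoothed``; imputed
    slots keep their provenance flag even though their values pass through
    the filter.  Segments shorter than 2 samples are returned unchanged.
    """
    config = config or KalmanConfig()
    out = trace.copy()
    for lo, hi in trace.segments():
        y = trace.values[lo:hi]
        if np.count_nonzero(~np.isnan(y)) < 2:
            continue
        smoothed = _filter_segment(y, config)
        keep = ~np.isnan(smoothed)
        out.values[lo:hi][keep] = smoothed[keep]
        seg_flags = out.flags[lo:hi]
        seg_flags[keep & (seg_flags == OBSERVED)] = SMOOTHED
        out.flags[lo:hi] = seg_flags
    return out
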