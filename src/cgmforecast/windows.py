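"""Supervised window construction and the chronological subset plan.

Forecasting is framed as sequence-to-sequence supervision: a 2-hour
history (24 five-minute steps, univariate glucose or glucose + insulin +
carb channels) predicts the next h glucose values (h=6 for a 30-minute
horizon, h=12 for 60 minutes).  Windows slide with a configurable stride
and never cross a gap of >= 30 minutes; target values are never imputed.

For incremental training a subject's span is partitioned chronologically
into an initial block of ``i`` days followed by 7-day blocks; the first
70% of blocks form the train/validation stream and the rest are held out
as the test period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    EXTRAPOLATED,
    INTERPOLATED,
    EligibilityError,
    EventSeries,
    GlucoseTrace,
    SubjectRecord,
)

HISTORY_STEPS = 24  # 2 hours on the 5-minute grid


@dataclass
class WindowSet:
    """Stacked supervised samples: ``X`` (n, 24, C), ``y`` (n, h)."""

    X: np.ndarray
    y: np.ndarray
    origin_idx: np.ndarray          # grid slot of the last history sample
    origin_times: pd.DatetimeIndex  # timestamp of that slot
    ph_minutes: int

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def horizon_steps(self) -> int:
        return self.y.shape[1]

    def subsample(self, idx) -> "WindowSet":
        return WindowSet(
            self.X[idx], self.y[idx], self.origin_idx[idx],
            self.origin_times[idx], self.ph_minutes,
        )

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if s.n > 0]
        if not sets:
            raise ValueError("no non-empty window sets to concatenate")
        return WindowSet(
            np.concatenate([s.X for s in sets]),
            np.concatenate([s.y for s in sets]),
            np.concatenate([s.origin_idx for s in sets]),
            sets[0].origin_times.append([s.origin_times for s in sets[1:]]),
            sets[0].ph_minutes,
        )


def make_windows(
    trace: GlucoseTrace,
    events: EventSeries | None = None,
    ph_minutes: int = 30,
    multivariate: bool = False,
    stride: int = 1,
) -> WindowSet:
    """Slide supervised windows over a (pre-processed) trace.

    Windows require every history and target slot to be non-missing within
    one segment (no window spans a >= 30-min gap), and every *target* slot
    to be a measured value (observed or smoothed), never an interpolated or
    extrapolated fill.  With ``multivariate`` the channels are ordered
    (glucose, basal, bolus, carbs).
    """
    if ph_minutes % trace.step_minutes:
        raise ValueError("prediction horizon must be a multiple of the grid step")
    h = ph_minutes // trace.step_minutes
    if multivariate and events is None:
        raise ValueError("multivariate windows need an EventSeries")

    window = HISTORY_STEPS + h
    Xs, ys, origins = [], [], []
    values = trace.values
    imputed_target = np.isin(trace.flags, (INTERPOLATED, EXTRAPOLATED))
    missing = trace.missing
    for lo, hi in trace.segments():
        if hi - lo < window:
            continue
        for s in range(lo, hi - window + 1, stride):
            hist = slice(s, s + HISTORY_STEPS)
            targ = slice(s + HISTORY_STEPS, s + window)
            if missing[hist].any() or missing[targ].any():
                continue
            if imputed_target[targ].any():
                continue
            if multivariate:
                x = np.stack(
                    [values[hist], events.basal[hist], events.bolus[hist], events.carbs[hist]],
                    axis=-1,
                )
            else:
                x = values[hist][:, None]
            Xs.append(x)
            ys.append(values[targ])
            origins.append(s + HISTORY_STEPS - 1)

    C = 4 if multivariate else 1
    if not Xs:
        return WindowSet(
            np.empty((0, HISTORY_STEPS, C)), np.empty((0, h)),
            np.empty(0, dtype=int), pd.DatetimeIndex([]), ph_minutes,
        )
    origin_idx = np.asarray(origins)
    return WindowSet(
        np.stack(Xs), np.stack(ys), origin_idx, trace.times[origin_idx], ph_minutes
    )


# ---------------------------------------------------------------------------
# chronological subset plan
# ---------------------------------------------------------------------------

@dataclass
class Block:
    index: int
    start_day: int  # inclusive, relative to the trace's first calendar day
    end_day: int    # exclusive
    role: str       # "train" | "test"

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day


@dataclass
class SubsetPlan:
    initial_days: int
    blocks: list[Block] = field(default_factory=list)
    test_fraction: float = 0.30

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def train_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.role == "train"]

    @property
    def test_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.role == "test"]

    def validation_day(self, block: Block) -> tuple[int, int]:
        """First calendar day of the subsequent block, as [day, day+1)."""
        nxt = self.blocks[block.index + 1]
        return nxt.start_day, nxt.start_day + 1

    def to_json(self, path=None) -> str:
        payload = {
            "initial_days": self.initial_days,
            "test_fraction": self.test_fraction,
            "blocks": [vars(b) for b in self.blocks],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(text_or_path) -> "SubsetPlan":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        plan = SubsetPlan(payload["initial_days"], test_fraction=payload["test_fraction"])
        plan.blocks = [Block(**b) for b in payload["blocks"]]
        return plan


def make_subset_plan(
    record: SubjectRecord,
    initial_days: int,
    test_fraction: float = 0.30,
    block_days: int = 7,
    min_total_days: int = 50,
) -> SubsetPlan:
    """Partition the subject's day span into the incremental-training blocks.

    The first block holds ``initial_days`` days, the rest 7 days each; a
    trailing remainder shorter than 7 days merges into the final block.
    The first floor(70%) of blocks are the train/validation stream, the
    remaining blocks the held-out test period.  Subjects with fewer than
    ``min_total_days`` days of data are ineligible.
    """
    if record.total_days < min_total_days:
        raise EligibilityError(
            f"{record.trace.subject_id}: {record.total_days} days < {min_total_days}"
        )
    span_days = int(record.trace.day_index()[-1]) + 1

    bounds = [0, initial_days]
    while bounds[-1] + block_days <= span_days:
        bounds.append(bounds[-1] + block_days)
    if bounds[-1] < span_days:
        if len(bounds) > 2:
            bounds[-1] = span_days  # merge short remainder into final block
        else:
            bounds.append(span_days)

    n_blocks = len(bounds) - 1
    n_train = int(np.floor((1.0 - test_fraction) * n_blocks))
    n_train = max(1, min(n_train, n_blocks - 1))
    plan = SubsetPlan(initial_days=initial_days, test_fraction=test_fraction)
    for k in range(n_blocks):
        role = "train" if k < n_train else "test"
        plan.blocks.append(Block(index=k, start_day=bounds[k], end_day=bounds[k + 1], role=role))
    return plan


def block_windows(
    trace: GlucoseTrace,
    block_or_days,
    events: EventSeries | None = None,
    **kwargs,
) -> WindowSet:
    """Windows fully contained in a block's (or day range's) slot span."""
    if isinstance(block_or_days, Block):
        day_lo, day_hi = block_or_days.start_day, block_or_days.end_day
    else:
        day_lo, day_hi = block_or_days
    lo, hi = trace.day_slot_bounds(day_lo, day_hi)
    sub_trace = trace.slice(lo, hi)
    sub_events = events.slice(lo, hi) if events is not None else None
    ws = make_windows(sub_trace, sub_events, **kwargs)
    ws.origin_idx = ws.origin_idx + lo  # back to absolute grid slots
    return ws
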