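"""Core time-series containers and subject I/O.

Everything downstream operates on a :class:`GlucoseTrace`: a regularly
gridded (5-minute) glucose series in mg/dL with an explicit missing marker
(NaN) and a per-sample provenance flag.  Raw CGM exports are snapped onto
the grid, cleaned of biologically implausible readings, and short sensor
dropouts are filled by linear interpolation (training data) or first-order
extrapolation (test data, which must never look into the future).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: provenance flag codes
OBSERVED = 0
INTERPOLATED = 1
EXTRAPOLATED = 2
SMOOTHED = 3

FLAG_NAMES = {
    OBSERVED: "observed",
    INTERPOLATED: "interpolated",
    EXTRAPOLATED: "extrapolated",
    SMOOTHED: "smoothed",
}

#: grid resolution of CGM sampling
STEP_MINUTES = 5
#: a run of >= this many consecutive missing slots (>= 30 min) is a "long
#: gap": it is never imputed and splits the trace into separate segments
LONG_GAP_SLOTS = 6
#: readings at or below this (mg/dL) are biologically implausible
IMPLAUSIBLE_MGDL = 15.0
#: slots per calendar day on the 5-minute grid
SLOTS_PER_DAY = 24 * 60 // STEP_MINUTES

#: canonical CSV column names
CANONICAL_COLUMNS = (
    "timestamp",
    "glucose_mgdl",
    "basal_uh",
    "bolus_u",
    "bolus_duration_min",
    "carbs_g",
)


class SchemaError(ValueError):
    """Malformed input file or column-mapping configuration."""


class EmptyInputError(ValueError):
    """No usable glucose values in the input."""


class InsufficientHistoryError(ValueError):
    """Too few observed samples to extrapolate from."""


class EligibilityError(ValueError):
    """Subject does not have enough days of data for incremental training."""


@dataclass
class GlucoseTrace:
    """Regularly gridded glucose series with provenance flags.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    start_time : pandas.Timestamp
        Timestamp of the first grid slot.
    values : ndarray of float
        Glucose in mg/dL, one entry per grid slot; NaN marks missing.
    flags : ndarray of uint8
        Per-slot provenance flag (``OBSERVED``/``INTERPOLATED``/...).
    step_minutes : int
        Grid resolution, 5 minutes for CGM data.
    """

    subject_id: str
    start_time: pd.Timestamp
    values: np.ndarray
    flags: np.ndarray = None
    step_minutes: int = STEP_MINUTES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.full(self.values.shape, OBSERVED, dtype=np.uint8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.uint8)
        if self.flags.shape != self.values.shape:
            raise ValueError("flags and values must have the same shape")
        self.start_time = pd.Timestamp(self.start_time)

    # -- basic structure ---------------------------------------------------
    @property
    def n_slots(self) -> int:
        return self.values.size

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(self.n_slots) * self.step_minutes, unit="m"
        )

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def observed_values(self) -> np.ndarray:
        """Non-missing values carrying the ``observed`` flag (never imputed)."""
        mask = ~self.missing & (self.flags == OBSERVED)
        return self.values[mask]

    def copy(self) -> "GlucoseTrace":
        return GlucoseTrace(
            self.subject_id,
            self.start_time,
            self.values.copy(),
            self.flags.copy(),
            self.step_minutes,
        )

    def slice(self, lo: int, hi: int) -> "GlucoseTrace":
        """Sub-trace over grid slots [lo, hi)."""
        lo = max(lo, 0)
        hi = min(hi, self.n_slots)
        return GlucoseTrace(
            self.subject_id,
            self.start_time + pd.Timedelta(minutes=lo * self.step_minutes),
            self.values[lo:hi].copy(),
            self.flags[lo:hi].copy(),
            self.step_minutes,
        )

    def day_index(self) -> np.ndarray:
        """Calendar-day index of each slot, day 0 = the start date."""
        t = self.times
        return ((t.normalize() - self.start_time.normalize()).days).to_numpy()

    def day_slot_bounds(self, day_lo: int, day_hi: int) -> tuple[int, int]:
        """Slot range [lo, hi) covering calendar days [day_lo, day_hi)."""
        d = self.day_index()
        inside = (d >= day_lo) & (d < day_hi)
        if not inside.any():
            return (0, 0)
        idx = np.nonzero(inside)[0]
        return int(idx[0]), int(idx[-1]) + 1

    def segments(self) -> list[tuple[int, int]]:
        """Maximal index ranges not containing a long (>= 30 min) gap.

        Short missing runs (< ``LONG_GAP_SLOTS``) stay inside a segment;
        runs of >= ``LONG_GAP_SLOTS`` consecutive missing slots separate
        segments and are excluded from them.
        """
        miss = self.missing
        n = miss.size
        segs: list[tuple[int, int]] = []
        i = 0
        seg_start = 0
        while i < n:
            if miss[i]:
                j = i
                while j < n and miss[j]:
                    j += 1
                if j - i >= LONG_GAP_SLOTS:
                    if i > seg_start:
                        segs.append((seg_start, i))
                    seg_start = j
                i = j
            else:
                i += 1
        if n > seg_start:
            segs.append((seg_start, n))
        return segs


@dataclass
class EventSeries:
    """Insulin and carbohydrate channels aligned to the glucose grid.

    ``basal`` is a forward-filled rate (U/h); ``bolus`` holds per-slot
    amounts (U) after spreading each dose over its duration; ``carbs`` holds
    grams at the meal's slot.  Slots with no record are exactly 0 for bolus
    and carbs.
    """

    basal: np.ndarray
    bolus: np.ndarray
    carbs: np.ndarray

    def __post_init__(self):
        self.basal = np.asarray(self.basal, dtype=float)
        self.bolus = np.asarray(self.bolus, dtype=float)
        self.carbs = np.asarray(self.carbs, dtype=float)
        if not (self.basal.shape == self.bolus.shape == self.carbs.shape):
            raise ValueError("event channels must share one grid")

    @property
    def n_slots(self) -> int:
        return self.basal.size

    def slice(self, lo: int, hi: int) -> "EventSeries":
        return EventSeries(
            self.basal[lo:hi].copy(), self.bolus[lo:hi].copy(), self.carbs[lo:hi].copy()
        )

    def copy(self) -> "EventSeries":
        return EventSeries(self.basal.copy(), self.bolus.copy(), self.carbs.copy())

    def meal_times(self, times: pd.DatetimeIndex) -> pd.DatetimeIndex:
        """Timestamps of slots with recorded carbohydrate intake."""
        return times[self.carbs > 0]


@dataclass
class SubjectRecord:
    """One subject's gridded glucose trace plus optional event channels."""

    trace: GlucoseTrace
    events: EventSeries | None = None
    meta: dict = field(default_factory=dict)

    @property
    def total_days(self) -> int:
        """Number of calendar days with at least one non-missing sample."""
        ok = ~self.trace.missing
        if not ok.any():
            return 0
        return int(np.unique(self.trace.day_index()[ok]).size)

    @property
    def multivariate_capable(self) -> bool:
        return self.events is not None


# ---------------------------------------------------------------------------
# cleaning and imputation
# ---------------------------------------------------------------------------

def exclude_implausible(trace: GlucoseTrace, threshold: float = IMPLAUSIBLE_MGDL) -> GlucoseTrace:
    """Remove (set missing) glucose readings at or below ``threshold`` mg/dL."""
    out = trace.copy()
    bad = ~out.missing & (out.values <= threshold)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning(
            "%s: excluded %d implausible reading(s) <= %g mg/dL",
            trace.subject_id, n_bad, threshold,
        )
        out.values[bad] = np.nan
        out.flags[bad] = OBSERVED
    return out


def interpolate_training_gaps(trace: GlucoseTrace) -> GlucoseTrace:
    """Fill interior gaps shorter than 30 minutes by linear interpolation.

    A gap of 1-5 consecutive missing slots flanked by observed values on
    both sides is filled on the line between the flanking values; the fills
    are flagged ``interpolated``.  Gaps of >= 6 slots (>= 30 minutes) and
    leading/trailing missing runs are left untouched.  Idempotent.
    """
    out = trace.copy()
    miss = out.missing
    n = miss.size
    i = 0
    while i < n:
        if not miss[i]:
            i += 1
            continue
        j = i
        while j < n and miss[j]:
            j += 1
        gap_len = j - i
        has_left = i > 0 and not np.isnan(out.values[i - 1])
        has_right = j < n and not np.isnan(out.values[j])
        if gap_len < LONG_GAP_SLOTS and has_left and has_right:
            x0, x1 = out.values[i - 1], out.values[j]
            # linear fill between the flanking samples on the 5-min grid
            frac = np.arange(1, gap_len + 1) / (gap_len + 1)
            out.values[i:j] = x0 + frac * (x1 - x0)
            out.flags[i:j] = INTERPOLATED
        i = j
    return out


def extrapolate_test_gap(history: GlucoseTrace | np.ndarray, n_slots: int) -> np.ndarray:
    """First-order extrapolation from the last two observed samples.

    Used on test data so no future values are ever consulted.  Returns
    ``n_slots`` values on the line through the two most recent non-missing
    samples of ``history`` (respecting their grid spacing).
    """
    values = history.values if isinstance(history, GlucoseTrace) else np.asarray(history, float)
    obs = np.nonzero(~np.isnan(values))[0]
    if obs.size < 2:
        raise InsufficientHistoryError(
            "first-order extrapolation needs at least two observed samples"
        )
    i1, i2 = obs[-2], obs[-1]
    slope = (values[i2] - values[i1]) / (i2 - i1)
    steps = np.arange(1, n_slots + 1)
    return values[i2] + slope * (values.size - 1 - i2 + steps) * 1.0


def fill_test_gaps(trace: GlucoseTrace) -> GlucoseTrace:
    """Fill short interior gaps causally by first-order extrapolation.

    Test-split counterpart of :func:`interpolate_training_gaps`: each gap of
    1-5 missing slots is filled on the line through the two observed samples
    immediately preceding it (never using future data); fills are flagged
    ``extrapolated``.  Long gaps remain missing.
    """
    out = trace.copy()
    miss = out.missing
    n = miss.size
    i = 0
    while i < n:
        if not miss[i]:
            i += 1
            continue
        j = i
        while j < n and miss[j]:
            j += 1
        gap_len = j - i
        if gap_len < LONG_GAP_SLOTS and i >= 2:
            left = out.values[:i]
            obs = np.nonzero(~np.isnan(left))[0]
            if obs.size >= 2:
                filled = extrapolate_test_gap(left, gap_len)
                out.values[i:j] = filled
                out.flags[i:j] = EXTRAPOLATED
        i = j
    return out


# ---------------------------------------------------------------------------
# event alignment
# ---------------------------------------------------------------------------

def _snap_slot(ts: pd.Timestamp, grid_start: pd.Timestamp, step_minutes: int) -> int:
    delta = (pd.Timestamp(ts) - grid_start).total_seconds() / 60.0
    return int(round(delta / step_minutes))


def align_events(
    basal_records=None,
    bolus_records=None,
    carb_records=None,
    *,
    grid_start: pd.Timestamp,
    n_slots: int,
    step_minutes: int = STEP_MINUTES,
) -> EventSeries:
    """Place raw basal/bolus/carb records onto the glucose grid.

    ``basal_records``: iterable of (timestamp, rate U/h); the rate is
    propagated forward until the next change.  ``bolus_records``: iterable
    of (timestamp, units) or (timestamp, units, duration_min); each dose is
    divided equally over its duration's grid slots (missing/zero duration
    puts the whole amount in one slot).  ``carb_records``: (timestamp,
    grams) placed at their slot.  Slots without records are exactly 0 for
    bolus and carbs.
    """
    basal = np.zeros(n_slots)
    bolus = np.zeros(n_slots)
    carbs = np.zeros(n_slots)
    grid_start = pd.Timestamp(grid_start)

    # basal: last-write-wins per slot, then carried forward
    if basal_records:
        changes: dict[int, float] = {}
        for ts, rate in basal_records:
            if rate < 0:
                raise ValueError(f"negative basal rate {rate} at {ts}")
            changes[_snap_slot(ts, grid_start, step_minutes)] = float(rate)
        current = 0.0
        change_slots = sorted(changes)
        ci = 0
        for s in range(n_slots):
            while ci < len(change_slots) and change_slots[ci] <= s:
                current = changes[change_slots[ci]]
                ci += 1
            basal[s] = current

    if bolus_records:
        for rec in bolus_records:
            ts, units = rec[0], float(rec[1])
            duration = float(rec[2]) if len(rec) > 2 and rec[2] is not None and not (
                isinstance(rec[2], float) and np.isnan(rec[2])
            ) else 0.0
            if units < 0:
                raise ValueError(f"negative bolus {units} at {ts}")
            s = _snap_slot(ts, grid_start, step_minutes)
            width = max(1, int(round(duration / step_minutes))) if duration > 0 else 1
            per_slot = units / width
            for k in range(width):
                idx = s + k
                if 0 <= idx < n_slots:
                    bolus[idx] += per_slot

    if carb_records:
        for ts, grams in carb_records:
            if grams < 0:
                raise ValueError(f"negative carbs {grams} at {ts}")
            s = _snap_slot(ts, grid_start, step_minutes)
            if 0 <= s < n_slots:
                carbs[s] += float(grams)

    return EventSeries(basal, bolus, carbs)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _load_schema(schema) -> dict:
    """Resolve a column-mapping config: dict, YAML/JSON path, or None."""
    if schema is None:
        return {c: c for c in CANONICAL_COLUMNS}
    if isinstance(schema, (str, Path)):
        text = Path(schema).read_text()
        schema = yaml.safe_load(text) if str(schema).endswith((".yml", ".yaml")) else json.loads(text)
    mapping = {c: c for c in CANONICAL_COLUMNS}
    mapping.update(schema)
    return mapping


def read_subject(path, schema=None, subject_id: str | None = None, clean: bool = True) -> SubjectRecord:
    """Read one subject's CSV into a grid-aligned :class:`SubjectRecord`.

    Raw timestamps are snapped to the nearest 5-minute slot (collisions
    resolved last-write-wins, with a warning); glucose readings <= 15 mg/dL
    are excluded as biologically implausible when ``clean`` is True.
    """
    path = Path(path)
    mapping = _load_schema(schema)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"cannot parse {path}: {exc}") from exc

    ts_col = mapping["timestamp"]
    glu_col = mapping["glucose_mgdl"]
    if ts_col not in df.columns or glu_col not in df.columns:
        raise SchemaError(
            f"{path}: required columns {ts_col!r}/{glu_col!r} not found "
            f"(have {list(df.columns)})"
        )
    try:
        ts = pd.to_datetime(df[ts_col])
    except Exception as exc:
        raise SchemaError(f"{path}: unparseable timestamps: {exc}") from exc
    glu = pd.to_numeric(df[glu_col], errors="coerce")
    if glu.notna().sum() == 0:
        raise EmptyInputError(f"{path}: glucose column {glu_col!r} is empty")

    # grid from the first timestamp, floored to a 5-minute boundary
    grid_start = ts.min().floor(f"{STEP_MINUTES}min")
    slots = ((ts - grid_start).dt.total_seconds() / 60.0 / STEP_MINUTES).round().astype(int)
    n_slots = int(slots.max()) + 1
    values = np.full(n_slots, np.nan)
    collisions = 0
    for s, v in zip(slots, glu):
        if np.isnan(v):
            continue
        if not np.isnan(values[s]):
            collisions += 1
        values[s] = v  # last write wins
    if collisions:
        logger.warning("%s: %d timestamp collision(s), kept last value", path, collisions)

    trace = GlucoseTrace(subject_id or path.stem, grid_start, values)
    if clean:
        trace = exclude_implausible(trace)

    events = None
    basal_col = mapping.get("basal_uh")
    bolus_col = mapping.get("bolus_u")
    dur_col = mapping.get("bolus_duration_min")
    carb_col = mapping.get("carbs_g")
    have_events = any(c in df.columns for c in (basal_col, bolus_col, carb_col))
    if have_events:
        basal_rec = []
        if basal_col in df.columns:
            sub = df[df[basal_col].notna()]
            basal_rec = list(zip(pd.to_datetime(sub[ts_col]), sub[basal_col].astype(float)))
        bolus_rec = []
        if bolus_col in df.columns:
            sub = df[df[bolus_col].notna()]
            durs = sub[dur_col] if dur_col in df.columns else pd.Series(np.nan, index=sub.index)
            bolus_rec = list(
                zip(pd.to_datetime(sub[ts_col]), sub[bolus_col].astype(float), durs)
            )
        carb_rec = []
        if carb_col in df.columns:
            sub = df[df[carb_col].notna()]
            carb_rec = list(zip(pd.to_datetime(sub[ts_col]), sub[carb_col].astype(float)))
        events = align_events(
            basal_rec, bolus_rec, carb_rec,
            grid_start=grid_start, n_slots=n_slots,
        )
    return SubjectRecord(trace=trace, events=events)


def write_subject(record: SubjectRecord, path) -> None:
    """Write a subject back to canonical-schema CSV (grid values verbatim)."""
    trace = record.trace
    df = pd.DataFrame({
        "timestamp": trace.times.strftime("%Y-%m-%dT%H:%M:%S"),
        "glucose_mgdl": [repr(float(v)) if not np.isnan(v) else "" for v in trace.values],
    })
    if record.events is not None:
        ev = record.events
        df["basal_uh"] = [repr(float(v)) for v in ev.basal]
        df["bolus_u"] = ["" if v == 0 else repr(float(v)) for v in ev.bolus]
        df["carbs_g"] = ["" if v == 0 else repr(float(v)) for v in ev.carbs]
    df.to_csv(path, index=False)


def check_eligibility(record: SubjectRecord, min_days: int = 50) -> None:
    """Raise unless the subject has enough days for incremental training."""
    if record.total_days < min_days:
        raise EligibilityError(
            f"{record.trace.subject_id}: {record.total_days} day(s) of data, "
            f"needs >= {min_days} for incremental training"
        )
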