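"""Incremental retraining with t-test-gated parameter transfer.

The central idea: rather than training a personal forecaster once on a
large historical record, the stacked LSTM is retrained block-by-block as a
subject's CGM stream accumulates.  Before retraining on a new block, the
glucose distributions of the current and previous blocks are compared by a
two-sample (Welch) t-test; if they do not differ significantly (p > 0.05)
the previous parameters are carried forward unchanged (parameter
transfer), skipping the retraining cost.  The first block always trains
from fresh initialization; every retraining warm-starts from the current
parameters.  Each stage is validated on the first day of the following
block, and the final model is scored on the held-out chronological test
period.

For subjects with no history (cold start), a pool of models pre-trained on
long donor records is screened on the subject's first day of data; the
best is then adapted with a 1-day update window for the first weeks before
switching to the weekly protocol.

The public surface follows the statsmodels convention: build an
:class:`IncrementalForecaster` from a :class:`~cgmforecast.data.SubjectRecord`,
call :meth:`fit`, and read estimates and diagnostics off the returned
:class:`IncrementalResults`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import evaluate
from .data import (
    EXTRAPOLATED,
    INTERPOLATED,
    GlucoseTrace,
    SubjectRecord,
    check_eligibility,
    exclude_implausible,
    fill_test_gaps,
    interpolate_training_gaps,
)
from .gv import GVProfile, compute_gv, recommend_initial_days
from .kalman import KalmanConfig, smooth
from .network import ArchitectureSpec, ForecastModel, TrainConfig, train_on_subset
from .windows import SubsetPlan, WindowSet, block_windows, make_subset_plan

logger = logging.getLogger(__name__)

SIGNIFICANCE = 0.05


def shift_test(current_block_values, previous_block_values) -> float:
    """Welch two-sample t-test p-value between two blocks' glucose values.

    Degenerate cases: both blocks constant with equal means -> p = 1 (no
    evidence of shift); constant with different means -> p = 0.
    """
    a = np.asarray(current_block_values, dtype=float)
    b = np.asarray(previous_block_values, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("shift test needs >= 2 non-missing values per block")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


@dataclass
class RetrainDecision:
    block_index: int
    p_value: float          # NaN for the first block (nothing to compare)
    action: str             # "retrain" | "skip"
    epochs_run: int
    validation_rmse: float  # mg/dL on the first day of the next block
    n_train_windows: int = 0
    reason: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class RetrainLog:
    decisions: list[RetrainDecision] = field(default_factory=list)

    @property
    def blocks_trained(self) -> int:
        return sum(1 for d in self.decisions if d.action == "retrain")

    @property
    def blocks_skipped(self) -> int:
        return sum(1 for d in self.decisions if d.action == "skip")

    @property
    def total_epochs(self) -> int:
        return sum(d.epochs_run for d in self.decisions)

    @property
    def skip_fraction(self) -> float:
        """Fraction of gated blocks (all but the first) that were skipped."""
        gated = [d for d in self.decisions if not np.isnan(d.p_value)]
        return sum(d.action == "skip" for d in gated) / len(gated) if gated else 0.0

    def validation_rmse_curve(self) -> list[float]:
        return [d.validation_rmse for d in self.decisions]

    def to_jsonl(self, path=None) -> str:
        lines = "\n".join(json.dumps(d.as_dict()) for d in self.decisions)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(lines + "\n")
        return lines


@dataclass
class PretrainedPool:
    """Donor models for cold-start selection; all must share one architecture."""

    entries: list  # of (donor_id, ForecastModel, donor_training_days)

    def __post_init__(self):
        if not self.entries:
            raise ValueError("pretrained pool is empty")
        spec0 = self.entries[0][1].spec
        for donor_id, model, _days in self.entries:
            if model.spec != spec0:
                raise ValueError(
                    f"donor {donor_id!r} has a different architecture than the pool"
                )

    @property
    def spec(self) -> ArchitectureSpec:
        return self.entries[0][1].spec

    def __len__(self) -> int:
        return len(self.entries)


def build_pool(models_with_meta, min_days: float) -> PretrainedPool:
    """Filter donors by training-history length.

    ``models_with_meta``: iterable of (donor_id, ForecastModel, total_days).
    """
    kept = [(d, m, days) for d, m, days in models_with_meta if days >= min_days]
    if not kept:
        raise ValueError(f"no donors with >= {min_days} training days")
    return PretrainedPool(kept)


# ---------------------------------------------------------------------------
# preprocessing shared by fit() and cold_start()
# ---------------------------------------------------------------------------

@dataclass
class PreparedData:
    raw: GlucoseTrace       # cleaned, short test gaps filled causally
    smoothed: GlucoseTrace  # cleaned + interpolated + Kalman smoothed (training)
    record: SubjectRecord


def prepare_record(record: SubjectRecord, kalman: KalmanConfig | None = None,
                   apply_smoothing: bool = True) -> PreparedData:
    """Clean once, then derive the training-view and evaluation-view traces.

    The training view is interpolated (gaps < 30 min) and Kalman smoothed;
    the evaluation view keeps raw values, filling short gaps only causally
    by first-order extrapolation so no future data leaks into histories.
    """
    clean = exclude_implausible(record.trace)
    train_trace = interpolate_training_gaps(clean)
    if apply_smoothing:
        train_trace = smooth(train_trace, kalman or KalmanConfig())
    eval_trace = fill_test_gaps(clean)
    return PreparedData(raw=eval_trace, smoothed=train_trace, record=record)


def _final_step_pairs(model: ForecastModel, ws: WindowSet) -> evaluate.PredictionSet:
    """Predict and keep the horizon-step (final output) value per window."""
    pred = model.predict(ws.X)[:, -1]
    return evaluate.PredictionSet(
        reference=ws.y[:, -1],
        predicted=pred,
        origin_times=ws.origin_times,
        horizon_minutes=ws.ph_minutes,
    )


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class IncrementalForecaster:
    """Incrementally retrained stacked-LSTM forecaster for one subject.

    Parameters
    ----------
    record : SubjectRecord
        The subject's gridded glucose trace (>= 50 days) and optional
        insulin/carb event channels.
    ph_minutes : {30, 60}
        Prediction horizon.
    multivariate : bool
        Use (glucose, basal, bolus, carbs) input channels instead of
        glucose alone.
    initial_days : int or "auto"
        Length of the first training block; "auto" recommends 7 days for
        high-GV subjects (interday CV > 36%) and 2 days for low-GV.
    parameter_transfer : bool
        Enable the t-test gate; when False every block is retrained
        (still warm-started).
    """

    def __init__(
        self,
        record: SubjectRecord,
        ph_minutes: int = 30,
        multivariate: bool = False,
        initial_days="auto",
        parameter_transfer: bool = True,
        arch: ArchitectureSpec | None = None,
        train_config: TrainConfig | None = None,
        kalman: KalmanConfig | None = None,
        apply_smoothing: bool = True,
        test_fraction: float = 0.30,
        stride: int = 1,
        min_total_days: int = 50,
    ):
        if ph_minutes not in (30, 60):
            raise ValueError("prediction horizon must be 30 or 60 minutes")
        if multivariate and record.events is None:
            raise ValueError("multivariate mode needs event channels")
        check_eligibility(record, min_total_days)

        self.record = record
        self.ph_minutes = ph_minutes
        self.h = ph_minutes // record.trace.step_minutes
        self.multivariate = multivariate
        self.parameter_transfer = parameter_transfer
        self.train_config = train_config or TrainConfig()
        self.kalman = kalman or KalmanConfig()
        self.apply_smoothing = apply_smoothing
        self.test_fraction = test_fraction
        self.stride = stride
        self.min_total_days = min_total_days

        self.prepared = prepare_record(record, self.kalman, apply_smoothing)
        self.gv_profile: GVProfile = compute_gv(exclude_implausible(record.trace))
        if initial_days == "auto":
            self.initial_days = recommend_initial_days(self.gv_profile.group)
        else:
            self.initial_days = recommend_initial_days(
                self.gv_profile.group, override=int(initial_days)
            )
        self.plan: SubsetPlan = make_subset_plan(
            record, self.initial_days, test_fraction, min_total_days=min_total_days
        )

        spec = arch or ArchitectureSpec()
        self.spec = ArchitectureSpec(
            history_steps=spec.history_steps,
            input_channels=4 if multivariate else 1,
            layer1_units=spec.layer1_units,
            layer2_units=spec.layer2_units,
            output_units=self.h,
            dropout_rate=spec.dropout_rate,
            activation=spec.activation,
        )

    # -- window helpers ----------------------------------------------------
    def _train_windows(self, block) -> WindowSet:
        return block_windows(
            self.prepared.smoothed, block, self.record.events,
            ph_minutes=self.ph_minutes, multivariate=self.multivariate,
            stride=self.stride,
        )

    def _eval_windows(self, day_range) -> WindowSet:
        return block_windows(
            self.prepared.raw, day_range, self.record.events,
            ph_minutes=self.ph_minutes, multivariate=self.multivariate,
            stride=1,
        )

    def _block_glucose(self, block) -> np.ndarray:
        """Raw observed glucose of a block (the shift-test statistic's input)."""
        lo, hi = self.record.trace.day_slot_bounds(block.start_day, block.end_day)
        clean = exclude_implausible(self.record.trace.slice(lo, hi))
        return clean.values[~clean.missing]

    # -- fitting -----------------------------------------------------------
    def fit(self, seed: int = 0, start_model: ForecastModel | None = None,
            keep_checkpoints: bool = False) -> "IncrementalResults":
        """Run the incremental protocol over the training blocks.

        ``start_model`` (e.g. a cold-start pool selection) replaces the
        fresh initialization of the first block; retraining then
        warm-starts from it.  ``keep_checkpoints`` retains a copy of the
        model after every stage (needed when the run will seed a
        pre-trained pool, or to audit parameter transfer).
        """
        cfg = self.train_config
        model = (start_model.copy() if start_model is not None
                 else ForecastModel.build(self.spec, seed))
        log = RetrainLog()
        checkpoints: list[ForecastModel] = []
        train_blocks = self.plan.train_blocks

        for m, block in enumerate(train_blocks):
            val_lo, val_hi = self.plan.validation_day(block)
            val_ws = self._eval_windows((val_lo, val_hi))
            train_ws = self._train_windows(block)

            if m == 0:
                p_value, action, reason = float("nan"), "retrain", "first block"
            else:
                p_value = shift_test(
                    self._block_glucose(block), self._block_glucose(train_blocks[m - 1])
                )
                if self.parameter_transfer and p_value > SIGNIFICANCE:
                    action, reason = "skip", "no significant distribution shift"
                else:
                    action, reason = "retrain", (
                        "significant distribution shift" if self.parameter_transfer
                        else "parameter transfer disabled"
                    )

            epochs_run = 0
            if action == "retrain":
                if train_ws.n == 0:
                    action, reason = "skip", "no training windows in block"
                elif val_ws.n == 0:
                    action, reason = "skip", "no validation windows on next day"
                else:
                    block_cfg = TrainConfig(
                        max_epochs=cfg.max_epochs, patience=cfg.patience,
                        batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                        clip_norm=cfg.clip_norm, seed=seed * 1000 + block.index,
                    )
                    model, epochs_run, _hist = train_on_subset(
                        model, train_ws.X, train_ws.y, val_ws.X, val_ws.y, block_cfg
                    )

            if val_ws.n > 0 and model.norm is not None:
                val_rmse = evaluate.rmse_pairs(_final_step_pairs(model, val_ws))
            else:
                val_rmse = float("nan")
            log.decisions.append(RetrainDecision(
                block_index=block.index, p_value=p_value, action=action,
                epochs_run=epochs_run, validation_rmse=val_rmse,
                n_train_windows=train_ws.n, reason=reason,
            ))
            if keep_checkpoints:
                checkpoints.append(model.copy())

        test_pairs = self._test_pairs(model)
        return IncrementalResults(self, model, log, test_pairs,
                                  checkpoints=checkpoints or None)

    def _test_pairs(self, model: ForecastModel) -> evaluate.PredictionSet | None:
        test_blocks = self.plan.test_blocks
        if not test_blocks or model.norm is None:
            return None
        sets = [
            self._eval_windows((b.start_day, b.end_day)) for b in test_blocks
        ]
        sets = [s for s in sets if s.n > 0]
        if not sets:
            return None
        ws = WindowSet.concatenate(sets)
        return _final_step_pairs(model, ws)


class IncrementalResults:
    """Fit results: final model, retrain provenance, and test-period scores."""

    def __init__(self, model_obj: IncrementalForecaster, model: ForecastModel,
                 retrain_log: RetrainLog, test_pairs: evaluate.PredictionSet | None,
                 checkpoints: list[ForecastModel] | None = None):
        self.model_obj = model_obj
        self.model = model
        self.retrain_log = retrain_log
        self.test_pairs = test_pairs
        self.checkpoints = checkpoints

    # -- headline quantities -----------------------------------------------
    @property
    def validation_rmse_curve(self) -> list[float]:
        return self.retrain_log.validation_rmse_curve()

    @property
    def test_rmse(self) -> float:
        if self.test_pairs is None:
            return float("nan")
        return evaluate.rmse_pairs(self.test_pairs)

    def ega(self) -> evaluate.EGAResult:
        if self.test_pairs is None:
            raise ValueError("no test predictions available")
        return evaluate.clarke_ega(self.test_pairs)

    def postprandial_rmse(self, window_minutes: int = 120) -> float:
        if self.test_pairs is None:
            raise ValueError("no test predictions available")
        events = self.model_obj.record.events
        if events is None:
            raise ValueError("no meal records for this subject")
        meals = events.meal_times(self.model_obj.record.trace.times)
        return evaluate.postprandial_rmse(self.test_pairs, meals, window_minutes)

    def report(self) -> dict:
        rep = {
            "subject_id": self.model_obj.record.trace.subject_id,
            "ph_minutes": self.model_obj.ph_minutes,
            "multivariate": self.model_obj.multivariate,
            "parameter_transfer": self.model_obj.parameter_transfer,
            "initial_days": self.model_obj.initial_days,
            "gv_group": self.model_obj.gv_profile.group,
            "interday_cv": self.model_obj.gv_profile.interday_cv,
            "blocks_trained": self.retrain_log.blocks_trained,
            "blocks_skipped": self.retrain_log.blocks_skipped,
            "total_epochs": self.retrain_log.total_epochs,
            "validation_rmse_curve": self.validation_rmse_curve,
            "test_rmse_mgdl": self.test_rmse,
        }
        if self.test_pairs is not None:
            rep["ega_zone_percent"] = self.ega().zone_fractions
        return rep

    def summary(self) -> str:
        r = self.report()
        lines = [
            "Incrementally Retrained Stacked LSTM - fit summary",
            "=" * 52,
            f"subject:              {r['subject_id']}",
            f"prediction horizon:   {r['ph_minutes']} min",
            f"inputs:               {'glucose+insulin+carbs' if r['multivariate'] else 'glucose only'}",
            f"GV group (interday CV): {r['gv_group']} ({r['interday_cv']:.1f}%)",
            f"initial window:       {r['initial_days']} day(s)",
            f"parameter transfer:   {'on' if r['parameter_transfer'] else 'off'}",
            f"blocks retrained/skipped: {r['blocks_trained']}/{r['blocks_skipped']}",
            f"total epochs:         {r['total_epochs']}",
            f"test RMSE:            {r['test_rmse_mgdl']:.2f} mg/dL",
        ]
        if "ega_zone_percent" in r:
            z = r["ega_zone_percent"]
            lines.append(
                "Clarke EGA zones:     "
                + "  ".join(f"{k}={z[k]:.2f}%" for k in "ABCDE")
            )
        curve = [v for v in r["validation_rmse_curve"] if np.isfinite(v)]
        if curve:
            lines.append(
                f"validation RMSE:      {curve[0]:.2f} -> {curve[-1]:.2f} mg/dL "
                f"over {len(curve)} block(s)"
            )
        return "\n".join(lines)


def run_incremental(
    record: SubjectRecord, plan_or_initial_days=None, config: TrainConfig | None = None,
    parameter_transfer: bool = True, seed: int = 0, **kwargs
) -> tuple[ForecastModel, RetrainLog]:
    """Functional wrapper over :class:`IncrementalForecaster`.

    ``plan_or_initial_days`` may be an int (initial block length in days)
    or None for the GV-based automatic choice.
    """
    initial = "auto" if plan_or_initial_days is None else plan_or_initial_days
    forecaster = IncrementalForecaster(
        record, initial_days=initial, parameter_transfer=parameter_transfer,
        train_config=config, **kwargs,
    )
    res = forecaster.fit(seed=seed)
    return res.model, res.retrain_log


# ---------------------------------------------------------------------------
# cold start
# ---------------------------------------------------------------------------

@dataclass
class ColdStartResult:
    selected_donor: str
    day1_rmse_by_donor: dict
    daily_rmse: list        # next-day RMSE for day d -> d+1 updates
    daily_days: list        # the day indices trained on
    model: ForecastModel
    weekly_log: RetrainLog | None = None


def cold_start(
    record: SubjectRecord,
    pool: PretrainedPool,
    ph_minutes: int = 30,
    multivariate: bool = False,
    train_config: TrainConfig | None = None,
    kalman: KalmanConfig | None = None,
    apply_smoothing: bool = True,
    n_daily_days: int = 50,
    continue_weekly: bool = False,
    stride: int = 1,
    seed: int = 0,
    from_scratch: bool = False,
) -> ColdStartResult:
    """Cold-start protocol: select from the pool on day 1, adapt daily.

    Every pool model forecasts the subject's day-1 windows; the lowest-RMSE
    model is selected (with ``from_scratch`` a fresh initialization is used
    instead, as the comparison arm).  For days 2..``n_daily_days`` the
    model is retrained on each day's windows (warm start, 1-day update
    window) and tested on the next day; the per-day next-day RMSE curve is
    returned.  With ``continue_weekly`` the remaining data then follows the
    7-day gated protocol.
    """
    cfg = train_config or TrainConfig()
    prepared = prepare_record(record, kalman, apply_smoothing)
    h = ph_minutes // record.trace.step_minutes
    spec = ArchitectureSpec(
        history_steps=pool.spec.history_steps,
        input_channels=4 if multivariate else 1,
        layer1_units=pool.spec.layer1_units,
        layer2_units=pool.spec.layer2_units,
        output_units=h,
        dropout_rate=pool.spec.dropout_rate,
        activation=pool.spec.activation,
    )
    if not from_scratch and pool.spec != spec:
        raise ValueError("pool architecture incompatible with requested setup")

    def eval_windows(day_lo, day_hi):
        return block_windows(
            prepared.raw, (day_lo, day_hi), record.events,
            ph_minutes=ph_minutes, multivariate=multivariate, stride=1,
        )

    def train_windows(day_lo, day_hi):
        return block_windows(
            prepared.smoothed, (day_lo, day_hi), record.events,
            ph_minutes=ph_minutes, multivariate=multivariate, stride=stride,
        )

    # --- day-1 selection
    sel_day = 0
    day1 = eval_windows(0, 1)
    if day1.n == 0:
        logger.warning("%s: no usable day-1 windows, selecting on day 2",
                       record.trace.subject_id)
        sel_day = 1
        day1 = eval_windows(1, 2)
        if day1.n == 0:
            raise ValueError("no usable windows on day 1 or day 2")

    day1_scores: dict[str, float] = {}
    if from_scratch:
        model = ForecastModel.build(spec, seed)
        selected = "(from scratch)"
    else:
        best = None
        for donor_id, donor_model, _days in pool.entries:
            score = evaluate.rmse_pairs(_final_step_pairs(donor_model, day1))
            day1_scores[donor_id] = score
            if best is None or score < best[1]:
                best = (donor_id, score, donor_model)
        selected = best[0]
        model = best[2].copy()

    # --- daily updates: train on day d, test on day d+1
    total_days = int(record.trace.day_index()[-1]) + 1
    last_daily = min(n_daily_days, total_days - 1)
    daily_rmse: list[float] = []
    daily_days: list[int] = []
    for d in range(sel_day + 1, last_daily):
        tr = train_windows(d, d + 1)
        nx = eval_windows(d + 1, d + 2)
        if tr.n == 0 or nx.n == 0:
            continue
        day_cfg = TrainConfig(
            max_epochs=cfg.max_epochs, patience=cfg.patience,
            batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
            clip_norm=cfg.clip_norm, seed=seed * 1000 + d,
        )
        model, _epochs, _hist = train_on_subset(
            model, tr.X, tr.y, nx.X, nx.y, day_cfg
        )
        daily_rmse.append(evaluate.rmse_pairs(_final_step_pairs(model, nx)))
        daily_days.append(d)

    weekly_log = None
    if continue_weekly and total_days - last_daily >= 15:
        # remaining data follows the 7-day gated protocol, warm-starting
        # from the daily-adapted model
        lo, hi = record.trace.day_slot_bounds(last_daily, total_days)
        sub = SubjectRecord(
            trace=record.trace.slice(lo, hi),
            events=record.events.slice(lo, hi) if record.events else None,
        )
        forecaster = IncrementalForecaster(
            sub, ph_minutes=ph_minutes, multivariate=multivariate,
            initial_days=7, parameter_transfer=True, train_config=cfg,
            kalman=kalman, apply_smoothing=apply_smoothing,
            stride=stride, min_total_days=15,
        )
        res = forecaster.fit(seed=seed, start_model=model)
        model = res.model
        weekly_log = res.retrain_log

    return ColdStartResult(
        selected_donor=selected,
        day1_rmse_by_donor=day1_scores,
        daily_rmse=daily_rmse,
        daily_days=daily_days,
        model=model,
        weekly_log=weekly_log,
    )
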