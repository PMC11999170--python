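"""The incremental retraining protocol: gating, transfer, cold start."""

import numpy as np
import pytest

from cgmforecast.incremental import (
    IncrementalForecaster,
    PretrainedPool,
    build_pool,
    cold_start,
)
from cgmforecast.network import ArchitectureSpec, ForecastModel, TrainConfig
from cgmforecast.simulate import GapModel, SimConfig, simulate_subject
from cgmforecast.windows import block_windows

TINY = ArchitectureSpec(layer1_units=16, layer2_units=8)
FAST = TrainConfig(max_epochs=8, patience=3, learning_rate=3e-3)


@pytest.fixture(scope="module")
def fits(sim_subject_10wk):
    """One with-transfer and one without-transfer fit, shared read-only."""
    out = {}
    for pt in (True, False):
        fc = IncrementalForecaster(
            sim_subject_10wk, initial_days=7, parameter_transfer=pt,
            arch=TINY, train_config=FAST, stride=3,
        )
        out[pt] = fc.fit(seed=0)
    return out


class TestGatedRetraining:
    def test_first_block_always_trained(self, fits):
        d0 = fits[True].retrain_log.decisions[0]
        assert d0.action == "retrain" and np.isnan(d0.p_value)

    def test_decision_consistency(self, fits):
        """(p <= 0.05) <=> retrain on every gated block with transfer on."""
        for d in fits[True].retrain_log.decisions[1:]:
            assert (d.p_value <= 0.05) == (d.action == "retrain"), vars(d)

    def test_stationary_subject_mostly_skipped(self, fits):
        log = fits[True].retrain_log
        assert log.skip_fraction >= 0.5

    def test_without_transfer_nothing_skipped(self, fits):
        assert fits[False].retrain_log.blocks_skipped == 0

    def test_transfer_saves_epochs(self, fits):
        assert fits[True].retrain_log.total_epochs < fits[False].retrain_log.total_epochs

    def test_log_totals_consistent(self, fits):
        log = fits[True].retrain_log
        n_after_first = len(log.decisions) - 1
        assert log.blocks_trained + log.blocks_skipped == n_after_first + 1

    def test_jsonl_roundtrip(self, fits, tmp_path):
        path = tmp_path / "log.jsonl"
        fits[True].retrain_log.to_jsonl(path)
        import json

        lines = [json.loads(l) for l in path.read_text().splitlines()]
        assert len(lines) == len(fits[True].retrain_log.decisions)
        assert lines[0]["action"] == "retrain"

    def test_regime_shift_triggers_retrain(self):
        """An abrupt +40 mg/dL mean shift must force retraining of its block."""
        rec = simulate_subject(SimConfig(
            n_days=70, seed=21, regime_shifts=((6, 40.0),),
            gap=GapModel(rate_per_day=0.0),
        ))
        fc = IncrementalForecaster(
            rec, initial_days=7, parameter_transfer=True,
            arch=TINY, train_config=FAST, stride=3,
        )
        res = fc.fit(seed=0)
        # week 6 starts at day 42: block with start_day 42 sees the shift
        shifted = [d for b, d in zip(fc.plan.train_blocks, res.retrain_log.decisions)
                   if b.start_day == 42]
        assert shifted and shifted[0].action == "retrain"

    def test_summary_renders(self, fits):
        text = fits[True].summary()
        assert "test RMSE" in text and "Clarke EGA" in text


class TestParameterIdentity:
    def test_skipped_blocks_carry_parameters_bit_exactly(self, sim_subject_10wk):
        """Parameters after a skipped block equal the previous stage exactly."""
        rec = sim_subject_10wk
        fc = IncrementalForecaster(
            rec, initial_days=7, parameter_transfer=True,
            arch=TINY, train_config=FAST, stride=3,
        )
        # replay fit manually to capture per-stage parameters
        model = ForecastModel.build(fc.spec, 0)
        from cgmforecast.network import train_on_subset
        from cgmforecast.incremental import shift_test

        prev = None
        blocks = fc.plan.train_blocks
        for m, block in enumerate(blocks):
            val_ws = fc._eval_windows(fc.plan.validation_day(block))
            train_ws = fc._train_windows(block)
            retrain = m == 0 or shift_test(
                fc._block_glucose(block), fc._block_glucose(blocks[m - 1])
            ) <= 0.05
            if retrain:
                model, _, _ = train_on_subset(
                    model, train_ws.X, train_ws.y, val_ws.X, val_ws.y, FAST
                )
            else:
                assert prev is not None and model.params_equal(prev)
            prev = model.copy()


class TestPool:
    def _models(self, n=3):
        return [(f"d{k}", ForecastModel.build(TINY, seed=k), days)
                for k, days in zip(range(n), (1200, 900, 1500))]

    def test_filter_by_days(self):
        pool = build_pool(self._models(), min_days=1000)
        assert len(pool) == 2

    def test_min_days_zero_keeps_all(self):
        assert len(build_pool(self._models(), min_days=0)) == 3

    def test_empty_result_raises(self):
        with pytest.raises(ValueError, match="donors"):
            build_pool(self._models(), min_days=1500 + 1)

    def test_mixed_specs_rejected(self):
        entries = self._models()
        other = ArchitectureSpec(layer1_units=4, layer2_units=2)
        entries.append(("odd", ForecastModel.build(other, seed=9), 2000))
        with pytest.raises(ValueError, match="architecture"):
            PretrainedPool(entries)


class TestColdStart:
    @pytest.fixture(scope="class")
    def donor_pool(self, sim_subject_10wk):
        """Two donors: one trained on generator-matched data, one mismatched."""
        from cgmforecast.network import train_on_subset

        pool_entries = []
        # matched donor: trained on another seed of the same generating process
        matched = simulate_subject(SimConfig(n_days=14, seed=77))
        # mismatched donor: very different baseline and variability
        odd = simulate_subject(SimConfig(
            n_days=14, seed=78, baseline_mean=260.0, circadian_amplitude=5.0,
        ))
        spec6 = ArchitectureSpec(layer1_units=16, layer2_units=8, output_units=6)
        for sid, rec, days in (("matched", matched, 1200), ("mismatch", odd, 1100)):
            ws = block_windows(rec.trace, (0, 14), ph_minutes=30, stride=3)
            val = block_windows(rec.trace, (12, 14), ph_minutes=30, stride=3)
            m = ForecastModel.build(spec6, seed=3)
            m, _, _ = train_on_subset(m, ws.X, ws.y, val.X, val.y, FAST)
            pool_entries.append((sid, m, days))
        return PretrainedPool(pool_entries)

    def test_matched_donor_selected(self, sim_subject_10wk, donor_pool):
        result = cold_start(
            sim_subject_10wk, donor_pool, train_config=FAST,
            n_daily_days=3, stride=3, seed=0,
        )
        assert result.selected_donor == "matched"
        assert result.day1_rmse_by_donor["matched"] < result.day1_rmse_by_donor["mismatch"]

    def test_pool_of_one_trivially_selected(self, sim_subject_10wk, donor_pool):
        single = PretrainedPool([donor_pool.entries[0]])
        result = cold_start(
            sim_subject_10wk, single, train_config=FAST,
            n_daily_days=3, stride=3, seed=0,
        )
        assert result.selected_donor == "matched"

    def test_daily_curve_recorded(self, sim_subject_10wk, donor_pool):
        result = cold_start(
            sim_subject_10wk, donor_pool, train_config=FAST,
            n_daily_days=6, stride=3, seed=0,
        )
        assert len(result.daily_rmse) >= 3
        assert all(r > 0 for r in result.daily_rmse)


class TestValidationErrors:
    def test_ineligible_subject(self):
        rec = simulate_subject(SimConfig(n_days=20, seed=1))
        with pytest.raises(Exception, match="day"):
            IncrementalForecaster(rec, arch=TINY, train_config=FAST)

    def test_multivariate_without_events(self, sim_subject_10wk):
        from cgmforecast.data import SubjectRecord

        bare = SubjectRecord(trace=sim_subject_10wk.trace)
        with pytest.raises(ValueError, match="event"):
            IncrementalForecaster(bare, multivariate=True, arch=TINY, train_config=FAST)

    def test_bad_horizon(self, sim_subject_10wk):
        with pytest.raises(ValueError, match="horizon"):
            IncrementalForecaster(sim_subject_10wk, ph_minutes=45,
                                  arch=TINY, train_config=FAST)
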