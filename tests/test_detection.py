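"""Torpor threshold derivation and bout segmentation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import heliotherm as ht
from heliotherm.detection import NormothermyModel

ANALYTIC_THRESHOLD = 37.5 - 2.576 * 0.5 - 3.0  # 33.212 °C


def trace_from(values, individual="x", interval=15.0):
    t = np.arange(len(values)) * interval
    return ht.TbTrace(individual=individual, time=t, tb=np.asarray(values, float))


class TestUpperMode:
    def test_normal_samples(self):
        rng = np.random.default_rng(1)
        tr = trace_from(rng.normal(37.5, 0.5, 3000))
        assert ht.estimate_upper_mode(tr, 0.5) == pytest.approx(37.5, abs=0.25)

    def test_bimodal_returns_upper(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate(
            [rng.normal(37.5, 0.5, 2100), rng.normal(20.0, 3.0, 900)]
        )
        assert ht.estimate_upper_mode(trace_from(vals), 0.5) == pytest.approx(
            37.5, abs=0.3
        )

    def test_constant_trace(self):
        tr = trace_from(np.full(200, 37.0))
        assert ht.estimate_upper_mode(tr, 0.5) == 37.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="100"):
            ht.estimate_upper_mode(trace_from(np.full(50, 37.0)), 0.5)


class TestNormothermicModel:
    def test_closed_form_threshold(self, cfg):
        """Normal(37.5, 0.5) normothermy → threshold ≈ 37.5 − 2.576·0.5 − 3."""
        rng = np.random.default_rng(3)
        tr = trace_from(rng.normal(37.5, 0.5, 3000))
        m = ht.fit_normothermic_model(tr, cfg)
        assert m.torpor_threshold == pytest.approx(ANALYTIC_THRESHOLD, abs=0.3)
        assert m.lower_99_bound < m.modal_tb

    def test_constant_normothermy_offset_only(self, cfg):
        tr = trace_from(np.full(200, 37.0))
        m = ht.fit_normothermic_model(tr, cfg)
        assert m.fitted_sd == 0.0
        assert m.torpor_threshold == pytest.approx(34.0)

    def test_threshold_linear_in_offset(self):
        rng = np.random.default_rng(4)
        tr = trace_from(rng.normal(37.5, 0.5, 1000))
        t1 = ht.fit_normothermic_model(tr, ht.ExperimentConfig(threshold_offset=3.0))
        t2 = ht.fit_normothermic_model(tr, ht.ExperimentConfig(threshold_offset=6.0))
        assert t2.torpor_threshold == pytest.approx(t1.torpor_threshold - 3.0)

    @given(shift=st.floats(-5.0, 5.0))
    def test_shift_equivariance(self, shift):
        """Adding c to every sample shifts mode, bound and threshold by c."""
        cfg = ht.ExperimentConfig()
        rng = np.random.default_rng(5)
        base = rng.normal(37.5, 0.5, 1000)
        m0 = ht.fit_normothermic_model(trace_from(base), cfg)
        m1 = ht.fit_normothermic_model(trace_from(base + shift), cfg)
        assert m1.modal_tb == pytest.approx(m0.modal_tb + shift, abs=1e-6)
        assert m1.lower_99_bound == pytest.approx(m0.lower_99_bound + shift, abs=1e-6)
        assert m1.torpor_threshold == pytest.approx(
            m0.torpor_threshold + shift, abs=1e-6
        )


def simple_model(threshold=33.2, bound=36.2, individual="x"):
    return NormothermyModel(
        individual=individual, modal_tb=37.5, fitted_sd=0.5,
        lower_99_bound=bound, torpor_threshold=threshold,
    )


class TestSegmentation:
    def test_never_below_threshold(self, cfg):
        tr = trace_from(np.full(300, 37.0))
        assert ht.segment_bouts(tr, simple_model(), cfg) == []

    def test_individual_mismatch(self, cfg):
        tr = trace_from(np.full(300, 37.0), individual="y")
        with pytest.raises(ValueError, match="does not match"):
            ht.segment_bouts(tr, simple_model(individual="x"), cfg)

    def test_short_gap_merged(self, cfg):
        """Two below-threshold runs split by one 15-min excursion form one bout."""
        vals = (
            [37.0] * 4
            + [30.0, 25.0, 20.0]      # run 1
            + [33.5]                  # 15 min above threshold (< merge_gap)
            + [20.0, 20.0, 22.0, 25.0, 28.0, 31.0]  # run 2 incl. early ramp
            + [34.0, 36.5, 37.2]      # ramp completes above threshold
            + [37.0] * 3
        )
        bouts = ht.segment_bouts(trace_from(vals), simple_model(), cfg)
        assert len(bouts) == 1
        b = bouts[0]
        assert b.entry_time == 4 * 15.0
        assert b.duration == 9 * 15.0  # merged gap excluded from duration
        assert b.tb_min == 20.0

    def test_long_gap_splits(self, cfg):
        vals = (
            [37.0] * 4
            + [30.0, 25.0, 27.0, 31.0, 34.0, 36.5]   # bout 1 + ramp
            + [37.0] * 4                              # 1 h above threshold
            + [30.0, 25.0, 27.0, 31.0, 34.0, 36.5]   # bout 2
            + [37.0] * 3
        )
        bouts = ht.segment_bouts(trace_from(vals), simple_model(), cfg)
        assert len(bouts) == 2

    def test_min_duration_discards_single_sample_run(self, cfg):
        vals = [37.0] * 4 + [30.0] + [37.0] * 6
        assert ht.segment_bouts(trace_from(vals), simple_model(), cfg) == []

    def test_bout_invariants_on_synthetic(self, cfg, weather36):
        spec = ht.TraceSpec(bout_probability_per_day=0.5)
        trace, _ = ht.simulate_tb_trace(spec, weather36, seed=8)
        model = ht.fit_normothermic_model(trace, cfg)
        bouts = ht.segment_bouts(trace, model, cfg)
        assert bouts
        t, tb = trace.valid_time, trace.valid_tb
        below_total = 0.0
        for b in bouts:
            assert b.tb_min < model.torpor_threshold
            assert b.entry_time < b.arousal_onset_time <= b.return_to_threshold_time
            if b.attainment_time is not None:
                assert b.return_to_threshold_time <= b.attainment_time
            assert b.duration >= cfg.min_bout_duration
            inside = (t >= b.entry_time) & (t < b.return_to_threshold_time)
            below_total += (tb[inside] < model.torpor_threshold).sum() * cfg.sampling_interval
        # duration conservation: durations sum to below-threshold time of kept runs
        assert sum(b.duration for b in bouts) == pytest.approx(below_total)

    def test_recovery_rate_and_entry_accuracy(self, recovery_results):
        """≥95 % of generated bouts recovered with entry within one interval."""
        res = recovery_results
        assert res["n_true"] >= 200
        assert res["n_matched"] >= 0.95 * res["n_true"]
        frac_close = np.mean(np.abs(res["entry_err"]) <= 15.0)
        assert frac_close >= 0.95


class TestFrequency:
    def test_half_days(self):
        days = {d: (1 if d < 18 else 0) for d in range(36)}
        assert ht.torpor_frequency(days) == 50.0

    def test_no_bouts(self):
        assert ht.torpor_frequency({d: 0 for d in range(10)}) == 0.0

    def test_printed_scale(self):
        days = {d: (1 if d < 21 else 0) for d in range(36)}
        assert ht.torpor_frequency(days) == pytest.approx(58.3, abs=0.05)

    def test_exclusions(self):
        days = {0: 1, 1: 0, 2: 1, 3: 0}
        assert ht.torpor_frequency(days, {1, 3}) == 100.0
        with pytest.raises(ValueError):
            ht.torpor_frequency(days, {7})
        with pytest.raises(ValueError):
            ht.torpor_frequency(days, {0, 1, 2, 3})


class TestCloudyMornings:
    def make_weather(self, morning_levels):
        """One sample every 30 min; constant irradiance during 07–09h."""
        times, irr = [], []
        for d, level in enumerate(morning_levels):
            for tod in range(0, 1440, 30):
                times.append(d * 1440 + tod)
                irr.append(level if 420 <= tod < 540 else 0.0)
        return ht.WeatherTrace(
            time=np.array(times, float),
            ta=np.zeros(len(times)),
            irradiance=np.array(irr, float),
        )

    def test_stated_rule(self, cfg):
        w = self.make_weather([161.0, 30.0, 100.0])
        cloudy = ht.classify_cloudy_mornings(w, cfg)
        assert cloudy == {1}  # 30/161 < 0.5; 100/161 > 0.5

    def test_max_day_is_clear(self, cfg):
        w = self.make_weather([161.0, 161.0])
        assert ht.classify_cloudy_mornings(w, cfg) == set()

    def test_all_zero_degenerate(self, cfg):
        w = self.make_weather([0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            ht.classify_cloudy_mornings(w, cfg)
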