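"""Gas-exchange conversion and metabolic endpoint extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import heliotherm as ht
from heliotherm.respirometry import MetabolicSummary, RespirometryRecording


def make_recording(vo2, phase, ta=None, time=None, rer=0.85):
    vo2 = np.asarray(vo2, float)
    n = len(vo2)
    return RespirometryRecording(
        time=np.arange(n, dtype=float) if time is None else np.asarray(time, float),
        vo2=vo2,
        vco2=vo2 * rer,
        chamber_ta=np.full(n, 25.0) if ta is None else np.asarray(ta, float),
        phase=np.asarray(phase),
    )


class TestGasToWatts:
    def test_reference_value(self):
        assert ht.gas_to_watts(1.0, 0.85) == pytest.approx(0.3398, abs=2e-4)

    def test_zero_vo2(self):
        assert ht.gas_to_watts(0.0, 0.85) == 0.0

    def test_monotone_in_rer(self):
        assert ht.gas_to_watts(1.0, 1.0) > ht.gas_to_watts(1.0, 0.71)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            ht.gas_to_watts(-0.1, 0.85)
        with pytest.raises(ValueError):
            ht.gas_to_watts(1.0, 2.0)

    @given(v=st.floats(0.0, 10.0), scale=st.floats(0.1, 5.0))
    def test_linear_in_vo2(self, v, scale):
        assert ht.gas_to_watts(v * scale, 0.85) == pytest.approx(
            scale * ht.gas_to_watts(v, 0.85), rel=1e-12, abs=1e-12
        )


class TestBaselineCorrect:
    def test_zero_baselines_unchanged(self):
        vo2 = [0.0] * 10 + [1.0] * 30 + [0.0] * 10
        phase = ["baseline"] * 10 + ["chamber"] * 30 + ["baseline"] * 10
        rec = make_recording(vo2, phase)
        out = ht.baseline_correct(rec)
        assert out.vo2[15] == pytest.approx(1.0)

    def test_linear_drift_interpolated(self):
        """Baselines 0 then 0.1 over 100 min remove 0.05 mid-trace."""
        n = 100
        phase = ["baseline"] * 10 + ["chamber"] * (n - 20) + ["baseline"] * 10
        vo2 = np.full(n, 1.0)
        vo2[:10] = 0.0
        vo2[-10:] = 0.1
        rec = make_recording(vo2, phase)
        out = ht.baseline_correct(rec)
        mid = int((rec.time[:10].mean() + rec.time[-10:].mean()) / 2)
        assert rec.vo2[mid] - out.vo2[mid] == pytest.approx(0.05, abs=5e-3)

    def test_drifting_bmr_recovery(self):
        """A linear analyzer drift is fully removed: BMR within 2 % of truth."""
        rec = ht.simulate_respirometry("bmr", {"bmr_w": 0.30, "noise_sd": 0.0}, seed=3)
        drift = 0.001 * rec.time  # mL/min per min, ends ~+0.5 mL/min
        rec = RespirometryRecording(
            time=rec.time, vo2=rec.vo2 + drift, vco2=rec.vco2 + drift * 0.85,
            chamber_ta=rec.chamber_ta, phase=rec.phase, animal_mass=rec.animal_mass,
        )
        bmr = ht.extract_bmr(ht.baseline_correct(rec))
        assert bmr == pytest.approx(0.30, rel=0.02)

    def test_requires_baseline(self):
        rec = make_recording([1.0] * 20, ["chamber"] * 20)
        with pytest.raises(ValueError, match="baseline"):
            ht.baseline_correct(rec)


class TestExtractBmr:
    def test_noise_free_constant(self):
        vo2 = np.full(120, 0.3 * 60.0 / (16.0 + 5.164 * 0.85))
        rec = make_recording(vo2, ["chamber"] * 120)
        assert ht.extract_bmr(rec, equilibration=0.0) == pytest.approx(0.30, abs=1e-9)

    def test_window_longer_than_recording(self):
        rec = make_recording(np.full(15, 1.0), ["chamber"] * 15)
        with pytest.raises(ValueError, match="short"):
            ht.extract_bmr(rec, window=60.0)

    def test_noisy_recovery_within_5pct(self):
        rec = ht.simulate_respirometry("bmr", {"bmr_w": 0.26}, seed=11)
        bmr = ht.extract_bmr(ht.baseline_correct(rec))
        assert bmr == pytest.approx(0.26, rel=0.05)


class TestNst:
    def test_identical_traces_zero_capacity(self):
        rec = ht.simulate_respirometry("nst", {"rmr_w": 0.4, "peak_w": 1.0}, seed=5)
        res = ht.nst_analysis(rec, rec)
        assert res.nst_capacity == pytest.approx(0.0, abs=1e-12)

    def test_recovery_within_5pct(self):
        na = ht.simulate_respirometry("nst", {"rmr_w": 0.4, "peak_w": 1.0}, seed=6)
        sal = ht.simulate_respirometry("nst", {"rmr_w": 0.4, "peak_w": 0.5}, seed=7)
        res = ht.nst_analysis(ht.baseline_correct(na), ht.baseline_correct(sal))
        assert res.nst_capacity == pytest.approx(0.5, rel=0.05)
        assert res.na_minus_rmr == pytest.approx(0.6, rel=0.05)

    def test_missing_injection_mark(self):
        rec = make_recording([1.0] * 40, ["baseline"] * 5 + ["rmr"] * 35)
        with pytest.raises(ValueError, match="injection"):
            ht.nst_analysis(rec, rec)


class TestNaDose:
    def test_printed_formula(self):
        assert ht.na_dose(52.4) == pytest.approx(12.33, abs=0.005)

    def test_unit_mass(self):
        assert ht.na_dose(1.0) == pytest.approx(2.53)

    def test_negative_exponent_variant(self):
        assert ht.na_dose(52.4, exponent=-0.4) == pytest.approx(0.519, abs=0.001)

    def test_invalid_mass(self):
        with pytest.raises(ValueError):
            ht.na_dose(0.0)


class TestMsum:
    def test_zero_noise_plateau(self):
        rec = ht.simulate_respirometry("msum", {"msum_w": 1.9, "noise_sd": 0.0}, seed=1)
        res = ht.extract_msum(rec)
        assert res.msum == pytest.approx(1.9, abs=0.01)
        assert res.plateau_found

    def test_monotone_rise_flagged(self):
        """VO2 still climbing when the ramp ends → no-plateau flag."""
        n = 120
        ta = 20.0 - (10.0 / 60.0) * np.arange(n)
        w = 0.6 + 0.01 * np.arange(n)  # rises throughout
        vo2 = w * 60.0 / (16.0 + 5.164 * 0.665)
        rec = make_recording(vo2, ["cold_ramp"] * n, ta=ta, rer=0.665)
        res = ht.extract_msum(rec)
        assert not res.plateau_found

    def test_requires_cold_ramp(self):
        rec = make_recording([1.0] * 30, ["chamber"] * 30)
        with pytest.raises(ValueError, match="cold_ramp"):
            ht.extract_msum(rec)


class TestTnzBreakpoint:
    @staticmethod
    def oracle(ta, rmr, grid):
        """Independent exhaustive SSE scan over hinge models."""
        best, best_sse = None, np.inf
        for c in grid:
            X = np.column_stack(
                [np.ones_like(ta), np.minimum(ta - c, 0), np.maximum(ta - c, 0)]
            )
            beta, *_ = np.linalg.lstsq(X, rmr, rcond=None)
            sse = float(np.sum((rmr - X @ beta) ** 2))
            if sse < best_sse:
                best, best_sse = c, sse
        return best

    def test_noise_free_exact(self):
        ta = np.array([20.0, 25.0, 28.0, 30.0, 33.0, 36.0])
        rmr = np.where(ta < 30.0, 0.26 + 0.05 * (30.0 - ta), 0.26)
        fit = ht.fit_tnz_breakpoint(ta, rmr)
        assert fit.lower_critical == pytest.approx(30.0, abs=0.1)
        grid = np.arange(ta.min() + 0.1, ta.max() - 0.05, 0.1)
        assert abs(fit.lower_critical - self.oracle(ta, rmr, grid)) <= 0.1

    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(12)
        ta = rng.uniform(18.0, 38.0, 40)
        rmr = np.where(ta < 29.0, 0.3 + 0.04 * (29.0 - ta), 0.3) + rng.normal(
            0, 0.02, 40
        )
        fit = ht.fit_tnz_breakpoint(ta, rmr)
        grid = np.arange(ta.min() + 0.1, ta.max() - 0.05, 0.1)
        assert abs(fit.lower_critical - self.oracle(ta, rmr, grid)) <= 0.1

    def test_design_points_with_noise(self):
        """Six Ta levels × six individuals recover the breakpoint within 1 °C."""
        rng = np.random.default_rng(13)
        ta = np.repeat([20.0, 25.0, 28.0, 30.0, 33.0, 36.0], 6)
        rmr = np.where(ta < 30.0, 0.26 + 0.05 * (30.0 - ta), 0.26)
        rmr = rmr + rng.normal(0, 0.01, ta.size)
        fit = ht.fit_tnz_breakpoint(ta, rmr)
        assert fit.lower_critical == pytest.approx(30.0, abs=1.0)

    def test_single_line_warns(self):
        ta = np.array([20.0, 25.0, 28.0, 30.0, 33.0, 36.0])
        rmr = 0.5 - 0.01 * ta
        fit = ht.fit_tnz_breakpoint(ta, rmr)
        assert fit.warning is not None

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ht.fit_tnz_breakpoint([20.0, 25.0, 30.0, 33.0], [1, 2, 3, 4])


class TestExpansibility:
    def test_printed_treatment_means(self):
        """Full-sun whole-animal means: 1.84 W Msum over 0.26 W BMR ≈ 7.08."""
        assert ht.metabolic_expansibility(1.84, 0.26) == pytest.approx(7.08, abs=0.005)

    def test_equal_rates(self):
        assert ht.metabolic_expansibility(0.5, 0.5) == 1.0

    def test_scale_invariance(self):
        assert ht.metabolic_expansibility(3.8, 0.52) == pytest.approx(
            ht.metabolic_expansibility(1.9, 0.26)
        )

    def test_invalid_bmr(self):
        with pytest.raises(ValueError):
            ht.metabolic_expansibility(1.9, 0.0)


class TestSummaryFlags:
    def test_low_rer_flagged_not_clamped(self):
        s = MetabolicSummary(individual="A1", rer=0.665)
        assert s.rer == 0.665
        assert any("rer" in f for f in s.flags)

    def test_msum_below_bmr_flagged(self):
        s = MetabolicSummary(individual="A1", bmr=0.4, msum=0.3)
        assert "msum_below_bmr" in s.flags
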