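import numpy as np
import pytest
from hypothesis import settings

import heliotherm as ht

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return ht.ExperimentConfig()


@pytest.fixture(scope="session")
def weather36():
    return ht.simulate_weather(36, seed=5)


@pytest.fixture(scope="session")
def dark36(weather36):
    """36-day weather with irradiance zeroed: purely endogenous rewarming."""
    w = weather36
    return ht.WeatherTrace(time=w.time, ta=w.ta, irradiance=np.zeros_like(w.irradiance))


@pytest.fixture(scope="session")
def recovery_results(cfg, dark36):
    """Full-pipeline parameter recovery on ~210 dark-weather bouts.

    Six simulated individuals, a bout every night, true endogenous rewarming
    rates drawn uniformly in [0.10, 0.30] °C min⁻¹, default noise.  Each
    detected bout is matched to its generated counterpart by entry-time
    proximity.
    """
    rate_err, entry_err, n_true, n_matched = [], [], 0, 0
    for i in range(6):
        spec = ht.TraceSpec(
            bout_probability_per_day=1.0,
            endogenous_rewarming_rate=(0.10, 0.30),
        )
        trace, truth = ht.simulate_tb_trace(spec, dark36, seed=100 + i)
        model = ht.fit_normothermic_model(trace, cfg)
        bouts = ht.segment_bouts(trace, model, cfg)
        n_true += truth.n_bouts
        for b in bouts:
            rate = ht.rewarming_rate(trace, b)
            gaps = (truth.bouts.entry_time - b.entry_time).abs()
            j = gaps.idxmin()
            if gaps[j] >= 60:
                continue
            n_matched += 1
            entry_err.append(b.entry_time - truth.bouts.threshold_cross_time[j])
            if rate is not None:
                rate_err.append(rate - truth.bouts.true_rate[j])
    return {
        "rate_err": np.asarray(rate_err),
        "entry_err": np.asarray(entry_err),
        "n_true": n_true,
        "n_matched": n_matched,
    }
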