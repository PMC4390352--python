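"""Does sunlight supplement or substitute metabolic heat during rewarming?

Two cohorts are simulated under the three shading treatments (100 %, 39.8 %
and 21.3 % irradiance transmission).  In *supplement* mode solar heat adds
to endogenous thermogenesis, so measured rewarming rates rise with
transmission; in *substitute* mode solar heat replaces metabolic heat
whenever passive warming is adequate, so rates never rise with transmission
(the animal saves energy instead).  The measured ordering of treatment
means discriminates the two modes.
"""

import numpy as np

import heliotherm as ht

cfg = ht.ExperimentConfig()
weather = ht.simulate_weather(36, seed=9)
TREATMENTS = ("full_sun", "partial_shade", "deep_shade")


def mean_rate(mode, treatment):
    spec = ht.TraceSpec(
        rewarming_mode=mode, treatment=treatment, bout_probability_per_day=0.6
    )
    rates = []
    for trace, _ in ht.simulate_cohort(4, spec, weather, seed=9):
        model = ht.fit_normothermic_model(trace, cfg)
        for b in ht.segment_bouts(trace, model, cfg):
            r = ht.rewarming_rate(trace, b)
            if r is not None:
                rates.append(r)
    return float(np.mean(rates))


for mode in ("supplement", "substitute"):
    rates = {t: mean_rate(mode, t) for t in TREATMENTS}
    print(f"{mode} mode, mean measured rewarming rate (degC/min):")
    for t in TREATMENTS:
        tau = cfg.treatment_transmissions[t]
        print(f"  {t:<14} (transmission {tau:4.2f}): {rates[t]:.3f}")
    ordered = rates["full_sun"] > rates["partial_shade"] > rates["deep_shade"]
    print(f"  strictly increasing with transmission: {ordered}\n")

print("a strict increase with transmission is the signature of solar")
print("supplementation of endogenous thermogenesis; its absence indicates")
print("substitution (same rate, less metabolic heat).")
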