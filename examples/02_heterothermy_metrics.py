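"""Per-individual heterothermy metrics from a detected bout list.

Computes the Heterothermy Index (RMS deviation of Tb from the modal
normothermic temperature), torpor frequency, per-bout rewarming rates and
the timing of arousal relative to sunrise.
"""

import heliotherm as ht

cfg = ht.ExperimentConfig()
weather = ht.simulate_weather(36, cloudy_days={4, 18}, seed=2)
spec = ht.TraceSpec(bout_probability_per_day=0.6)
trace, _ = ht.simulate_tb_trace(spec, weather, seed=2)

model = ht.fit_normothermic_model(trace, cfg)
bouts = ht.segment_bouts(trace, model, cfg)
excluded = ht.classify_cloudy_mornings(weather, cfg)
summary = ht.summarize_individual(trace, bouts, model, excluded_days=excluded)

print(f"Heterothermy Index  : {summary.hi:5.2f} degC "
      "(0 = perfect homeothermy at the mode)")
print(f"torpor frequency    : {summary.torpor_frequency:5.1f} % of days "
      f"({len(excluded)} cloudy mornings excluded)")
print(f"mean rewarming rate : {summary.mean_rewarming_rate:.3f} degC/min")
print(f"mean bout duration  : {summary.mean_bout_duration:5.0f} min")

sunrise = spec.sunrise_time
print("\narousal onset relative to sunrise (positive = before sunrise):")
for b in bouts[:5]:
    onset_tod = b.arousal_onset_time % 1440
    lead = ht.minutes_before_sunrise(onset_tod, sunrise)
    print(f"  day {b.entry_day:2d}: {lead:5.0f} min before sunrise")
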