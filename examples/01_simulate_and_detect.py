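"""Simulate a winter Tb record and detect its torpor bouts.

Generates 36 days of 15-min body-temperature data for one elephant shrew
(torpor on about half of nights), derives the individual's torpor threshold
from its own Tb distribution, and segments the trace into bouts.
"""

import heliotherm as ht

cfg = ht.ExperimentConfig()
weather = ht.simulate_weather(36, seed=1)
spec = ht.TraceSpec(bout_probability_per_day=0.5)
trace, truth = ht.simulate_tb_trace(spec, weather, seed=1)

model = ht.fit_normothermic_model(trace, cfg)
print(f"modal normothermic Tb : {model.modal_tb:6.2f} degC")
print(f"fitted upper-tail sd  : {model.fitted_sd:6.2f} degC")
print(f"lower 99% bound       : {model.lower_99_bound:6.2f} degC")
print(f"torpor threshold      : {model.torpor_threshold:6.2f} degC "
      f"(bound minus {cfg.threshold_offset} degC offset)")

bouts = ht.segment_bouts(trace, model, cfg)
print(f"\ndetected {len(bouts)} bouts ({truth.n_bouts} generated)")
print(f"{'entry':>8}{'onset':>8}{'duration':>10}{'Tb-min':>8}")
for b in bouts[:5]:
    print(f"{b.entry_time:8.0f}{b.arousal_onset_time:8.0f}"
          f"{b.duration:10.0f}{b.tb_min:8.2f}")
print("(times in minutes since midnight of day 0; durations in minutes;")
print(" Tb-min is the bout's lowest body temperature)")
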