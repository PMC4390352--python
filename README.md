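# heliotherm

Analysis pipeline for **torpor and solar-assisted rewarming** in small
endotherms, built around implanted body-temperature (Tb) loggers, weather
records and open-flow respirometry. The motivating system is the eastern
rock elephant shrew (*Elephantulus myurus*), a ~52 g afrotherian that uses
torpor on most winter nights and basks while rewarming — raising the
question whether sunlight **supplements** endogenous thermogenesis (rates
add) or **substitutes** for it (energy saved, rates unchanged or lower).

The package is a library: import it from Python, or start from the short
narrative scripts in `examples/`.

## What it computes

**Torpor detection** (`heliotherm.detection`). Each individual's torpor
threshold is derived from its own Tb distribution: fit a normal
distribution to all samples at or above the upper modal Tb (half-normal
reflection with the mean pinned to the mode), take the lower bound of the
two-sided 99 % interval, and subtract a fixed 3 °C offset:

```
threshold = Tb_mod − 2.576·σ̂ − 3 °C
```

Bouts run from the first sample below threshold to the return to
threshold, with short above-threshold chatter merged and sub-30-min runs
discarded; each bout carries its entry, arousal-onset, attainment time,
duration, and minimum Tb.

**Heterothermy metrics** (`heliotherm.metrics`). The Heterothermy Index

```
HI = sqrt( Σ (Tb_mod − Tb_i)² / (n − 1) )
```

over all samples; per-bout rewarming rates as the OLS slope of Tb on time
over the arousal ramp; torpor frequency (% of days with a bout, cloudy
mornings excluded); daily minimum Tb; arousal timing relative to sunrise.

**Passive-rewarming biophysics** (`heliotherm.biophysics`). The maximum
rate at which solar heat gain alone can warm torpid tissue:

```
RPmax = SHG / (s·Mb),   SHG = G · SA · p · a · 60
```

with irradiance `G` (W m⁻²), surface area `SA` (Meeh estimate
`5.33·Mb^⅔` cm²), projected fraction `p ≈ 0.30`, absorptance `a`
(0.20–0.60 in small mammals) and tissue specific heat
`s = 3.43 J g⁻¹ °C⁻¹`.

**Respirometry** (`heliotherm.respirometry`). VO₂ → watts via the
RER-dependent Joule equivalent `(16 + 5.164·RER) J per mL O₂`; baseline
drift correction; BMR (minimum running mean), NST capacity (noradrenalin
peak minus saline peak), summit metabolism Msum (helox cold-ramp plateau),
metabolic expansibility Msum/BMR, and the thermoneutral-zone lower
critical temperature by continuous two-segment regression.

**Synthetic data** (`heliotherm.synthetic`). Generators for weather
(half-sine winter irradiance, clear-day 07h00–09h00 mean 161 W m⁻²), Tb
traces (Newtonian entry cooling, drawn bout minima, linear rewarming in
supplement or substitute mode under the three shade treatments: 100 %,
39.8 %, 21.3 % transmission) and respirometry recordings — all with full
ground truth for recovery testing.

## Worked example

```python
import heliotherm as ht

cfg = ht.ExperimentConfig()
weather = ht.simulate_weather(36, seed=1)
trace, truth = ht.simulate_tb_trace(
    ht.TraceSpec(bout_probability_per_day=0.5), weather, seed=1)

model = ht.fit_normothermic_model(trace, cfg)
bouts = ht.segment_bouts(trace, model, cfg)
summary = ht.summarize_individual(trace, bouts, model)
print(f"{model.torpor_threshold:.2f} {len(bouts)} {summary.hi:.2f}")
```

prints `33.24 17 8.40`: the individual's torpor threshold is 33.24 °C
(modal Tb 37.5 °C, fitted sd ≈ 0.5 °C), all 17 generated bouts are
recovered, and the HI of 8.40 °C summarises how far Tb strayed from the
mode over the 36 days. For
the biophysics:

```python
scn = ht.BiophysicalScenario(body_mass=52.4,
                             surface_area=ht.estimate_surface_area(52.4),
                             irradiance=161.0)
print(ht.rpmax_band(scn, 0.20, 0.60))
```

prints `(0.024, 0.072)` °C min⁻¹ — the passive-rewarming band for a
52.4 g animal in mean morning sun. A full-sun vs deep-shade difference in
mean rewarming rate of 0.05 °C min⁻¹ falls inside this band, i.e. solar
heat gain alone can account for it (`examples/03_passive_rewarming.py`).

`examples/05_supplement_vs_substitute.py` runs paired cohorts through the
whole pipeline and shows the discriminating signature: mean measured
rewarming rates 0.158 > 0.153 > 0.152 °C min⁻¹ across decreasing
transmission in supplement mode, and no increase (≈0.149 throughout) in
substitute mode.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch on seeded synthetic data: a
three-treatment, two-mode cohort of Tb traces (threshold fitting, bout
segmentation, heterothermy summaries with cloudy-morning exclusion), the
passive-rewarming worked example, and the respirometry battery (BMR, NST,
Msum, expansibility, TNZ breakpoint), printing each stage's summary and
writing the results JSON to `--out`.
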