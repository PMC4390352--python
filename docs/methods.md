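# Methods

This note records the models implemented, the defaults chosen where the
methodology leaves latitude, and what the synthetic-data tests do and do
not establish.

## Torpor threshold from the Tb distribution

A heterotherm's Tb distribution has a tight upper (normothermic) mode and
a broad cold tail from torpor, so a per-individual threshold is derived
from the distribution itself rather than imposed:

1. **Upper mode.** Histogram at 0.5 °C bins, edges anchored at the sample
   minimum (so the estimate is exactly equivariant under adding a constant
   to every sample). Candidate modes are local maxima holding ≥ 5 % of
   samples (a prominence floor against noise spikes); the
   highest-temperature candidate wins, ties broken toward warmer bins, and
   the winner is refined by a parabola through its three bins. Fewer than
   100 valid samples is an error. A degenerate spread (< 1 bin) returns
   the median directly.
2. **Half-normal tail fit.** Only samples ≥ the mode are used, so a
   two-parameter fit is ill-posed; the mean is pinned to the mode and
   `σ̂ = sqrt(mean((x − mode)²))` over the upper tail (reflection
   estimator, consistent for the normal σ). At least 30 upper-tail
   samples are required. σ̂ = 0 (constant normothermy) is legal: the
   threshold then sits exactly `offset` below the mode.
3. **Threshold.** `threshold = mode − z·σ̂ − offset` with `z = 2.576` and
   `offset = 3 °C`. The "lower 99 % interval" is read as the 0.5th
   percentile of the fitted *distribution of Tb* (two-sided 99 %), not a
   standard error of the mean — a mean-CI would collapse with n and make
   the offset dominate for every individual. `z` and `offset` are
   configurable.

## Bout segmentation

Below-threshold runs are merged when separated by less than `merge_gap`
(30 min, two samples) above threshold; merged bouts below
`min_bout_duration` (30 min) of below-threshold time are discarded.
Duration counts only below-threshold samples (merged gaps excluded), so
per-bout durations always sum to the total below-threshold time of the
retained runs.

*Arousal onset* is the last local minimum before the upward threshold
crossing, located by walking back from the crossing while Tb decreases by
more than `arousal_tolerance` (0.25 °C, twice the logger resolution) per
step, then forward over any sub-tolerance steps. The tolerance prevents
plateau measurement noise from dragging the onset one to three samples
into the flat plateau. *Attainment* is the first sample at/above the
lower 99 % bound after onset (reaching the mode itself is a plausible
alternative endpoint; the bound was chosen because noise makes the mode a
fluctuating target and the bound marks re-entry into the fitted
normothermic distribution). A trailing run that never returns to
threshold has no observable arousal and is discarded with a warning.

## Rewarming rate

OLS slope of Tb on time over the **strict interior** of
[onset, attainment]. Under 15-min sampling the bracketing samples need
not lie on the warming ramp: the onset sample is the last plateau sample
(the continuous ramp starts inside the following interval), and the
attainment sample can fall past the ramp's end when the bound is crossed
between samples. Either off-ramp endpoint acts as a hinge and biases the
slope low — by about 5 % at typical ramp lengths, measured on synthetic
bouts (inclusive window: RMSE 0.016, bias −0.011 °C min⁻¹; strict
interior: RMSE 0.006, bias 0.0002 against generator truth). Windows with
fewer than three interior samples leave the rate undefined with a flag.

## Heterothermy Index

`HI = sqrt(Σ (Tb_mod − Tb_i)²/(n−1))` over **all** valid samples, as the
index is defined; a `sub_modal_only` switch restricts to samples below the
mode for comparison with studies that use that variant. HI is a pure
distributional statistic — invariant to sample order — and the
implementation is checked against a brute-force two-pass oracle.

## Cloudy-morning exclusion and torpor frequency

A morning is cloudy when its 07h00–09h00 mean irradiance falls below half
the study-period maximum of that statistic; days without morning samples
are indeterminate and excluded. Torpor frequency is the percentage of
non-excluded days with at least one bout, a bout belonging to the day of
its entry (a bout spanning midnight counts once, toward its entry day).

## Passive rewarming biophysics

`RPmax = SHG/(s·Mb)` with `SHG = G·SA·p·a·60` J min⁻¹. Defaults: tissue
specific heat `s = 3.43 J g⁻¹ °C⁻¹`, projected fraction `p = 0.30`,
absorptance 0.20 (typical small mammal; up to 0.60), surface area from a
Meeh relation `SA = k·Mb^(2/3)` with `k = 5.3346` — an explicit
calibration reproducing the reported 74.7 cm² mean surface area at the
52.4 g pooled mean body mass, not a derivation of the original
surface-area method. The model ignores convective, radiative and
conductive exchange entirely: RPmax is the ceiling on solar-only warming,
useful for asking whether an observed between-treatment rate difference
*could* be purely solar.

## Respirometry

* **Joule equivalent.** `W = VO₂·(16 + 5.164·RER)/60` (VO₂ in mL min⁻¹
  STP) — the standard flow-respirometry relation. RER outside 0.71–1.00
  is flagged, never clamped (cold-stressed animals genuinely fall below
  0.71; RER outside 0.3–1.3 is rejected as implausible).
* **Baseline correction.** Segment means anchored at baseline midpoints,
  linear drift interpolated between anchors and subtracted; the first
  3 min of each baseline are discarded as analyzer switch transient. A
  single baseline degrades to a constant offset with a warning.
* **BMR**: minimum 10-min running mean over the chamber phase, skipping a
  15-min equilibration so chamber washout cannot pose as the basal
  minimum. **NST**: RMR = pre-injection mean; peaks = maximum 10-min
  running mean within 1.5 h post-injection; capacity = NA − SAL peak (the
  NA − RMR variant is reported alongside). **Msum**: maximum 5-min
  running mean during the cold ramp; the plateau is declared where the
  running mean's slope against Ta changes sign or drops below
  0.01 W °C⁻¹, else the result is flagged no-plateau. Window widths are
  unstated in the source protocols; these defaults are documented and
  configurable.
* **TNZ breakpoint**: continuous hinge model
  `RMR = a + b₁·min(Ta−c,0) + b₂·max(Ta−c,0)`, with `c` found by 0.1 °C
  grid search minimising SSE (optionally with the upper segment
  constrained flat). Flags: breakpoint at the grid edge; SSE improvement
  over a single line below tolerance.
* **NA dose**: `2.53·Mb^0.4` mg kg⁻¹ as printed; the exponent's sign
  conflicts with the usual mass-specific dosing convention, so −0.4 is
  selectable and neither is asserted.
* Mass-specific outputs use the mean of pre- and post-measurement masses.

## Synthetic generators

The study's raw logger data are not deposited; the generators emulate the
stated statistical structure so every stage is testable against ground
truth.

* **Weather**: per-day half-sine irradiance between 06h55 sunrise and
  17h30 sunset, peak scaled so the clear-day 07h00–09h00 mean equals
  161 W m⁻² (the study-period morning average; samples then span the
  reported 10–340 W m⁻² morning band); cloudy days attenuated by
  U(0.05, 0.3). Ta is a 2–20 °C sinusoid with its minimum at sunrise
  (mid-winter highveld values).
* **Tb traces**: normothermic samples Normal(37.5, 0.5) °C — free
  generator parameters, not species claims. Measurement noise 0.125 °C
  (half the logger resolution) is added to every sample; the
  physiological component is drawn at `sqrt(0.5² − 0.125²)` so the
  normothermic distribution is exactly Normal(mean, 0.5). Bouts occur
  with probability 0.5 per night, entry U(19h00, 23h00), Newtonian
  cooling toward Ta at k = 0.02 min⁻¹ (plateau within ~2 h — a standard
  small-endotherm cooling assumption; the entry model is otherwise
  unconstrained), plateau at a minimum drawn N(15.3, 6.8) truncated to
  [8.9, 25] °C (the reported mean/SD and observed extreme), and linear
  rewarming starting U(10, 90) min before sunrise at 0.15 °C min⁻¹
  endogenous rate (matching the deep-shade treatment mean, where solar
  input is smallest). Rewarming is piecewise linear because the
  estimator is a linear slope; curvature would conflate generator and
  estimator error.
* **Rewarming modes.** *Supplement*: instantaneous rate = endogenous +
  RPmax(t) from the treatment-transmitted irradiance (transmissions 1.0 /
  0.398 / 0.213). *Substitute*: when transmitted RPmax(t) ≥ a floor of
  0.05 °C min⁻¹ (within the 0.01–0.10 range inferred for passive basking
  rewarming) the animal rewarms passively at min(endogenous, RPmax);
  otherwise endogenously. This operationalises substitution as
  replacement of the heat source without rate gain — rates can only stay
  equal or fall as transmission rises — which is the testable encoding of
  the supplementation-vs-substitution contrast. A bare
  min(endogenous, RPmax) rule would *increase* with transmission and
  contradict the substitution prediction, which is why the floor exists.
* **Ground truth** records, per bout, the entry minute, the minute the
  noise-free trajectory crosses the analytic threshold, the rewarming
  onset, the mean applied warming rate over full steps (the final capped
  step would dilute it), and both drawn and realized minima.
* **Respirometry**: 1-min sampling, first-order washout (τ = 30 s,
  a multiplexed subsampler), Gaussian VO₂ noise (sd 0.02 mL min⁻¹ ≈
  0.007 W). BMR recordings include random activity bouts so only quiet
  stretches reach basal level; NST responses rise linearly to the peak by
  15 min, hold to 45 min, then decay; Msum ramps cool at 10 °C h⁻¹ with
  power climbing linearly to the plateau.

**What the synthetic tests establish — and don't.** Green recovery tests
show the estimators are unbiased and precise *for data generated under
the model's own assumptions* (exact-normal normothermy, piecewise-linear
ramps, iid noise). They say nothing about behavioural artifacts real
loggers see (incomplete arousals, activity spikes, shade-seeking
movement, gradual drift of the normothermic setpoint), none of which are
modelled.

## Numerical choices

Histogram tie-breaks toward the warmer bin; parabolic refinement skipped
when the three-bin curvature is non-negative; bout durations computed as
below-threshold sample counts × interval (robust to trace gaps); the TNZ
grid search is exhaustive, so it matches a brute-force SSE scan to within
one grid step by construction; all generators are bit-reproducible under
a fixed seed, and paired cohorts (same seed, different treatment or mode)
share every non-solar random draw.

## Known limitations

No multi-day hibernation logic; no Bayesian/changepoint alternatives to
threshold crossing; no radiative–convective heat balance (wind, longwave,
conduction); no raw-analyzer signal processing (inputs are computed
VO₂/VCO₂ rates); sunrise times are supplied as a table, not computed from
an ephemeris; inferential statistics (mixed models, multiple comparisons)
are deliberately out of scope — the pipeline emits per-individual summary
tables ready for any stats package.
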