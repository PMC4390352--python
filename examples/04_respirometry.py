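"""Metabolic endpoints from synthetic open-flow respirometry recordings.

BMR from a long thermoneutral run, NST capacity from paired noradrenalin/
saline injections, summit metabolism from a helox cold ramp, and the
thermoneutral-zone breakpoint from RMR-vs-Ta data.
"""

import numpy as np

import heliotherm as ht

# --- BMR: minimum 10-min running mean over an 8-h recording
bmr_rec = ht.baseline_correct(
    ht.simulate_respirometry("bmr", {"bmr_w": 0.26}, seed=4)
)
bmr = ht.extract_bmr(bmr_rec)
print(f"BMR                : {bmr:.3f} W (generated at 0.260 W)")

# --- NST capacity: NA peak minus SAL peak
na = ht.baseline_correct(
    ht.simulate_respirometry("nst", {"rmr_w": 0.40, "peak_w": 1.00}, seed=5)
)
sal = ht.baseline_correct(
    ht.simulate_respirometry("nst", {"rmr_w": 0.40, "peak_w": 0.50}, seed=6)
)
nst = ht.nst_analysis(na, sal)
print(f"RMR                : {nst.rmr:.3f} W")
print(f"NA / SAL peaks     : {nst.na_peak:.3f} / {nst.sal_peak:.3f} W")
print(f"NST capacity       : {nst.nst_capacity:.3f} W (NA minus SAL)")
print(f"NA dose (52.4 g)   : {ht.na_dose(52.4):.2f} mg/kg")

# --- Msum: helox cold-exposure plateau
msum_rec = ht.baseline_correct(
    ht.simulate_respirometry("msum", {"msum_w": 1.90}, seed=7)
)
msum = ht.extract_msum(msum_rec)
print(f"Msum               : {msum.msum:.3f} W "
      f"(plateau at Ta {msum.plateau_ta:.1f} degC)")
print(f"expansibility      : {ht.metabolic_expansibility(msum.msum, bmr):.2f} "
      "(Msum/BMR; typical mammals fall in 4-8)")

# --- TNZ lower critical temperature
rng = np.random.default_rng(8)
ta = np.repeat([20.0, 25.0, 28.0, 30.0, 33.0, 36.0], 6)
rmr = np.where(ta < 30.0, 0.26 + 0.05 * (30.0 - ta), 0.26)
fit = ht.fit_tnz_breakpoint(ta, rmr + rng.normal(0, 0.01, ta.size))
print(f"TNZ lower critical : {fit.lower_critical:.1f} degC "
      f"(slope below: {fit.slope_below:.3f} W/degC)")
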