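"""Synthetic Tb traces, weather and respirometry with known ground truth.

The study's raw logger data are not deposited, so every downstream stage is
exercised against generated records that carry the statistical structure the
analysis assumes:

* normothermic Tb samples are Normal(mean, sd) around a (optionally
  circadian-modulated) setpoint;
* on bout nights, Tb leaves the setpoint at a random evening entry time and
  cools Newtonianly toward air temperature, plateaus at a drawn minimum, and
  rewarms linearly starting at a drawn pre-sunrise time;
* the realized rewarming rate encodes the supplementation/substitution
  contrast — in *supplement* mode solar heat adds to endogenous
  thermogenesis (rate = endogenous + RPmax(t)); in *substitute* mode solar
  heat replaces it whenever passive warming is adequate
  (rate = min(endogenous, RPmax(t)) when RPmax ≥ a floor, else endogenous);
* winter weather is a per-day half-sine irradiance profile scaled so the
  clear-day 07h00–09h00 mean matches the study's 161 W m⁻², with cloudy
  days attenuated to 5–30 %.

Every drawn quantity is recorded in :class:`GroundTruth` so that recovery
tests can compare estimates with the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biophysics import BiophysicalScenario, max_passive_rewarming_rate
from .config import DEFAULT_TRANSMISSIONS, ExperimentConfig
from .io import MINUTES_PER_DAY, TbTrace, WeatherTrace

__all__ = [
    "TraceSpec",
    "GroundTruth",
    "simulate_weather",
    "simulate_tb_trace",
    "simulate_cohort",
    "simulate_respirometry",
]


@dataclass
class TraceSpec:
    """Parameters of one simulated individual's Tb record.

    Defaults describe a mid-winter eastern rock elephant shrew: 15-min
    sampling over 36 days, normothermic Tb 37.5 ± 0.5 °C, torpor on about
    half of nights with bout minima 15.3 ± 6.8 °C (truncated to the observed
    range), Newtonian entry cooling (k = 0.02 min⁻¹, plateau within ~2 h)
    and an endogenous rewarming rate of 0.15 °C min⁻¹ starting 10–90 min
    before the 06h55 sunrise.
    """

    n_days: int = 36
    normothermic_mean: float = 37.5
    normothermic_sd: float = 0.5
    circadian_amplitude: float = 0.0
    circadian_acrophase: float = 840.0  # minutes; peak setpoint at 14h00
    bout_probability_per_day: float = 0.5
    entry_window: tuple[float, float] = (1140.0, 1380.0)  # 19h00–23h00
    tb_min_mean: float = 15.3
    tb_min_sd: float = 6.8
    tb_min_range: tuple[float, float] = (8.9, 25.0)
    cooling_rate_constant: float = 0.02  # min⁻¹
    endogenous_rewarming_rate: float | tuple[float, float] = 0.15  # °C min⁻¹
    rewarming_mode: str = "supplement"
    treatment: str = "full_sun"
    sunrise_time: float = 415.0  # 06h55
    arousal_lead_window: tuple[float, float] = (10.0, 90.0)  # min before sunrise
    measurement_noise: float = 0.125  # °C, half the logger resolution
    substitution_floor: float = 0.05  # °C min⁻¹; passive rate deemed adequate
    scenario: BiophysicalScenario = field(default_factory=BiophysicalScenario)

    def __post_init__(self) -> None:
        if not 0 <= self.bout_probability_per_day <= 1:
            raise ValueError("bout_probability_per_day must be in [0, 1]")
        if self.normothermic_sd <= 0:
            raise ValueError("normothermic_sd must be > 0")
        lo = self.endogenous_rewarming_rate
        if isinstance(lo, tuple):
            if lo[0] <= 0 or lo[1] < lo[0]:
                raise ValueError("endogenous rate range must be positive and ordered")
        elif lo <= 0:
            raise ValueError("endogenous_rewarming_rate must be > 0")
        if self.rewarming_mode not in ("supplement", "substitute"):
            raise ValueError("rewarming_mode must be 'supplement' or 'substitute'")
        if not (0 <= self.entry_window[0] < self.entry_window[1] <= MINUTES_PER_DAY):
            raise ValueError("entry_window must lie within a single day")
        if self.measurement_noise >= self.normothermic_sd:
            raise ValueError("measurement_noise must be below normothermic_sd")


@dataclass
class GroundTruth:
    """True values drawn while generating a trace (one row per bout).

    Columns of ``bouts``: day, entry_time, threshold_cross_time,
    arousal_onset_time, attainment_time, true_rate, tb_min_drawn,
    tb_min_realized, endogenous_rate, truncated.
    """

    individual: str
    normothermic_mean: float
    normothermic_sd: float
    threshold_true: float
    bouts: pd.DataFrame

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    def to_csv(self, path) -> None:
        df = self.bouts.copy()
        df.insert(0, "individual", self.individual)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# weather


def simulate_weather(
    n_days: int,
    peak_irradiance: float | None = None,
    cloudy_days: set[int] = frozenset(),
    seed: int | np.random.Generator = 0,
    *,
    morning_mean_target: float = 161.0,
    sunrise: float = 415.0,
    sunset: float = 1050.0,
    ta_mean: float = 11.0,
    ta_amplitude: float = 9.0,
    step: float = 5.0,
) -> WeatherTrace:
    """Winter weather: half-sine daily irradiance and a sinusoidal Ta.

    On clear days irradiance follows ``peak · sin(π(t−sunrise)/daylength)``;
    by default the peak is chosen so the 07h00–09h00 mean equals
    ``morning_mean_target`` (161 W m⁻², the study-period morning average).
    Days listed in ``cloudy_days`` are attenuated by a factor drawn
    uniformly in [0.05, 0.3].  Air temperature is a 24-h sinusoid with its
    minimum at sunrise (winter default 2–20 °C).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    daylength = sunset - sunrise
    if peak_irradiance is None:
        tod = np.arange(420.0, 540.0, step)  # the 07h00–09h00 sample grid
        shape_mean = float(np.mean(np.sin(np.pi * (tod - sunrise) / daylength)))
        peak_irradiance = morning_mean_target / shape_mean
    if peak_irradiance <= 0:
        raise ValueError("peak_irradiance must be > 0")

    t = np.arange(0.0, n_days * MINUTES_PER_DAY, step)
    tod = t % MINUTES_PER_DAY
    day = (t // MINUTES_PER_DAY).astype(int)
    up = (tod >= sunrise) & (tod <= sunset)
    irr = np.zeros_like(t)
    irr[up] = peak_irradiance * np.sin(np.pi * (tod[up] - sunrise) / daylength)
    factors = np.ones(n_days)
    for d in sorted(cloudy_days):
        if 0 <= d < n_days:
            factors[d] = rng.uniform(0.05, 0.3)
    irr *= factors[day]
    ta = ta_mean - ta_amplitude * np.cos(2 * np.pi * (tod - sunrise) / MINUTES_PER_DAY)
    return WeatherTrace(time=t, ta=ta, irradiance=irr)


# ---------------------------------------------------------------------------
# Tb traces


def _draw_tb_min(rng: np.random.Generator, spec: TraceSpec) -> float:
    lo, hi = spec.tb_min_range
    hi = min(hi, spec.normothermic_mean - 10.0)
    for _ in range(1000):
        x = rng.normal(spec.tb_min_mean, spec.tb_min_sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(spec.tb_min_mean, lo, hi))


def simulate_tb_trace(
    spec: TraceSpec,
    weather: WeatherTrace,
    seed: int | np.random.Generator = 0,
    config: ExperimentConfig | None = None,
) -> tuple[TbTrace, GroundTruth]:
    """Generate one individual's Tb trace plus its ground truth.

    The noise-free trajectory is built at 1-min resolution, then sampled at
    the configured interval.  Measurement noise (sd ``measurement_noise``)
    is added to every sample; normothermic samples additionally receive the
    physiological scatter needed so that their total spread equals
    ``normothermic_sd`` exactly.

    ``GroundTruth.threshold_true`` is the analytic torpor threshold implied
    by the generator (mean − z·sd − offset with the config's z and offset),
    and per-bout ``threshold_cross_time`` the minute the noise-free Tb first
    falls below it.
    """
    cfg = config or ExperimentConfig()
    rng = np.random.default_rng(seed)
    n_min = spec.n_days * MINUTES_PER_DAY
    if weather.time[-1] < n_min - MINUTES_PER_DAY:
        raise ValueError("weather trace does not cover spec.n_days")

    t = np.arange(n_min, dtype=float)
    setpoint = spec.normothermic_mean + spec.circadian_amplitude * np.cos(
        2 * np.pi * (t - spec.circadian_acrophase) / MINUTES_PER_DAY
    )
    ta = weather.ta_at(t)
    irr = weather.irradiance_at(t)
    tau = DEFAULT_TRANSMISSIONS.get(spec.treatment)
    if config is not None:
        tau = config.treatment_transmissions.get(spec.treatment, tau)
    if tau is None:
        raise ValueError(f"unknown treatment {spec.treatment!r}")
    # RPmax per unit irradiance for this animal; scales linearly with G
    rp_unit = max_passive_rewarming_rate(spec.scenario.replace(irradiance=1.0))

    tb = setpoint.copy()
    torpid = np.zeros(n_min, dtype=bool)
    thr_true = (
        spec.normothermic_mean
        - cfg.threshold_z * spec.normothermic_sd
        - cfg.threshold_offset
    )

    rows = []
    for d in range(spec.n_days - 1):
        if rng.random() >= spec.bout_probability_per_day:
            continue
        entry = int(d * MINUTES_PER_DAY + rng.uniform(*spec.entry_window))
        sunrise_abs = (d + 1) * MINUTES_PER_DAY + spec.sunrise_time
        onset = int(sunrise_abs - rng.uniform(*spec.arousal_lead_window))
        tb_min_drawn = _draw_tb_min(rng, spec)
        er = spec.endogenous_rewarming_rate
        endog = float(rng.uniform(*er)) if isinstance(er, tuple) else float(er)

        # Newtonian cooling toward Ta, floored at the drawn bout minimum
        k = spec.cooling_rate_constant
        x = tb[entry]
        cross = None
        for m in range(entry, onset):
            x = max(tb_min_drawn, x - k * (x - ta[m]))
            tb[m + 1] = x
            if cross is None and x < thr_true:
                cross = m + 1
        tb_min_real = float(tb[entry : onset + 1].min())

        # linear rewarming at the realized (mode-dependent) rate
        m = onset
        x = tb[onset]
        applied_rates = []
        while m + 1 < n_min and x < setpoint[m + 1]:
            rp = rp_unit * irr[m] * tau
            if spec.rewarming_mode == "supplement":
                rate = endog + rp
            else:
                rate = min(endog, rp) if rp >= spec.substitution_floor else endog
            if x + rate < setpoint[m + 1]:
                applied_rates.append(rate)  # full, uncapped warming step
            x = min(x + rate, setpoint[m + 1])
            m += 1
            tb[m] = x
        attain = m
        truncated = attain >= n_min - 1 and x < setpoint[attain]
        torpid[entry : attain + 1] = True
        # the realized rate is the mean applied warming rate over full steps;
        # the final (capped) step would otherwise dilute it
        true_rate = float(np.mean(applied_rates)) if applied_rates else np.nan
        rows.append(
            {
                "day": d,
                "entry_time": float(entry),
                "threshold_cross_time": float(cross) if cross is not None else np.nan,
                "arousal_onset_time": float(onset),
                "attainment_time": float(attain),
                "true_rate": float(true_rate),
                "tb_min_drawn": tb_min_drawn,
                "tb_min_realized": tb_min_real,
                "endogenous_rate": endog,
                "truncated": truncated,
            }
        )

    idx = np.arange(0, n_min, int(cfg.sampling_interval))
    obs = tb[idx] + rng.normal(0.0, spec.measurement_noise, size=idx.size)
    physio_sd = math.sqrt(spec.normothermic_sd**2 - spec.measurement_noise**2)
    normo = ~torpid[idx]
    obs[normo] += rng.normal(0.0, physio_sd, size=int(normo.sum()))

    columns = [
        "day", "entry_time", "threshold_cross_time", "arousal_onset_time",
        "attainment_time", "true_rate", "tb_min_drawn", "tb_min_realized",
        "endogenous_rate", "truncated",
    ]
    truth = GroundTruth(
        individual=f"sim-{spec.treatment}",
        normothermic_mean=spec.normothermic_mean,
        normothermic_sd=spec.normothermic_sd,
        threshold_true=thr_true,
        bouts=pd.DataFrame(rows, columns=columns),
    )
    trace = TbTrace(individual=truth.individual, time=t[idx], tb=obs)
    return trace, truth


def simulate_cohort(
    n_individuals: int,
    spec: TraceSpec,
    weather: WeatherTrace,
    seed: int = 0,
    config: ExperimentConfig | None = None,
) -> list[tuple[TbTrace, GroundTruth]]:
    """Generate ``n_individuals`` independent traces from one spec.

    Individual ``i`` uses the derived seed ``seed + i``, so cohorts generated
    with the same base seed but different treatments/modes are *paired*:
    every random draw that does not depend on the treatment (entry times,
    bout minima, endogenous rates) is identical across the cohorts, and only
    the solar contribution differs.
    """
    out = []
    for i in range(n_individuals):
        trace, truth = simulate_tb_trace(spec, weather, seed=seed + i, config=config)
        trace.individual = f"{truth.individual}-{i:02d}"
        truth.individual = trace.individual
        out.append((trace, truth))
    return out


# ---------------------------------------------------------------------------
# respirometry

from .respirometry import RespirometryRecording  # noqa: E402  (cycle-free: types only)

#: Default measurement noise on VO2, mL O2 min⁻¹ (≈0.007 W at RER 0.85).
VO2_NOISE_SD = 0.02


def _w_to_vo2(watts: np.ndarray, rer: float) -> np.ndarray:
    return watts * 60.0 / (16.0 + 5.164 * rer)


def _washout(levels: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """First-order analyzer/chamber washout applied to an ideal level series."""
    out = np.empty_like(levels)
    out[0] = levels[0]
    a = math.exp(-1.0 / tau)
    for i in range(1, len(levels)):
        out[i] = levels[i] + (out[i - 1] - levels[i]) * a
    return out


def simulate_respirometry(
    kind: str,
    true_params: dict,
    seed: int | np.random.Generator = 0,
) -> RespirometryRecording:
    """Generate a phase-marked gas-exchange recording of a given protocol.

    Parameters
    ----------
    kind
        ``"bmr"`` — baseline / 8-h chamber / baseline, quiet level =
        ``bmr_w`` with occasional activity bouts;
        ``"nst"`` — baseline / 2-h RMR / 1.5-h post-injection / baseline,
        injection response rising to ``peak_w`` and holding;
        ``"msum"`` — helox baseline then a cold ramp (Ta falling 10 °C h⁻¹)
        during which metabolic power climbs to the ``msum_w`` plateau.
    true_params
        ``bmr``: bmr_w, [rer=0.85, mass=52.4, noise_sd, drift_w, hours=8];
        ``nst``: rmr_w, peak_w, [rer, mass, noise_sd];
        ``msum``: msum_w, [start_w=0.6, plateau_ta, ta_start=20, rer=0.665,
        mass, noise_sd].

    All recordings are sampled at 1-min resolution with first-order washout
    at phase transitions and Gaussian noise on VO2 (default sd 0.02 mL min⁻¹).
    """
    rng = np.random.default_rng(seed)
    noise = float(true_params.get("noise_sd", VO2_NOISE_SD))
    mass = float(true_params.get("mass", 52.4))

    if kind == "bmr":
        rer = float(true_params.get("rer", 0.85))
        bmr_w = float(true_params["bmr_w"])
        hours = float(true_params.get("hours", 8.0))
        n_chamber = int(hours * 60)
        w = np.full(n_chamber, bmr_w)
        # activity bouts elevate metabolism; quiet stretches reach basal level
        n_bouts = max(1, int(hours))
        for _ in range(n_bouts):
            s = rng.integers(0, n_chamber - 40)
            w[s : s + int(rng.uniform(15, 40))] *= rng.uniform(1.5, 3.0)
        phases = ["baseline"] * 10 + ["chamber"] * n_chamber + ["baseline"] * 10
        levels = np.concatenate([np.zeros(10), _w_to_vo2(w, rer), np.zeros(10)])
        ta = np.full(len(levels), 30.0)
    elif kind == "nst":
        rer = float(true_params.get("rer", 0.85))
        rmr_w = float(true_params["rmr_w"])
        peak_w = float(true_params["peak_w"])
        n_rmr, n_inj = 120, 90
        w_rmr = np.full(n_rmr, rmr_w)
        ti = np.arange(n_inj, dtype=float)
        rise = np.clip(ti / 15.0, 0.0, 1.0)
        decay = np.where(ti > 45, np.exp(-(ti - 45) / 30.0), 1.0)
        w_inj = rmr_w + (peak_w - rmr_w) * rise * decay
        phases = (
            ["baseline"] * 5 + ["rmr"] * n_rmr + ["injection"] * n_inj + ["baseline"] * 5
        )
        levels = np.concatenate(
            [np.zeros(5), _w_to_vo2(w_rmr, rer), _w_to_vo2(w_inj, rer), np.zeros(5)]
        )
        ta = np.full(len(levels), 25.0)
    elif kind == "msum":
        rer = float(true_params.get("rer", 0.665))
        msum_w = float(true_params["msum_w"])
        start_w = float(true_params.get("start_w", 0.6))
        ta_start = float(true_params.get("ta_start", 20.0))
        plateau_ta = float(true_params.get("plateau_ta", 2.0))
        cool = 10.0 / 60.0  # °C min⁻¹
        n_base = 7
        n_ramp = int((ta_start - plateau_ta) / cool) + 25
        ta_ramp = ta_start - cool * np.arange(n_ramp)
        slope = (msum_w - start_w) / (ta_start - plateau_ta)
        w = np.minimum(msum_w, start_w + slope * (ta_start - ta_ramp))
        phases = (
            ["helox_baseline"] * n_base + ["cold_ramp"] * n_ramp
            + ["helox_baseline"] * 5
        )
        levels = np.concatenate([np.zeros(n_base), _w_to_vo2(w, rer), np.zeros(5)])
        ta = np.concatenate([np.full(n_base, ta_start), ta_ramp, np.full(5, ta_ramp[-1])])
    else:
        raise ValueError(f"unknown respirometry kind {kind!r}")

    vo2 = _washout(levels) + rng.normal(0.0, noise, size=len(levels))
    vo2 = np.clip(vo2, 0.0, None)
    return RespirometryRecording(
        time=np.arange(len(vo2), dtype=float),
        vo2=vo2,
        vco2=vo2 * rer,
        chamber_ta=ta,
        phase=np.array(phases),
        animal_mass=mass,
    )
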