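"""Open-flow respirometry: gas exchange to metabolic power and its extremes.

Converts VO2 traces to watts with an RER-dependent Joule equivalent
(16 + 5.164·RER J per mL O2), corrects analyzer drift against bracketing
baselines, and extracts the protocol endpoints:

* **BMR** — minimum running-mean power over a long thermoneutral recording;
* **NST capacity** — peak metabolic response to a noradrenalin injection
  minus the peak response to a saline control;
* **Msum** — maximum cold-induced power in a helox atmosphere under a
  sliding cold-exposure ramp, with plateau detection;
* **metabolic expansibility** — Msum/BMR;
* **TNZ lower critical temperature** — breakpoint of a continuous
  two-segment regression of resting metabolic rate on air temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

logger = logging.getLogger("heliotherm.respirometry")

__all__ = [
    "RespirometryRecording",
    "MetabolicSummary",
    "gas_to_watts",
    "baseline_correct",
    "extract_bmr",
    "nst_analysis",
    "na_dose",
    "extract_msum",
    "fit_tnz_breakpoint",
    "metabolic_expansibility",
]

#: RER range outside which values are physiologically surprising and flagged
#: (but never clamped; sub-0.71 values do occur during acute cold stress).
RER_EXPECTED = (0.71, 1.00)


@dataclass
class RespirometryRecording:
    """A phase-marked gas-exchange trace.

    ``time`` in minutes, ``vo2``/``vco2`` in mL min⁻¹ (STP), ``chamber_ta``
    in °C, ``phase`` a per-sample label (``baseline``, ``chamber``, ``rmr``,
    ``injection``, ``helox_baseline``, ``cold_ramp``).
    """

    time: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    chamber_ta: np.ndarray
    phase: np.ndarray
    animal_mass: float = 52.4

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        self.chamber_ta = np.asarray(self.chamber_ta, dtype=float)
        self.phase = np.asarray(self.phase)
        n = len(self.time)
        if not all(len(a) == n for a in (self.vo2, self.vco2, self.chamber_ta, self.phase)):
            raise ValueError("all channels must share the recording length")
        if np.any(self.vo2 < 0):
            raise ValueError("vo2 must be >= 0")
        if self.animal_mass <= 0:
            raise ValueError("animal_mass must be > 0")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time))) if len(self) > 1 else 1.0

    @property
    def rer(self) -> float:
        """Mean respiratory exchange ratio VCO2/VO2 over animal phases."""
        sel = ~np.isin(self.phase, ("baseline", "helox_baseline"))
        v = self.vo2[sel]
        if v.sum() <= 0:
            return 0.85
        return float(self.vco2[sel].sum() / v.sum())

    def watts(self, rer: float | None = None) -> np.ndarray:
        """Metabolic power per sample, W."""
        r = self.rer if rer is None else rer
        return gas_to_watts(self.vo2, r)


class NSTResult(NamedTuple):
    rmr: float
    na_peak: float
    sal_peak: float
    nst_capacity: float
    na_minus_rmr: float


class MsumResult(NamedTuple):
    msum: float
    plateau_ta: float
    plateau_found: bool


class TnzFit(NamedTuple):
    lower_critical: float
    intercept: float
    slope_below: float
    slope_above: float
    sse: float
    warning: str | None


@dataclass
class MetabolicSummary:
    """Per-individual heat-production summary."""

    individual: str
    bmr: float | None = None
    rmr: float | None = None
    na_peak: float | None = None
    sal_peak: float | None = None
    nst_capacity: float | None = None
    msum: float | None = None
    metabolic_expansibility: float | None = None
    rer: float | None = None
    tnz_lower_critical: float | None = None
    flags: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = []
        if self.rer is not None and not RER_EXPECTED[0] <= self.rer <= RER_EXPECTED[1]:
            self.flags.append(f"rer_outside_expected_range:{self.rer:.3f}")
        if self.nst_capacity is not None and self.nst_capacity < 0:
            self.flags.append("negative_nst_capacity")
        if self.msum is not None and self.bmr is not None and self.msum < self.bmr:
            self.flags.append("msum_below_bmr")


# ---------------------------------------------------------------------------


def gas_to_watts(vo2, rer: float):
    """Convert oxygen consumption to power: W = VO2 · (16 + 5.164·RER) / 60.

    ``vo2`` in mL O2 min⁻¹ (scalar or array).  RER outside 0.71–1.00 is
    permitted but logged; outside 0.3–1.3 it is rejected as implausible.
    """
    vo2 = np.asarray(vo2, dtype=float)
    if np.any(vo2 < 0):
        raise ValueError("vo2 must be >= 0")
    if not 0.3 <= rer <= 1.3:
        raise ValueError(f"implausible RER {rer}")
    if not RER_EXPECTED[0] <= rer <= RER_EXPECTED[1]:
        logger.warning("RER %.3f outside the expected 0.71–1.00 range", rer)
    out = vo2 * (16.0 + 5.164 * rer) / 60.0
    return float(out) if out.ndim == 0 else out


def baseline_correct(rec: RespirometryRecording) -> RespirometryRecording:
    """Subtract analyzer drift interpolated between baseline segments.

    The mean VO2 (and VCO2) of each baseline phase is anchored at the
    segment's midpoint time; drift between successive anchors is linearly
    interpolated (and extrapolated as constant beyond the outermost
    baselines) and subtracted from the whole trace.  The first ``settle``
    minutes of each baseline segment are discarded before averaging, since
    they carry washout from the preceding animal channel.  With a single
    baseline a constant offset is removed and a warning logged.
    """
    base_labels = ("baseline", "helox_baseline")
    is_base = np.isin(rec.phase, base_labels)
    if not is_base.any():
        raise ValueError("no baseline phase in recording")
    settle = 3.0  # minutes of switch transient discarded per baseline
    # contiguous baseline segments
    idx = np.flatnonzero(is_base)
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits], [idx[-1]]])
    anchors_t, anchors_o2, anchors_co2 = [], [], []
    for s, e in zip(starts, ends):
        t_seg = rec.time[s : e + 1]
        trim = min(settle, 0.5 * (t_seg[-1] - t_seg[0]))
        keep = slice(s + int(np.searchsorted(t_seg, t_seg[0] + trim)), e + 1)
        anchors_t.append(rec.time[keep].mean())
        anchors_o2.append(rec.vo2[keep].mean())
        anchors_co2.append(rec.vco2[keep].mean())
    if len(anchors_t) == 1:
        logger.warning("single baseline: applying constant-offset correction")
    drift_o2 = np.interp(rec.time, anchors_t, anchors_o2)
    drift_co2 = np.interp(rec.time, anchors_t, anchors_co2)
    return RespirometryRecording(
        time=rec.time.copy(),
        vo2=np.clip(rec.vo2 - drift_o2, 0.0, None),
        vco2=np.clip(rec.vco2 - drift_co2, 0.0, None),
        chamber_ta=rec.chamber_ta.copy(),
        phase=rec.phase.copy(),
        animal_mass=rec.animal_mass,
    )


def _running_mean(x: np.ndarray, n: int) -> np.ndarray:
    if n > len(x):
        raise ValueError("window longer than series")
    c = np.convolve(x, np.ones(n) / n, mode="valid")
    return c


def extract_bmr(
    rec: RespirometryRecording,
    window: float = 10.0,
    rer: float | None = None,
    equilibration: float = 15.0,
) -> float:
    """Basal metabolic rate: minimum running-mean power over the recording.

    ``window`` is the running-mean width in minutes (default 10).  The first
    ``equilibration`` minutes of the animal phase are skipped so that the
    chamber-washout transient cannot masquerade as the basal minimum.
    """
    animal = ~np.isin(rec.phase, ("baseline", "helox_baseline"))
    w = rec.watts(rer)[animal]
    t = rec.time[animal]
    keep = t >= t[0] + equilibration
    w = w[keep]
    n = max(2, int(round(window / rec.dt)))
    if len(w) < 2 * n:
        raise ValueError(
            f"recording too short: {len(w)} samples for a {n}-sample window"
        )
    return float(_running_mean(w, n).min())


def nst_analysis(
    rec_na: RespirometryRecording,
    rec_sal: RespirometryRecording,
    window: float = 10.0,
    rer: float | None = None,
) -> NSTResult:
    """NST capacity from paired noradrenalin and saline recordings.

    RMR is the mean power over the pre-injection phase of the NA recording;
    each peak is the maximum ``window``-minute running mean within 1.5 h
    after its injection mark.  Capacity is NA peak − SAL peak; the
    alternative definition NA peak − RMR is reported alongside.
    """
    def peak(rec: RespirometryRecording) -> float:
        if "injection" not in rec.phase:
            raise ValueError("recording lacks an injection phase mark")
        w = rec.watts(rer)
        inj = np.flatnonzero(rec.phase == "injection")
        t0 = rec.time[inj[0]]
        sel = inj[rec.time[inj] <= t0 + 90.0]
        n = max(2, int(round(window / rec.dt)))
        if len(sel) < n:
            raise ValueError("post-injection phase shorter than the peak window")
        return float(_running_mean(w[sel], n).max())

    if "rmr" not in rec_na.phase:
        raise ValueError("NA recording lacks an RMR phase mark")
    rmr = float(rec_na.watts(rer)[rec_na.phase == "rmr"].mean())
    na_peak, sal_peak = peak(rec_na), peak(rec_sal)
    capacity = na_peak - sal_peak
    if capacity < 0:
        logger.warning("negative NST capacity (%.3f W): flagged", capacity)
    return NSTResult(rmr, na_peak, sal_peak, capacity, na_peak - rmr)


def na_dose(body_mass: float, exponent: float = 0.4, coefficient: float = 2.53) -> float:
    """Noradrenalin dose in mg per kg: ``2.53 · Mb^exponent`` (Mb in g).

    The printed exponent is +0.4; the conventional mass-specific dosing form
    uses −0.4 (dose per kg decreasing with mass).  Both are supported via
    ``exponent``; neither is asserted as correct.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    return coefficient * body_mass**exponent


def extract_msum(
    rec: RespirometryRecording,
    window: float = 5.0,
    rer: float | None = None,
    slope_tol: float = 0.01,
) -> MsumResult:
    """Summit metabolism from a helox cold-exposure ramp.

    Msum is the maximum ``window``-minute running mean of power during the
    ``cold_ramp`` phase.  The plateau is detected where the running mean's
    slope against chamber Ta changes sign or falls below ``slope_tol``
    (W per °C) over consecutive windows; if the power is still climbing when
    the ramp ends, the result is flagged ``plateau_found=False``.
    """
    ramp = rec.phase == "cold_ramp"
    if not ramp.any():
        raise ValueError("recording lacks a cold_ramp phase")
    w = rec.watts(rer)[ramp]
    ta = rec.chamber_ta[ramp]
    n = max(2, int(round(window / rec.dt)))
    if len(w) < 2 * n:
        raise ValueError("cold ramp too short for the running-mean window")
    rm = _running_mean(w, n)
    rm_ta = _running_mean(ta, n)
    msum = float(rm.max())

    plateau_found = False
    plateau_ta = float(rm_ta[int(np.argmax(rm))])
    # chunk-wise slope of running mean vs Ta; Ta decreases along the ramp so
    # the rise phase has dW/dTa < 0 and the plateau slope ~ 0
    step = n
    for s in range(0, len(rm) - step, step):
        dta = rm_ta[s + step] - rm_ta[s]
        if dta == 0:
            continue
        slope = (rm[s + step] - rm[s]) / dta
        if slope >= 0 or abs(slope) < slope_tol:
            plateau_found = True
            plateau_ta = float(rm_ta[s])
            break
    if not plateau_found:
        logger.warning("no plateau before ramp end; Msum may be underestimated")
    return MsumResult(msum, plateau_ta, plateau_found)


def fit_tnz_breakpoint(
    ta, rmr, grid_step: float = 0.1, flat_above: bool = False
) -> TnzFit:
    """Continuous two-segment least-squares fit of RMR on Ta.

    The breakpoint (lower critical temperature of the thermoneutral zone) is
    found by dense grid search over the interior Ta range, minimising the
    total SSE of the hinge model

        RMR = a + b₁·min(Ta − c, 0) + b₂·max(Ta − c, 0).

    With ``flat_above=True`` the upper segment is constrained horizontal
    (b₂ = 0).  Warnings are raised (as fit flags) for a breakpoint at the
    range edge and for data indistinguishable from a single line.
    """
    ta = np.asarray(ta, dtype=float)
    rmr = np.asarray(rmr, dtype=float)
    if len(np.unique(ta)) < 5:
        raise ValueError("need >= 5 distinct Ta values")
    lo, hi = ta.min() + grid_step, ta.max() - grid_step
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    def sse_at(c: float) -> tuple[float, np.ndarray]:
        below = np.minimum(ta - c, 0.0)
        above = np.maximum(ta - c, 0.0)
        cols = [np.ones_like(ta), below] + ([] if flat_above else [above])
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, rmr, rcond=None)
        resid = rmr - X @ beta
        return float(resid @ resid), beta

    results = [sse_at(c) for c in grid]
    sses = np.array([r[0] for r in results])
    k = int(np.argmin(sses))
    best_sse, beta = results[k]
    bp = float(grid[k])

    # single straight line for comparison
    X1 = np.column_stack([np.ones_like(ta), ta])
    b1, *_ = np.linalg.lstsq(X1, rmr, rcond=None)
    sse_line = float(np.sum((rmr - X1 @ b1) ** 2))

    warning = None
    if k in (0, len(grid) - 1):
        warning = "breakpoint_at_range_edge"
    elif sse_line - best_sse < 1e-12 + 1e-3 * sse_line:
        warning = "no_breakpoint_evidence"
    if warning:
        logger.warning("TNZ fit: %s", warning)
    slope_above = 0.0 if flat_above else float(beta[2])
    return TnzFit(bp, float(beta[0]), float(beta[1]), slope_above, best_sse, warning)


def metabolic_expansibility(msum: float, bmr: float) -> float:
    """Metabolic expansibility ME = Msum / BMR (unitless)."""
    if bmr <= 0:
        raise ValueError("bmr must be > 0")
    return msum / bmr
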