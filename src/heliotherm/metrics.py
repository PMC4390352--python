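"""Heterothermy metrics: HI, rewarming rates, daily minima, timing.

The Heterothermy Index summarises how far and how often Tb departs from the
modal normothermic temperature:

    HI = sqrt( Σᵢ (Tb_mod − Tb_i)² / (n − 1) )

over all valid samples i — normothermic and torpid alike.  It is a pure
distributional statistic (invariant to reordering of samples) measured in
°C, zero for perfect homeothermy at the mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detection import NormothermyModel, TorporBout, bout_days, torpor_frequency
from .io import MINUTES_PER_DAY, TbTrace

logger = logging.getLogger("heliotherm.metrics")

__all__ = [
    "HeterothermySummary",
    "heterothermy_index",
    "rewarming_rate",
    "minutes_before_sunrise",
    "daily_tb_min",
    "summarize_individual",
]


@dataclass
class HeterothermySummary:
    """Per-individual heterothermy summary (one row of the output table)."""

    individual: str
    hi: float
    torpor_frequency: float
    mean_rewarming_rate: float | None
    mean_bout_duration: float | None
    tb_min_daily: list[tuple[int, float]] = field(default_factory=list)
    n_bouts: int = 0

    def __post_init__(self) -> None:
        if self.hi < 0:
            raise ValueError("hi must be >= 0")
        if not 0 <= self.torpor_frequency <= 100:
            raise ValueError("torpor_frequency must be within [0, 100]")


def heterothermy_index(
    trace: TbTrace, modal_tb: float, sub_modal_only: bool = False
) -> float:
    """Heterothermy Index in °C.

    Parameters
    ----------
    trace
        Body-temperature trace; only valid samples enter the sum.
    modal_tb
        The individual's modal normothermic Tb.
    sub_modal_only
        If True, restrict the sum to samples below ``modal_tb`` (a variant
        used by some studies for cross-study comparison).  The default
        includes every sample, as the index is defined.
    """
    vals = trace.valid_tb
    if sub_modal_only:
        vals = vals[vals < modal_tb]
    n = len(vals)
    if n < 2:
        raise ValueError(f"need >= 2 samples for HI, got {n}")
    return float(np.sqrt(np.sum((modal_tb - vals) ** 2) / (n - 1)))


def rewarming_rate(trace: TbTrace, bout: TorporBout) -> float | None:
    """OLS slope of Tb on time over the arousal ramp, °C min⁻¹.

    The regression runs from arousal onset to the attainment of normothermic
    Tb, using the strict interior of that window.  The bracketing samples
    are excluded because under discrete sampling they need not lie on the
    warming ramp: the onset sample is the last *torpid* sample (still at the
    plateau minimum, with the continuous ramp starting somewhere inside the
    following interval), and the attainment sample can fall past the ramp's
    end when the bound is reached between samples.  Either off-ramp endpoint
    acts as a hinge that biases the slope low by up to ~5 % at 15-min
    sampling; the interior samples all lie on the ramp.  With fewer than 3
    interior samples (or no attainment observed) the bout is flagged and the
    rate left undefined.  The computed rate is stored on
    ``bout.rewarming_rate``.
    """
    if bout.attainment_time is None:
        bout.rate_flag = "no_attainment"
        return None
    t = trace.valid_time
    tb = trace.valid_tb
    sel = (t > bout.arousal_onset_time) & (t < bout.attainment_time)
    if sel.sum() < 3:
        bout.rate_flag = "too_few_samples"
        return None
    tw, yw = t[sel], tb[sel]
    if np.ptp(tw) == 0:
        bout.rate_flag = "degenerate_window"
        return None
    slope = stats.linregress(tw, yw).slope
    bout.rewarming_rate = float(slope)
    return float(slope)


def minutes_before_sunrise(event_time: float, sunrise_time: float) -> float:
    """Sunrise minus event time on the same day's clock (positive = before)."""
    return sunrise_time - event_time


def daily_tb_min(trace: TbTrace) -> list[tuple[int, float]]:
    """Minimum valid Tb per calendar day, as (day index, °C) pairs.

    Days without any valid sample are omitted with a warning.
    """
    t, tb = trace.valid_time, trace.valid_tb
    out: list[tuple[int, float]] = []
    all_days = range(trace.n_days)
    days = (t // MINUTES_PER_DAY).astype(int)
    for d in all_days:
        sel = days == d
        if not sel.any():
            logger.warning("%s: day %d has no valid samples", trace.individual, d)
            continue
        out.append((d, float(tb[sel].min())))
    return out


def summarize_individual(
    trace: TbTrace,
    bouts: list[TorporBout],
    model: NormothermyModel,
    excluded_days: set[int] = frozenset(),
) -> HeterothermySummary:
    """Aggregate one individual's trace and bouts into a summary row.

    Rate and duration means are taken over bouts with a defined rewarming
    rate; rates are computed first if absent.  Torpor frequency counts entry
    days among non-excluded observed days.
    """
    for b in bouts:
        if b.rewarming_rate is None and b.rate_flag is None:
            rewarming_rate(trace, b)
    rates = [b.rewarming_rate for b in bouts if b.rewarming_rate is not None]
    durations = [b.duration for b in bouts]
    freq = torpor_frequency(bout_days(bouts, trace.n_days), excluded_days)
    return HeterothermySummary(
        individual=trace.individual,
        hi=heterothermy_index(trace, model.modal_tb),
        torpor_frequency=freq,
        mean_rewarming_rate=float(np.mean(rates)) if rates else None,
        mean_bout_duration=float(np.mean(durations)) if durations else None,
        tb_min_daily=daily_tb_min(trace),
        n_bouts=len(bouts),
    )
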