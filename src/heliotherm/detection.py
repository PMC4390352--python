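"""Torpor threshold estimation and bout segmentation.

Small heterotherms have a strongly right-skewed, often bimodal Tb
distribution: a tight upper (normothermic) mode and a broad low-temperature
tail contributed by torpor.  Rather than imposing a fixed cut-off, each
individual's torpor threshold is derived from its own distribution:

1. find the *upper mode* of the Tb histogram;
2. fit a normal distribution to all samples at or above that mode
   (half-normal reflection, mean pinned to the mode);
3. take the lower bound of the two-sided 99 % interval of that fit
   (mode − 2.576·sd);
4. subtract a fixed 3 °C safety offset.

Temperatures below the resulting threshold are classified torpid.  A bout
runs from the first sample below threshold (entry) to the first subsequent
sample back at/above it; brief above-threshold chatter between runs is
merged and too-short runs discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import ExperimentConfig
from .io import MINUTES_PER_DAY, TbTrace, WeatherTrace

logger = logging.getLogger("heliotherm.detection")

__all__ = [
    "NormothermyModel",
    "TorporBout",
    "estimate_upper_mode",
    "fit_normothermic_model",
    "segment_bouts",
    "torpor_frequency",
    "bout_days",
    "classify_cloudy_mornings",
]

#: Minimum fraction of all samples a histogram bin must hold to qualify as a
#: candidate mode (guards against noise spikes in sparse bins).
MODE_PROMINENCE = 0.05


@dataclass
class NormothermyModel:
    """Fitted normothermic Tb distribution and derived torpor threshold."""

    individual: str
    modal_tb: float
    fitted_sd: float
    lower_99_bound: float
    torpor_threshold: float
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.fitted_sd < 0:
            raise ValueError("fitted_sd must be >= 0")
        if self.lower_99_bound > self.modal_tb:
            raise ValueError("lower_99_bound must not exceed modal_tb")


@dataclass
class TorporBout:
    """One torpor bout.

    Times are minutes since midnight of day 0.  ``duration`` is the total
    time spent below threshold within the bout (merged above-threshold gaps
    excluded).  ``rewarming_rate`` is filled by
    :func:`heliotherm.metrics.rewarming_rate`.
    """

    individual: str
    entry_time: float
    arousal_onset_time: float
    return_to_threshold_time: float
    attainment_time: float | None
    duration: float
    tb_min: float
    rewarming_rate: float | None = None
    rate_flag: str | None = field(default=None)

    @property
    def entry_day(self) -> int:
        return int(self.entry_time // MINUTES_PER_DAY)


def estimate_upper_mode(trace: TbTrace, bin_width: float = 0.5) -> float:
    """Centre of the highest-temperature local maximum of the Tb histogram.

    Candidate modes are local maxima holding at least 5 % of all valid
    samples; ties between equal-height upper bins are broken toward the
    higher temperature.  The returned value is refined by fitting a parabola
    through the three bins around the winning maximum.

    Raises
    ------
    ValueError
        If fewer than 100 valid samples are available (the distribution fit
        would be unreliable).
    """
    vals = trace.valid_tb
    if len(vals) < 100:
        raise ValueError(f"need >= 100 valid samples, got {len(vals)}")
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < bin_width:
        # Degenerate spread: the histogram has a single occupied bin and its
        # centre would quantise the answer; report the median instead.
        return float(np.median(vals))
    # edges anchored at the sample minimum so that shifting every sample by a
    # constant shifts the estimated mode by exactly that constant
    n_bins = int(np.ceil((hi - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    padded = np.concatenate([[0], counts, [0]])
    floor = MODE_PROMINENCE * len(vals)
    best = None
    for i in range(len(counts)):
        c = padded[i + 1]
        if c >= padded[i] and c >= padded[i + 2] and c >= floor:
            best = i  # keep scanning: last qualifying bin = highest temperature
    if best is None:
        best = int(np.argmax(counts))
    cl, cm, cr = padded[best], padded[best + 1], padded[best + 2]
    denom = cl - 2 * cm + cr
    mode = centers[best]
    if denom < 0:
        mode = mode + 0.5 * bin_width * (cl - cr) / denom
    return float(mode)


def fit_normothermic_model(trace: TbTrace, config: ExperimentConfig) -> NormothermyModel:
    """Fit the normothermic distribution and derive the torpor threshold.

    The fit uses only samples at or above the upper mode: with the mean
    pinned to the mode, the upper half-sample estimates the sd by reflection,
    ``sd = sqrt(mean((x − mode)²))`` over ``x ≥ mode``.  Then

        lower_99_bound  = mode − threshold_z · sd
        torpor_threshold = lower_99_bound − threshold_offset
    """
    mode = estimate_upper_mode(trace, config.histogram_bin)
    vals = trace.valid_tb
    upper = vals[vals >= mode]
    if len(upper) < 30:
        raise ValueError(
            f"only {len(upper)} samples at/above the mode; need >= 30 for the fit"
        )
    sd = float(np.sqrt(np.mean((upper - mode) ** 2)))
    bound = mode - config.threshold_z * sd
    return NormothermyModel(
        individual=trace.individual,
        modal_tb=mode,
        fitted_sd=sd,
        lower_99_bound=bound,
        torpor_threshold=bound - config.threshold_offset,
        n_samples=len(vals),
    )


def _runs_below(below: np.ndarray) -> list[tuple[int, int]]:
    """Start/end (inclusive) index pairs of consecutive True runs."""
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def segment_bouts(
    trace: TbTrace, model: NormothermyModel, config: ExperimentConfig
) -> list[TorporBout]:
    """Segment a Tb trace into torpor bouts against the fitted threshold.

    Entry is the first sample below threshold in a below-threshold run;
    arousal is the return to the threshold value.  Runs separated by less
    than ``merge_gap`` minutes above threshold are merged; merged bouts
    shorter than ``min_bout_duration`` (time below threshold) are discarded.
    The arousal *onset* is the last local minimum of Tb preceding the upward
    crossing (found by walking back from the crossing while Tb decreases),
    and ``attainment_time`` the first sample at/above the lower 99 % bound
    after onset.  A trailing run that never returns to threshold before the
    trace ends is discarded (its arousal is unobserved).
    """
    if trace.individual != model.individual:
        raise ValueError(
            f"trace individual {trace.individual!r} does not match model "
            f"{model.individual!r}"
        )
    t = trace.valid_time
    tb = trace.valid_tb
    thr = model.torpor_threshold
    below = tb < thr
    runs = _runs_below(below)
    if not runs:
        return []

    interval = config.sampling_interval
    # merge runs separated by short above-threshold gaps
    merged: list[list[tuple[int, int]]] = [[runs[0]]]
    for run in runs[1:]:
        prev_end = merged[-1][-1][1]
        gap = t[run[0]] - t[prev_end] - interval  # time spent at/above threshold
        if gap < config.merge_gap:
            merged[-1].append(run)
        else:
            merged.append([run])

    bouts: list[TorporBout] = []
    for group in merged:
        below_idx = np.concatenate([np.arange(s, e + 1) for s, e in group])
        duration = len(below_idx) * interval
        if duration < config.min_bout_duration:
            continue
        first, last = group[0][0], group[-1][1]
        if last + 1 >= len(t):
            logger.warning(
                "%s: trailing below-threshold run discarded (no return to threshold)",
                trace.individual,
            )
            continue
        # walk back from the sample just below the upward crossing while Tb
        # is decreasing backward by more than the noise tolerance: the stop
        # is the last local minimum (noise on the flat plateau produces
        # sub-tolerance dips that must not drag the onset earlier)
        j = last
        while j > first and tb[j - 1] < tb[j] - config.arousal_tolerance:
            j -= 1
        # plateau noise can stop the walk one sample early; advance over any
        # sub-tolerance steps so the onset is the *last* sample at the minimum
        while j < last and tb[j + 1] < tb[j] + config.arousal_tolerance:
            j += 1
        arousal_onset = t[j]
        return_time = t[last + 1]
        attain = None
        after = np.flatnonzero((t >= arousal_onset) & (tb >= model.lower_99_bound))
        if after.size:
            attain = float(t[after[0]])
        bouts.append(
            TorporBout(
                individual=trace.individual,
                entry_time=float(t[first]),
                arousal_onset_time=float(arousal_onset),
                return_to_threshold_time=float(return_time),
                attainment_time=attain,
                duration=float(duration),
                tb_min=float(tb[below_idx].min()),
            )
        )
    return bouts


def bout_days(bouts: list[TorporBout], n_days: int) -> dict[int, int]:
    """Map every observed day to its bout count (a bout belongs to its entry day)."""
    counts = {d: 0 for d in range(n_days)}
    for b in bouts:
        counts[b.entry_day] = counts.get(b.entry_day, 0) + 1
    return counts


def torpor_frequency(
    bouts_by_day: Mapping[int, int], excluded_days: set[int] = frozenset()
) -> float:
    """Percentage of (non-excluded) days on which at least one bout began."""
    if not set(excluded_days) <= set(bouts_by_day):
        raise ValueError("excluded_days must be a subset of the observed days")
    kept = [d for d in bouts_by_day if d not in excluded_days]
    if not kept:
        raise ValueError("no non-excluded days")
    used = sum(1 for d in kept if bouts_by_day[d] >= 1)
    return 100.0 * used / len(kept)


def classify_cloudy_mornings(
    weather: WeatherTrace, config: ExperimentConfig
) -> set[int]:
    """Day indices whose 07h00–09h00 mean irradiance marks a cloudy morning.

    A day is cloudy when its morning mean falls below
    ``cloud_ratio_cutoff`` × the study-period maximum of that daily
    statistic.  Days with no morning samples are indeterminate and excluded.
    """
    means = {d: weather.morning_mean_irradiance(d) for d in range(weather.n_days)}
    defined = {d: m for d, m in means.items() if np.isfinite(m)}
    if not defined:
        raise ValueError("no day has 07h00–09h00 irradiance samples")
    ref = max(defined.values())
    if ref <= 0:
        raise ValueError("all-zero morning irradiance: degenerate reference")
    cloudy = {d for d, m in defined.items() if m < config.cloud_ratio_cutoff * ref}
    indeterminate = set(means) - set(defined)
    if indeterminate:
        logger.warning(
            "days %s have no morning irradiance samples; treated as excluded",
            sorted(indeterminate),
        )
    return cloudy | indeterminate
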