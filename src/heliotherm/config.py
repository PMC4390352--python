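"""Run configuration and experiment metadata.

Every constant the analysis depends on (the 3 °C threshold offset, the 99 %
quantile multiplier, the 15-min sampling interval, the shade-cloth
transmissions...) lives in :class:`ExperimentConfig` so that it is visible and
overridable per run, either programmatically or from a YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["ExperimentConfig", "IndividualRecord", "DEFAULT_TRANSMISSIONS"]

#: Fraction of ambient solar irradiance transmitted to the animal under each
#: housing treatment.  Shade cloth reduced irradiance by 78.7 % (deep shade)
#: and 60.2 % (partial shade) relative to the unshaded control.
DEFAULT_TRANSMISSIONS: Mapping[str, float] = {
    "full_sun": 1.0,
    "partial_shade": 0.398,
    "deep_shade": 0.213,
}


@dataclass
class ExperimentConfig:
    """Tunable constants of the heterothermy analysis.

    Parameters
    ----------
    sampling_interval
        Logger sampling interval in minutes (iButton default: 15).
    threshold_z
        Quantile multiplier for the lower bound of the fitted normothermic
        distribution; 2.576 corresponds to a two-sided 99 % interval.
    threshold_offset
        Fixed offset in °C subtracted from the lower 99 % bound to obtain the
        torpor threshold.
    histogram_bin
        Bin width in °C for the modal-Tb histogram.
    min_bout_duration
        Below-threshold runs shorter than this (minutes) are discarded.
    merge_gap
        Above-threshold gaps shorter than this (minutes) between consecutive
        below-threshold runs are merged into a single bout.
    cloud_ratio_cutoff
        A morning is "cloudy" when its 07h00–09h00 mean irradiance falls below
        this fraction of the study-period maximum of that statistic.
    arousal_tolerance
        Minimum backward Tb decrease (°C) treated as real when locating the
        last local minimum before the upward crossing; decreases smaller than
        this are attributed to logger noise on the torpor plateau.  Twice the
        logger resolution by default.
    rng_seed
        Default seed for stochastic components.
    treatment_transmissions
        Mapping treatment label → fraction of irradiance transmitted.
    """

    sampling_interval: float = 15.0
    threshold_z: float = 2.576
    threshold_offset: float = 3.0
    histogram_bin: float = 0.5
    min_bout_duration: float = 30.0
    merge_gap: float = 30.0
    cloud_ratio_cutoff: float = 0.5
    arousal_tolerance: float = 0.25
    rng_seed: int = 0
    treatment_transmissions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRANSMISSIONS)
    )

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.threshold_offset <= 0:
            raise ValueError("threshold_offset must be > 0")
        if self.histogram_bin <= 0:
            raise ValueError("histogram_bin must be > 0")
        if self.threshold_z <= 0:
            raise ValueError("threshold_z must be > 0")
        for name, tau in self.treatment_transmissions.items():
            if not 0.0 < tau <= 1.0:
                raise ValueError(
                    f"transmission for {name!r} must be in (0, 1], got {tau}"
                )

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        """Load a configuration from a YAML key–value file.

        Unknown keys are rejected so that typos do not silently fall back to
        defaults.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class IndividualRecord:
    """Metadata for one study animal."""

    id: str
    sex: str
    body_mass_pre: float
    body_mass_post: float
    treatment: str

    def __post_init__(self) -> None:
        if self.body_mass_pre <= 0 or self.body_mass_post <= 0:
            raise ValueError("body mass must be > 0")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")

    @property
    def mean_mass(self) -> float:
        """Mean of pre- and post-experiment body mass (g)."""
        return 0.5 * (self.body_mass_pre + self.body_mass_post)
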