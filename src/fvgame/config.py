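"""Configuration objects for the simulator and the study pipeline.

Both configs are plain dataclasses with explicit validation; ``validate()``
raises :class:`ConfigError` naming the offending field so that CLI users get
actionable messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import yaml

__all__ = ["ConfigError", "SimConfig", "StudyConfig", "FRUIT", "VEGETABLE", "CATEGORIES"]

FRUIT = "fruit"
VEGETABLE = "vegetable"
CATEGORIES = (FRUIT, VEGETABLE)

#: volume of one serving, in cups.  The cafeteria served roughly quarter-cup
#: portions (slightly smaller for K-2, slightly larger for grades 6-8); a
#: single attendance-weighted value is used because the waste measure is
#: school-level.
DEFAULT_SERVING_CUPS = 0.25


class ConfigError(ValueError):
    """A configuration field failed validation."""


def _require(ok: bool, name: str, msg: str) -> None:
    if not ok:
        raise ConfigError(f"{name}: {msg}")


@dataclass
class SimConfig:
    """Parameters of the synthetic cafeteria study.

    Defaults emulate the study design: a 10-day baseline whose consumption
    declines as the novelty of free fruit and vegetables wears off (the
    vegetable series stabilises after ``stabilization_day``, the fruit series
    keeps declining through baseline), followed by a 13-day gamification
    phase in which only the day's randomly targeted food is elevated by
    ``effect_size`` (in proportion-of-serving units).  Day-to-day noise is a
    stationary AR(1) process on the latent consumption level.
    """

    n_baseline_days: int = 10
    n_intervention_days: int = 13
    n_students: int = 180
    #: per student-day probability of absence (the school had ~180 enrolled
    #: "minus students who were absent on any given day")
    absence_rate: float = 0.06
    #: latent proportion-of-serving consumed on baseline day 1, per category
    baseline_start_level: Mapping[str, float] = field(
        default_factory=lambda: {FRUIT: 0.80, VEGETABLE: 0.52}
    )
    #: fractional decline in the latent level per early-baseline day
    novelty_decay: float = 0.07
    #: day index (1-based) after which the vegetable baseline stops declining;
    #: the fruit baseline declines through all baseline days
    stabilization_day: int = 5
    #: lag-1 autocorrelation of the daily noise
    ar1_phi: float = 0.30
    #: marginal SD of the daily noise, proportion units
    noise_sd: float = 0.05
    #: additive target-day increase in proportion-of-serving, per category
    effect_size: Mapping[str, float] = field(
        default_factory=lambda: {FRUIT: 0.35, VEGETABLE: 0.30}
    )
    #: variety -> grams per serving; None loads the packaged table
    serving_weight_table: Mapping[str, float] | None = None
    #: volume of one serving in cups
    serving_cups: float = DEFAULT_SERVING_CUPS
    rng_seed: int = 0

    @property
    def n_days(self) -> int:
        return self.n_baseline_days + self.n_intervention_days

    def validate(self) -> "SimConfig":
        _require(self.n_baseline_days >= 5, "n_baseline_days",
                 "need >= 5 baseline days (CDC and SMA require >= 5 points)")
        _require(self.n_intervention_days >= 1, "n_intervention_days", "must be >= 1")
        _require(self.n_students > 0, "n_students", "must be positive")
        _require(0.0 <= self.absence_rate <= 1.0, "absence_rate", "must be in [0, 1]")
        _require(0.0 <= self.novelty_decay <= 1.0, "novelty_decay", "must be in [0, 1]")
        _require(abs(self.ar1_phi) < 1.0, "ar1_phi", "|phi| must be < 1")
        _require(self.noise_sd >= 0.0, "noise_sd", "must be >= 0")
        _require(self.serving_cups > 0.0, "serving_cups", "must be positive")
        _require(1 <= self.stabilization_day <= self.n_baseline_days,
                 "stabilization_day", "must fall within the baseline")
        for cat in CATEGORIES:
            _require(cat in self.baseline_start_level, "baseline_start_level",
                     f"missing category {cat!r}")
            _require(self.baseline_start_level[cat] >= 0.0, "baseline_start_level",
                     f"{cat} level must be >= 0")
            _require(cat in self.effect_size, "effect_size", f"missing category {cat!r}")
            _require(self.effect_size[cat] >= 0.0, "effect_size",
                     f"{cat} effect must be >= 0")
        return self

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class StudyConfig:
    """Options of the study analysis pipeline."""

    #: how many final baseline days form the comparison baseline
    baseline_comparison_days: int = 5
    sd_multiplier: float = 0.5
    alpha: float = 0.05
    n_sims: int = 5000
    seed: int = 0
    serving_cups: float = DEFAULT_SERVING_CUPS
    #: neutral Likert anchor the survey tests compare against
    survey_mu0: float = 3.0
    #: invited-group sizes used for response-rate bookkeeping
    n_invited: Mapping[str, int] = field(
        default_factory=lambda: {"teacher": 8, "parent": 152}
    )

    def validate(self, n_baseline_days: int | None = None) -> "StudyConfig":
        _require(self.baseline_comparison_days >= 1, "baseline_comparison_days",
                 "must be >= 1")
        if n_baseline_days is not None:
            _require(self.baseline_comparison_days <= n_baseline_days,
                     "baseline_comparison_days",
                     f"exceeds available baseline days ({n_baseline_days})")
        _require(0.0 < self.alpha < 1.0, "alpha", "must be in (0, 1)")
        _require(self.sd_multiplier >= 0.0, "sd_multiplier", "must be >= 0")
        _require(self.n_sims >= 100, "n_sims", "must be >= 100")
        _require(self.serving_cups > 0.0, "serving_cups", "must be positive")
        return self

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        return asdict(self)
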