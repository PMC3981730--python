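"""Synthetic cafeteria study generator.

Emulates the structure of the real study so the whole pipeline is testable
without the (unpublished) raw records: a 10-day baseline in which school-wide
consumption declines as the novelty of unlimited free fruit and vegetables
wears off (the vegetable series stabilises mid-baseline, the fruit series
keeps declining), then a 13-day gamification phase in which each day one
randomly chosen category is targeted (never more than three consecutive days
the same) and only the targeted category's consumption is elevated.

The latent process per category is

    mean_t  = max(0, level_t + effect * 1[target day])
    value_t = max(0, mean_t + e_t),   e_t stationary AR(1), marginal SD = noise_sd

and daily weights are synthesised *backwards* from the latent value: the
serving weight comes from the variety table, attendance is enrolment minus
binomial absences, and supply/unserved/waste weights are chosen so that the
waste measure recovers the latent value, then rounded to the instrument
resolutions (100 g for the floor scale weighing supply, unserved and waste;
1 g for the portion scale weighing servings and dressing).  The rounding
leaves a known recovery tolerance of 50 g / (S * N) in proportion units,
which downstream tests use as their oracle tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import fixtures
from .config import CATEGORIES, FRUIT, VEGETABLE, SimConfig
from .consumption import DailyMealRecord
from .game import select_target

__all__ = ["GroundTruth", "SurveyResponse", "generate_meal_records", "generate_surveys"]

#: 100 g floor-scale resolution for supply/unserved/waste weights
SUPPLY_RESOLUTION_G = 100.0
#: 1 g portion-scale resolution for serving and dressing weights
PORTION_RESOLUTION_G = 1.0

_FRUIT_MENU = ("mandarin oranges", "oranges", "bananas", "applesauce", "peaches")
_VEG_MENU = ("salad", "veggie sticks", "carrots", "corn", "green beans")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected (the recovery oracle).

    ``latent_mean`` excludes noise, ``latent_value`` includes it; both are in
    proportion-of-serving units, indexed by day within category.
    ``recovery_tol`` is the per-record proportion tolerance implied by
    weight rounding.
    """

    latent_mean: Mapping[str, tuple[float, ...]]
    latent_value: Mapping[str, tuple[float, ...]]
    target_sequence: tuple[str, ...]
    effect_size: Mapping[str, float]
    phase_means: Mapping[str, Mapping[str, float]]
    recovery_tol: tuple[float, ...] = field(default=())


def _round_to(x: float, resolution: float) -> float:
    return float(np.rint(x / resolution) * resolution)


def _latent_levels(cfg: SimConfig, category: str) -> np.ndarray:
    """Noise-free novelty-decline level for every study day."""
    start = cfg.baseline_start_level[category]
    # vegetables stabilise after stabilization_day; fruit declines through
    # the whole baseline; both are flat during the intervention
    last_decline_day = cfg.stabilization_day if category == VEGETABLE \
        else cfg.n_baseline_days
    days = np.arange(1, cfg.n_days + 1)
    exponent = np.minimum(days, last_decline_day) - 1
    return start * (1.0 - cfg.novelty_decay) ** exponent


def _ar1_noise(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``noise_sd``."""
    n = cfg.n_days
    if cfg.noise_sd == 0.0:
        return np.zeros(n)
    phi = cfg.ar1_phi
    e = np.empty(n)
    e[0] = rng.normal(0.0, cfg.noise_sd)
    innov_sd = cfg.noise_sd * np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + rng.normal(0.0, innov_sd)
    return e


def _school_days(n: int, start: str = "2014-01-06") -> list[str]:
    """n consecutive school days (weekdays) as ISO dates."""
    return [d.date().isoformat() for d in pd.bdate_range(start=start, periods=n)]


def generate_meal_records(
    config: SimConfig | None = None,
) -> tuple[list[DailyMealRecord], GroundTruth]:
    """Simulate one complete study: 2 records (fruit, vegetable) per day.

    Deterministic given ``config.rng_seed``.  Returns the record list in
    (day, category) order plus the :class:`GroundTruth` oracle.
    """
    cfg = (config or SimConfig()).validate()
    rng = np.random.default_rng(cfg.rng_seed)
    weights = dict(cfg.serving_weight_table or fixtures.serving_weight_table())
    dressed = fixtures.dressed_varieties()

    # the day's target category, one entry per intervention day
    targets: list[str] = []
    for _ in range(cfg.n_intervention_days):
        targets.append(select_target(targets, rng))

    levels = {c: _latent_levels(cfg, c) for c in CATEGORIES}
    noise = {c: _ar1_noise(cfg, rng) for c in CATEGORIES}
    dates = _school_days(cfg.n_days)
    absences = rng.binomial(cfg.n_students, cfg.absence_rate, size=cfg.n_days)

    records: list[DailyMealRecord] = []
    latent_mean = {c: [] for c in CATEGORIES}
    latent_value = {c: [] for c in CATEGORIES}
    tols: list[float] = []
    for day_idx in range(cfg.n_days):
        is_intervention = day_idx >= cfg.n_baseline_days
        phase = "gamification" if is_intervention else "baseline"
        day_target = targets[day_idx - cfg.n_baseline_days] if is_intervention else None
        n_attend = int(cfg.n_students - absences[day_idx])
        for category in CATEGORIES:
            menu = _FRUIT_MENU if category == FRUIT else _VEG_MENU
            variety = menu[day_idx % len(menu)]
            S = float(weights[variety])
            on_target = day_target == category
            mean_t = max(0.0, levels[category][day_idx]
                         + (cfg.effect_size[category] if on_target else 0.0))
            value_t = max(0.0, mean_t + noise[category][day_idx])
            latent_mean[category].append(mean_t)
            latent_value[category].append(value_t)

            consumed_g = value_t * S * n_attend
            dressing = _round_to(0.5 * n_attend, PORTION_RESOLUTION_G) \
                if variety in dressed else 0.0
            waste = _round_to(float(rng.uniform(0.2, 0.6)) * consumed_g,
                              SUPPLY_RESOLUTION_G)
            unserved = _round_to(1000.0 + float(rng.uniform(0.2, 0.5)) * consumed_g,
                                 SUPPLY_RESOLUTION_G)
            # unserved and waste are already multiples of the supply
            # resolution, so rounding P leaves the recovered numerator
            # within half a resolution step of the latent consumed weight
            supply = _round_to(consumed_g + unserved + waste + dressing,
                               SUPPLY_RESOLUTION_G)
            if supply - unserved - waste - dressing < 0.0:
                # rounding can push a near-zero numerator negative; one
                # resolution step keeps the record valid within tolerance
                supply += SUPPLY_RESOLUTION_G
            target_label = "none" if not is_intervention \
                else ("self" if on_target else "other")
            records.append(DailyMealRecord(
                date=dates[day_idx], phase=phase, category=category,
                variety=variety, target=target_label,
                P=supply, U=unserved, W=waste, dressing=dressing,
                S=S, N=n_attend,
            ).validate())
            tols.append((SUPPLY_RESOLUTION_G / 2.0) / (S * n_attend))

    nb = cfg.n_baseline_days
    phase_means = {
        c: {
            "baseline": float(np.mean(latent_value[c][:nb])),
            "gamification": float(np.mean(latent_value[c][nb:])),
        }
        for c in CATEGORIES
    }
    truth = GroundTruth(
        latent_mean={c: tuple(v) for c, v in latent_mean.items()},
        latent_value={c: tuple(v) for c, v in latent_value.items()},
        target_sequence=tuple(targets),
        effect_size=dict(cfg.effect_size),
        phase_means=phase_means,
        recovery_tol=tuple(tols),
    )
    return records, truth


@dataclass(frozen=True)
class SurveyResponse:
    group: str  # 'teacher' or 'parent'
    respondent: int
    item: str
    rating: int


def generate_surveys(
    config: SimConfig | None = None,
    true_shift: float = 0.0,
    n_teachers: int = 7,
    n_parents: int = 35,
    n_teacher_items: int = 5,
    n_parent_items: int = 10,
    rating_sd: float = 1.0,
) -> list[SurveyResponse]:
    """Simulate post-intervention Likert surveys.

    Each rating is a latent normal centred at ``3 + true_shift`` (3 is the
    neutral anchor on the 1-5 agreement scale) rounded and clipped to the
    integer scale.  Group sizes default to the study's respondent counts
    (7 teachers, 35 parents).  Deterministic given ``config.rng_seed``.
    """
    cfg = (config or SimConfig()).validate()
    # independent stream from the meal-record simulation
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 7]))
    rows: list[SurveyResponse] = []
    for group, n_resp, n_items, prefix in (
        ("teacher", n_teachers, n_teacher_items, "T"),
        ("parent", n_parents, n_parent_items, "P"),
    ):
        latent = 3.0 + true_shift + rng.normal(0.0, rating_sd, size=(n_resp, n_items))
        ratings = np.clip(np.rint(latent), 1, 5).astype(int)
        for r in range(n_resp):
            for i in range(n_items):
                rows.append(SurveyResponse(group=group, respondent=r + 1,
                                           item=f"{prefix}{i + 1}",
                                           rating=int(ratings[r, i])))
    return rows
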