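"""Percentile-schedule goal engine and cooperative-game bookkeeping.

The daily consumption goal is a percentile schedule of reinforcement: the
goal for a category is set from the last 10 consumption values observed on
that category's target days (seeded with the 10 baseline days), such that
the school has met or exceeded the goal on 4 of those 10 days.  Operationally
that is the 7th ascending order statistic of the 10-value window: for
distinct values exactly the top 4 are at or above it.  A nearest-rank "60th
percentile" is also available but the 4-of-10 criterion is the default,
because it is the schedule's operational definition.

Game bookkeeping: the target food alternates randomly with no category
targeted more than three consecutive days; meeting a goal earns one currency
unit per 1% of a serving by which the goal is exceeded; villains are captured
when the 1st, 8th and 11th goals are met, the last capture ending the game.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .config import CATEGORIES, FRUIT, VEGETABLE

__all__ = [
    "WINDOW_LEN",
    "GOAL_RANK",
    "VILLAIN_THRESHOLDS",
    "GOALS_TO_WIN",
    "GoalState",
    "GameState",
    "LedgerRow",
    "compute_goal",
    "update_window",
    "select_target",
    "evaluate_day",
    "advance_game",
    "replay_ledger",
]

WINDOW_LEN = 10
#: 1-based ascending rank of the window value used as the goal
GOAL_RANK = 7
#: cumulative goals-met counts at which a villain is captured
VILLAIN_THRESHOLDS = (1, 8, 11)
GOALS_TO_WIN = 11
#: tolerance absorbing float error in currency / goal-met arithmetic
_EPS = 1e-9


def compute_goal(window: Sequence[float], method: str = "four_of_ten") -> float:
    """Goal from a 10-value consumption window.

    method='four_of_ten' (default): the 7th ascending order statistic, the
    smallest window value with exactly 4 values at-or-above it when values
    are distinct (with ties, at most 4 values exceed it strictly).
    method='nearest_rank': classical nearest-rank 60th percentile,
    ceil(0.6 * 10) = the 6th order statistic.
    """
    vals = [float(v) for v in window]
    if len(vals) != WINDOW_LEN:
        raise ValueError(f"window must hold exactly {WINDOW_LEN} values, got {len(vals)}")
    if any(not math.isfinite(v) or v < 0 for v in vals):
        raise ValueError("window values must be finite and non-negative")
    ordered = sorted(vals)
    if method == "four_of_ten":
        return ordered[GOAL_RANK - 1]
    if method == "nearest_rank":
        return ordered[math.ceil(0.6 * WINDOW_LEN) - 1]
    raise ValueError(f"unknown percentile method {method!r}")


@dataclass(frozen=True)
class GoalState:
    """Rolling goal window for one food category, oldest value first."""

    category: str
    window: tuple[float, ...]
    current_goal: float

    @classmethod
    def from_history(cls, category: str, values: Sequence[float],
                     method: str = "four_of_ten") -> "GoalState":
        window = tuple(float(v) for v in values)
        return cls(category=category, window=window,
                   current_goal=compute_goal(window, method))


def update_window(state: GoalState, new_value: float,
                  method: str = "four_of_ten") -> GoalState:
    """Drop the oldest window value, append ``new_value``, recompute the goal."""
    if new_value < 0:
        raise ValueError(f"consumption cannot be negative: {new_value!r}")
    window = state.window[1:] + (float(new_value),)
    return GoalState(category=state.category, window=window,
                     current_goal=compute_goal(window, method))


def select_target(history: Sequence[str], rng: np.random.Generator) -> str:
    """Pick today's target category.

    A fair coin between fruit and vegetable, except that after three
    consecutive days of the same target the other category is forced, so no
    category is ever targeted more than three days running.
    """
    if len(history) >= 3 and len(set(history[-3:])) == 1:
        last = history[-1]
        return VEGETABLE if last == FRUIT else FRUIT
    return CATEGORIES[int(rng.integers(0, 2))]


def evaluate_day(consumption: float, goal: float) -> tuple[bool, int]:
    """Goal-met flag and currency earned for one target day.

    The goal counts as met at equality.  One currency unit is earned per
    whole 1% of a serving by which consumption exceeds the goal (fractions
    floored, with a tiny tolerance so exact percentages survive float
    representation).
    """
    if consumption < 0 or goal < 0:
        raise ValueError("consumption and goal must be non-negative")
    met = consumption >= goal - _EPS
    excess = max(0.0, consumption - goal)
    currency = int(math.floor(100.0 * excess + _EPS))
    return met, currency


@dataclass(frozen=True)
class LedgerRow:
    """One gamification day as recorded by the engine."""

    day: int
    target: str
    goal: float
    consumption: float | None
    met: bool
    currency_earned: int
    goals_met_cum: int
    villains_captured: int


@dataclass(frozen=True)
class GameState:
    """Cumulative game bookkeeping."""

    currency: int = 0
    goals_met: int = 0
    villains_captured: int = 0
    episode_index: int = 0
    game_over: bool = False
    ledger: tuple[LedgerRow, ...] = field(default_factory=tuple)

    def spend(self, amount: int) -> "GameState":
        """Explicit purchase event (the only way currency decreases)."""
        if not 0 <= amount <= self.currency:
            raise ValueError("cannot spend more currency than the balance")
        return replace(self, currency=self.currency - amount)


def _villains_for(goals_met: int) -> int:
    return sum(goals_met >= t for t in VILLAIN_THRESHOLDS)


def advance_game(
    state: GameState,
    met: bool,
    *,
    day: int | None = None,
    target: str = "",
    goal: float = 0.0,
    consumption: float | None = None,
    currency_earned: int = 0,
) -> GameState:
    """Record one gamification day.

    Meeting the goal increments the goals-met count, advances the narrative
    episode, banks the earned currency, and captures a villain at the 1st,
    8th and 11th goals; the 11th goal ends the game (a terminal flag, not an
    error, so post-game days can still be recorded).
    """
    goals_met = state.goals_met + (1 if met else 0)
    row = LedgerRow(
        day=day if day is not None else len(state.ledger) + 1,
        target=target,
        goal=goal,
        consumption=consumption,
        met=met,
        currency_earned=currency_earned,
        goals_met_cum=goals_met,
        villains_captured=_villains_for(goals_met),
    )
    return GameState(
        currency=state.currency + max(0, currency_earned),
        goals_met=goals_met,
        villains_captured=_villains_for(goals_met),
        episode_index=state.episode_index + (1 if met else 0),
        game_over=goals_met >= GOALS_TO_WIN,
        ledger=state.ledger + (row,),
    )


def replay_ledger(
    targets: Sequence[str],
    met_flags: Sequence[bool],
    goals: Sequence[float] | None = None,
    consumptions: Sequence[float] | None = None,
) -> GameState:
    """Replay a recorded gamification phase from its target/met columns.

    Returns the final :class:`GameState`; currency is accumulated only when
    per-day goal and consumption values are supplied.
    """
    if len(targets) != len(met_flags):
        raise ValueError("targets and met_flags must have equal length")
    state = GameState()
    for i, (target, met) in enumerate(zip(targets, met_flags)):
        goal = goals[i] if goals is not None else 0.0
        cons = consumptions[i] if consumptions is not None else None
        earned = 0
        if cons is not None and goals is not None:
            _, earned = evaluate_day(cons, goal)
        state = advance_game(
            state, bool(met), day=i + 1, target=target, goal=goal,
            consumption=cons, currency_earned=earned,
        )
    return state
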