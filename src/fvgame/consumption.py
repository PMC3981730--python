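"""Waste-based school-level consumption measurement.

The cafeteria measure works from four weights taken each day for each food
category: the prepared supply ``P``, the unserved remainder ``U``, the waste
collected from trays ``W``, and (on dressed-vegetable days) the dressing
weight.  With a single-serving weight ``S`` and ``N`` students in attendance,

    proportion = (P - U - W - dressing) / (S * N)

is the between-student average proportion of one serving consumed.  The
numerator is school-wide grams consumed; dividing by ``S`` converts to
servings and by ``N`` to a per-student average.  Proportions are converted
to grams per student (``proportion * S``) and cups per student
(``proportion * serving volume``) for reporting.

A negative numerator is treated as corrupt input, not clamped: every
subtraction in the measure biases consumption downward, so a value below
zero signals a weighing inconsistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import DEFAULT_SERVING_CUPS

__all__ = [
    "DailyMealRecord",
    "ConsumptionPoint",
    "PhaseSummary",
    "RecordValidationError",
    "compute_consumption",
    "compute_series",
    "phase_summary",
    "percent_increase",
]

PHASES = ("baseline", "gamification")
TARGET_LABELS = ("self", "other", "none")


class RecordValidationError(ValueError):
    """A daily record violates the measure's invariants."""


@dataclass(frozen=True)
class DailyMealRecord:
    """One food category on one school day.

    Weights in grams: ``P`` prepared supply, ``U`` unserved supply, ``W``
    collected waste, ``dressing`` (0 when none was served), ``S`` one
    serving with inedible portions removed.  ``N`` is attendance.
    ``target`` says whether this category was the day's game target
    ('self'), the other category was ('other'), or no game ran ('none').
    """

    date: str
    phase: str
    category: str
    variety: str
    target: str
    P: float
    U: float
    W: float
    dressing: float
    S: float
    N: int

    def validate(self) -> "DailyMealRecord":
        if self.phase not in PHASES:
            raise RecordValidationError(f"{self.date}: unknown phase {self.phase!r}")
        if self.target not in TARGET_LABELS:
            raise RecordValidationError(f"{self.date}: unknown target label {self.target!r}")
        for name in ("P", "U", "W", "dressing"):
            if getattr(self, name) < 0:
                raise RecordValidationError(f"{self.date}: {name} < 0")
        if self.U > self.P:
            raise RecordValidationError(f"{self.date}: unserved weight exceeds supply")
        if self.S <= 0:
            raise RecordValidationError(f"{self.date}: serving weight must be positive")
        if self.N <= 0:
            raise RecordValidationError(f"{self.date}: attendance must be positive")
        return self


@dataclass(frozen=True)
class ConsumptionPoint:
    """Per-day per-student consumption in three equivalent units."""

    date: str
    category: str
    phase: str
    target: str
    proportion: float
    grams_per_student: float
    cups_per_student: float


def compute_consumption(
    record: DailyMealRecord, serving_cups: float = DEFAULT_SERVING_CUPS
) -> ConsumptionPoint:
    """Apply the waste measure to one validated daily record.

    Raises :class:`RecordValidationError` (citing the record's date) when the
    consumed weight comes out negative or the denominator is degenerate.
    """
    record.validate()
    consumed_g = record.P - record.U - record.W - record.dressing
    if consumed_g < 0:
        raise RecordValidationError(
            f"{record.date}: negative consumed weight ({consumed_g:g} g) — "
            "weighing inconsistency"
        )
    denom = record.S * record.N
    if denom == 0:
        raise RecordValidationError(f"{record.date}: serving weight x attendance is zero")
    proportion = consumed_g / denom
    return ConsumptionPoint(
        date=record.date,
        category=record.category,
        phase=record.phase,
        target=record.target,
        proportion=proportion,
        grams_per_student=proportion * record.S,
        cups_per_student=proportion * serving_cups,
    )


def compute_series(
    records: Iterable[DailyMealRecord], serving_cups: float = DEFAULT_SERVING_CUPS
) -> list[ConsumptionPoint]:
    """Measure every record, preserving order."""
    return [compute_consumption(r, serving_cups) for r in records]


@dataclass(frozen=True)
class PhaseSummary:
    """Mean and SEM over days (not students) of a filtered series."""

    n_days: int
    mean_proportion: float
    sem_proportion: float
    mean_grams: float
    sem_grams: float
    mean_cups: float
    sem_cups: float
    #: False when only one day is available and the SEM is reported as 0
    sem_defined: bool


class EmptySelectionError(ValueError):
    """No points remain after phase/target filtering."""


def phase_summary(
    series: Sequence[ConsumptionPoint],
    phase: str | None = None,
    target: str | None = None,
) -> PhaseSummary:
    """Day-level mean and SEM of a consumption series, optionally filtered.

    ``phase`` and ``target`` restrict the selection ('baseline' /
    'gamification'; 'self' / 'other' / 'none').  SEM uses the n-1 sample SD
    over days; with a single day it is undefined and reported as 0 with
    ``sem_defined=False``.
    """
    pts = [
        p for p in series
        if (phase is None or p.phase == phase) and (target is None or p.target == target)
    ]
    if not pts:
        raise EmptySelectionError(
            f"no consumption points match phase={phase!r}, target={target!r}"
        )
    n = len(pts)

    def _ms(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        mean = float(arr.mean())
        sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        return mean, sem

    mp, sp = _ms([p.proportion for p in pts])
    mg, sg = _ms([p.grams_per_student for p in pts])
    mc, sc = _ms([p.cups_per_student for p in pts])
    return PhaseSummary(
        n_days=n,
        mean_proportion=mp, sem_proportion=sp,
        mean_grams=mg, sem_grams=sg,
        mean_cups=mc, sem_cups=sc,
        sem_defined=n > 1,
    )


def percent_increase(baseline_mean: float, treatment_mean: float) -> tuple[int, float]:
    """Percent change from baseline, as (half-up-rounded int, raw value).

    Raises ``ValueError`` when the baseline mean is not positive.
    """
    if baseline_mean <= 0:
        raise ValueError(f"baseline mean must be positive, got {baseline_mean!r}")
    raw = 100.0 * (treatment_mean - baseline_mean) / baseline_mean
    rounded = math.floor(raw + 0.5)  # half-up, not banker's rounding
    return rounded, raw
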