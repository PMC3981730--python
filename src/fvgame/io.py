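"""CSV readers and writers for meal records, surveys and derived series.

Meal-records dialect (UTF-8, RFC 4180):

    date,phase,category,variety,target,P_g,U_g,W_g,dressing_g,S_g,N

Surveys dialect:

    group,item,rating

Readers validate strictly: missing required columns fail, unknown columns
warn, and malformed rows raise with the offending CSV line number.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import pandas as pd

from .consumption import ConsumptionPoint, DailyMealRecord, RecordValidationError
from .synthetic import SurveyResponse

__all__ = [
    "SchemaError",
    "MEAL_COLUMNS",
    "SURVEY_COLUMNS",
    "write_meal_csv",
    "read_meal_csv",
    "write_survey_csv",
    "read_survey_csv",
    "write_consumption_csv",
]

MEAL_COLUMNS = ["date", "phase", "category", "variety", "target",
                "P_g", "U_g", "W_g", "dressing_g", "S_g", "N"]
SURVEY_COLUMNS = ["group", "item", "rating"]
CONSUMPTION_COLUMNS = ["date", "category", "phase", "target",
                       "proportion", "g_per_student", "cups_per_student"]


class SchemaError(ValueError):
    """A CSV file does not match the expected schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=3)


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    _check_columns(df, required, path)
    return df


def write_meal_csv(records: Iterable[DailyMealRecord], path) -> None:
    rows = [
        {"date": r.date, "phase": r.phase, "category": r.category,
         "variety": r.variety, "target": r.target, "P_g": r.P, "U_g": r.U,
         "W_g": r.W, "dressing_g": r.dressing, "S_g": r.S, "N": r.N}
        for r in records
    ]
    pd.DataFrame(rows, columns=MEAL_COLUMNS).to_csv(
        path, index=False, lineterminator="\r\n")


def read_meal_csv(path) -> list[DailyMealRecord]:
    """Parse and validate a meal-records CSV, in file order.

    Raises :class:`SchemaError` naming the CSV line (header = line 1) for
    any row that fails to parse or violates the measure's invariants.
    """
    df = _read_csv(path, MEAL_COLUMNS)
    records: list[DailyMealRecord] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            rec = DailyMealRecord(
                date=str(row["date"]),
                phase=str(row["phase"]).strip().lower(),
                category=str(row["category"]).strip().lower(),
                variety=str(row["variety"]).strip().lower(),
                target=str(row["target"]).strip().lower(),
                P=float(row["P_g"]), U=float(row["U_g"]), W=float(row["W_g"]),
                dressing=float(row["dressing_g"]), S=float(row["S_g"]),
                N=int(float(row["N"])),
            ).validate()
        except (ValueError, TypeError, RecordValidationError) as exc:
            raise SchemaError(f"{path}: line {line_no}: {exc}") from exc
        records.append(rec)
    return records


def write_survey_csv(responses: Iterable[SurveyResponse], path) -> None:
    rows = [{"group": r.group, "item": r.item, "rating": r.rating}
            for r in responses]
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(
        path, index=False, lineterminator="\r\n")


def read_survey_csv(path) -> pd.DataFrame:
    """Parse a survey CSV; ratings must be integers in 1..5."""
    df = _read_csv(path, SURVEY_COLUMNS)
    out_rows = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        try:
            rating = int(float(row["rating"]))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: line {line_no}: bad rating "
                              f"{row['rating']!r}") from exc
        if not 1 <= rating <= 5:
            raise SchemaError(f"{path}: line {line_no}: rating {rating} "
                              "outside the 1-5 scale")
        out_rows.append({"group": str(row["group"]).strip().lower(),
                         "item": str(row["item"]).strip(), "rating": rating})
    if not out_rows:
        raise SchemaError(f"{path}: no survey rows")
    return pd.DataFrame(out_rows, columns=SURVEY_COLUMNS)


def write_consumption_csv(points: Iterable[ConsumptionPoint], path) -> None:
    rows = [
        {"date": p.date, "category": p.category, "phase": p.phase,
         "target": p.target, "proportion": p.proportion,
         "g_per_student": p.grams_per_student,
         "cups_per_student": p.cups_per_student}
        for p in points
    ]
    pd.DataFrame(rows, columns=CONSUMPTION_COLUMNS).to_csv(
        path, index=False, lineterminator="\r\n")
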