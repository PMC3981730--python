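"""Packaged reference tables: serving weights and the published game ledger."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml

__all__ = [
    "serving_weight_table",
    "variety_category",
    "dressed_varieties",
    "printed_game_ledger",
]


@lru_cache(maxsize=1)
def _weights_yaml() -> dict:
    ref = resources.files("fvgame.data").joinpath("serving_weights.yaml")
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


def serving_weight_table() -> dict[str, float]:
    """Variety -> grams per quarter-cup serving.

    Salad and green-bean weights are measured values; the remainder are
    synthetic fixture values (see the data file) for simulation use.
    """
    return dict(_weights_yaml()["grams_per_quarter_cup"])


def variety_category() -> dict[str, str]:
    """Variety -> 'fruit' | 'vegetable'."""
    return dict(_weights_yaml()["category"])


def dressed_varieties() -> set[str]:
    """Varieties served with dressing (dressing weight enters the measure)."""
    return set(_weights_yaml()["dressed"])


def printed_game_ledger() -> pd.DataFrame:
    """The 13-day gamification bookkeeping table as published.

    Columns: day, goal_cups, goal_g, target_food, nontarget_food, met (bool),
    plus a derived target_category column ('fruit'/'vegetable').
    """
    ref = resources.files("fvgame.data").joinpath("game_ledger.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    df["met"] = df["met"].str.lower().eq("yes")
    cats = variety_category()
    df["target_category"] = df["target_food"].str.lower().map(cats)
    if df["target_category"].isna().any():
        missing = df.loc[df["target_category"].isna(), "target_food"].tolist()
        raise ValueError(f"unknown varieties in ledger fixture: {missing}")
    return df
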