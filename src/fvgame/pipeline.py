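"""End-to-end study analysis: measurement -> game replay -> statistics -> report.

``run_study`` reproduces the published analysis structure on any conforming
meal-records CSV (typically a synthetic study):

1. waste-measure consumption for every day and category;
2. phase summaries (proportion / grams / cups, mean + SEM over days) against
   a trimmed comparison baseline (the final ``baseline_comparison_days``
   days, default 5 — consumption early in baseline is inflated by novelty);
3. simulation modeling analysis per category on the trimmed baseline plus
   *all* intervention days, ignoring target labels (did consumption rise at
   all after baseline?);
4. conservative dual-criteria tests per category on target days only and on
   non-target days only (did it rise *because* of the game?);
5. a replay of the game's percentile-schedule bookkeeping from the measured
   consumption series;
6. survey statistics per item: median, distribution-free lower CI bound,
   exact Wilcoxon signed-rank p against the neutral rating.

The report is a plain dict serialisable to JSON/markdown, byte-identical
across runs with identical inputs and seeds.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CATEGORIES, StudyConfig
from .consumption import (ConsumptionPoint, DailyMealRecord, compute_series,
                          percent_increase, phase_summary)
from .game import (WINDOW_LEN, GameState, GoalState, advance_game,
                   evaluate_day, update_window)
from .io import read_meal_csv, read_survey_csv
from .stats import PhaseSeries, cdc_test, median_ci, sma_test, slope_trend_test, \
    wilcoxon_signed_rank

__all__ = ["run_study", "replay_game_from_points", "survey_stats",
           "write_report_json", "write_report_markdown", "DesignValidityError"]


class DesignValidityError(ValueError):
    """The data cannot support the requested analysis design."""


def _by_category(points: Sequence[ConsumptionPoint], category: str
                 ) -> list[ConsumptionPoint]:
    return [p for p in points if p.category == category]


def _values(points: Sequence[ConsumptionPoint]) -> list[float]:
    return [p.proportion for p in points]


def _summary_dict(points, phase=None, target=None) -> dict:
    s = phase_summary(points, phase=phase, target=target)
    return {
        "n_days": s.n_days,
        "proportion": {"mean": s.mean_proportion, "sem": s.sem_proportion},
        "grams": {"mean": s.mean_grams, "sem": s.sem_grams},
        "cups": {"mean": s.mean_cups, "sem": s.sem_cups},
        "sem_defined": s.sem_defined,
    }


def replay_game_from_points(
    points: Sequence[ConsumptionPoint],
    window_len: int = WINDOW_LEN,
    percentile_method: str = "four_of_ten",
) -> GameState:
    """Re-run the goal engine over a measured consumption series.

    Each category's goal window is seeded with its final ``window_len``
    baseline days; on every gamification day the target category's goal is
    read from its window, the day is scored (goal met at equality, one
    currency unit per whole 1% of a serving above goal), and only target-day
    values re-enter that category's window.
    """
    goal_states: dict[str, GoalState] = {}
    for category in CATEGORIES:
        base = [p.proportion for p in points
                if p.category == category and p.phase == "baseline"]
        if len(base) < window_len:
            raise DesignValidityError(
                f"goal window needs {window_len} baseline days for "
                f"{category}, found {len(base)}")
        goal_states[category] = GoalState.from_history(
            category, base[-window_len:], percentile_method)

    game = GameState()
    game_days = sorted(
        {p.date for p in points if p.phase == "gamification"})
    for day_no, date in enumerate(game_days, start=1):
        todays = [p for p in points if p.date == date and p.target == "self"]
        if len(todays) != 1:
            raise DesignValidityError(
                f"{date}: expected exactly one target-day record, "
                f"found {len(todays)}")
        point = todays[0]
        state = goal_states[point.category]
        met, earned = evaluate_day(point.proportion, state.current_goal)
        game = advance_game(game, met, day=day_no, target=point.category,
                            goal=state.current_goal,
                            consumption=point.proportion,
                            currency_earned=earned)
        goal_states[point.category] = update_window(
            state, point.proportion, percentile_method)
    return game


def survey_stats(surveys: pd.DataFrame, config: StudyConfig) -> dict:
    """Per-item survey table: median, lower CI bound, Wilcoxon p.

    Teacher items are judged by the lower bound of the distribution-free
    median CI (a signed-rank test is hopeless at n = 7: one dissenting
    rating kills it); parent items by the exact Wilcoxon signed-rank test
    against the neutral rating.
    """
    mu0 = config.survey_mu0
    out: dict = {"groups": {}}
    for group, gdf in surveys.groupby("group"):
        n_resp = int(gdf.groupby("item").size().max())
        items = {}
        for item, idf in gdf.groupby("item"):
            ratings = idf["rating"].to_numpy()
            ci = median_ci(ratings, level=0.95)
            try:
                wres = wilcoxon_signed_rank(ratings, mu0=mu0)
                w_p = wres.p_value
            except ValueError:
                w_p = None  # every rating at the neutral anchor
            median = float(np.median(ratings))
            if group == "teacher":
                significant = bool(ci.computable and ci.lower is not None
                                   and ci.lower > mu0)
                rule = "median_ci"
            else:
                significant = bool(w_p is not None and w_p < config.alpha)
                rule = "wilcoxon"
            items[item] = {
                "n": int(ratings.size),
                "median": median,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
                "ci_coverage": ci.achieved_coverage,
                "wilcoxon_p": w_p,
                "significant": significant,
                "rule": rule,
            }
        group_info = {"n_respondents": n_resp, "items": items}
        invited = config.n_invited.get(group)
        if invited:
            group_info["n_invited"] = int(invited)
            group_info["response_rate_pct"] = 100.0 * n_resp / invited
        out["groups"][group] = group_info
    return out


def _analyze_category(
    points: Sequence[ConsumptionPoint],
    category: str,
    config: StudyConfig,
    seed: int,
) -> dict:
    cpts = _by_category(points, category)
    base_pts = [p for p in cpts if p.phase == "baseline"]
    game_pts = [p for p in cpts if p.phase == "gamification"]
    nb = len(base_pts)
    if nb < config.baseline_comparison_days:
        raise DesignValidityError(
            f"{category}: {nb} baseline days < baseline_comparison_days="
            f"{config.baseline_comparison_days}")
    if len(game_pts) < 5 or config.baseline_comparison_days < 5:
        raise DesignValidityError(
            f"{category}: CDC needs >= 5 days in each phase")
    trimmed = base_pts[-config.baseline_comparison_days:]

    summaries = {
        "baseline_full": _summary_dict(cpts, phase="baseline"),
        "baseline_comparison": _summary_dict(trimmed),
        "gamification_all": _summary_dict(cpts, phase="gamification"),
        "gamification_target": _summary_dict(cpts, phase="gamification",
                                             target="self"),
        "gamification_nontarget": _summary_dict(cpts, phase="gamification",
                                                target="other"),
    }

    increases = {}
    for unit in ("proportion", "grams", "cups"):
        b = summaries["baseline_comparison"][unit]["mean"]
        g = summaries["gamification_all"][unit]["mean"]
        rounded, raw = percent_increase(b, g)
        increases[unit] = {"rounded": rounded, "raw": raw}

    sma_series = PhaseSeries.from_phases(_values(trimmed), _values(game_pts))
    sma = sma_test(sma_series, n_sims=config.n_sims, kind="pearson",
                   tail="two", seed=seed)
    baseline_trend = slope_trend_test(_values(base_pts), seed=seed + 1)

    target_vals = _values([p for p in game_pts if p.target == "self"])
    nontarget_vals = _values([p for p in game_pts if p.target == "other"])
    cdc = {}
    for label, vals in (("target_days", target_vals),
                        ("nontarget_days", nontarget_vals)):
        if len(vals) >= 5:
            cdc[label] = cdc_test(_values(trimmed), vals,
                                  sd_multiplier=config.sd_multiplier,
                                  alpha=config.alpha).to_dict()
        else:
            cdc[label] = {"test": "cdc", "skipped": True,
                          "reason": f"only {len(vals)} days (< 5)"}

    return {
        "summaries": summaries,
        "percent_increase_vs_comparison_baseline": increases,
        "sma": sma.to_dict(),
        "baseline_trend": baseline_trend.to_dict(),
        "cdc": cdc,
    }


def run_study(
    meal_csv,
    survey_csv=None,
    config: StudyConfig | None = None,
    records: Sequence[DailyMealRecord] | None = None,
    surveys: pd.DataFrame | None = None,
) -> dict:
    """Run the complete study analysis and return the report dict.

    Inputs may be CSV paths or in-memory objects (``records`` /
    ``surveys`` override the paths).  Deterministic given
    ``config.seed``.
    """
    cfg = (config or StudyConfig())
    if records is None:
        records = read_meal_csv(meal_csv)
    if surveys is None and survey_csv is not None:
        surveys = read_survey_csv(survey_csv)
    n_baseline = len({r.date for r in records if r.phase == "baseline"})
    cfg.validate(n_baseline_days=n_baseline)

    points = compute_series(records, serving_cups=cfg.serving_cups)
    report: dict = {
        "options": cfg.to_dict(),
        "n_records": len(records),
        "n_baseline_days": n_baseline,
        "n_gamification_days": len(
            {r.date for r in records if r.phase == "gamification"}),
        "categories": {},
    }
    for i, category in enumerate(CATEGORIES):
        report["categories"][category] = _analyze_category(
            points, category, cfg, seed=cfg.seed + 101 * (i + 1))

    has_targets = any(p.target == "self" for p in points)
    if has_targets and n_baseline >= WINDOW_LEN:
        game = replay_game_from_points(points)
        report["game"] = {
            "goals_met": game.goals_met,
            "villains_captured": game.villains_captured,
            "currency": game.currency,
            "game_over": game.game_over,
            "ledger": [
                {"day": r.day, "target": r.target, "goal": r.goal,
                 "consumption": r.consumption, "met": r.met,
                 "currency_earned": r.currency_earned,
                 "villains_captured": r.villains_captured}
                for r in game.ledger
            ],
        }

    if surveys is not None:
        report["surveys"] = survey_stats(surveys, cfg)
    return report


def write_report_json(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def _md_pct(entry: dict) -> str:
    return f"{entry['rounded']}% (raw {entry['raw']:.2f}%)"


def write_report_markdown(report: dict, path) -> None:
    """Human-readable summary of the same numbers as the JSON report."""
    lines = ["# Study report", ""]
    for category, cat in report["categories"].items():
        s = cat["summaries"]
        inc = cat["percent_increase_vs_comparison_baseline"]
        lines += [
            f"## {category.capitalize()}",
            "",
            f"- comparison baseline: {s['baseline_comparison']['cups']['mean']:.3f} cups "
            f"({s['baseline_comparison']['grams']['mean']:.2f} g) per student-day",
            f"- gamification: {s['gamification_all']['cups']['mean']:.3f} cups "
            f"({s['gamification_all']['grams']['mean']:.2f} g) per student-day",
            f"- increase: {_md_pct(inc['cups'])} in cups, {_md_pct(inc['grams'])} in grams",
            f"- SMA: R = {cat['sma']['r_obs']:.3f}, p = {cat['sma']['p_value']:.4f}",
        ]
        for label, c in cat["cdc"].items():
            if c.get("skipped"):
                lines.append(f"- CDC {label}: skipped ({c['reason']})")
            else:
                lines.append(
                    f"- CDC {label}: {c['n_above_both']}/{c['n_treatment']} above "
                    f"both criteria, p = {c['binomial_p']:.4f}"
                    f"{' *' if c['significant'] else ''}")
        lines.append("")
    if "game" in report:
        g = report["game"]
        lines += [
            "## Game replay",
            "",
            f"- goals met: {g['goals_met']}; villains captured: "
            f"{g['villains_captured']}; currency: {g['currency']}; "
            f"game over: {g['game_over']}",
            "",
        ]
    if "surveys" in report:
        lines += ["## Surveys", ""]
        for group, ginfo in report["surveys"]["groups"].items():
            rate = ginfo.get("response_rate_pct")
            rate_s = f", response rate {rate:.1f}%" if rate is not None else ""
            lines.append(f"### {group.capitalize()} "
                         f"(n = {ginfo['n_respondents']}{rate_s})")
            lines.append("")
            lines.append("| item | n | median | CI lower | Wilcoxon p | sig |")
            lines.append("|------|---|--------|----------|------------|-----|")
            for item, st in ginfo["items"].items():
                wp = "—" if st["wilcoxon_p"] is None else f"{st['wilcoxon_p']:.4f}"
                lo = "—" if st["ci_lower"] is None else f"{st['ci_lower']:g}"
                lines.append(
                    f"| {item} | {st['n']} | {st['median']:g} | {lo} | {wp} | "
                    f"{'*' if st['significant'] else ''} |")
            lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
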