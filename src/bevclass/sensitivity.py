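"""Two-scenario sensitivity analysis for mixed foodcodes.

Some foodcodes cover several branded beverages that disagree on low-calorie
sweetener content, so a recalled item on such a code cannot be assigned a
sweetener exposure.  The sensitivity analysis runs the entire pipeline
twice -- once counting every mixed code as LCSB, once as SB -- and reports
how consumer-group sizes, least-squares means, and the adjusted significance
pattern move between the two extremes.  The classification table itself is
scenario-invariant; only group assignment (and hence the outcome models)
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .classify import (
    ClassificationTable,
    StrategyConfig,
    SweetenerClass,
    build_classification_table,
)
from .fndds import BrandedProduct, FoodcodeRecord, Thresholds
from .recall import (
    ConsumerGroup,
    Scenario,
    assign_groups,
    build_participant_days,
)
from .survey import OUTCOMES, OutcomeModel

__all__ = ["ScenarioResult", "ScenarioDiff", "run_scenario", "diff_scenarios", "run_sensitivity"]

#: Default outcome-model grid: every outcome under Model 1, the three
#: non-energy outcomes also under Model 2 (energy is Model 2's adjustment).
DEFAULT_MODEL_GRID: tuple[tuple[str, int], ...] = tuple(
    [(o, 1) for o in OUTCOMES] + [(o, 2) for o in OUTCOMES if o != "energy_kcal"]
)


@dataclass
class ScenarioResult:
    """Pipeline output under one mixed-code treatment."""

    scenario: str
    group_n: dict[str, int]
    class_counts: dict[str, int]
    models: dict[tuple[str, int], dict] = field(default_factory=dict)
    days: pd.DataFrame | None = None

    @property
    def n_grouped(self) -> int:
        return sum(n for g, n in self.group_n.items() if g != ConsumerGroup.UNGROUPED.value)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "group_n": self.group_n,
            "class_counts": self.class_counts,
            "models": {f"{o}/model{m}": s for (o, m), s in self.models.items()},
        }


@dataclass
class ScenarioDiff:
    """Contrast between the two mixed-code treatments.

    ``delta_n`` is per-group n(a) - n(b); ``significance_flips`` lists
    (outcome, model, pair) whose adjusted significance at 0.05 differs;
    ``max_abs_dlsm`` is the largest absolute least-squares-mean shift per
    outcome/model.
    """

    scenario_a: str
    scenario_b: str
    delta_n: dict[str, int]
    significance_flips: list[tuple[str, int, str]]
    max_abs_dlsm: dict[tuple[str, int], float]

    def to_dict(self) -> dict:
        return {
            "scenario_a": self.scenario_a,
            "scenario_b": self.scenario_b,
            "delta_n": self.delta_n,
            "significance_flips": [
                {"outcome": o, "model": m, "pair": p} for o, m, p in self.significance_flips
            ],
            "max_abs_dlsm": {f"{o}/model{m}": v for (o, m), v in self.max_abs_dlsm.items()},
        }


def run_scenario(
    foodcodes: Sequence[FoodcodeRecord],
    products: Sequence[BrandedProduct],
    participants: pd.DataFrame,
    recall_items: pd.DataFrame,
    scenario: Scenario | str,
    cfg: StrategyConfig | None = None,
    th: Thresholds | None = None,
    model_grid: Sequence[tuple[str, int]] | None = None,
    table: ClassificationTable | None = None,
    fit_models: bool = True,
    keep_days: bool = False,
) -> ScenarioResult:
    """Classify, assign groups, and fit the outcome models for one scenario.

    The pipeline is deterministic: identical inputs and configuration give
    identical results (no stage draws random numbers).  `model_grid`
    restricts which (outcome, model) pairs are fitted; `fit_models=False`
    stops after group assignment (useful for group-size contrasts).
    """
    scenario = Scenario(scenario)
    th = th or Thresholds()
    if table is None:
        table = build_classification_table(foodcodes, products, cfg, th)
    days = build_participant_days(participants, recall_items, table, foodcodes, th)
    days = assign_groups(days, scenario, th)

    group_n = {g.value: 0 for g in ConsumerGroup}
    group_n.update(days["group"].value_counts().to_dict())
    counts = table.counts()
    result = ScenarioResult(
        scenario=scenario.value,
        group_n=group_n,
        class_counts={c.value: counts[c] for c in SweetenerClass},
        days=days if keep_days else None,
    )
    if not fit_models:
        return result

    frame = days.merge(participants, on="participant_id", how="left")
    for outcome, model in model_grid if model_grid is not None else DEFAULT_MODEL_GRID:
        om = OutcomeModel(outcome=outcome, model=model).fit(frame)
        result.models[(outcome, model)] = om.summary()
    return result


def diff_scenarios(a: ScenarioResult, b: ScenarioResult, alpha: float = 0.05) -> ScenarioDiff:
    """Contrast two scenario results.

    Errors if participant conservation is violated (the scenarios must
    repartition the same eligible population) or if the classification
    counts differ (classification is scenario-invariant by construction).
    """
    n_a = sum(a.group_n.values())
    n_b = sum(b.group_n.values())
    if n_a != n_b:
        raise ValueError(f"participant totals differ between scenarios: {n_a} vs {n_b}")
    if a.class_counts != b.class_counts:
        raise ValueError("classification counts differ between scenarios")
    delta_n = {g: a.group_n.get(g, 0) - b.group_n.get(g, 0) for g in a.group_n}

    flips: list[tuple[str, int, str]] = []
    max_abs_dlsm: dict[tuple[str, int], float] = {}
    for key in a.models:
        if key not in b.models:
            continue
        sa, sb = a.models[key], b.models[key]
        for pair in sa["p_adj"]:
            if pair in sb["p_adj"] and (sa["p_adj"][pair] < alpha) != (sb["p_adj"][pair] < alpha):
                flips.append((key[0], key[1], pair))
        shared = set(sa["lsm"]) & set(sb["lsm"])
        max_abs_dlsm[key] = max(
            (abs(sa["lsm"][g] - sb["lsm"][g]) for g in shared), default=0.0
        )
    return ScenarioDiff(
        scenario_a=a.scenario,
        scenario_b=b.scenario,
        delta_n=delta_n,
        significance_flips=sorted(flips),
        max_abs_dlsm=max_abs_dlsm,
    )


def run_sensitivity(
    foodcodes: Sequence[FoodcodeRecord],
    products: Sequence[BrandedProduct],
    participants: pd.DataFrame,
    recall_items: pd.DataFrame,
    cfg: StrategyConfig | None = None,
    th: Thresholds | None = None,
    model_grid: Sequence[tuple[str, int]] | None = None,
    fit_models: bool = True,
) -> dict:
    """Both scenarios plus their contrast, as a JSON-ready report."""
    th = th or Thresholds()
    table = build_classification_table(foodcodes, products, cfg, th)
    a = run_scenario(
        foodcodes, products, participants, recall_items, Scenario.MIXED_AS_LCSB,
        cfg, th, model_grid, table=table, fit_models=fit_models,
    )
    b = run_scenario(
        foodcodes, products, participants, recall_items, Scenario.MIXED_AS_SB,
        cfg, th, model_grid, table=table, fit_models=fit_models,
    )
    d = diff_scenarios(a, b)
    return {
        "mixed_as_lcsb": a.to_dict(),
        "mixed_as_sb": b.to_dict(),
        "diff": d.to_dict(),
    }
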