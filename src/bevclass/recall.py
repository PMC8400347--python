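"""Recall-day processing: volumes, plain-water intake, eligibility, groups.

Recalled beverage amounts are stored as grams; analysis happens in fluid
ounces, converted with each foodcode's own grams-per-fluid-ounce factor
(beverages sweetened with low-calorie sweeteners are less dense than
sugar-sweetened ones, so a shared factor would bias volume comparisons).
Plain-water intake comes from the dietary questionnaire variable, converted
at the plain-water density of 29.6 g/fl oz, with a discrepancy flag when the
questionnaire total disagrees with the summed plain-water recall items.

Participants (children and adolescents aged 2-17 with one reliable in-person
recall and no diabetes diagnosis) are assigned to one of four consumer
groups against a 4 fl oz threshold; foodcodes whose sweetener content is
ambiguous ("mixed") are resolved under two scenarios, counting their volume
either as LCSB or as SB.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationTable, SweetenerClass
from .fndds import FoodcodeRecord, Thresholds

__all__ = [
    "ConsumerGroup",
    "Scenario",
    "ParticipantDay",
    "WATER_CODES",
    "UNSWEETENED_CARBONATED_CODES",
    "grams_to_floz",
    "eligibility_filter",
    "water_intake",
    "beverage_totals",
    "assign_group",
    "build_participant_days",
    "assign_groups",
    "DAYS_COLUMNS",
]

#: Plain-water foodcodes: tap, bottled, baby water.
WATER_CODES = frozenset({94000100, 94100100, 94300100})

#: Unsweetened carbonated water; never counted as plain water.
UNSWEETENED_CARBONATED_CODES = frozenset({92410210})

#: Absolute tolerance (g) between questionnaire water and summed water items.
WATER_DISCREPANCY_TOLERANCE_G = 1.0

DAYS_COLUMNS = [
    "participant_id",
    "oz_lcsb",
    "oz_sb",
    "oz_mixed",
    "oz_water",
    "water_discrepancy",
]


class ConsumerGroup(str, enum.Enum):
    WATER = "WATER"
    LCSB = "LCSB"
    SB = "SB"
    LCSB_SB = "LCSB_SB"
    UNGROUPED = "UNGROUPED"


class Scenario(str, enum.Enum):
    """How mixed-foodcode volume is counted in group assignment."""

    MIXED_AS_LCSB = "MIXED_AS_LCSB"
    MIXED_AS_SB = "MIXED_AS_SB"


@dataclass(frozen=True)
class ParticipantDay:
    """One participant's recall-day beverage volumes (fl oz) and group."""

    participant_id: str
    oz_lcsb: float
    oz_sb: float
    oz_mixed: float
    oz_water: float
    water_discrepancy: bool
    group: ConsumerGroup | None = None


def grams_to_floz(grams: float, factor: float) -> float:
    """Convert a mass in grams to fluid ounces with a density factor."""
    if factor <= 0:
        raise ValueError(f"grams-per-fl-oz factor must be positive, got {factor}")
    return grams / factor


def eligibility_filter(participant: Mapping) -> bool:
    """Analysis-population filter: aged 2-17, one reliable in-person recall,
    no physician diabetes diagnosis."""
    return (
        2 <= participant["age_years"] <= 17
        and bool(participant["reliable_recall"])
        and not bool(participant["diabetes_dx"])
    )


def water_intake(
    participant: Mapping,
    recall_items: pd.DataFrame,
    water_codes: frozenset[int] = WATER_CODES,
    th: Thresholds | None = None,
    tolerance_g: float = WATER_DISCREPANCY_TOLERANCE_G,
) -> tuple[float, bool]:
    """Plain-water intake (fl oz) and a questionnaire/recall discrepancy flag.

    The questionnaire variable is the authoritative source; it is converted
    at the plain-water density.  The flag is set when the questionnaire grams
    differ from the summed recall grams over the plain-water foodcodes by
    more than `tolerance_g` (these totals should agree but fail to in a small
    share of real recalls).
    """
    th = th or Thresholds()
    q_grams = float(participant["questionnaire_water_g"])
    if q_grams < 0:
        raise ValueError(
            f"participant {participant['participant_id']}: negative questionnaire water"
        )
    mask = recall_items["code"].isin(water_codes)
    summed = float(recall_items.loc[mask, "grams"].sum())
    oz = q_grams / th.water_g_per_floz
    return oz, abs(q_grams - summed) > tolerance_g


def beverage_totals(
    recall_items: pd.DataFrame,
    tab: ClassificationTable,
    foodcodes: Sequence[FoodcodeRecord],
    water_codes: frozenset[int] = WATER_CODES,
    unsweetened_carbonated_codes: frozenset[int] = UNSWEETENED_CARBONATED_CODES,
) -> pd.DataFrame:
    """Per-participant sweetened-beverage volumes (fl oz) by class.

    Each item is converted with its own foodcode's conversion factor and
    summed into the LCSB, SB, or MIXED column of its classification;
    NONSWEETENED codes (including plain and unsweetened carbonated water)
    contribute nothing.  Items on codes absent from the classification table
    raise an error listing the orphans.
    """
    factors = {r.code: r.grams_per_floz for r in foodcodes}
    ignorable = water_codes | unsweetened_carbonated_codes
    codes = recall_items["code"].to_numpy()
    orphans = sorted(
        {int(c) for c in codes if c not in tab.labels and c not in ignorable}
    )
    if orphans:
        raise ValueError(f"recall items reference foodcodes absent from the classification table: {orphans}")

    out: dict[str, dict[str, float]] = {}
    grams = recall_items["grams"].to_numpy()
    pids = recall_items["participant_id"].to_numpy()
    for pid, code, g in zip(pids, codes, grams):
        code = int(code)
        if code in ignorable:
            continue
        cls = tab.labels[code]
        if cls is SweetenerClass.NONSWEETENED:
            continue
        if code not in factors:
            raise ValueError(f"no conversion factor for foodcode {code}")
        oz = grams_to_floz(float(g), factors[code])
        row = out.setdefault(pid, {"oz_lcsb": 0.0, "oz_sb": 0.0, "oz_mixed": 0.0})
        key = {
            SweetenerClass.LCSB: "oz_lcsb",
            SweetenerClass.SB: "oz_sb",
            SweetenerClass.MIXED: "oz_mixed",
        }[cls]
        row[key] += oz
    rows = [
        {"participant_id": pid, **vals} for pid, vals in sorted(out.items())
    ]
    return pd.DataFrame(rows, columns=["participant_id", "oz_lcsb", "oz_sb", "oz_mixed"])


def assign_group(
    day: ParticipantDay | Mapping,
    scenario: Scenario | str,
    th: Thresholds | None = None,
) -> ConsumerGroup:
    """Consumer-group assignment against the 4 fl oz threshold.

    Mixed-code volume counts toward the effective LCSB total under
    MIXED_AS_LCSB and toward the effective SB total under MIXED_AS_SB.
    "At least" is inclusive (>=) and "fewer than" strict (<), exactly as the
    group definitions are worded.
    """
    th = th or Thresholds()
    scenario = Scenario(scenario)
    get = day.__getitem__ if isinstance(day, Mapping) else lambda k: getattr(day, k)
    oz_lcsb, oz_sb = float(get("oz_lcsb")), float(get("oz_sb"))
    oz_mixed, oz_water = float(get("oz_mixed")), float(get("oz_water"))
    if scenario is Scenario.MIXED_AS_LCSB:
        eff_lcsb, eff_sb = oz_lcsb + oz_mixed, oz_sb
    else:
        eff_lcsb, eff_sb = oz_lcsb, oz_sb + oz_mixed
    t = th.group_min_oz
    if eff_lcsb >= t and eff_sb >= t:
        return ConsumerGroup.LCSB_SB
    if eff_lcsb >= t:
        return ConsumerGroup.LCSB
    if eff_sb >= t:
        return ConsumerGroup.SB
    if oz_water >= t:
        return ConsumerGroup.WATER
    return ConsumerGroup.UNGROUPED


def build_participant_days(
    participants: pd.DataFrame,
    recall_items: pd.DataFrame,
    tab: ClassificationTable,
    foodcodes: Sequence[FoodcodeRecord],
    th: Thresholds | None = None,
    water_codes: frozenset[int] = WATER_CODES,
    unsweetened_carbonated_codes: frozenset[int] = UNSWEETENED_CARBONATED_CODES,
) -> pd.DataFrame:
    """Recall-day volume table for the eligible analysis population.

    Returns one row per eligible participant with per-class beverage volumes,
    plain-water intake, and the water-discrepancy flag.  Group assignment is
    scenario-specific and applied separately (:func:`assign_groups`).
    """
    th = th or Thresholds()
    eligible = participants[participants.apply(eligibility_filter, axis=1)]
    items = recall_items[recall_items["participant_id"].isin(set(eligible["participant_id"]))]
    totals = beverage_totals(
        items, tab, foodcodes, water_codes, unsweetened_carbonated_codes
    )
    days = eligible[["participant_id"]].merge(totals, on="participant_id", how="left")
    for col in ("oz_lcsb", "oz_sb", "oz_mixed"):
        days[col] = days[col].fillna(0.0)

    grouped = dict(tuple(items.groupby("participant_id")))
    empty = items.iloc[0:0]
    oz_water, flags = [], []
    for _, p in eligible.iterrows():
        own = grouped.get(p["participant_id"], empty)
        oz, flag = water_intake(p, own, water_codes, th)
        oz_water.append(oz)
        flags.append(flag)
    days["oz_water"] = oz_water
    days["water_discrepancy"] = flags
    return days[DAYS_COLUMNS]


def assign_groups(
    days: pd.DataFrame,
    scenario: Scenario | str,
    th: Thresholds | None = None,
) -> pd.DataFrame:
    """Copy of `days` with a ``group`` column for the given scenario."""
    th = th or Thresholds()
    out = days.copy()
    out["group"] = [
        assign_group(row, scenario, th).value for _, row in days.iterrows()
    ]
    return out
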