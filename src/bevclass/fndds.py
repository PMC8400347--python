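"""Domain records and delimited-text I/O for dietary-survey foodcode data.

The national dietary-recall infrastructure identifies every consumed item by
an 8-digit foodcode whose nutrient values, descriptions, and fluid-ounce-to-
gram conversion factor are published per 2-year survey cycle.  This module
holds the record types for that world -- foodcodes, branded products filed
under a foodcode, per-participant recall items, and participant records with
complex-survey design variables -- together with CSV readers/writers and a
cross-cycle audit utility.

All files are comma-separated UTF-8 with a mandatory header.  Multi-valued
cells (ingredient lists) use ``;`` as the inner separator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FoodcodeRecord",
    "BrandedProduct",
    "RecallItem",
    "Thresholds",
    "CycleAudit",
    "normalize_text",
    "tokenize",
    "read_foodcode_table",
    "write_foodcode_table",
    "read_products",
    "write_products",
    "read_recalls",
    "write_recalls",
    "read_participants",
    "write_participants",
    "audit_cycles",
    "FOODCODE_COLUMNS",
    "PRODUCT_COLUMNS",
    "RECALL_COLUMNS",
    "PARTICIPANT_COLUMNS",
    "OUTCOME_COLUMNS",
]

FOODCODE_COLUMNS = [
    "code",
    "cycle",
    "main_description",
    "additional_description",
    "wweia_category",
    "kcal_per_100g",
    "grams_per_floz",
]

PRODUCT_COLUMNS = [
    "brand",
    "code",
    "cycle",
    "ingredients",
    "kcal_per_8floz_mfr",
    "ingredients_known",
]

RECALL_COLUMNS = ["participant_id", "code", "grams"]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "age_years",
    "sex",
    "race_ethnicity",
    "income",
    "physical_activity",
    "bmi_percentile",
    "diabetes_dx",
    "reliable_recall",
    "questionnaire_water_g",
    "stratum_id",
    "psu_id",
    "weight",
]

#: Dietary-outcome columns; optional in participants.csv, required by the
#: outcome models.
OUTCOME_COLUMNS = ["energy_kcal", "carbohydrate_g", "total_sugar_g", "added_sugar_g"]

_WS_RE = re.compile(r"\s+")
_PUNCT_RE = re.compile(r"[^\w\s]")


def normalize_text(text: str) -> str:
    """Normalize free text for lexicon matching.

    Lowercases, maps hyphens to spaces (so ``sugar-free`` == ``sugar free``),
    strips remaining punctuation, and collapses whitespace.  Archived labels
    and database descriptions vary typographically; matching happens on this
    canonical form only.
    """
    text = text.lower().replace("-", " ").replace("/", " ")
    text = _PUNCT_RE.sub("", text)
    return _WS_RE.sub(" ", text).strip()


def tokenize(text: str) -> list[str]:
    """Whole-word tokens of the normalized text."""
    norm = normalize_text(text)
    return norm.split() if norm else []


class TableReadError(ValueError):
    """A delimited input file violated the schema or a record invariant."""


@dataclass(frozen=True)
class FoodcodeRecord:
    """One foodcode's descriptors and nutrient facts in one survey cycle.

    ``kcal_per_100g`` is the database energy density; ``grams_per_floz`` is
    the beverage-specific density used to convert reported fluid ounces to
    grams (plain water: 29.6 g/fl oz; observed beverage range roughly 16-37).
    """

    code: int
    cycle: str
    main_description: str
    additional_description: str
    wweia_category: int
    kcal_per_100g: float
    grams_per_floz: float

    def __post_init__(self) -> None:
        if not (isinstance(self.code, int) and 10_000_000 <= self.code <= 99_999_999):
            raise ValueError(f"foodcode {self.code!r} is not an 8-digit integer")
        if not self.cycle:
            raise ValueError("cycle label must be non-empty")
        if not (self.kcal_per_100g >= 0 and math.isfinite(self.kcal_per_100g)):
            raise ValueError(f"code {self.code}: kcal_per_100g must be finite and >= 0")
        if not (10 <= self.grams_per_floz <= 40):
            raise ValueError(
                f"code {self.code}: grams_per_floz {self.grams_per_floz} outside [10, 40]"
            )


@dataclass(frozen=True)
class BrandedProduct:
    """A named beverage filed under a foodcode in one cycle.

    ``ingredients`` is the ordered ingredient list, or ``None`` when no
    contemporaneous ingredient list could be located (an archived label gap);
    an unknown list is distinct from a known-empty one.  ``kcal_per_8floz_mfr``
    is the manufacturer-declared energy per 8 fl oz serving, ``None`` when the
    product could not be located.
    """

    brand: str
    code: int
    cycle: str
    ingredients: tuple[str, ...] | None
    kcal_per_8floz_mfr: float | None = None

    def __post_init__(self) -> None:
        if not (10_000_000 <= self.code <= 99_999_999):
            raise ValueError(f"product {self.brand!r}: foodcode {self.code!r} not 8 digits")
        if self.kcal_per_8floz_mfr is not None and not (
            self.kcal_per_8floz_mfr >= 0 and math.isfinite(self.kcal_per_8floz_mfr)
        ):
            raise ValueError(f"product {self.brand!r}: manufacturer kcal must be >= 0")

    @property
    def ingredients_known(self) -> bool:
        return self.ingredients is not None


@dataclass(frozen=True)
class RecallItem:
    """One recalled item: a foodcode and the consumed mass in grams."""

    participant_id: str
    code: int
    grams: float

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise ValueError(f"recall item {self.participant_id}/{self.code}: grams < 0")


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs used across the pipeline, in the units of their names.

    ``group_min_oz`` is the consumer-group threshold ("at least 4 oz").  The
    three caloric-density cut-offs per 8 fl oz serving are the regulatory
    low-calorie (<40) and no-calorie (<5) definitions and the published
    <6.7 kcal/8 oz criterion; the fourth is the <50 kcal/240 g mass-basis
    criterion.  ``water_g_per_floz`` is the plain-water density.
    """

    group_min_oz: float = 4.0
    fda_low_kcal_per_8floz: float = 40.0
    fda_no_kcal_per_8floz: float = 5.0
    leahy_kcal_per_8floz: float = 6.7
    maillot_kcal_per_240g: float = 50.0
    water_g_per_floz: float = 29.6

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be strictly positive")
        if not (
            self.fda_no_kcal_per_8floz
            < self.leahy_kcal_per_8floz
            < self.fda_low_kcal_per_8floz
            < self.maillot_kcal_per_240g
        ):
            raise ValueError("caloric thresholds must satisfy fda_no < leahy < fda_low < maillot")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableReadError(f"{path}: missing required column(s) {missing}")


def read_foodcode_table(path, cycle: str) -> list[FoodcodeRecord]:
    """Read a per-cycle foodcode table.

    Rows whose ``cycle`` column differs from `cycle` are rejected (dropped).
    Malformed codes and missing conversion factors raise :class:`TableReadError`
    naming the offending line/code.  (code, cycle) must be unique.
    """
    df = pd.read_csv(path, dtype={"code": str}, float_precision="round_trip")
    _require_columns(df, FOODCODE_COLUMNS, str(path))
    records: list[FoodcodeRecord] = []
    seen: set[int] = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if str(row["cycle"]) != cycle:
            continue
        code_str = str(row["code"]).strip()
        if not re.fullmatch(r"\d{8}", code_str):
            raise TableReadError(f"{path}, line {line}: malformed foodcode {code_str!r} (not 8 digits)")
        code = int(code_str)
        if code in seen:
            raise TableReadError(f"{path}, line {line}: duplicate (code, cycle) ({code}, {cycle})")
        if pd.isna(row["grams_per_floz"]):
            raise TableReadError(f"{path}: missing conversion factor for code {code}")
        try:
            rec = FoodcodeRecord(
                code=code,
                cycle=cycle,
                main_description=str(row["main_description"]),
                additional_description=(
                    "" if pd.isna(row["additional_description"]) else str(row["additional_description"])
                ),
                wweia_category=int(row["wweia_category"]),
                kcal_per_100g=float(row["kcal_per_100g"]),
                grams_per_floz=float(row["grams_per_floz"]),
            )
        except (ValueError, TypeError) as exc:
            raise TableReadError(f"{path}, line {line}: {exc}") from exc
        seen.add(code)
        records.append(rec)
    return records


def write_foodcode_table(records: Iterable[FoodcodeRecord], path) -> None:
    rows = [
        {
            "code": f"{r.code:08d}",
            "cycle": r.cycle,
            "main_description": r.main_description,
            "additional_description": r.additional_description,
            "wweia_category": r.wweia_category,
            "kcal_per_100g": repr(r.kcal_per_100g),
            "grams_per_floz": repr(r.grams_per_floz),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=FOODCODE_COLUMNS).to_csv(path, index=False)


def read_products(path, cycle: str | None = None) -> list[BrandedProduct]:
    """Read branded-product records; optionally restrict to one cycle.

    The ``ingredients`` cell is ``;``-separated; ``ingredients_known`` False
    marks products whose contemporaneous label could not be located, in which
    case the ingredient list is treated as unknown (not empty).
    """
    df = pd.read_csv(path, dtype={"code": str}, float_precision="round_trip")
    _require_columns(df, PRODUCT_COLUMNS, str(path))
    out: list[BrandedProduct] = []
    for idx, row in df.iterrows():
        line = idx + 2
        if cycle is not None and str(row["cycle"]) != cycle:
            continue
        code_str = str(row["code"]).strip()
        if not re.fullmatch(r"\d{8}", code_str):
            raise TableReadError(f"{path}, line {line}: malformed foodcode {code_str!r}")
        known = _parse_bool(row["ingredients_known"], path, line, "ingredients_known")
        if known:
            cell = "" if pd.isna(row["ingredients"]) else str(row["ingredients"])
            ingredients = tuple(s.strip() for s in cell.split(";") if s.strip())
        else:
            ingredients = None
        kcal = None if pd.isna(row["kcal_per_8floz_mfr"]) else float(row["kcal_per_8floz_mfr"])
        out.append(
            BrandedProduct(
                brand=str(row["brand"]),
                code=int(code_str),
                cycle=str(row["cycle"]),
                ingredients=ingredients,
                kcal_per_8floz_mfr=kcal,
            )
        )
    return out


def write_products(products: Iterable[BrandedProduct], path) -> None:
    rows = []
    for p in products:
        rows.append(
            {
                "brand": p.brand,
                "code": f"{p.code:08d}",
                "cycle": p.cycle,
                "ingredients": "" if p.ingredients is None else "; ".join(p.ingredients),
                "kcal_per_8floz_mfr": "" if p.kcal_per_8floz_mfr is None else repr(p.kcal_per_8floz_mfr),
                "ingredients_known": p.ingredients is not None,
            }
        )
    pd.DataFrame(rows, columns=PRODUCT_COLUMNS).to_csv(path, index=False)


def _parse_bool(value, path, line, col) -> bool:
    if isinstance(value, (bool,)):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise TableReadError(f"{path}, line {line}: column {col}: cannot parse boolean {value!r}")


def read_recalls(path) -> pd.DataFrame:
    """Read per-participant recall items (grams by foodcode)."""
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    _require_columns(df, RECALL_COLUMNS, str(path))
    df = df.copy()
    df["code"] = df["code"].astype(int)
    df["grams"] = df["grams"].astype(float)
    if (df["grams"] < 0).any():
        bad = df.index[df["grams"] < 0][0] + 2
        raise TableReadError(f"{path}, line {bad}: negative grams")
    return df[RECALL_COLUMNS]


def write_recalls(df: pd.DataFrame, path) -> None:
    df[RECALL_COLUMNS].to_csv(path, index=False)


def read_participants(path) -> pd.DataFrame:
    """Read participant records (demographics, design variables, outcomes).

    The four dietary-outcome columns are optional on read; models that need
    them will complain if absent.
    """
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    _require_columns(df, PARTICIPANT_COLUMNS, str(path))
    df = df.copy()
    for col in ("diabetes_dx", "reliable_recall"):
        df[col] = df[col].map(lambda v: _parse_bool(v, path, "?", col))
    if (df["weight"] <= 0).any():
        raise TableReadError(f"{path}: survey weights must be strictly positive")
    if ((df["bmi_percentile"] < 0) | (df["bmi_percentile"] > 100)).any():
        raise TableReadError(f"{path}: bmi_percentile outside [0, 100]")
    if (df["questionnaire_water_g"] < 0).any():
        raise TableReadError(f"{path}: negative questionnaire_water_g")
    if df["participant_id"].duplicated().any():
        raise TableReadError(f"{path}: duplicate participant_id")
    keep = PARTICIPANT_COLUMNS + [c for c in OUTCOME_COLUMNS if c in df.columns]
    return df[keep]


def write_participants(df: pd.DataFrame, path) -> None:
    cols = PARTICIPANT_COLUMNS + [c for c in OUTCOME_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


@dataclass
class CycleAudit:
    """Cross-cycle audit of foodcode tables.

    Presence/absence and drift findings are computed per code over the set of
    cycles, so the report does not depend on the order cycles are supplied in.
    """

    cycles: tuple[str, ...]
    partial_codes: dict[int, tuple[str, ...]] = field(default_factory=dict)
    description_drift: list[int] = field(default_factory=list)
    category_drift: list[int] = field(default_factory=list)
    category_union_count: int | None = None
    per_cycle_category_counts: dict[str, int] = field(default_factory=dict)


def audit_cycles(
    tables: Mapping[str, Sequence[FoodcodeRecord]],
    category_set: set[int] | None = None,
) -> CycleAudit:
    """Audit foodcode tables across survey cycles.

    Reports codes present in only some cycles, codes whose description or
    category changed, and -- when `category_set` is given -- how many distinct
    codes ever appeared in those categories (the union a pooled analysis would
    need) together with per-cycle counts.
    """
    if len(tables) < 2:
        raise ValueError("audit_cycles needs at least 2 cycles")
    cycles = tuple(sorted(tables))
    by_code: dict[int, dict[str, FoodcodeRecord]] = {}
    for cyc in cycles:
        for rec in tables[cyc]:
            by_code.setdefault(rec.code, {})[cyc] = rec
    audit = CycleAudit(cycles=cycles)
    for code in sorted(by_code):
        present = tuple(c for c in cycles if c in by_code[code])
        recs = [by_code[code][c] for c in present]
        if len(present) < len(cycles):
            audit.partial_codes[code] = present
        descs = {(r.main_description, r.additional_description) for r in recs}
        if len(descs) > 1:
            audit.description_drift.append(code)
        if len({r.wweia_category for r in recs}) > 1:
            audit.category_drift.append(code)
    if category_set is not None:
        union = {
            code
            for code, recs in by_code.items()
            if any(r.wweia_category in category_set for r in recs.values())
        }
        audit.category_union_count = len(union)
        audit.per_cycle_category_counts = {
            cyc: sum(1 for r in tables[cyc] if r.wweia_category in category_set)
            for cyc in cycles
        }
    return audit
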