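"""Beverage classification: four published strategy proxies and an
ingredient-based reference classifier with mixed-code detection.

Published analyses of national dietary-recall data have identified
low-calorie-sweetened beverages (LCSBs) in four general ways: (1) the
numbering structure of the foodcode database ("diet" carbonated soft drinks),
(2) the survey's food-category scheme (diet-drink categories), (3) caloric
density cut-offs, and (4) text searches of foodcode descriptions.  None of
these proxies agrees with the others, and none reliably tracks whether the
branded beverages filed under a foodcode actually list a low-calorie
sweetener (LCS) among their ingredients.

The reference classifier here works from the ingredient evidence itself: a
foodcode is LCSB when every known product under it lists at least one LCS
(a product listing both sugar and an LCS counts as LCS-containing), SB when
no product lists an LCS but at least one lists a caloric sweetener, MIXED
when some but not all products list an LCS, and NONSWEETENED when no product
lists any sweetener at all.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fndds import BrandedProduct, FoodcodeRecord, Thresholds, normalize_text, tokenize

__all__ = [
    "SweetenerClass",
    "Strategy3Criterion",
    "KcalSource",
    "StrategyConfig",
    "KcalPerServing",
    "ClassificationTable",
    "StrategyComparison",
    "UnknownClassificationError",
    "kcal_per_serving",
    "manufacturer_kcal_per_8floz",
    "strategy1_fndds_prefix",
    "strategy2_wweia",
    "strategy3_caloric_density",
    "strategy4_text",
    "find_lcs",
    "classify_by_ingredients",
    "build_classification_table",
    "compare_strategies",
    "STRATEGY_IDS",
]

STRATEGY_IDS = ("s1", "s2", "s3", "s4")


class SweetenerClass(str, enum.Enum):
    """Sweetener-exposure class of a foodcode within one cycle."""

    LCSB = "LCSB"
    SB = "SB"
    MIXED = "MIXED"
    NONSWEETENED = "NONSWEETENED"


class Strategy3Criterion(str, enum.Enum):
    FDA_LOW = "FDA_LOW"  # < 40 kcal / 8 fl oz
    FDA_NO = "FDA_NO"  # < 5 kcal / 8 fl oz
    LEAHY = "LEAHY"  # < 6.7 kcal / 8 fl oz
    MAILLOT = "MAILLOT"  # < 50 kcal / 240 g


class KcalSource(str, enum.Enum):
    FNDDS = "FNDDS"
    MANUFACTURER = "MANUFACTURER"


#: Low-calorie sweeteners recognized in ingredient lists.
DEFAULT_LCS_LEXICON = (
    "aspartame",
    "sucralose",
    "acesulfame potassium",
    "acek",
    "saccharin",
    "neotame",
    "advantame",
    "stevia",
    "steviol glycosides",
    "rebaudioside a",
    "reba",
    "rebiana",
    "monk fruit",
    "luo han guo",
)

#: Caloric sweeteners; a product listing one (and no LCS) is sugar-sweetened.
CALORIC_SWEETENER_TERMS = (
    "sugar",
    "cane sugar",
    "brown sugar",
    "high fructose corn syrup",
    "corn syrup",
    "sucrose",
    "glucose",
    "dextrose",
    "fructose",
    "maltose",
    "honey",
    "agave",
    "cane juice",
    "fruit juice concentrate",
)

#: Description terms that explicitly assert LCS content.  Deliberately
#: narrower than the strategy-4 list: "light", "reduced sugar", "less sugar"
#: describe products that may be sugar-only, so they never override (or stand
#: in for) ingredient evidence.
EXPLICIT_LCS_TERMS = (
    "low calorie sweetener",
    "no calorie sweetener",
    "sugar free",
    "diet",
    "dietetic",
    "artificial sweetener",
)


@dataclass(frozen=True)
class StrategyConfig:
    """Configuration of the four strategy proxies and the LCS lexicon."""

    strategy1_prefix: str = "924"
    strategy1_terms: tuple[str, ...] = (
        "sugar free",
        "reduced sugar",
        "low calorie sweetener",
        "no calorie sweetener",
    )
    strategy2_categories: frozenset[int] = frozenset({7102, 7104, 7106})
    strategy3_criterion: Strategy3Criterion = Strategy3Criterion.FDA_LOW
    strategy3_kcal_source: KcalSource = KcalSource.FNDDS
    strategy4_terms: tuple[str, ...] = (
        "diet",
        "dietetic",
        "low calorie",
        "no sugar added",
        "light",
        "lite",
        "sugar free",
        "sugar substitute",
        "low calorie sweetener",
        "no calorie sweetener",
        "reduced sugar",
        "less sugar",
        "zero calorie",
    )
    lcs_lexicon: tuple[str, ...] = DEFAULT_LCS_LEXICON
    explicit_lcs_terms: tuple[str, ...] = EXPLICIT_LCS_TERMS
    caloric_sweetener_terms: tuple[str, ...] = CALORIC_SWEETENER_TERMS


@dataclass(frozen=True)
class KcalPerServing:
    """Energy content on the two serving bases used by density criteria.

    An 8 fl oz serving weighs ``8 * grams_per_floz`` grams, so
    ``kcal_per_8floz = kcal_per_100g * 8 * grams_per_floz / 100``; the mass
    basis is simply ``kcal_per_240g = kcal_per_100g * 2.4`` and never involves
    the fluid-ounce factor.  Either field may be None when the underlying
    value (e.g. a manufacturer declaration) is unavailable.
    """

    kcal_per_8floz: float | None
    kcal_per_240g: float | None
    source: KcalSource


class UnknownClassificationError(ValueError):
    """Raised when a foodcode carries no usable classification evidence."""


def kcal_per_serving(rec: FoodcodeRecord) -> KcalPerServing:
    """Database energy per 8 fl oz and per 240 g for a foodcode."""
    k8 = rec.kcal_per_100g * (8.0 * rec.grams_per_floz) / 100.0
    k240 = rec.kcal_per_100g * 2.4
    return KcalPerServing(kcal_per_8floz=k8, kcal_per_240g=k240, source=KcalSource.FNDDS)


def manufacturer_kcal_per_8floz(products: Sequence[BrandedProduct]) -> float | None:
    """Foodcode-level manufacturer kcal/8 fl oz: minimum over known products.

    When brands under one code disagree, the minimum is the most inclusive
    value for low-calorie screening; None when no product declares energy.
    """
    vals = [p.kcal_per_8floz_mfr for p in products if p.kcal_per_8floz_mfr is not None]
    return min(vals) if vals else None


def _phrase_in_tokens(tokens: Sequence[str], phrase_tokens: Sequence[str]) -> bool:
    n, m = len(tokens), len(phrase_tokens)
    if m == 0 or m > n:
        return False
    return any(tuple(tokens[i : i + m]) == tuple(phrase_tokens) for i in range(n - m + 1))


def _match_any_term(text: str, terms: Iterable[str]) -> bool:
    """Whole-token matching: single-word terms match whole tokens only, so
    "diet" does not fire on "dietary"; multiword terms match as contiguous
    token phrases; hyphen/space variants are equivalent."""
    tokens = tokenize(text)
    return any(_phrase_in_tokens(tokens, tokenize(term)) for term in terms)


def description_matches(rec: FoodcodeRecord, terms: Iterable[str]) -> bool:
    text = f"{rec.main_description} {rec.additional_description}"
    return _match_any_term(text, terms)


def strategy1_fndds_prefix(rec: FoodcodeRecord, cfg: StrategyConfig | None = None) -> bool:
    """Foodcode-numbering proxy: carbonated-soft-drink prefix plus a
    sugar-free/low-calorie description."""
    cfg = cfg or StrategyConfig()
    if not f"{rec.code:08d}".startswith(cfg.strategy1_prefix):
        return False
    return description_matches(rec, cfg.strategy1_terms)


def strategy2_wweia(rec: FoodcodeRecord, cfg: StrategyConfig | None = None) -> bool:
    """Survey food-category proxy: the three diet-drink categories."""
    cfg = cfg or StrategyConfig()
    return rec.wweia_category in cfg.strategy2_categories


def strategy3_caloric_density(
    k: KcalPerServing,
    cfg: StrategyConfig | None = None,
    th: Thresholds | None = None,
) -> bool | None:
    """Caloric-density proxy under the configured criterion.

    Comparisons are strict ``<`` throughout; boundary values are excluded.
    Returns None (explicitly unknown, not False) when the kcal figure the
    criterion needs is unavailable.
    """
    cfg = cfg or StrategyConfig()
    th = th or Thresholds()
    crit = Strategy3Criterion(cfg.strategy3_criterion)
    if crit is Strategy3Criterion.MAILLOT:
        if k.kcal_per_240g is None:
            return None
        return k.kcal_per_240g < th.maillot_kcal_per_240g
    if k.kcal_per_8floz is None:
        return None
    cut = {
        Strategy3Criterion.FDA_LOW: th.fda_low_kcal_per_8floz,
        Strategy3Criterion.FDA_NO: th.fda_no_kcal_per_8floz,
        Strategy3Criterion.LEAHY: th.leahy_kcal_per_8floz,
    }[crit]
    return k.kcal_per_8floz < cut


def strategy4_text(rec: FoodcodeRecord, cfg: StrategyConfig | None = None) -> bool:
    """Description text-search proxy over the configured term list."""
    cfg = cfg or StrategyConfig()
    return description_matches(rec, cfg.strategy4_terms)


def find_lcs(ingredients: Sequence[str], lexicon: Sequence[str] = DEFAULT_LCS_LEXICON) -> tuple[str, ...]:
    """Recognized low-calorie sweeteners in an ingredient list.

    Each ingredient string is normalized and each lexicon entry is matched as
    a whole-token phrase inside it, so "acesulfame potassium" matches in
    "sucralose and acesulfame potassium" but "reba" does not fire inside
    another word.  Returns lexicon entries in lexicon order, deduplicated.
    """
    found: list[str] = []
    ing_tokens = [tokenize(i) for i in ingredients]
    for term in lexicon:
        pt = tokenize(term)
        if any(_phrase_in_tokens(toks, pt) for toks in ing_tokens):
            found.append(term)
    return tuple(found)


def _has_caloric_sweetener(ingredients: Sequence[str], cfg: StrategyConfig) -> bool:
    ing_tokens = [tokenize(i) for i in ingredients]
    return any(
        _phrase_in_tokens(toks, tokenize(term))
        for term in cfg.caloric_sweetener_terms
        for toks in ing_tokens
    )


def _classify_with_reason(
    code: int,
    cycle: str,
    products: Sequence[BrandedProduct],
    rec: FoodcodeRecord | None,
    cfg: StrategyConfig,
) -> tuple[SweetenerClass, str]:
    for p in products:
        if p.code != code or p.cycle != cycle:
            raise ValueError(
                f"product {p.brand!r} ({p.code}, {p.cycle}) does not belong to ({code}, {cycle})"
            )
    explicit = rec is not None and description_matches(rec, cfg.explicit_lcs_terms)
    known = [p for p in products if p.ingredients is not None]
    unknown_n = len(products) - len(known)
    note = f"; {unknown_n} product(s) with unknown ingredients excluded" if unknown_n else ""

    if not known:
        if explicit:
            return (
                SweetenerClass.LCSB,
                f"description explicitly indicates LCS; no known ingredient lists{note}",
            )
        raise UnknownClassificationError(
            f"code {code} ({cycle}): all products have unknown ingredients and the "
            "description does not explicitly indicate LCS"
        )

    with_lcs = [p for p in known if find_lcs(p.ingredients, cfg.lcs_lexicon)]
    n_lcs, n_known = len(with_lcs), len(known)
    if n_lcs == n_known:
        return SweetenerClass.LCSB, f"all {n_known} known product(s) list an LCS{note}"
    if n_lcs > 0:
        return (
            SweetenerClass.MIXED,
            f"{n_lcs} of {n_known} known product(s) list an LCS{note}",
        )
    # No known product lists an LCS.
    sugary = any(_has_caloric_sweetener(p.ingredients, cfg) for p in known)
    conflict = "; description suggests LCS but ingredients win (conflict logged)" if explicit else ""
    if sugary:
        return SweetenerClass.SB, f"no known product lists an LCS; caloric sweetener present{note}{conflict}"
    return (
        SweetenerClass.NONSWEETENED,
        f"no known product lists any sweetener{note}{conflict}",
    )


def classify_by_ingredients(
    code: int,
    cycle: str,
    products: Sequence[BrandedProduct],
    rec: FoodcodeRecord | None = None,
    cfg: StrategyConfig | None = None,
) -> SweetenerClass:
    """Ingredient-based reference classification of one (code, cycle).

    A product listing both sugar and an LCS counts as LCS-containing.
    Products with unknown ingredient lists are excluded from the
    all/some/none tally; if no evidence remains and the description does not
    explicitly assert LCS, an :class:`UnknownClassificationError` is raised
    rather than guessing.  When ingredient evidence contradicts an explicit
    description, the ingredients win.
    """
    cls, _ = _classify_with_reason(code, cycle, products, rec, cfg or StrategyConfig())
    return cls


@dataclass
class ClassificationTable:
    """Per-cycle classification of a foodcode universe.

    ``labels`` is total over the input codes; ``strategy_flags`` holds the
    boolean result of each strategy proxy per code (None where strategy 3
    lacked its kcal figure); ``provenance`` records the evidence behind each
    label.  Deterministic given inputs and configuration.
    """

    cycle: str
    labels: dict[int, SweetenerClass] = field(default_factory=dict)
    strategy_flags: dict[tuple[int, str], bool | None] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)

    def counts(self) -> dict[SweetenerClass, int]:
        out = {c: 0 for c in SweetenerClass}
        for cls in self.labels.values():
            out[cls] += 1
        return out

    def codes_with_class(self, cls: SweetenerClass) -> list[int]:
        return sorted(c for c, v in self.labels.items() if v is cls)

    def flagged(self, strategy: str) -> list[int]:
        return sorted(c for (c, s), v in self.strategy_flags.items() if s == strategy and v)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code in sorted(self.labels):
            rows.append(
                {
                    "code": code,
                    "cycle": self.cycle,
                    "class": self.labels[code].value,
                    **{s: self.strategy_flags.get((code, s)) for s in STRATEGY_IDS},
                    "provenance": self.provenance.get(code, ""),
                }
            )
        return pd.DataFrame(rows, columns=["code", "cycle", "class", *STRATEGY_IDS, "provenance"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cycle: str) -> "ClassificationTable":
        tab = cls(cycle=cycle)
        for _, row in df.iterrows():
            code = int(row["code"])
            tab.labels[code] = SweetenerClass(row["class"])
            for s in STRATEGY_IDS:
                v = row.get(s)
                tab.strategy_flags[(code, s)] = None if pd.isna(v) else bool(v)
            tab.provenance[code] = str(row.get("provenance", ""))
        return tab


def build_classification_table(
    foodcodes: Sequence[FoodcodeRecord],
    products: Sequence[BrandedProduct],
    cfg: StrategyConfig | None = None,
    th: Thresholds | None = None,
    permissive: bool = False,
) -> ClassificationTable:
    """Classify every foodcode of one cycle and fill all strategy flags.

    Unknown-classification errors abort unless `permissive` is set, in which
    case they are downgraded to warnings and the code falls back to the
    <40 kcal/8 fl oz density rule on database energy (recorded in
    provenance) so that the label map stays total.
    """
    cfg = cfg or StrategyConfig()
    th = th or Thresholds()
    if not foodcodes:
        return ClassificationTable(cycle="")
    cycles = {r.cycle for r in foodcodes}
    if len(cycles) > 1:
        raise ValueError(f"foodcodes span multiple cycles: {sorted(cycles)}")
    cycle = next(iter(cycles))
    by_code: dict[int, list[BrandedProduct]] = {}
    for p in products:
        if p.cycle == cycle:
            by_code.setdefault(p.code, []).append(p)

    tab = ClassificationTable(cycle=cycle)
    for rec in foodcodes:
        prods = by_code.get(rec.code, [])
        try:
            cls, reason = _classify_with_reason(rec.code, cycle, prods, rec, cfg)
        except UnknownClassificationError as exc:
            if not permissive:
                raise
            warnings.warn(str(exc), stacklevel=2)
            k = kcal_per_serving(rec)
            cls = (
                SweetenerClass.LCSB
                if k.kcal_per_8floz < th.fda_low_kcal_per_8floz
                else SweetenerClass.SB
            )
            reason = "fallback: unknown ingredients, labeled by <40 kcal/8 fl oz density rule"
        tab.labels[rec.code] = cls
        tab.provenance[rec.code] = reason
        if cfg.strategy3_kcal_source is KcalSource.MANUFACTURER:
            mfr = manufacturer_kcal_per_8floz(prods)
            k = KcalPerServing(
                kcal_per_8floz=mfr,
                kcal_per_240g=None,
                source=KcalSource.MANUFACTURER,
            )
        else:
            k = kcal_per_serving(rec)
        tab.strategy_flags[(rec.code, "s1")] = strategy1_fndds_prefix(rec, cfg)
        tab.strategy_flags[(rec.code, "s2")] = strategy2_wweia(rec, cfg)
        tab.strategy_flags[(rec.code, "s3")] = strategy3_caloric_density(k, cfg, th)
        tab.strategy_flags[(rec.code, "s4")] = strategy4_text(rec, cfg)
    return tab


@dataclass
class StrategyComparison:
    """Cross-strategy agreement summary over one classification table."""

    totals: dict[str, int]
    ingredient_lcsb_total: int
    agreement: dict[tuple[str, str], tuple[int, int]]  # (agree, disagree)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strategy_a": a, "strategy_b": b, "agree": ag, "disagree": dis}
            for (a, b), (ag, dis) in sorted(self.agreement.items())
        ]
        return pd.DataFrame(rows)


def compare_strategies(tab: ClassificationTable) -> StrategyComparison:
    """Per-strategy LCSB totals and pairwise agreement counts.

    A strategy-3 flag of None (kcal unavailable) counts as not flagged in the
    totals and is skipped in pairwise comparisons involving strategy 3.
    """
    codes = sorted(tab.labels)
    totals = {
        s: sum(1 for c in codes if tab.strategy_flags.get((c, s))) for s in STRATEGY_IDS
    }
    agreement: dict[tuple[str, str], tuple[int, int]] = {}
    for i, a in enumerate(STRATEGY_IDS):
        for b in STRATEGY_IDS[i + 1 :]:
            agree = disagree = 0
            for c in codes:
                fa, fb = tab.strategy_flags.get((c, a)), tab.strategy_flags.get((c, b))
                if fa is None or fb is None:
                    continue
                if fa == fb:
                    agree += 1
                else:
                    disagree += 1
            agreement[(a, b)] = (agree, disagree)
    return StrategyComparison(
        totals=totals,
        ingredient_lcsb_total=sum(
            1 for c in codes if tab.labels[c] is SweetenerClass.LCSB
        ),
        agreement=agreement,
    )
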