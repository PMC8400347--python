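"""Synthetic dietary-survey data generator.

Emulates the structures the pipeline consumes -- a per-cycle foodcode
universe with branded products, a child/adolescent participant population
with a stratified, clustered, weighted survey design, and per-participant
recall items -- so that every pipeline stage and statistical property can be
exercised without external survey data.  The generator mirrors the features
that make real recall data awkward:

* a small share of foodcodes are *mixed* (their branded products disagree on
  low-calorie sweetener content);
* database and manufacturer energy values disagree, occasionally landing on
  opposite sides of the 40 kcal/8 fl oz low-calorie boundary;
* beverage densities vary by foodcode (conversion factors drawn from the
  24-32 g/fl oz range), and volumes are generated in fluid ounces but stored
  as grams via each code's own factor so the pipeline's conversion is
  genuinely exercised;
* roughly 3% of questionnaire plain-water totals disagree with the summed
  plain-water recall items.

Every draw flows from one seed; identical configurations produce
byte-identical CSV output.  A :class:`TruthRecord` carries enough
bookkeeping (true code classes, per-scenario true groups, true outcome
means) to score any pipeline output exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import SweetenerClass
from .fndds import (
    OUTCOME_COLUMNS,
    BrandedProduct,
    FoodcodeRecord,
    Thresholds,
    read_foodcode_table,
    read_products,
    write_foodcode_table,
    write_participants,
    write_products,
    write_recalls,
)
from .recall import WATER_CODES, ConsumerGroup, Scenario

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "gen_universe",
    "gen_population",
    "fixture_table2",
    "fixture_table3",
    "write_dataset",
    "TABLE2_CYCLE",
]

TABLE2_CYCLE = "2013-2016-combined"

_GROUPS = ("WATER", "LCSB", "SB", "LCSB_SB", "UNGROUPED")

_RACE_LEVELS = ("hispanic", "nh_black", "nh_white", "other")
_INCOME_LEVELS = ("high", "low", "middle")
_ACTIVITY_LEVELS = ("active", "moderate", "sedentary")

# Fixed covariate effects shared by generator and recoverable by the models.
_AGE_CENTER, _BMI_CENTER = 9.5, 50.0
_COV_EFFECTS = {
    "energy_kcal": {"age": 14.0, "male": 70.0, "bmi": 0.8},
    "carbohydrate_g": {"age": 5.0, "male": 8.0, "bmi": 0.1},
    "total_sugar_g": {"age": 2.0, "male": 3.0, "bmi": 0.05},
    "added_sugar_g": {"age": 1.0, "male": 2.0, "bmi": 0.05},
}
_RACE_EFFECTS = {"hispanic": 0.0, "nh_black": 20.0, "nh_white": 10.0, "other": -10.0}
_INCOME_EFFECTS = {"high": 0.0, "low": 15.0, "middle": 5.0}
_ACTIVITY_EFFECTS = {"active": 25.0, "moderate": 10.0, "sedentary": 0.0}
# The categorical shifts above apply to energy; other outcomes use a tenth.
_CAT_SCALE = {"energy_kcal": 1.0, "carbohydrate_g": 0.1, "total_sugar_g": 0.1, "added_sugar_g": 0.1}
# Coupling of non-energy outcomes to the energy noise term (makes Model 2's
# energy adjustment consequential).
_ENERGY_COUPLING = {"carbohydrate_g": 0.05, "total_sugar_g": 0.03, "added_sugar_g": 0.02}


def _default_effects() -> dict:
    return {
        "energy_kcal": {"WATER": 0.0, "LCSB": 160.0, "SB": 320.0, "LCSB_SB": 490.0, "UNGROUPED": 0.0},
        "carbohydrate_g": {"WATER": 0.0, "LCSB": 34.0, "SB": 60.0, "LCSB_SB": 89.0, "UNGROUPED": 0.0},
        "total_sugar_g": {"WATER": 0.0, "LCSB": 24.0, "SB": 46.0, "LCSB_SB": 65.0, "UNGROUPED": 0.0},
        "added_sugar_g": {"WATER": 0.0, "LCSB": 27.0, "SB": 36.0, "LCSB_SB": 55.0, "UNGROUPED": 0.0},
    }


def _default_baselines() -> dict:
    return {"energy_kcal": 1560.0, "carbohydrate_g": 192.0, "total_sugar_g": 72.0, "added_sugar_g": 33.0}


def _default_noise() -> dict:
    return {"energy_kcal": 450.0, "carbohydrate_g": 60.0, "total_sugar_g": 35.0, "added_sugar_g": 28.0}


def _default_propensities() -> dict:
    return {"WATER": 0.15, "LCSB": 0.08, "SB": 0.61, "LCSB_SB": 0.11, "UNGROUPED": 0.05}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic survey.

    Universe composition mirrors a single-cycle sweetened-beverage universe
    (roughly 30% LCSB, 58% SB, 4% mixed, 8% non-sweetened); conversion
    factors span 24-32 g/fl oz; the water-questionnaire mismatch rate is 3%.
    Group propensities and the additive outcome effects follow the ordering
    water < LCSB < SB < LCSB+SB for energy.  ``mixed_consumer_rate`` is the
    share of sweetened-beverage consumers whose recall routes additional
    volume through a mixed foodcode (the lever the two-scenario analysis
    exercises); mixed volume is never given to water-only or ungrouped
    participants.
    """

    seed: int = 0
    cycle: str = "2013-2014"
    # universe
    n_codes: int = 300
    frac_lcsb: float = 0.30
    frac_sb: float = 0.58
    frac_mixed: float = 0.04
    frac_nonsweetened: float = 0.08
    brands_per_code: tuple[int, int] = (1, 3)
    kcal_lcsb_8floz: tuple[float, float] = (0.0, 15.0)
    kcal_sb_8floz: tuple[float, float] = (60.0, 160.0)
    kcal_mixed_8floz: tuple[float, float] = (60.0, 140.0)
    mfr_noise_sd: float = 3.0
    mfr_discordance_rate: float = 0.10
    lcs_and_sugar_rate: float = 0.20
    conversion_factor_range: tuple[float, float] = (24.0, 32.0)
    # population
    n_participants: int = 1200
    group_propensities: dict = field(default_factory=_default_propensities)
    mixed_consumer_rate: float = 0.08
    baselines: dict = field(default_factory=_default_baselines)
    effect_sizes: dict = field(default_factory=_default_effects)
    noise_sd: dict = field(default_factory=_default_noise)
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_sigma: float = 0.5
    water_mismatch_rate: float = 0.03
    ineligible_rate: float = 0.05

    def __post_init__(self) -> None:
        fracs = [self.frac_lcsb, self.frac_sb, self.frac_mixed, self.frac_nonsweetened]
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("universe composition fractions must be >= 0 and sum to 1")
        if abs(sum(self.group_propensities.values()) - 1.0) > 1e-9:
            raise ValueError("group propensities must sum to 1")
        if set(self.group_propensities) != set(_GROUPS):
            raise ValueError(f"group propensities must cover {_GROUPS}")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise standard deviations must be >= 0")
        if self.brands_per_code[0] < 1 or self.brands_per_code[1] < self.brands_per_code[0]:
            raise ValueError("brands_per_code must be an increasing range with min >= 1")
        if self.frac_mixed > 0 and self.n_codes > 0 and self.brands_per_code[1] < 2:
            raise ValueError("mixed codes need brands_per_code max >= 2")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthRecord:
    """Generator bookkeeping sufficient to score pipeline output exactly."""

    code_class: dict[int, SweetenerClass] = field(default_factory=dict)
    intended_group: dict[str, str] = field(default_factory=dict)
    group_by_scenario: dict[str, dict[str, str]] = field(default_factory=dict)
    outcome_mean: dict[str, dict[str, float]] = field(default_factory=dict)
    volumes: dict[str, dict[str, float]] = field(default_factory=dict)

    def class_counts(self, include_water: bool = False) -> dict[SweetenerClass, int]:
        out = {c: 0 for c in SweetenerClass}
        for code, cls in self.code_class.items():
            if not include_water and code in WATER_CODES:
                continue
            out[cls] += 1
        return out


def _largest_remainder(n: int, fracs: list[float]) -> list[int]:
    """Integer composition summing to n, apportioned by largest remainder."""
    raw = [f * n for f in fracs]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


_LCS_POOL = ("aspartame", "sucralose", "acesulfame potassium", "stevia", "neotame")
_SUGAR_POOL = ("sugar", "high fructose corn syrup")


def gen_universe(cfg: GeneratorConfig) -> tuple[list[FoodcodeRecord], list[BrandedProduct], TruthRecord]:
    """Generate a foodcode universe with branded products.

    The class composition matches the configured fractions exactly (largest
    remainder apportionment); mixed codes carry at least two products that
    disagree on LCS content; LCSB products may list sugar alongside an LCS.
    The three plain-water foodcodes ride along as NONSWEETENED extras on top
    of ``n_codes``.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    counts = _largest_remainder(
        cfg.n_codes, [cfg.frac_lcsb, cfg.frac_sb, cfg.frac_mixed, cfg.frac_nonsweetened]
    )
    classes = (
        [SweetenerClass.LCSB] * counts[0]
        + [SweetenerClass.SB] * counts[1]
        + [SweetenerClass.MIXED] * counts[2]
        + [SweetenerClass.NONSWEETENED] * counts[3]
    )
    rng.shuffle(classes)
    # 8-digit beverage codes; avoid the reserved plain/carbonated water codes.
    pool = 92000000 + rng.choice(400000, size=cfg.n_codes + 1, replace=False)
    codes = sorted(int(c) for c in pool if c != 92410210)[: cfg.n_codes]

    kcal_range = {
        SweetenerClass.LCSB: cfg.kcal_lcsb_8floz,
        SweetenerClass.SB: cfg.kcal_sb_8floz,
        SweetenerClass.MIXED: cfg.kcal_mixed_8floz,
        SweetenerClass.NONSWEETENED: (0.0, 0.0),
    }
    descriptions = {
        SweetenerClass.LCSB: "Fruit flavored drink, diet",
        SweetenerClass.SB: "Fruit drink",
        SweetenerClass.MIXED: "Fruit juice drink, with high vitamin C",
        SweetenerClass.NONSWEETENED: "Carbonated water, unsweetened",
    }

    foodcodes: list[FoodcodeRecord] = []
    products: list[BrandedProduct] = []
    truth = TruthRecord()
    lo_b, hi_b = cfg.brands_per_code
    for i, (code, cls) in enumerate(zip(codes, classes)):
        factor = float(rng.uniform(*cfg.conversion_factor_range))
        k8 = float(rng.uniform(*kcal_range[cls]))
        if cls is SweetenerClass.LCSB:
            category = 7106 if rng.random() < 0.5 else 7204
        elif cls is SweetenerClass.SB:
            category = 7202 if rng.random() < 0.5 else 7204
        elif cls is SweetenerClass.MIXED:
            category = 7204
        else:
            category = 7832
        foodcodes.append(
            FoodcodeRecord(
                code=code,
                cycle=cfg.cycle,
                main_description=f"{descriptions[cls]}, variant {i}",
                additional_description="",
                wweia_category=category,
                kcal_per_100g=k8 * 100.0 / (8.0 * factor),
                grams_per_floz=factor,
            )
        )
        truth.code_class[code] = cls

        n_brands = int(rng.integers(lo_b, hi_b + 1))
        if cls is SweetenerClass.MIXED:
            n_brands = max(2, n_brands)
            n_with_lcs = int(rng.integers(1, n_brands))
        elif cls is SweetenerClass.LCSB:
            n_with_lcs = n_brands
        else:
            n_with_lcs = 0
        for b in range(n_brands):
            if b < n_with_lcs:
                ingredients = ["water", str(rng.choice(_LCS_POOL))]
                if rng.random() < cfg.lcs_and_sugar_rate:
                    ingredients.append(str(rng.choice(_SUGAR_POOL)))
            elif cls is SweetenerClass.NONSWEETENED:
                ingredients = ["carbonated water"]
            else:
                ingredients = ["water", str(rng.choice(_SUGAR_POOL))]
            mfr = max(0.0, k8 + float(rng.normal(0.0, cfg.mfr_noise_sd)))
            if rng.random() < cfg.mfr_discordance_rate:
                # Land the manufacturer value on the far side of the 40 kcal
                # low-calorie boundary from the database value.
                mfr = float(rng.uniform(45.0, 90.0)) if k8 < 40.0 else float(rng.uniform(5.0, 35.0))
            products.append(
                BrandedProduct(
                    brand=f"Brand {code}-{b}",
                    code=code,
                    cycle=cfg.cycle,
                    ingredients=tuple(ingredients),
                    kcal_per_8floz_mfr=round(mfr, 1),
                )
            )

    water_rows = [
        (94000100, "Water, tap", 7702),
        (94100100, "Water, bottled, unsweetened", 7704),
        (94300100, "Water, baby", 7704),
    ]
    for code, desc, category in water_rows:
        foodcodes.append(
            FoodcodeRecord(
                code=code,
                cycle=cfg.cycle,
                main_description=desc,
                additional_description="",
                wweia_category=category,
                kcal_per_100g=0.0,
                grams_per_floz=29.6,
            )
        )
        products.append(
            BrandedProduct(
                brand=f"Water {code}",
                code=code,
                cycle=cfg.cycle,
                ingredients=("water",),
                kcal_per_8floz_mfr=0.0,
            )
        )
        truth.code_class[code] = SweetenerClass.NONSWEETENED
    return foodcodes, products, truth


def _true_group(lcsb: float, sb: float, mixed: float, water: float, scenario: Scenario, t: float) -> str:
    eff_l = lcsb + mixed if scenario is Scenario.MIXED_AS_LCSB else lcsb
    eff_s = sb + mixed if scenario is Scenario.MIXED_AS_SB else sb
    if eff_l >= t and eff_s >= t:
        return "LCSB_SB"
    if eff_l >= t:
        return "LCSB"
    if eff_s >= t:
        return "SB"
    if water >= t:
        return "WATER"
    return "UNGROUPED"


def gen_population(
    cfg: GeneratorConfig,
    foodcodes: list[FoodcodeRecord],
    truth: TruthRecord,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate participants, recall items, and completed truth bookkeeping.

    Beverage volumes are drawn on the correct side of the 4 fl oz group
    threshold for each participant's intended group, then stored as grams via
    each consumed foodcode's own conversion factor.  Outcomes are additive:
    baseline + group effect + covariate effects + Gaussian noise.  A
    configured share of questionnaire water totals is perturbed to disagree
    with the summed plain-water items.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    th = Thresholds()
    n = cfg.n_participants
    factor = {r.code: r.grams_per_floz for r in foodcodes}
    codes_by_class: dict[SweetenerClass, list[int]] = {c: [] for c in SweetenerClass}
    for code, cls in truth.code_class.items():
        if code not in WATER_CODES and code in factor:
            codes_by_class[cls].append(code)
    for lst in codes_by_class.values():
        lst.sort()

    pids = [f"P{i:05d}" for i in range(n)]
    age = rng.integers(2, 18, n).astype(float)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    race = rng.choice(_RACE_LEVELS, size=n, p=[0.30, 0.20, 0.35, 0.15])
    income = rng.choice(_INCOME_LEVELS, size=n, p=[0.3, 0.35, 0.35])
    activity = rng.choice(_ACTIVITY_LEVELS, size=n, p=[0.35, 0.4, 0.25])
    bmi = rng.uniform(5.0, 95.0, n)
    stratum = rng.integers(1, cfg.n_strata + 1, n)
    psu = rng.integers(1, cfg.psus_per_stratum + 1, n)
    weight = rng.lognormal(0.0, cfg.weight_sigma, n)
    diabetes = np.zeros(n, dtype=bool)
    reliable = np.ones(n, dtype=bool)

    n_inelig = int(round(cfg.ineligible_rate * n))
    inelig_idx = rng.choice(n, size=n_inelig, replace=False)
    for j, idx in enumerate(inelig_idx):
        mode = j % 3
        if mode == 0:
            age[idx] = float(rng.integers(18, 25))
        elif mode == 1:
            diabetes[idx] = True
        else:
            reliable[idx] = False

    groups = rng.choice(
        _GROUPS, size=n, p=[cfg.group_propensities[g] for g in _GROUPS]
    )

    def draw_volumes(g: str) -> tuple[float, float, float]:
        """(lcsb, sb, water) fl oz on the correct side of the threshold."""
        below = lambda: float(rng.uniform(0.0, 3.5))
        above = lambda hi: float(rng.uniform(4.5, hi))
        if g == "WATER":
            return below(), below(), above(30.0)
        if g == "LCSB":
            return above(24.0), below(), float(rng.uniform(0.0, 25.0))
        if g == "SB":
            return below(), above(30.0), float(rng.uniform(0.0, 25.0))
        if g == "LCSB_SB":
            return above(20.0), above(20.0), float(rng.uniform(0.0, 25.0))
        return below(), below(), below()  # UNGROUPED

    have_mixed = bool(codes_by_class[SweetenerClass.MIXED])
    recall_rows: list[dict] = []
    q_water = np.zeros(n)
    mismatch = rng.random(n) < cfg.water_mismatch_rate
    vol = np.zeros((n, 4))  # lcsb, sb, mixed, water

    def emit_items(pid: str, oz: float, code_pool: list[int], water: bool = False) -> None:
        if oz <= 0 or not code_pool:
            return
        k = 1 if len(code_pool) == 1 or rng.random() < 0.5 else 2
        chosen = [int(c) for c in rng.choice(code_pool, size=k, replace=False)]
        if k == 1:
            shares = [1.0]
        else:
            u = float(rng.uniform(0.3, 0.7))
            shares = [u, 1.0 - u]
        for code, s in zip(chosen, shares):
            f = th.water_g_per_floz if water else factor[code]
            recall_rows.append(
                {"participant_id": pid, "code": code, "grams": oz * s * f}
            )

    for i, pid in enumerate(pids):
        g = groups[i]
        lcsb_oz, sb_oz, water_oz = draw_volumes(g)
        mixed_oz = 0.0
        if (
            have_mixed
            and g in ("LCSB", "SB", "LCSB_SB")
            and rng.random() < cfg.mixed_consumer_rate
        ):
            mixed_oz = float(rng.uniform(0.5, 6.0))
        vol[i] = (lcsb_oz, sb_oz, mixed_oz, water_oz)
        emit_items(pid, lcsb_oz, codes_by_class[SweetenerClass.LCSB])
        emit_items(pid, sb_oz, codes_by_class[SweetenerClass.SB])
        emit_items(pid, mixed_oz, codes_by_class[SweetenerClass.MIXED])
        emit_items(pid, water_oz, sorted(WATER_CODES & set(factor)), water=True)
        q = water_oz * th.water_g_per_floz
        if mismatch[i]:
            q += float(rng.uniform(10.0, 80.0))
        q_water[i] = q

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "age_years": age,
            "sex": sex,
            "race_ethnicity": race,
            "income": income,
            "physical_activity": activity,
            "bmi_percentile": bmi,
            "diabetes_dx": diabetes,
            "reliable_recall": reliable,
            "questionnaire_water_g": q_water,
            "stratum_id": stratum,
            "psu_id": psu,
            "weight": weight,
        }
    )

    energy_noise = rng.normal(0.0, 1.0, n) * cfg.noise_sd["energy_kcal"]
    male = (sex == "male").astype(float)
    for outcome in OUTCOME_COLUMNS:
        ce = _COV_EFFECTS[outcome]
        scale = _CAT_SCALE[outcome]
        mean = (
            cfg.baselines[outcome]
            + np.array([cfg.effect_sizes[outcome][g] for g in groups])
            + ce["age"] * (age - _AGE_CENTER)
            + ce["male"] * male
            + ce["bmi"] * (bmi - _BMI_CENTER)
            + scale * np.array([_RACE_EFFECTS[r] for r in race])
            + scale * np.array([_INCOME_EFFECTS[v] for v in income])
            + scale * np.array([_ACTIVITY_EFFECTS[a] for a in activity])
        )
        if outcome == "energy_kcal":
            values = mean + energy_noise
        else:
            noise = rng.normal(0.0, 1.0, n) * cfg.noise_sd[outcome]
            values = mean + _ENERGY_COUPLING[outcome] * energy_noise + noise
        participants[outcome] = values
        truth.outcome_mean[outcome] = dict(zip(pids, mean))

    recalls = pd.DataFrame(recall_rows, columns=["participant_id", "code", "grams"])

    truth.intended_group = dict(zip(pids, groups))
    water_pipeline_oz = q_water / th.water_g_per_floz
    for scenario in Scenario:
        truth.group_by_scenario[scenario.value] = {
            pid: _true_group(
                vol[i, 0], vol[i, 1], vol[i, 2], water_pipeline_oz[i], scenario, th.group_min_oz
            )
            for i, pid in enumerate(pids)
        }
    truth.volumes = {
        pid: {
            "oz_lcsb": vol[i, 0],
            "oz_sb": vol[i, 1],
            "oz_mixed": vol[i, 2],
            "oz_water": water_pipeline_oz[i],
        }
        for i, pid in enumerate(pids)
    }
    return participants, recalls, truth


def _data_path(name: str) -> Path:
    return Path(resources.files("bevclass").joinpath("data", name))


def fixture_table2() -> tuple[list[FoodcodeRecord], list[BrandedProduct]]:
    """The packaged 17-foodcode worked-example universe.

    A published fruit-juice-drink subcategory ("low calorie", codes starting
    9255) across the 2013-2016 cycles, with per-brand manufacturer energy and
    the low-calorie sweeteners each brand listed.  Two of the 17 codes list
    no LCS in any product; none is mixed.
    """
    foodcodes = read_foodcode_table(_data_path("table2_foodcodes.csv"), TABLE2_CYCLE)
    products = read_products(_data_path("table2_products.csv"), TABLE2_CYCLE)
    return foodcodes, products


def fixture_table3() -> tuple[list[FoodcodeRecord], list[BrandedProduct]]:
    """The packaged mixed-foodcode worked example.

    One fruit-juice-drink foodcode whose branded products disagree on LCS
    content (some list sucralose, most none), the canonical mixed code.
    """
    foodcodes = read_foodcode_table(_data_path("table3_foodcodes.csv"), TABLE2_CYCLE)
    products = read_products(_data_path("table3_products.csv"), TABLE2_CYCLE)
    return foodcodes, products


def write_dataset(
    outdir,
    foodcodes: list[FoodcodeRecord],
    products: list[BrandedProduct],
    participants: pd.DataFrame,
    recalls: pd.DataFrame,
    truth: TruthRecord | None = None,
) -> None:
    """Write the four CSV schemas (plus truth.csv when given) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_foodcode_table(foodcodes, outdir / "foodcodes.csv")
    write_products(products, outdir / "products.csv")
    write_participants(participants, outdir / "participants.csv")
    write_recalls(recalls, outdir / "recalls.csv")
    if truth is not None:
        rows = [
            {"kind": "code_class", "key": code, "value": cls.value}
            for code, cls in sorted(truth.code_class.items())
        ]
        rows += [
            {"kind": "intended_group", "key": pid, "value": g}
            for pid, g in sorted(truth.intended_group.items())
        ]
        for scen, mapping in sorted(truth.group_by_scenario.items()):
            rows += [
                {"kind": f"group_{scen}", "key": pid, "value": g}
                for pid, g in sorted(mapping.items())
            ]
        pd.DataFrame(rows, columns=["kind", "key", "value"]).to_csv(
            outdir / "truth.csv", index=False
        )
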