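"""Strategy proxies, the ingredient-based classifier, and their comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bevclass.classify import (
    DEFAULT_LCS_LEXICON,
    KcalPerServing,
    KcalSource,
    Strategy3Criterion,
    StrategyConfig,
    SweetenerClass,
    UnknownClassificationError,
    build_classification_table,
    classify_by_ingredients,
    compare_strategies,
    find_lcs,
    kcal_per_serving,
    strategy1_fndds_prefix,
    strategy2_wweia,
    strategy3_caloric_density,
    strategy4_text,
)
from bevclass.fndds import BrandedProduct, FoodcodeRecord, Thresholds
from bevclass.synthetic import TABLE2_CYCLE, GeneratorConfig, gen_universe


def _rec(code=92550040, desc="Fruit juice drink, diet", extra="", category=7204,
         kcal=19.1667, factor=30.0, cycle="c1"):
    return FoodcodeRecord(
        code=code,
        cycle=cycle,
        main_description=desc,
        additional_description=extra,
        wweia_category=category,
        kcal_per_100g=kcal,
        grams_per_floz=factor,
    )


def _prod(lcs=(), sugar=False, code=92550040, cycle="c1", brand="b", unknown=False):
    if unknown:
        ingredients = None
    else:
        ingredients = ("water",) + tuple(lcs) + (("sugar",) if sugar else ())
    return BrandedProduct(brand=brand, code=code, cycle=cycle, ingredients=ingredients)


class TestKcalPerServing:
    def test_zero_energy_is_zero_on_both_bases(self):
        k = kcal_per_serving(_rec(kcal=0.0, factor=25.0))
        assert k.kcal_per_8floz == 0.0 and k.kcal_per_240g == 0.0

    def test_eight_floz_serving_uses_conversion_factor(self):
        k = kcal_per_serving(_rec(kcal=19.18, factor=30.0))
        assert k.kcal_per_8floz == pytest.approx(46.03, abs=0.005)

    def test_mass_basis_ignores_factor(self):
        k = kcal_per_serving(_rec(kcal=100.0, factor=25.0))
        assert k.kcal_per_8floz == pytest.approx(200.0)
        assert k.kcal_per_240g == pytest.approx(240.0)


class TestStrategy1:
    def test_diet_soft_drink_with_extended_terms(self):
        cfg = StrategyConfig(strategy1_terms=("sugar free", "reduced sugar", "diet"))
        rec = _rec(code=92410560, desc="Soft drink, fruit flavored, caffeine containing, diet")
        assert strategy1_fndds_prefix(rec, cfg)

    def test_fruit_drink_subcategory_never_matches_prefix(self, table2):
        foodcodes, _ = table2
        assert not any(strategy1_fndds_prefix(r) for r in foodcodes)

    def test_prefix_match_with_blank_description(self):
        assert not strategy1_fndds_prefix(_rec(code=92410560, desc="", extra=""))


class TestStrategy2:
    @pytest.mark.parametrize("category,expected", [(7106, True), (7102, True), (7204, False)])
    def test_diet_categories(self, category, expected):
        assert strategy2_wweia(_rec(category=category)) is expected

    def test_lcs_water_outside_diet_categories_missed(self):
        # Carbonated water sweetened with low-calorie sweetener sits in an
        # enhanced-water category, so the category proxy misses it.
        rec = _rec(
            code=92410250,
            desc="Carbonated water, sweetened, with low-calorie sweetener",
            category=7832,
        )
        assert not strategy2_wweia(rec)


class TestStrategy3:
    def _k(self, k8, basis_240=None, source=KcalSource.FNDDS):
        return KcalPerServing(kcal_per_8floz=k8, kcal_per_240g=basis_240, source=source)

    def test_database_vs_manufacturer_flip_low_calorie(self):
        cfg = StrategyConfig(strategy3_criterion=Strategy3Criterion.FDA_LOW)
        assert strategy3_caloric_density(self._k(46.0), cfg) is False
        assert strategy3_caloric_density(self._k(10.0, source=KcalSource.MANUFACTURER), cfg) is True

    def test_leahy_flip_between_sources(self):
        cfg = StrategyConfig(strategy3_criterion=Strategy3Criterion.LEAHY)
        assert strategy3_caloric_density(self._k(5.0), cfg) is True
        assert strategy3_caloric_density(self._k(60.0, source=KcalSource.MANUFACTURER), cfg) is False

    def test_boundary_is_excluded(self):
        cfg = StrategyConfig(strategy3_criterion=Strategy3Criterion.FDA_LOW)
        assert strategy3_caloric_density(self._k(40.0), cfg) is False

    def test_unknown_kcal_is_unknown_not_false(self):
        cfg = StrategyConfig(strategy3_criterion=Strategy3Criterion.MAILLOT)
        assert strategy3_caloric_density(self._k(10.0, basis_240=None), cfg) is None

    def test_threshold_monotonicity(self, table2):
        # Stricter cut-offs flag subsets of looser ones on the same basis.
        foodcodes, _ = table2
        flagged = {}
        for crit in (Strategy3Criterion.FDA_NO, Strategy3Criterion.LEAHY, Strategy3Criterion.FDA_LOW):
            cfg = StrategyConfig(strategy3_criterion=crit)
            flagged[crit] = {
                r.code for r in foodcodes if strategy3_caloric_density(kcal_per_serving(r), cfg)
            }
        assert flagged[Strategy3Criterion.FDA_NO] <= flagged[Strategy3Criterion.LEAHY]
        assert flagged[Strategy3Criterion.LEAHY] <= flagged[Strategy3Criterion.FDA_LOW]


class TestStrategy4:
    @pytest.mark.parametrize(
        "desc,expected",
        [
            ("Fruit juice drink, diet", True),
            ("Fruit juice drink, with high Vitamin C", False),
            ("Dietary supplement drink", False),  # no whole-token "diet"
            ("Sunny D, reduced sugar", True),
        ],
    )
    def test_whole_token_matching(self, desc, expected):
        assert strategy4_text(_rec(desc=desc)) is expected

    @pytest.mark.parametrize(
        "variant", ["Sugar-free drink", "SUGAR FREE DRINK", "sugar-FREE drink", "Sugar  free drink"]
    )
    def test_case_and_hyphen_invariance(self, variant):
        assert strategy4_text(_rec(desc=variant))


class TestFindLcs:
    def test_finds_lexicon_entries_as_phrases(self):
        found = find_lcs(("water", "sucralose", "acesulfame potassium"))
        assert "sucralose" in found and "acesulfame potassium" in found

    def test_no_partial_word_matches(self):
        assert find_lcs(("rebate coupon syrup",)) == ()

    def test_empty_ingredients_find_nothing(self):
        assert find_lcs(()) == ()


class TestIngredientClassifier:
    def test_single_sugar_product_is_sb(self):
        prods = [_prod(sugar=True)]
        assert classify_by_ingredients(92550040, "c1", prods, _rec(desc="Capri Sun, fruit juice drink")) is SweetenerClass.SB

    def test_mixed_when_products_disagree(self, table3):
        foodcodes, products = table3
        cls = classify_by_ingredients(92530610, TABLE2_CYCLE, products, foodcodes[0])
        assert cls is SweetenerClass.MIXED

    def test_lcs_plus_sugar_counts_as_lcs(self):
        # A product listing sucralose and neotame along with high fructose
        # corn syrup is LCS-containing.
        prods = [
            BrandedProduct(
                brand="mineral water",
                code=92410110,
                cycle="c1",
                ingredients=("water", "high fructose corn syrup", "sucralose", "neotame"),
            )
        ]
        assert classify_by_ingredients(92410110, "c1", prods) is SweetenerClass.LCSB

    def test_all_unknown_without_explicit_description_errors(self):
        prods = [_prod(unknown=True)]
        with pytest.raises(UnknownClassificationError, match="92550040"):
            classify_by_ingredients(92550040, "c1", prods, _rec(desc="Fruit juice drink, light"))

    def test_unknown_products_excluded_from_tally(self):
        # One unknown label plus two LCS-listing labels: still LCSB.
        prods = [_prod(lcs=("reba",), brand="a"), _prod(lcs=("sucralose",), brand="b"),
                 _prod(unknown=True, brand="c")]
        assert classify_by_ingredients(92550040, "c1", prods) is SweetenerClass.LCSB

    def test_explicit_description_suffices_without_products(self):
        rec = _rec(code=92410250, desc="Carbonated water, sweetened, with low-calorie sweetener")
        assert classify_by_ingredients(92410250, "c1", [], rec) is SweetenerClass.LCSB

    def test_ingredients_override_explicit_description(self):
        rec = _rec(desc="Fruit juice drink, diet")
        prods = [_prod(sugar=True)]
        assert classify_by_ingredients(92550040, "c1", prods, rec) is SweetenerClass.SB

    def test_no_sweetener_at_all_is_nonsweetened(self):
        prods = [
            BrandedProduct(brand="a", code=92410210, cycle="c1", ingredients=("carbonated water",))
        ]
        assert classify_by_ingredients(92410210, "c1", prods) is SweetenerClass.NONSWEETENED

    def test_product_from_wrong_code_rejected(self):
        with pytest.raises(ValueError, match="does not belong"):
            classify_by_ingredients(92550041, "c1", [_prod()], None)

    @given(st.randoms(use_true_random=False))
    def test_invariant_to_product_order_and_duplication(self, rnd):
        prods = [
            _prod(lcs=("aspartame",), brand="a"),
            _prod(sugar=True, brand="b"),
            _prod(lcs=("stevia",), sugar=True, brand="c"),
        ]
        baseline = classify_by_ingredients(92550040, "c1", prods)
        shuffled = list(prods) + [rnd.choice(prods)]
        rnd.shuffle(shuffled)
        assert classify_by_ingredients(92550040, "c1", shuffled) is baseline


class TestClassificationTable:
    def test_table2_composition(self, table2_tab):
        counts = table2_tab.counts()
        assert counts[SweetenerClass.LCSB] == 15
        assert counts[SweetenerClass.SB] == 2
        assert counts[SweetenerClass.MIXED] == 0

    def test_empty_universe(self):
        tab = build_classification_table([], [])
        assert tab.labels == {}

    def test_planted_composition_recovered(self, small_world, small_world_tab):
        _, _, _, _, _, truth = small_world
        want = truth.class_counts(include_water=True)
        got = small_world_tab.counts()
        assert got == want

    def test_single_product_universe_has_no_mixed(self):
        cfg = GeneratorConfig(seed=11, n_codes=40, frac_mixed=0.0, frac_sb=0.62,
                              brands_per_code=(1, 1))
        foodcodes, products, _ = gen_universe(cfg)
        tab = build_classification_table(foodcodes, products)
        assert tab.counts()[SweetenerClass.MIXED] == 0

    def test_mixed_requires_multiple_brands(self):
        with pytest.raises(ValueError, match="brands_per_code"):
            GeneratorConfig(brands_per_code=(1, 1))

    def test_permissive_mode_keeps_labels_total(self):
        rec = _rec(desc="Fruit juice drink")  # no explicit term
        prods = [_prod(unknown=True)]
        with pytest.warns(UserWarning, match="unknown ingredients"):
            tab = build_classification_table([rec], prods, permissive=True)
        assert rec.code in tab.labels
        assert "fallback" in tab.provenance[rec.code]

    def test_matches_brute_force_oracle_on_small_universes(self):
        # Independent reclassification: membership checks against the raw
        # generator vocabularies, no shared tokenization path.
        lcs_pool = set(DEFAULT_LCS_LEXICON)
        sugar_pool = {"sugar", "high fructose corn syrup"}
        for seed in range(5):
            cfg = GeneratorConfig(seed=seed, n_codes=50, n_participants=10)
            foodcodes, products, _ = gen_universe(cfg)
            tab = build_classification_table(foodcodes, products)
            by_code = {}
            for p in products:
                by_code.setdefault(p.code, []).append(p)
            for rec in foodcodes:
                prods = by_code[rec.code]
                has = [bool(lcs_pool & set(p.ingredients)) for p in prods]
                if all(has):
                    want = SweetenerClass.LCSB
                elif any(has):
                    want = SweetenerClass.MIXED
                elif any(sugar_pool & set(p.ingredients) for p in prods):
                    want = SweetenerClass.SB
                else:
                    want = SweetenerClass.NONSWEETENED
                assert tab.labels[rec.code] is want, rec.code


class TestCompareStrategies:
    def test_category_proxy_flags_five_worked_example_codes(self, table2_tab):
        cmp = compare_strategies(table2_tab)
        assert cmp.totals["s2"] == 5
        assert cmp.totals["s1"] == 0

    def test_leahy_flags_four_lcs_containing_codes(self, table2):
        foodcodes, products = table2
        cfg = StrategyConfig(strategy3_criterion=Strategy3Criterion.LEAHY)
        tab = build_classification_table(foodcodes, products, cfg)
        lcsb = set(tab.codes_with_class(SweetenerClass.LCSB))
        assert len([c for c in tab.flagged("s3") if c in lcsb]) == 4

    def test_single_code_table_trivially_consistent(self):
        rec = _rec(desc="Fruit flavored drink, diet", category=7106)
        tab = build_classification_table([rec], [_prod(lcs=("aspartame",))])
        cmp = compare_strategies(tab)
        for (a, b), (agree, disagree) in cmp.agreement.items():
            assert agree + disagree == 1
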