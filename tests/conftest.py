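import pytest
from hypothesis import HealthCheck, settings

from bevclass.classify import build_classification_table
from bevclass.synthetic import GeneratorConfig, fixture_table2, fixture_table3, gen_population, gen_universe

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=40,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table2():
    """The 17-foodcode worked-example universe with its branded products."""
    return fixture_table2()


@pytest.fixture(scope="session")
def table2_tab(table2):
    foodcodes, products = table2
    return build_classification_table(foodcodes, products)


@pytest.fixture(scope="session")
def table3():
    return fixture_table3()


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic survey: universe, population, and truth."""
    cfg = GeneratorConfig(seed=7, n_codes=60, n_participants=400)
    foodcodes, products, truth = gen_universe(cfg)
    participants, recalls, truth = gen_population(cfg, foodcodes, truth)
    return cfg, foodcodes, products, participants, recalls, truth


@pytest.fixture(scope="session")
def small_world_tab(small_world):
    _, foodcodes, products, *_ = small_world
    return build_classification_table(foodcodes, products)
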