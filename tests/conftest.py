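import numpy as np
import pandas as pd
import pytest

from ricascade.config import GRADIENT_LAYER, ScenarioConfig, default_scenario
from ricascade.synth import make_environment


@pytest.fixture(scope="session")
def scenario() -> ScenarioConfig:
    """Default 8-species study system, fixed seed."""
    return default_scenario(rng_seed=0)


@pytest.fixture(scope="session")
def env(scenario):
    return make_environment(scenario)


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """Two-species system with moderate niche overlap, for cheap pair tests."""
    species = ["sp_a", "sp_b"]
    return ScenarioConfig(
        species=species,
        niche_optima={"sp_a": {GRADIENT_LAYER: 40.0}, "sp_b": {GRADIENT_LAYER: 60.0}},
        niche_breadths={sp: {GRADIENT_LAYER: 5.0} for sp in species},
        n_presences={sp: 120 for sp in species},
        flowering_mean={"sp_a": 50.0, "sp_b": 80.0},
        flowering_sd={sp: 8.0 for sp in species},
        fruit_prob_within={sp: 0.6 for sp in species},
        fruit_prob_between={sp: 0.4 for sp in species},
        seed_viab_within={sp: 0.8 for sp in species},
        seed_viab_between={sp: 0.6 for sp in species},
        pollen_germ_within={sp: 0.6 for sp in species},
        pollen_germ_between={sp: 0.3 for sp in species},
        rng_seed=7,
    )


@pytest.fixture()
def crosses_frame() -> pd.DataFrame:
    """Hand-built crosses table: acceptor A has rich data, C has none."""
    rows = [
        # acceptor A: within + two donors, one donor below min_n
        ("A", "A", "within", 10, 5, 100, 80, 500, 300),
        ("A", "B", "between", 10, 3, 60, 30, 500, 250),
        ("A", "B", "between", 10, 1, 40, 10, 500, 200),
        ("A", "D", "between", 4, 2, 20, 10, 200, 90),  # n < 5: excluded
        # acceptor B: within only
        ("B", "B", "within", 8, 4, 80, 60, 400, 240),
    ]
    return pd.DataFrame(rows, columns=[
        "acceptor", "donor", "treatment", "n_pollinations", "n_fruits",
        "n_seeds_total", "n_seeds_viable", "n_pollen_total", "n_pollen_germinated",
    ])


@pytest.fixture()
def flowering_frame() -> pd.DataFrame:
    rows = []
    rid = 0
    for sp, days in (("A", [3, 10]), ("B", [10, 12, 13])):
        for d in days:
            rows.append((f"r{rid}", sp, d, "garden", 0, None))
            rid += 1
    return pd.DataFrame(rows, columns=[
        "record_id", "species", "onset_day", "source", "year", "block",
    ])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
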