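import numpy as np
import pandas as pd
import pytest

from gravidbiome import synthetic_cohort as sc
from gravidbiome.feature_tables import CountTable


@pytest.fixture(scope="session")
def small_scenario() -> sc.ScenarioConfig:
    """Desk-scale scenario small enough for per-test model fits."""
    config = sc.default_scenario()
    config.sites = {k: 60 for k in config.sites}
    return config


@pytest.fixture(scope="session")
def small_cohort(small_scenario):
    return sc.generate_cohort(small_scenario, seed=11)


@pytest.fixture(scope="session")
def alpha_frame(small_scenario) -> pd.DataFrame:
    return sc.generate_alpha_outcomes(small_scenario, seed=11)


@pytest.fixture()
def toy_table() -> CountTable:
    """3 taxa x 4 samples with known lineages."""
    data = pd.DataFrame(
        {
            "S1": [5, 0, 2],
            "S2": [1, 1, 1],
            "S3": [0, 10, 0],
            "S4": [4, 4, 4],
        },
        index=["tA", "tB", "tC"],
    )
    lineages = pd.Series(
        {
            "tA": "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Ruminococcus",
            "tB": "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae",
            "tC": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prevotellaceae;Prevotella",
        }
    )
    return CountTable(data, lineages)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
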