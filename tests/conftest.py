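from importlib import resources

import pandas as pd
import pytest
import yaml
from hypothesis import HealthCheck, settings

from preventcea import cost_table, default_simulation_config, pipeline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def targets_raw() -> dict:
    """Packaged calibration-target mapping, including the published
    accumulated values, their printed precision and rounding-exception flags."""
    text = resources.files("preventcea").joinpath("data/trial_targets.yaml").read_text()
    return yaml.safe_load(text)


@pytest.fixture(scope="session")
def sim_config():
    return default_simulation_config()


@pytest.fixture(scope="session")
def cost_df() -> pd.DataFrame:
    return cost_table()


@pytest.fixture(scope="session")
def published_artifacts():
    """Full pipeline run in published-means mode (deterministic)."""
    return pipeline.run_all(published_means=True)


@pytest.fixture()
def small_records() -> pd.DataFrame:
    """Three hand-written records in one arm, with one missing cell."""
    base = {
        "child_id": ["a", "b", "c"],
        "strategy": ["SLN"] * 3,
        "wave": [2, 3, 4],
        "sex": ["girl", "boy", "girl"],
        "age": [9, 10, 11],
    }
    values = {
        "masc_t1": [10.0, 12.0, 14.0],
        "masc_t2": [9.0, 11.0, None],
        "masc_t3": [8.0, 10.0, 12.0],
        "smfq_t1": [5.0, 6.0, 7.0],
        "smfq_t2": [4.0, 5.0, 6.0],
        "smfq_t3": [3.0, 4.0, 5.0],
        "hrqol_t1": [0.7, 0.8, 0.9],
        "hrqol_t2": [0.7, 0.8, 0.9],
        "hrqol_t3": [0.7, 0.8, 0.9],
    }
    return pd.DataFrame({**base, **values})
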