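import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promarch.synthetic import (
    SyntheticConfig,
    gen_annotation,
    gen_expression,
    gen_paralog_families,
    gen_peaks,
    gen_richness,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=101, n_transcripts=400, n_families=60,
                           n_samples={"tissue": 40, "primary_cell": 20, "cancer_cell_line": 20})


@pytest.fixture(scope="session")
def small_world(small_config):
    """A small but complete synthetic dataset shared across test modules."""
    anns = gen_annotation(small_config)
    richness = gen_richness(small_config)
    peaks, _ = gen_peaks(small_config, anns, richness)
    expr = gen_expression(small_config, anns, richness)
    paralogs = gen_paralog_families(small_config)
    return {
        "config": small_config,
        "annotations": anns,
        "richness": richness,
        "peaks": peaks,
        "expression": expr,
        "paralogs": paralogs,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
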