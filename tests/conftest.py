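import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from temdyn import SimConfig
from temdyn.synthetic import generate_genome

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast synthetic world: 2 x 40-kb chromosomes, ~50 TEs, 5k reads."""
    return SimConfig(
        seed=7,
        chrom_length=40_000,
        centromere_half_width=9_000,
        n_te_per_class={"A": 24, "B": 12, "depleted": 12},
        length_params={"A": (350.0, 0.4), "B": (1200.0, 0.4), "depleted": (400.0, 0.4)},
        reads_per_library=5_000,
        n_dmr=10,
        dmr_length=250,
        coverage_per_cytosine=15.0,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_annotation(small_world):
    return small_world[0]


@pytest.fixture(scope="session")
def small_truth(small_world):
    return small_world[1]


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def toy_sites() -> pd.DataFrame:
    """Hand-sized cytosine table for weighted-methylation arithmetic."""
    return pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "pos": [10, 20, 30, 40],
        "strand": ["+", "+", "-", "+"],
        "tri": ["CAA", "CAT", "CTA", "CGA"],
        "context": ["CHH", "CHH", "CHH", "CG"],
        "subcontext": ["CWA", "nonCWA", "CWA", "n/a"],
        "mc": [2, 3, 0, 5],
        "cov": [4, 6, 5, 5],
    })
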