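import numpy as np
import pytest
from hypothesis import settings

from methcompare.pipeline import RunConfig, run_pipeline
from methcompare.simulate import SimConfig, simulate_species

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# scaled-down study conditions for fast unit tests; the acceptance suite runs
# the full-size defaults
SMALL_SIM = dict(
    autosome_len=500_000,
    x_len=200_000,
    n_imprinted=4,
    n_valleys=2,
    pmd_len=40_000,
    n_germline_genes=4,
    n_methylated_cgi_genes=6,
    n_ordinary_genes=12,
    n_lcp_genes=4,
    n_extra_cgis=4,
    n_te=20,
    n_x_subject=12,
    n_x_escapee=4,
)


@pytest.fixture(scope="session")
def species_a():
    """One full-size synthetic species (the default study conditions)."""
    return simulate_species(SimConfig(species="A", seed=11))


@pytest.fixture(scope="session")
def result_small():
    """A complete pipeline run on a scaled-down synthetic species."""
    cfg = RunConfig(species="S", seed=5, simulate=dict(SMALL_SIM))
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
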