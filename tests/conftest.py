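import numpy as np
import pytest

from ahekit.pipeline import run_pipeline
from ahekit.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def e2e_result():
    """One full pipeline run at study-like conditions, shared across tests.

    8 taxa, 30 loci, 20x depth, 0.3% base error, 1% contaminant reads.
    """
    cfg = SimulationConfig(seed=11, n_taxa=8, n_loci=30,
                           base_error_rate=0.003, contam_fraction=0.01)
    return run_pipeline(cfg, aligner_fallback=True)
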