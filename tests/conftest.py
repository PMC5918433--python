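import numpy as np
import pytest

from hapodds.probability import ReadObservation
from hapodds.simulate import SimulationConfig, simulate_to_dir


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_read():
    def _make(seq: str, e=0.01, read_id: str = "r", **kw) -> ReadObservation:
        if np.isscalar(e):
            e = np.full(len(seq), float(e))
        return ReadObservation(read_id, seq, np.asarray(e, dtype=float), **kw)

    return _make


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 30-kb simulated benchmark shared across tests (seed fixed)."""
    config = SimulationConfig(
        contig_length=30_000, seed=7, n_snps=10, n_insertions=3,
        n_deletions=3, n_decoys=15,
    )
    outdir = tmp_path_factory.mktemp("small_sim")
    paths = simulate_to_dir(config, outdir)
    return config, paths
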