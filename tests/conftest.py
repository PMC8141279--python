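import numpy as np
import pandas as pd
import pytest

from dmlkit.genome import build_genome
from dmlkit.io import FilteredMatrix, Methylome
from dmlkit.simulate import DMRSpec, SimulationConfig, simulate_methylomes


@pytest.fixture(scope="session")
def genome():
    return build_genome(1, 100_000, 0.01, seed=7, with_sequence=True)


@pytest.fixture(scope="session")
def two_chrom_genome():
    return build_genome(2, 50_000, 0.02, seed=1)


def make_matrix(meth, total, groups=("CD8", "CD8", "CD8", "DN", "DN", "DN")):
    """FilteredMatrix from raw count arrays (n_cpg, n_samples)."""
    meth = np.atleast_2d(np.asarray(meth, dtype=np.int64))
    total = np.atleast_2d(np.asarray(total, dtype=np.int64))
    n = meth.shape[0]
    keys = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n + 1) * 100, "strand": "+"})
    return FilteredMatrix(
        keys=keys, meth=meth, total=total,
        sample_ids=[f"s{i}" for i in range(meth.shape[1])],
        groups=list(groups[: meth.shape[1]]),
    )


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture(scope="session")
def spiked_dataset(genome):
    """Methylomes with one strong hypo DMR plus truth, shared across tests."""
    cfg = SimulationConfig(mean_coverage=30.0, seed=11)
    pos = genome.cpg_positions["chr1"]
    dmr = DMRSpec("chr1", int(pos[100] - 1), int(pos[150]), "hypo", -0.5, 0.9)
    methylomes, truth = simulate_methylomes(genome, [dmr], cfg)
    return methylomes, truth, dmr
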