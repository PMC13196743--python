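import numpy as np
import pytest

from poolgate.config import LayoutConfig, SAParams
from poolgate.fixtures import SequenceSetSpec, gen_sequence_set
from poolgate.ligation import LigationMatrix


@pytest.fixture(scope="session")
def identity_matrix():
    return LigationMatrix.identity()


@pytest.fixture(scope="session")
def uniform_matrix():
    return LigationMatrix(np.ones((256, 256)))


@pytest.fixture(scope="session")
def synthetic_matrix():
    """Moderately promiscuous ligase profile: 90% on-target per row."""
    return LigationMatrix.make_synthetic(0.9, seed=1)


@pytest.fixture(scope="session")
def tight_matrix():
    """High-orthogonality profile close to empirical high-fidelity data."""
    return LigationMatrix.make_synthetic(0.99, seed=1)


@pytest.fixture(scope="session")
def ten_gene_set():
    """High-identity 714-nt pool, the four-fragment stress scale."""
    return gen_sequence_set(
        SequenceSetSpec(
            mode="identity",
            target_identity=(0.86, 0.90),
            n_sequences=10,
            length=714,
            seed=11,
        )
    )


@pytest.fixture
def four_frag_cfg():
    """300-nt oligos, 50-site budget, four fragments per gene."""
    return LayoutConfig(gg_budget=50, fragments_override=4)


@pytest.fixture
def quick_sa():
    return SAParams(n_steps=150, n_restarts=2, base_seed=0)


@pytest.fixture(scope="session")
def small_library(ten_gene_set_s=None):
    """A fully designed 10-gene library shared by emitter/simulator tests."""
    from poolgate.design import design_library

    genes = gen_sequence_set(
        SequenceSetSpec(
            mode="identity",
            target_identity=(0.86, 0.90),
            n_sequences=10,
            length=714,
            seed=11,
        )
    ).genes
    cfg = LayoutConfig(gg_budget=50, fragments_override=4)
    matrix = LigationMatrix.make_synthetic(0.9, seed=1)
    lib = design_library(
        genes,
        matrix,
        cfg=cfg,
        sa=SAParams(n_steps=150, n_restarts=2, base_seed=0),
        seed=4,
    )
    return genes, cfg, matrix, lib
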