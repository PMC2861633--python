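import numpy as np
import pytest

from graphmer.data_prep import standardize
from graphmer.synthetic_data import (
    PlantedMotif,
    SyntheticSpec,
    default_motifs,
    generate,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-motif dataset shared by read-only tests."""
    motifs = default_motifs(8)
    for m in motifs:
        m.copies_per_target = 3
        m.target_fraction = 0.2
        m.mutation_rate = 0.1
    spec = SyntheticSpec(
        n_genes=150,
        n_timepoints=8,
        promoter_length=200,
        n_exons=30,
        exon_length=300,
        motifs=motifs,
        seed=7,
    )
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def std_xy(rng):
    """Random standardized regression problem with planted linear structure."""
    n, p, q = 60, 30, 4
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, q))
    Y = X @ B + 0.1 * rng.normal(size=(n, q))
    Xs, _ = standardize(X)
    Ys, _ = standardize(Y)
    return Xs, Ys
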