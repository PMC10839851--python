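import numpy as np
import pytest

from dualhub import rdm as rdm_mod
from dualhub import synth


def random_rdm(n, rng, labels=None):
    """Random valid dissimilarity matrix (symmetric, zero diagonal)."""
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    if labels is None:
        labels = [f"c{i:02d}" for i in range(n)]
    return rdm_mod.RDM(labels, m)


@pytest.fixture(scope="session")
def concepts_small():
    """12 event + 12 object concepts in an 6-d space (fast fixture)."""
    return synth.make_concept_space(12, 12, dim=6, seed=101)


@pytest.fixture(scope="session")
def design_small(concepts_small):
    return synth.make_design(concepts_small, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(4321)
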