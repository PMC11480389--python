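import numpy as np
import pytest
import scipy.sparse as sp

from gliostate.io import CountMatrix
from gliostate.simulate import SimParams, generate_cohort


def dense_matrix(array, gene_prefix="g", cell_prefix="c") -> CountMatrix:
    """Build a CountMatrix from a dense genes x cells array."""
    array = np.asarray(array)
    return CountMatrix(
        genes=[f"{gene_prefix}{i}" for i in range(array.shape[0])],
        cells=[f"{cell_prefix}{j}" for j in range(array.shape[1])],
        counts=sp.csr_matrix(array),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic cohort (2,000 genes / 2,000 cells, seed 17)."""
    return generate_cohort(SimParams())


@pytest.fixture(scope="session")
def default_params():
    return SimParams()
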