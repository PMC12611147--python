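import numpy as np
import pytest

from pottsnet import LatticeState, ModelParams


@pytest.fixture
def small_params():
    """Desk-scale model: same physics as the defaults on a 32-site lattice."""
    return ModelParams(
        lattice_size=32,
        n_cells_initial=8,
        D=0.5,
        secretion_rate=0.3,
        pde_substeps=4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state(rng, size=8, n_ids=4, field_scale=1.0):
    """Random multi-cell lattice with a random non-negative field."""
    lattice = rng.integers(0, n_ids, size=(size, size)).astype(np.int32)
    field = field_scale * rng.random((size, size))
    return LatticeState(lattice, field)
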