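import numpy as np
import pytest

from dgat.graph import make_adjacency_state
from dgat.layers import GATLayerParams
from dgat.montage import Montage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tetra_montage():
    """Four electrodes at unit-sphere tetrahedron vertices."""
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3)
    return Montage("tetra4", ("A", "B", "C", "D"), v)


def random_valid_w0(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric adjacency with unit diagonal and entries in [0, 1]."""
    a = rng.random((n, n))
    w0 = (a + a.T) / 2
    np.fill_diagonal(w0, 1.0)
    return w0


def random_layer(
    rng: np.random.Generator,
    n: int,
    f_in: int,
    f_out: int,
    n_heads: int,
    beta: float = 0.5,
    **kwargs,
):
    """A DGATLayer over a random valid adjacency, plus its pieces."""
    from dgat.layers import DGATLayer

    params = GATLayerParams.init(rng, n_heads, f_in, f_out)
    state = make_adjacency_state(random_valid_w0(rng, n), beta=beta)
    return DGATLayer(params, state, **kwargs), params, state
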