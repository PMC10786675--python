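import numpy as np
import pytest

from scdmv import RegionCounts, ZoibParams


def draw_zoib_cells(theta: ZoibParams, n_cells: int, depth, rng) -> RegionCounts:
    """Simulate one group's per-cell counts directly from the mixture law."""
    comp = rng.choice(3, size=n_cells, p=[theta.pi0, theta.pi1, theta.w_beta])
    p = np.where(comp == 0, 0.0, np.where(comp == 1, 1.0, 0.5))
    in_beta = comp == 2
    if in_beta.any():
        p[in_beta] = rng.beta(theta.alpha, theta.beta, size=int(in_beta.sum()))
    n = np.broadcast_to(np.asarray(depth), (n_cells,)).copy()
    return RegionCounts(rng.binomial(n, p), n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
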