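import numpy as np
import pytest

from mmrst import make_hierarchy, rook_adjacency, simulate_panel

PAPER_LIKE_SHARES = (0.12, 0.14, 0.14, 0.12, 0.11, 0.29, 0.08)


@pytest.fixture(scope="session")
def small_world():
    """32-county balanced hierarchy on a 4x8 lattice with rook adjacency."""
    hierarchy, geometry = make_hierarchy(2, 2, 2, 4, 0.3, seed=1)
    weights = rook_adjacency(geometry)
    return hierarchy, geometry, weights


@pytest.fixture(scope="session")
def small_panel(small_world):
    hierarchy, _, weights = small_world
    panel, truth = simulate_panel(
        hierarchy, weights, 10, PAPER_LIKE_SHARES, seed=5
    )
    return panel, truth


@pytest.fixture(scope="session")
def medium_world():
    """216-county hierarchy (3x3x3x8) used by the slower model tests."""
    hierarchy, geometry = make_hierarchy(3, 3, 3, 8, 0.4, seed=2)
    weights = rook_adjacency(geometry)
    return hierarchy, geometry, weights


def random_connected_weights(n, rng):
    """Random connected graph on n nodes (spanning chain + extra edges)."""
    from mmrst.weights import SpatialWeights

    ids = [f"u{i}" for i in range(n)]
    pairs = [(ids[i], ids[i + 1]) for i in range(n - 1)]
    extra = rng.integers(0, n, size=(n, 2))
    pairs += [(ids[a], ids[b]) for a, b in extra if a != b]
    return SpatialWeights.from_edge_pairs(ids, pairs)
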