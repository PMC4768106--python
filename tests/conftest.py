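import numpy as np
import pytest

from signedgame import SignedNetwork


@pytest.fixture
def triangle_unbalanced() -> SignedNetwork:
    """Undirected triangle with edges +1, +1, -1 (one odd negative cycle)."""
    return SignedNetwork(
        ["a", "b", "c"], [("a", "b", 1), ("b", "c", 1), ("a", "c", -1)]
    )


@pytest.fixture
def triangle_positive() -> SignedNetwork:
    """All-positive triangle (balanced; H = 2|E| = 6 with everyone allied)."""
    return SignedNetwork(
        ["a", "b", "c"], [("a", "b", 1), ("b", "c", 1), ("a", "c", 1)]
    )


@pytest.fixture
def mutual_dislike_triangle() -> SignedNetwork:
    """Directed 3-cycle of mutual like/dislike pairs: every ordered pair
    (v1,v2), (v2,v3), (v3,v1) has a positive edge one way and a negative
    edge back, so the symmetrized coefficients all cancel."""
    return SignedNetwork(
        ["v1", "v2", "v3"],
        [
            ("v1", "v2", 1), ("v2", "v1", -1),
            ("v2", "v3", 1), ("v3", "v2", -1),
            ("v3", "v1", 1), ("v1", "v3", -1),
        ],
        directed=True,
    )


@pytest.fixture
def single_negative_edge() -> SignedNetwork:
    return SignedNetwork(["x", "y"], [("x", "y", -1)])


def all_states(net: SignedNetwork):
    """Every spin assignment of a small network."""
    import itertools

    from signedgame import StrategyState

    for spins in itertools.product([1.0, -1.0], repeat=net.n_nodes):
        yield StrategyState(net, np.array(spins))
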