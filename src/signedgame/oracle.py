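"""Exact minimum structural conflicts by exhaustive enumeration.

Finding the frustration index is NP-hard, so exact answers are only
practical on small networks; this module enumerates every bipartition to
validate the heuristic.  The global sign-flip symmetry (``v`` and ``-v``
have identical conflicts) lets us pin the first node to ``+1`` and
enumerate ``2^(|V|-1)`` assignments.  Assignments are visited in Gray-code
order — consecutive assignments differ in a single node — so each step
updates the conflict count in O(degree) instead of O(|E|).
"""

from __future__ import annotations

import numpy as np

from .fitness import StrategyState
from .graph import SignedNetwork

__all__ = ["NetworkTooLargeError", "exact_min_conflicts"]


class NetworkTooLargeError(ValueError):
    """Enumeration refused; use the evolutionary-game heuristic instead."""


def exact_min_conflicts(
    net: SignedNetwork, max_nodes: int = 22
) -> tuple[float, StrategyState]:
    """Exact minimum conflict count (or weight) and one minimizer.

    Deterministic; enumerates ``2^(|V|-1)`` assignments, feasible up to
    roughly ``max_nodes`` nodes (the default 22 takes seconds).
    """
    n = net.n_nodes
    if n > max_nodes:
        raise NetworkTooLargeError(
            f"{n} nodes exceeds the enumeration cap of {max_nodes}; "
            "use signedgame.dynamics.run for large networks"
        )

    src = net.edge_src
    dst = net.edge_dst
    wgt = net.edge_weight
    cost = np.abs(wgt) if net.weighted else np.ones(wgt.size)
    # incident edge indices per node, for O(degree) Gray-code updates
    incident: list[list[int]] = [[] for _ in range(n)]
    for e in range(wgt.size):
        incident[int(src[e])].append(e)
        incident[int(dst[e])].append(e)

    spins = np.ones(n)
    sat = spins[src] * wgt * spins[dst] > 0
    conflicts = float(cost[~sat].sum()) if wgt.size else 0.0

    best = conflicts
    best_spins = spins.copy()
    if n > 1:
        for g in range(1, 1 << (n - 1)):
            # Gray code: bit b of the code flips at step g where b is the
            # number of trailing zeros of g; node 0 stays pinned at +1.
            node = (g & -g).bit_length()  # trailing zeros + 1
            for e in incident[node]:
                delta = cost[e]
                u, v = int(src[e]), int(dst[e])
                if spins[u] * wgt[e] * spins[v] > 0:
                    conflicts += delta  # satisfied edge becomes a conflict
                else:
                    conflicts -= delta
            spins[node] = -spins[node]
            if conflicts < best:
                best = conflicts
                best_spins = spins.copy()

    if not net.weighted:
        best = float(round(best))
    return best, StrategyState(net, best_spins)
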