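"""Benchmark generators for signed networks.

``generate_planted`` builds a *designated* network: a balanced two-part
construction (positive edges inside each half, negative edges across)
whose balance is then damaged by reversing the sign of ``s`` randomly
sampled edges.  Under the planted bipartition exactly those ``s`` edges
are conflicts, so ``s`` (or, weighted, the total absolute weight of the
flipped edges) is a pre-established upper bound on the frustration index
— the true minimum can only be equal or slightly smaller.

``generate_random_signed`` draws unconstrained Erdős–Rényi-style signed
networks for property tests and oracle comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import SignedNetwork

__all__ = ["PlantedSpec", "generate_planted", "generate_random_signed"]


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a designated network with a planted conflict bound.

    The network has ``2 * n_half`` nodes split into two equal parts,
    ``m_within`` positive edges inside *each* part (so ``2 * m_within``
    positive edges in total), ``m_cross`` negative edges between the
    parts, and ``s_planted`` sign reversals sampled without replacement
    from the full edge set.
    """

    n_half: int
    m_within: int
    m_cross: int
    s_planted: int
    weighted: bool = False
    directed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_half
        if n < 1:
            raise ValueError("n_half must be >= 1")
        max_within = n * (n - 1) if self.directed else n * (n - 1) // 2
        max_cross = 2 * n * n if self.directed else n * n
        if not 0 <= self.m_within <= max_within:
            raise ValueError(
                f"m_within must be in [0, {max_within}] for n_half={n}"
            )
        if not 0 <= self.m_cross <= max_cross:
            raise ValueError(f"m_cross must be in [0, {max_cross}] for n_half={n}")
        if not 0 <= self.s_planted <= 2 * self.m_within + self.m_cross:
            raise ValueError("s_planted exceeds the number of edges")

    @property
    def n_edges(self) -> int:
        return 2 * self.m_within + self.m_cross


def _within_pairs(n: int, offset: int, directed: bool) -> tuple[np.ndarray, np.ndarray]:
    """All candidate node-index pairs inside one part of size n."""
    if directed:
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = i != j
        return i[mask] + offset, j[mask] + offset
    i, j = np.triu_indices(n, k=1)
    return i + offset, j + offset


def _cross_pairs(n: int, directed: bool) -> tuple[np.ndarray, np.ndarray]:
    """Candidate pairs between part A (0..n-1) and part B (n..2n-1)."""
    i, j = np.meshgrid(np.arange(n), np.arange(n, 2 * n), indexing="ij")
    a, b = i.ravel(), j.ravel()
    if directed:
        return np.concatenate([a, b]), np.concatenate([b, a])
    return a, b


def _draw_abs_weights(rng: np.random.Generator, m: int) -> np.ndarray:
    """|w| ~ Uniform(0, 1), open at zero (a zero weight is not an edge)."""
    w = rng.random(m)
    while np.any(w == 0.0):
        w[w == 0.0] = rng.random(np.count_nonzero(w == 0.0))
    return w


def generate_planted(
    spec: PlantedSpec,
) -> tuple[SignedNetwork, dict[str, int], float]:
    """Generate a designated network.

    Returns ``(network, planted_partition, planted_bound)`` where the
    planted partition assigns ``+1`` to part A and ``-1`` to part B and
    the bound is ``s_planted`` (unweighted) or the total absolute weight
    of the flipped edges (weighted).  Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_half
    nodes = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]

    srcs: list[np.ndarray] = []
    dsts: list[np.ndarray] = []
    signs: list[np.ndarray] = []
    for offset in (0, n):
        ci, cj = _within_pairs(n, offset, spec.directed)
        pick = rng.choice(ci.size, size=spec.m_within, replace=False)
        srcs.append(ci[pick])
        dsts.append(cj[pick])
        signs.append(np.ones(spec.m_within))
    ci, cj = _cross_pairs(n, spec.directed)
    pick = rng.choice(ci.size, size=spec.m_cross, replace=False)
    srcs.append(ci[pick])
    dsts.append(cj[pick])
    signs.append(-np.ones(spec.m_cross))

    src = np.concatenate(srcs)
    dst = np.concatenate(dsts)
    sign = np.concatenate(signs)
    m = src.size

    weight = sign * _draw_abs_weights(rng, m) if spec.weighted else sign.copy()

    flip_idx = rng.choice(m, size=spec.s_planted, replace=False)
    weight[flip_idx] = -weight[flip_idx]
    planted_bound = (
        float(np.abs(weight[flip_idx]).sum()) if spec.weighted else float(spec.s_planted)
    )

    net = SignedNetwork(
        nodes,
        [(nodes[u], nodes[v], w) for u, v, w in zip(src, dst, weight)],
        directed=spec.directed,
        weighted=spec.weighted,
    )
    partition = {lbl: (1 if lbl.startswith("a") else -1) for lbl in nodes}
    return net, partition, planted_bound


def generate_random_signed(
    n_nodes: int,
    n_edges: int,
    p_negative: float = 0.5,
    *,
    weighted: bool = False,
    directed: bool = False,
    seed: int = 0,
) -> SignedNetwork:
    """Uniform random signed network: distinct node pairs, each edge
    negative with probability ``p_negative``; weighted mode draws
    ``|w| ~ Uniform(0, 1)``."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 0 <= p_negative <= 1:
        raise ValueError("p_negative must be a probability")
    max_edges = n_nodes * (n_nodes - 1) if directed else n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must be in [0, {max_edges}] for {n_nodes} nodes")

    rng = np.random.default_rng(seed)
    if directed:
        i, j = np.meshgrid(np.arange(n_nodes), np.arange(n_nodes), indexing="ij")
        mask = i != j
        ci, cj = i[mask], j[mask]
    else:
        ci, cj = np.triu_indices(n_nodes, k=1)
    pick = rng.choice(ci.size, size=n_edges, replace=False)
    src, dst = ci[pick], cj[pick]
    sign = np.where(rng.random(n_edges) < p_negative, -1.0, 1.0)
    weight = sign * _draw_abs_weights(rng, n_edges) if weighted else sign

    nodes = [f"n{i}" for i in range(n_nodes)]
    return SignedNetwork(
        nodes,
        [(nodes[u], nodes[v], w) for u, v, w in zip(src, dst, weight)],
        directed=directed,
        weighted=weighted,
    )
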