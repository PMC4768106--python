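"""Fitness and conflict computations for signed networks.

Under a bipartition of the nodes into two alliances, encoded as spins
``v_i in {+1, -1}``, an edge is *satisfied* when ``v_i e_ij v_j > 0``
(positive within an alliance or negative across) and a *conflict*
otherwise.  The game assigns each node the payoff

    f_i = sum_{j in N_i} v_i e_ij v_j          (undirected, unweighted)
    f_i = sum_{j in N_i} v_i w_ij v_j          (weighted)
    f_i = sum_j v_i (e_ij + e_ji) v_j          (directed, symmetrized)

and the network the fitness ``H(V) = sum_i f_i`` (undirected; every edge
is counted once from each endpoint, so a conflict-free assignment gives
``H = 2|E|``).  For directed networks ``H`` sums ``v_i e_ij v_j`` over
directed edges, each counted once, so ``sum_i f_i = 2 H``.

Because every edge contributes ``+|w|`` when satisfied and ``-|w|`` when
in conflict, the minimum number (or total weight) of edges to delete to
reach structural balance — the frustration index — is recovered from the
maximal fitness alone:

    s = (2 * total - H) / 4     (undirected; total = |E| or sum |w|)
    s = (total - H) / 2         (directed)

The exact balance test (``is_balanced``) does not need the game at all:
a network is balanced iff every cycle has an even number of negative
edges, decided in linear time by sign-constrained 2-coloring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .graph import SignedNetwork

__all__ = [
    "StrategyState",
    "BalanceCertificate",
    "FitnessInconsistencyError",
    "node_fitness",
    "network_fitness",
    "count_conflicts",
    "conflict_edges",
    "conflicts_from_fitness",
    "is_balanced",
    "write_partition",
    "read_partition",
]


class FitnessInconsistencyError(ValueError):
    """A (total, H) pair is not realizable by any spin assignment."""


@dataclass
class StrategyState:
    """Per-node alliance assignment with cached payoffs.

    ``spins`` is aligned with ``net.nodes``.  The caches (per-node payoff
    ``f`` and network fitness ``H``) are filled lazily and maintained
    incrementally by the game dynamics; ``check_caches`` asserts they
    agree with a from-scratch recomputation.
    """

    net: SignedNetwork
    spins: np.ndarray
    node_fitness_cache: np.ndarray | None = field(default=None, repr=False)
    network_fitness_cache: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.spins = np.asarray(self.spins, dtype=np.float64)
        if self.spins.shape != (self.net.n_nodes,):
            raise ValueError("spins must have one entry per node")
        if not np.all(np.abs(self.spins) == 1.0):
            raise ValueError("spins must be +1 or -1")

    # -- constructors --------------------------------------------------

    @classmethod
    def all_plus(cls, net: SignedNetwork) -> "StrategyState":
        """Every node in the ``+1`` alliance (the game's initial state)."""
        return cls(net, np.ones(net.n_nodes))

    @classmethod
    def from_assignment(
        cls, net: SignedNetwork, assignment: Mapping[str, int]
    ) -> "StrategyState":
        spins = np.empty(net.n_nodes)
        for label, v in assignment.items():
            spins[net.index_of(label)] = v
        if len(assignment) != net.n_nodes:
            missing = set(net.nodes) - set(assignment)
            raise ValueError(f"assignment misses nodes: {sorted(missing)[:5]} ...")
        return cls(net, spins)

    # -- views ---------------------------------------------------------

    @property
    def assignment(self) -> dict[str, int]:
        return {n: int(v) for n, v in zip(self.net.nodes, self.spins)}

    def spin_of(self, label: str) -> int:
        return int(self.spins[self.net.index_of(label)])

    def copy(self) -> "StrategyState":
        return StrategyState(self.net, self.spins.copy())

    # -- caches ---------------------------------------------------------

    def refresh_caches(self) -> None:
        """Recompute per-node payoffs and network fitness from scratch."""
        indptr, indices, coeff = self.net.adjacency_csr()
        f = np.empty(self.net.n_nodes)
        for i in range(self.net.n_nodes):
            lo, hi = indptr[i], indptr[i + 1]
            f[i] = self.spins[i] * np.dot(coeff[lo:hi], self.spins[indices[lo:hi]])
        self.node_fitness_cache = f
        self.network_fitness_cache = network_fitness(self.net, self)

    def check_caches(self, atol: float = 1e-9) -> None:
        """Assert the incremental caches match a full recomputation."""
        if self.node_fitness_cache is None or self.network_fitness_cache is None:
            raise AssertionError("caches not initialized")
        fresh = StrategyState(self.net, self.spins.copy())
        fresh.refresh_caches()
        assert fresh.node_fitness_cache is not None
        if not np.allclose(
            self.node_fitness_cache, fresh.node_fitness_cache, atol=atol
        ):
            raise AssertionError("node fitness cache diverged from recomputation")
        if abs(self.network_fitness_cache - fresh.network_fitness_cache) > atol:
            raise AssertionError("network fitness cache diverged from recomputation")


@dataclass(frozen=True)
class BalanceCertificate:
    """Outcome of the exact balance test.

    Either ``balanced`` with a zero-conflict ``partition``, or unbalanced
    with a ``witness_edge`` that closes a cycle carrying an odd number of
    negative edges (for directed networks, possibly an antiparallel pair
    with contradictory signs).
    """

    balanced: bool
    partition: dict[str, int] | None = None
    witness_edge: tuple[str, str, float] | None = None


# ---------------------------------------------------------------------------
# fitness / conflicts


def _check_state(net: SignedNetwork, state: StrategyState) -> None:
    if state.net is not net and state.net.nodes != net.nodes:
        raise ValueError("state does not belong to this network")


def node_fitness(net: SignedNetwork, state: StrategyState, i: str) -> float:
    """Payoff ``f_i`` of one node under the current assignment."""
    _check_state(net, state)
    idx = net.index_of(i)
    indptr, indices, coeff = net.adjacency_csr()
    lo, hi = indptr[idx], indptr[idx + 1]
    return float(
        state.spins[idx] * np.dot(coeff[lo:hi], state.spins[indices[lo:hi]])
    )


def network_fitness(net: SignedNetwork, state: StrategyState) -> float:
    """Network fitness ``H(V)``.

    Undirected: sum over ordered pairs, i.e. each edge counted twice, so
    a balanced assignment reaches ``H = 2|E|`` (or twice the total weight).
    Directed: each directed edge counted once.
    """
    _check_state(net, state)
    terms = state.spins[net.edge_src] * net.edge_weight * state.spins[net.edge_dst]
    h = float(terms.sum())
    return h if net.directed else 2.0 * h


def _conflict_mask(net: SignedNetwork, state: StrategyState) -> np.ndarray:
    return (
        state.spins[net.edge_src] * net.edge_weight * state.spins[net.edge_dst]
    ) < 0


def count_conflicts(net: SignedNetwork, state: StrategyState) -> float:
    """Number (unweighted) or total absolute weight (weighted) of conflict
    edges: negative edges within an alliance or positive edges across.
    Directed edges are counted individually."""
    _check_state(net, state)
    mask = _conflict_mask(net, state)
    if net.weighted:
        return float(np.abs(net.edge_weight[mask]).sum())
    return float(mask.sum())


def conflict_edges(
    net: SignedNetwork, state: StrategyState
) -> list[tuple[str, str, float]]:
    """The conflict edges themselves (labels + weight), in edge order."""
    _check_state(net, state)
    mask = _conflict_mask(net, state)
    return [
        (net.nodes[u], net.nodes[v], float(w))
        for u, v, w in zip(
            net.edge_src[mask], net.edge_dst[mask], net.edge_weight[mask]
        )
    ]


def conflicts_from_fitness(
    total: float,
    H: float,
    mode: str = "undirected",
    *,
    weighted: bool = False,
) -> float:
    """Recover the structural-conflict count/weight from the fitness.

    ``total`` is ``|E|`` (unweighted) or ``sum |w_ij|`` (weighted); for
    directed networks, over directed edges.  Satisfied and conflict edges
    contribute ``+|w|`` and ``-|w|`` to the once-per-edge fitness sum, so
    ``s = (total - H/2) / 2`` undirected (where H double-counts) and
    ``s = (total - H) / 2`` directed.

    Raises :class:`FitnessInconsistencyError` when the result is negative
    or, in unweighted mode, not an integer.
    """
    if mode not in ("undirected", "directed"):
        raise ValueError(f"mode must be 'undirected' or 'directed', got {mode!r}")
    if mode == "undirected":
        s = (2.0 * total - H) / 4.0
    else:
        s = (total - H) / 2.0
    if s < -1e-9:
        raise FitnessInconsistencyError(f"negative conflict count {s} from (total={total}, H={H})")
    if not weighted:
        if abs(s - round(s)) > 1e-9:
            raise FitnessInconsistencyError(
                f"non-integer conflict count {s} from (total={total}, H={H})"
            )
        return float(round(s))
    return float(s)


# ---------------------------------------------------------------------------
# exact balance test


def is_balanced(net: SignedNetwork) -> BalanceCertificate:
    """Exact structural-balance test by sign-constrained 2-coloring.

    A signed network is balanced iff all its cycles carry an even number
    of negative edges; equivalently the nodes 2-color so that positive
    edges join like colors and negative edges unlike colors.  Directed
    networks are tested on the underlying undirected sign pattern, and an
    antiparallel pair with contradictory signs is itself a witness of
    imbalance.  Runs in ``O(|V| + |E|)``.
    """
    n = net.n_nodes
    # Underlying undirected sign pattern; detect contradictory antiparallel
    # pairs on the way.
    pair_sign: dict[tuple[int, int], float] = {}
    adj: list[list[tuple[int, float, float]]] = [[] for _ in range(n)]
    for u, v, w in zip(net.edge_src, net.edge_dst, net.edge_weight):
        u, v, w = int(u), int(v), float(w)
        key = (min(u, v), max(u, v))
        sign = 1.0 if w > 0 else -1.0
        if key in pair_sign:
            if pair_sign[key] != sign:
                return BalanceCertificate(
                    balanced=False,
                    witness_edge=(net.nodes[u], net.nodes[v], w),
                )
            continue  # same sign: no new constraint
        pair_sign[key] = sign
        adj[u].append((v, sign, w))
        adj[v].append((u, sign, w))

    color = np.zeros(n, dtype=np.int64)  # 0 = unvisited
    for root in range(n):
        if color[root] != 0:
            continue
        color[root] = 1
        queue = [root]
        while queue:
            i = queue.pop()
            for j, sign, w in adj[i]:
                want = color[i] if sign > 0 else -color[i]
                if color[j] == 0:
                    color[j] = want
                    queue.append(j)
                elif color[j] != want:
                    return BalanceCertificate(
                        balanced=False,
                        witness_edge=(net.nodes[i], net.nodes[j], w),
                    )
    partition = {net.nodes[i]: int(color[i]) for i in range(n)}
    return BalanceCertificate(balanced=True, partition=partition)


# ---------------------------------------------------------------------------
# partition I/O (two-column TSV: node, alliance)


def write_partition(assignment: Mapping[str, int], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node\talliance\n")
        for node, v in assignment.items():
            fh.write(f"{node}\t{int(v):+d}\n")


def read_partition(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            node, v = line.split("\t")
            out[node] = int(v)
    return out
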