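"""Signed-network data model and plain-text edge-list I/O.

A signed network is a graph ``G = (V, E)`` whose edges carry a sign
``e_ij in {+1, -1}`` (unweighted mode) or a nonzero real weight ``w_ij``
(weighted mode).  Edges may be undirected (``e_ij = e_ji``, at most one
edge per unordered pair) or directed (at most one edge per ordered pair;
the two orientations are independent).  Self-loops and zero weights are
invalid everywhere in balance theory and are rejected at construction.

The on-disk format is a whitespace-separated three-column edge list
(``source  target  sign-or-weight``), with ``#`` comment lines — the
dialect used by the common signed-network corpora (SNAP, KONECT).
Node identifiers are opaque strings; positional indices never appear in
files.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SignedNetwork",
    "GraphValidationError",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
]


class GraphValidationError(ValueError):
    """An edge set violates a signed-network invariant."""


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""


class SignedNetwork:
    """An immutable signed network.

    Parameters
    ----------
    nodes:
        Node labels, in order.  Duplicates are rejected.  Nodes with no
        incident edge are allowed (the label list is authoritative).
    edges:
        Iterable of ``(source, target, weight)`` triples with string
        labels and nonzero real weight.  In unweighted mode every weight
        must be exactly ``+1`` or ``-1``.
    directed, weighted:
        Mode flags; they fix which invariants are enforced and how the
        fitness machinery interprets the edges.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str, float]],
        *,
        directed: bool = False,
        weighted: bool = False,
    ) -> None:
        self.nodes: tuple[str, ...] = tuple(str(n) for n in nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphValidationError("duplicate node labels")
        self.directed = bool(directed)
        self.weighted = bool(weighted)
        self._index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}

        src: list[int] = []
        dst: list[int] = []
        wts: list[float] = []
        seen: set[tuple[int, int]] = set()
        for u, v, w in edges:
            u, v = str(u), str(v)
            try:
                iu, iv = self._index[u], self._index[v]
            except KeyError as exc:
                raise GraphValidationError(f"edge endpoint {exc} is not a declared node")
            w = float(w)
            if iu == iv:
                raise GraphValidationError(f"self-loop on node {u!r}")
            if w == 0.0:
                raise GraphValidationError(f"zero-weight edge {u!r} -> {v!r}")
            if not self.weighted and w not in (1.0, -1.0):
                raise GraphValidationError(
                    f"unweighted network requires signs +/-1, got {w} on {u!r} -> {v!r}"
                )
            key = (iu, iv) if self.directed else (min(iu, iv), max(iu, iv))
            if key in seen:
                raise GraphValidationError(
                    f"duplicate {'directed ' if self.directed else ''}edge {u!r} -- {v!r}"
                )
            seen.add(key)
            src.append(iu)
            dst.append(iv)
            wts.append(w)

        self.edge_src: np.ndarray = np.asarray(src, dtype=np.int64)
        self.edge_dst: np.ndarray = np.asarray(dst, dtype=np.int64)
        self.edge_weight: np.ndarray = np.asarray(wts, dtype=np.float64)
        self._adjacency: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    # -- basic views --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Edge count; directed edges are counted individually."""
        return int(self.edge_src.size)

    @property
    def total_weight(self) -> float:
        """Sum of ``|w_ij|`` over edges; equals ``|E|`` when unweighted."""
        return float(np.abs(self.edge_weight).sum())

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node {label!r}") from None

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Edges as ``(source label, target label, weight)`` triples."""
        return [
            (self.nodes[u], self.nodes[v], float(w))
            for u, v, w in zip(self.edge_src, self.edge_dst, self.edge_weight)
        ]

    # -- adjacency ----------------------------------------------------

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetrized adjacency in CSR form: ``(indptr, indices, coeff)``.

        The coefficient attached to the unordered pair ``{i, j}`` is the
        one the node-fitness sum uses: ``w_ij`` for an undirected edge,
        and ``w_ij + w_ji`` for a directed pair (either orientation may
        be absent, contributing zero).  Antiparallel directed edges with
        opposite signs therefore cancel, which is exactly what makes the
        directed game dynamics well behaved.
        """
        if self._adjacency is None:
            n = self.n_nodes
            pair_coeff: dict[tuple[int, int], float] = {}
            for u, v, w in zip(self.edge_src, self.edge_dst, self.edge_weight):
                key = (min(u, v), max(u, v))
                pair_coeff[key] = pair_coeff.get(key, 0.0) + float(w)
            deg = np.zeros(n + 1, dtype=np.int64)
            for i, j in pair_coeff:
                deg[i + 1] += 1
                deg[j + 1] += 1
            indptr = np.cumsum(deg)
            indices = np.zeros(indptr[-1], dtype=np.int64)
            coeff = np.zeros(indptr[-1], dtype=np.float64)
            cursor = indptr[:-1].copy()
            for (i, j), c in pair_coeff.items():
                indices[cursor[i]] = j
                coeff[cursor[i]] = c
                cursor[i] += 1
                indices[cursor[j]] = i
                coeff[cursor[j]] = c
                cursor[j] += 1
            self._adjacency = (indptr, indices, coeff)
        return self._adjacency

    def neighbors(self, label: str) -> tuple[str, ...]:
        """Neighbor set ``N_i`` of a node.

        For directed networks this is the union of in- and out-neighbors:
        the node-fitness sum touches every incident edge regardless of
        orientation.  Note that an antiparallel pair whose coefficient
        cancels still makes the nodes neighbors.
        """
        i = self.index_of(label)
        nbrs: set[int] = set()
        for u, v in zip(self.edge_src, self.edge_dst):
            if u == i:
                nbrs.add(int(v))
            elif v == i:
                nbrs.add(int(u))
        return tuple(self.nodes[j] for j in sorted(nbrs))

    # -- equality (used by round-trip tests) --------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        if (self.nodes, self.directed, self.weighted) != (
            other.nodes,
            other.directed,
            other.weighted,
        ):
            return False
        def canon(net: SignedNetwork) -> set[tuple]:
            out = set()
            for u, v, w in net.edge_list():
                if not net.directed and v < u:
                    u, v = v, u
                out.add((u, v, w))
            return out
        return canon(self) == canon(other)

    def __repr__(self) -> str:
        kind = ("directed" if self.directed else "undirected") + (
            ", weighted" if self.weighted else ""
        )
        return f"SignedNetwork({self.n_nodes} nodes, {self.n_edges} edges, {kind})"


def read_edge_list(
    path,
    *,
    directed: bool = False,
    weighted: bool = False,
) -> SignedNetwork:
    """Read a three-column signed edge list.

    Each non-comment, non-blank line is ``source target value`` separated
    by arbitrary whitespace.  Node labels are taken verbatim as strings.
    In unweighted mode any positive value maps to ``+1`` and any negative
    to ``-1``; a zero value is rejected.

    Raises
    ------
    EdgeListParseError
        Malformed line (fewer than three fields, or non-numeric value),
        reported with its line number.
    GraphValidationError
        Self-loop, duplicate pair, or zero weight.
    """
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    edges: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                # "# node <label>" directives preserve isolated nodes and
                # node order across a write/read round trip; any other
                # comment is ignored.
                fields = line[1:].split()
                if len(fields) == 2 and fields[0] == "node":
                    lbl = fields[1]
                    if lbl not in seen_nodes:
                        seen_nodes.add(lbl)
                        nodes.append(lbl)
                continue
            if not line:
                continue
            fields = line.split()
            if len(fields) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 'source target value', got {line!r}"
                )
            u, v, sval = fields[0], fields[1], fields[2]
            try:
                w = float(sval)
            except ValueError:
                raise EdgeListParseError(
                    f"{path}:{lineno}: third field {sval!r} is not a number"
                ) from None
            if w == 0.0:
                raise GraphValidationError(f"{path}:{lineno}: zero-valued edge")
            if not weighted:
                w = 1.0 if w > 0 else -1.0
            for lbl in (u, v):
                if lbl not in seen_nodes:
                    seen_nodes.add(lbl)
                    nodes.append(lbl)
            edges.append((u, v, w))
    return SignedNetwork(nodes, edges, directed=directed, weighted=weighted)


def write_edge_list(net: SignedNetwork, path) -> None:
    """Write a network as a three-column edge list (round-trips with
    :func:`read_edge_list` at full floating-point precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        kind = "directed" if net.directed else "undirected"
        kind += " weighted" if net.weighted else " unweighted"
        fh.write(f"# signed edge list ({kind}): source target weight\n")
        for n in net.nodes:
            fh.write(f"# node {n}\n")
        for u, v, w in net.edge_list():
            if not net.weighted:
                fh.write(f"{u}\t{v}\t{int(w):d}\n")
            else:
                fh.write(f"{u}\t{v}\t{w!r}\n")
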