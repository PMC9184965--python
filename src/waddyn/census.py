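"""Exhaustive census of decision-graph topologies on n attractors.

A decision graph is a simple undirected graph whose vertices are attractors
and whose edges mark saddle-mediated direct transitions.  The census
enumerates all isomorphism classes of such graphs on ``n`` labelled vertices
(optionally connected only), so that any empirically reconstructed decision
graph can be matched against a canonical inventory.

Isomorphism classes are identified by an exact canonical certificate: the
lexicographically smallest edge bitmask over all vertex permutations,
evaluated for every edge subset at once with vectorized permutation index
tables.  This is exact for the sizes the census is intended for (n <= 7);
larger n raise rather than silently degrade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

__all__ = [
    "TopologyCensus",
    "TopologyClass",
    "enumerate_topologies",
    "match_topology",
    "CensusSizeError",
]

#: largest vertex count for which brute-force enumeration is allowed
MAX_CENSUS_N = 7


class CensusSizeError(ValueError):
    """Vertex count too large for exact brute-force enumeration."""


def _edge_list(n: int) -> list[tuple[int, int]]:
    return list(combinations(range(n), 2))


def _perm_edge_table(n: int) -> np.ndarray:
    """Row p, column e: index of edge e after applying permutation p."""
    edges = _edge_list(n)
    edge_index = {e: k for k, e in enumerate(edges)}
    perms = list(permutations(range(n)))
    table = np.empty((len(perms), len(edges)), dtype=np.int64)
    for p_i, perm in enumerate(perms):
        for e_i, (u, v) in enumerate(edges):
            pu, pv = perm[u], perm[v]
            table[p_i, e_i] = edge_index[(min(pu, pv), max(pu, pv))]
    return table


def canonical_certificate(n: int, edges) -> int:
    """Smallest edge bitmask of the graph over all vertex relabellings."""
    if n > MAX_CENSUS_N:
        raise CensusSizeError(
            f"exact canonicalization supports n <= {MAX_CENSUS_N}, got {n}"
        )
    edge_ix = {e: k for k, e in enumerate(_edge_list(n))}
    present = []
    for u, v in edges:
        u, v = int(u), int(v)
        if u == v:
            raise ValueError("decision graphs have no self-loops")
        present.append(edge_ix[(min(u, v), max(u, v))])
    table = _perm_edge_table(n)
    pow2 = np.int64(1) << table  # exact: at most C(7,2)=21 bits
    if not present:
        return 0
    images = pow2[:, sorted(set(present))].sum(axis=1)
    return int(images.min())


@dataclass(frozen=True)
class TopologyClass:
    """One isomorphism class of decision graphs."""

    n_vertices: int
    certificate: int
    edges: tuple  # representative edge list (vertices 0..n-1)
    n_edges: int
    connected: bool
    degree_sequence: tuple

    def to_json_dict(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "certificate": self.certificate,
            "edges": [list(e) for e in self.edges],
            "n_edges": self.n_edges,
            "connected": self.connected,
            "degree_sequence": list(self.degree_sequence),
        }


def _is_connected(n, edges) -> bool:
    if n <= 1:
        return True
    adj = {i: set() for i in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == n


@dataclass
class TopologyCensus:
    """The full inventory of decision-graph classes on ``n`` vertices."""

    n_vertices: int
    classes: list
    connected_only: bool

    def __len__(self):
        return len(self.classes)

    @property
    def certificates(self) -> set:
        return {c.certificate for c in self.classes}

    def to_json_dict(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "connected_only": self.connected_only,
            "n_classes": len(self.classes),
            "classes": [c.to_json_dict() for c in self.classes],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


def enumerate_topologies(n: int, connected_only: bool = True) -> TopologyCensus:
    """Enumerate all decision-graph isomorphism classes on ``n`` attractors.

    Every edge subset of the complete graph is canonicalized at once with a
    vectorized permutation table; one representative per distinct certificate
    is kept, ordered by (edge count, certificate).
    """
    if n < 1:
        raise ValueError("need at least one vertex")
    if n > MAX_CENSUS_N:
        raise CensusSizeError(
            f"exact enumeration supports n <= {MAX_CENSUS_N}, got {n}"
        )
    edges = _edge_list(n)
    m = len(edges)
    table = _perm_edge_table(n)
    pow2 = np.int64(1) << table  # (n_perms, m)
    edge_cols = [pow2[:, k] for k in range(m)]

    # ascending orbit sweep: the first unseen mask is the smallest member of
    # its isomorphism orbit and therefore its canonical certificate; mark the
    # whole orbit (its images under every vertex permutation) as seen
    seen = np.zeros(1 << m, dtype=bool)
    reps: dict[int, int] = {}
    for mask in range(1 << m):
        if seen[mask]:
            continue
        cols = [edge_cols[k] for k in range(m) if (mask >> k) & 1]
        if cols:
            images = np.sum(cols, axis=0)
        else:
            images = np.zeros(1, dtype=np.int64)
        seen[images] = True
        reps[mask] = mask

    classes = []
    for cert, mask in reps.items():
        e_rep = tuple(edges[k] for k in range(m) if (mask >> k) & 1)
        conn = _is_connected(n, e_rep)
        if connected_only and not conn:
            continue
        degs = [0] * n
        for u, v in e_rep:
            degs[u] += 1
            degs[v] += 1
        classes.append(
            TopologyClass(
                n_vertices=n,
                certificate=cert,
                edges=e_rep,
                n_edges=len(e_rep),
                connected=conn,
                degree_sequence=tuple(sorted(degs, reverse=True)),
            )
        )
    classes.sort(key=lambda c: (c.n_edges, c.certificate))
    return TopologyCensus(n_vertices=n, classes=classes, connected_only=connected_only)


def match_topology(census: TopologyCensus, edges, n: int | None = None) -> TopologyClass | None:
    """Find the census class isomorphic to the given decision graph.

    ``edges`` may use arbitrary hashable vertex names; ``n`` defaults to the
    census size and must equal it.  Returns ``None`` when the graph is not in
    the census (e.g. disconnected graphs in a connected-only census).
    """
    names = sorted({u for e in edges for u in e})
    n = census.n_vertices if n is None else n
    if n != census.n_vertices:
        raise ValueError(
            f"graph has {n} vertices but census covers {census.n_vertices}"
        )
    if len(names) > n:
        raise ValueError("more distinct vertex names than vertices")
    ix = {name: k for k, name in enumerate(names)}
    cert = canonical_certificate(n, [(ix[u], ix[v]) for u, v in edges])
    for c in census.classes:
        if c.certificate == cert:
            return c
    return None
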