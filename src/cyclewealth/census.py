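"""Per-node and per-graph censuses of short simple cycles and simple paths.

A *k-cycle* is a closed walk of k edges over k distinct vertices; for
k <= 5 this coincides with the set of closed walks over contiguous
distinct edges (two edge-disjoint sub-cycles would need at least six
edges), so the simple-cycle census below is also the geodesic-cycle
census in that range.  A *k-path* is a simple path of exactly k edges
(k+1 distinct vertices).

The per-node cycle count ``Cy_k(n)`` is the number of distinct k-cycles
that contain node ``n``; the per-node path count is the number of
distinct k-paths on which ``n`` lies at any position (endpoint or
interior), matching the semantics of the classical ``kpath.census``
motif counters.

Every distinct cycle is counted exactly once using a canonical form:
the smallest vertex label comes first and traversal proceeds toward the
smaller of its two cycle neighbours.  Undirected paths are canonicalised
by orienting them from the smaller-labelled endpoint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["CensusResult", "cycle_census", "path_census", "brute_force_census"]

_K_MIN = 3
_K_MAX_GUARD = 6
_BRUTE_FORCE_NODE_GUARD = 14


@dataclass
class CensusResult:
    """Cycle/path census of one undirected simple graph.

    Attributes
    ----------
    k_range : list of int
        Motif sizes covered (3..K).
    node_cycle_counts : DataFrame (node x k)
        Number of distinct simple k-cycles each node belongs to.
    node_path_counts : DataFrame (node x k)
        Number of distinct simple k-edge paths each node lies on.
    graph_cycle_totals, graph_path_totals : dict k -> int
    cycle_membership : dict k -> list of tuple
        Canonical vertex sequences, one per distinct cycle (present only
        when requested; the sequence, not the vertex set, is stored so
        that distinct cycles on the same vertex set stay distinct).
    """

    k_range: list[int]
    node_cycle_counts: pd.DataFrame
    node_path_counts: pd.DataFrame
    graph_cycle_totals: dict[int, int]
    graph_path_totals: dict[int, int]
    cycle_membership: dict[int, list[tuple]] | None = None

    def validate_identities(self) -> None:
        """Assert the handshake identities linking node and graph totals.

        Each k-cycle contributes k node incidences; each k-path
        contributes k+1.
        """
        for k in self.k_range:
            s = int(self.node_cycle_counts[k].sum())
            if s != k * self.graph_cycle_totals[k]:
                raise AssertionError(
                    f"cycle identity violated at k={k}: {s} != "
                    f"{k}*{self.graph_cycle_totals[k]}"
                )
            s = int(self.node_path_counts[k].sum())
            if s != (k + 1) * self.graph_path_totals[k]:
                raise AssertionError(
                    f"path identity violated at k={k}: {s} != "
                    f"{k + 1}*{self.graph_path_totals[k]}"
                )


def _check_graph(graph: nx.Graph, K: int) -> None:
    if not (_K_MIN <= K <= _K_MAX_GUARD):
        raise ValueError(
            f"K={K} outside the enumeration guard [{_K_MIN}, {_K_MAX_GUARD}]"
        )
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("census requires a simple undirected graph")
    for u, v in graph.edges():
        if u == v:
            raise ValueError(f"self-loop on node {u!r} — graph is not simple")


def _index_graph(graph: nx.Graph):
    """Sort nodes (stringwise for mixed/opaque labels) and build int adjacency."""
    try:
        nodes = sorted(graph.nodes())
    except TypeError:
        nodes = sorted(graph.nodes(), key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [sorted(idx[w] for w in graph.neighbors(v)) for v in nodes]
    return nodes, adj


def _empty_result(nodes, k_range) -> tuple[pd.DataFrame, pd.DataFrame]:
    zeros = np.zeros((len(nodes), len(k_range)), dtype=np.int64)
    cyc = pd.DataFrame(zeros.copy(), index=nodes, columns=k_range)
    pat = pd.DataFrame(zeros.copy(), index=nodes, columns=k_range)
    return cyc, pat


def cycle_census(graph: nx.Graph, K: int = 5, with_membership: bool = False) -> CensusResult:
    """Count simple cycles of lengths 3..K per node and per graph.

    Every distinct cycle is counted once; each member node's count is
    incremented once per cycle.  ``with_membership=True`` additionally
    returns the canonical vertex sequence of every cycle (needed for
    composition scoring and for permutation nulls, where the cycle set
    is fixed while node attributes change).
    """
    _check_graph(graph, K)
    k_range = list(range(_K_MIN, K + 1))
    nodes, adj = _index_graph(graph)
    n = len(nodes)
    cyc_counts = np.zeros((n, len(k_range)), dtype=np.int64)
    totals = {k: 0 for k in k_range}
    membership: dict[int, list[tuple]] = {k: [] for k in k_range}

    # DFS from each anchor over vertices with index > anchor; a cycle is
    # canonical iff its anchor is its minimum and the second vertex is
    # smaller than the last (direction tie-break).
    path = [0] * (K + 1)
    on_path = [False] * n
    for a in range(n):
        if len(adj[a]) < 2:
            continue
        path[0] = a
        on_path[a] = True
        stack = [(w, 1) for w in reversed(adj[a]) if w > a]
        # iterative DFS carrying explicit depth; unwind via sentinel
        frames: list[tuple[int, int]] = stack
        trail: list[int] = []
        while frames:
            v, depth = frames.pop()
            while trail and len(trail) >= depth:
                on_path[trail.pop()] = False
            path[depth] = v
            trail.append(v)
            on_path[v] = True
            closes = a in adj[v] if depth >= 2 else False
            k = depth + 1
            if closes and k >= _K_MIN and k <= K and path[1] < v:
                ki = k - _K_MIN
                totals[k] += 1
                cyc_counts[a, ki] += 1
                for d in range(1, depth + 1):
                    cyc_counts[path[d], ki] += 1
                if with_membership:
                    membership[k].append(tuple(nodes[path[d]] for d in range(k)))
            if depth < K - 1:
                for w in adj[v]:
                    if w > a and not on_path[w]:
                        frames.append((w, depth + 1))
        while trail:
            on_path[trail.pop()] = False
        on_path[a] = False

    node_cyc = pd.DataFrame(cyc_counts, index=nodes, columns=k_range)
    node_pat = pd.DataFrame(
        np.zeros_like(cyc_counts), index=nodes, columns=k_range
    )
    return CensusResult(
        k_range=k_range,
        node_cycle_counts=node_cyc,
        node_path_counts=node_pat,
        graph_cycle_totals=totals,
        graph_path_totals={k: 0 for k in k_range},
        cycle_membership=membership if with_membership else None,
    )


def path_census(graph: nx.Graph, K: int = 5) -> CensusResult:
    """Count simple paths of exactly k edges (k in 3..K) per node and graph.

    A path is counted once in its canonical orientation (from the
    smaller-labelled endpoint); node incidence covers endpoints and
    interior nodes alike.
    """
    _check_graph(graph, K)
    k_range = list(range(_K_MIN, K + 1))
    nodes, adj = _index_graph(graph)
    n = len(nodes)
    path_counts = np.zeros((n, len(k_range)), dtype=np.int64)
    totals = {k: 0 for k in k_range}

    path = [0] * (K + 1)
    on_path = [False] * n
    for s in range(n):
        if not adj[s]:
            continue
        path[0] = s
        on_path[s] = True
        frames = [(w, 1) for w in reversed(adj[s])]
        trail: list[int] = []
        while frames:
            v, depth = frames.pop()
            while trail and len(trail) >= depth:
                on_path[trail.pop()] = False
            path[depth] = v
            trail.append(v)
            on_path[v] = True
            k = depth  # edges so far
            if _K_MIN <= k <= K and s < v:
                ki = k - _K_MIN
                totals[k] += 1
                for d in range(depth + 1):
                    path_counts[path[d], ki] += 1
            if depth < K:
                for w in adj[v]:
                    if not on_path[w]:
                        frames.append((w, depth + 1))
        while trail:
            on_path[trail.pop()] = False
        on_path[s] = False

    node_pat = pd.DataFrame(path_counts, index=nodes, columns=k_range)
    node_cyc = pd.DataFrame(
        np.zeros_like(path_counts), index=nodes, columns=k_range
    )
    return CensusResult(
        k_range=k_range,
        node_cycle_counts=node_cyc,
        node_path_counts=node_pat,
        graph_cycle_totals={k: 0 for k in k_range},
        graph_path_totals=totals,
    )


def full_census(graph: nx.Graph, K: int = 5, with_membership: bool = False) -> CensusResult:
    """Run both censuses and merge into a single result."""
    c = cycle_census(graph, K, with_membership=with_membership)
    p = path_census(graph, K)
    return CensusResult(
        k_range=c.k_range,
        node_cycle_counts=c.node_cycle_counts,
        node_path_counts=p.node_path_counts,
        graph_cycle_totals=c.graph_cycle_totals,
        graph_path_totals=p.graph_path_totals,
        cycle_membership=c.cycle_membership,
    )


def brute_force_census(graph: nx.Graph, K: int = 5) -> CensusResult:
    # Test oracle: enumerate ordered vertex tuples, keep adjacency-valid
    # simple walks, dedupe by canonical form.  Exponential; guarded.
    _check_graph(graph, K)
    if graph.number_of_nodes() > _BRUTE_FORCE_NODE_GUARD:
        raise ValueError(
            f"brute_force_census is limited to {_BRUTE_FORCE_NODE_GUARD} nodes"
        )
    k_range = list(range(_K_MIN, K + 1))
    nodes, adj = _index_graph(graph)
    n = len(nodes)
    adjset = [set(a) for a in adj]
    cyc_counts = np.zeros((n, len(k_range)), dtype=np.int64)
    pat_counts = np.zeros((n, len(k_range)), dtype=np.int64)
    cyc_totals = {k: 0 for k in k_range}
    pat_totals = {k: 0 for k in k_range}
    membership: dict[int, list[tuple]] = {k: [] for k in k_range}

    for k in k_range:
        seen_cycles = set()
        seen_paths = set()
        for tup in itertools.permutations(range(n), k):
            ok = all(tup[i + 1] in adjset[tup[i]] for i in range(k - 1))
            if not ok:
                continue
            # cycle: k vertices, closing edge back to start
            if tup[0] in adjset[tup[-1]]:
                m = tup.index(min(tup))
                rot = tup[m:] + tup[:m]
                canon = min(rot, (rot[0],) + tuple(reversed(rot[1:])))
                if canon not in seen_cycles:
                    seen_cycles.add(canon)
                    cyc_totals[k] += 1
                    for v in canon:
                        cyc_counts[v, k - _K_MIN] += 1
                    membership[k].append(tuple(nodes[v] for v in canon))
        for tup in itertools.permutations(range(n), k + 1):
            ok = all(tup[i + 1] in adjset[tup[i]] for i in range(k))
            if not ok:
                continue
            canon = min(tup, tuple(reversed(tup)))
            if canon not in seen_paths:
                seen_paths.add(canon)
                pat_totals[k] += 1
                for v in canon:
                    pat_counts[v, k - _K_MIN] += 1

    return CensusResult(
        k_range=k_range,
        node_cycle_counts=pd.DataFrame(cyc_counts, index=nodes, columns=k_range),
        node_path_counts=pd.DataFrame(pat_counts, index=nodes, columns=k_range),
        graph_cycle_totals=cyc_totals,
        graph_path_totals=pat_totals,
        cycle_membership=membership,
    )


def closed_walk_census_totals(graph: nx.Graph, K: int = 5) -> dict[int, int]:
    """Oracle: count closed walks over contiguous *distinct edges* per length.

    For k <= 5 these coincide with simple cycles, which is what makes the
    simple-cycle implementation a faithful geodesic-cycle census in the
    3..5 range.  Enumerates edge-distinct closed walks directly.
    """
    _check_graph(graph, K)
    if graph.number_of_nodes() > _BRUTE_FORCE_NODE_GUARD:
        raise ValueError("walk oracle limited to small graphs")
    nodes, adj = _index_graph(graph)
    totals = {k: 0 for k in range(_K_MIN, K + 1)}
    seen: dict[int, set] = {k: set() for k in totals}

    def walk(start, v, used_edges, seq):
        if _K_MIN <= len(seq) <= K and v == start and len(seq) > 1:
            pass  # handled at extension time
        for w in adj[v]:
            e = (min(v, w), max(v, w))
            if e in used_edges:
                continue
            nseq = seq + (w,)
            k = len(nseq) - 1
            if w == start and _K_MIN <= k <= K:
                body = nseq[:-1]
                m = body.index(min(body))
                rot = body[m:] + body[:m]
                canon = min(rot, (rot[0],) + tuple(reversed(rot[1:])))
                if canon not in seen[k]:
                    seen[k].add(canon)
                    totals[k] += 1
            if k < K and w != start:
                walk(start, w, used_edges | {e}, nseq)

    for s in range(len(nodes)):
        walk(s, s, frozenset(), (s,))
    return totals
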