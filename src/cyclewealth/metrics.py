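"""Cycle composition ("cycle quality"), wealth assortativity, and centralities.

The k-cycle composition of a node summarises the wealth of the *alters*
on the k-cycles the node participates in.  Two variants are computed:

* ``literal``:  sum of alter wealth over all the node's k-cycles divided
  by ``k * (number of cycles)`` — the divisor counts the node itself even
  though it is excluded from the sum, so an all-wealth-w graph scores
  ``(k-1) * w / k``.
* ``alters_mean``: the same sum divided by ``(k-1) * (number of cycles)``
  — the plain average wealth of alter incidences, which equals w in the
  all-w case.  The two differ only by the constant factor (k-1)/k; the
  alters-mean variant is the default for downstream models because it is
  the direct "average wealth of the alters" and standardisation removes
  the constant anyway.

Nodes participating in no k-cycle are *undefined* (NaN), not zero: they
are excluded from composition models rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .census import CensusResult

__all__ = [
    "CompositionResult",
    "AssortativityMatrix",
    "cycle_composition",
    "composition_table",
    "assortativity_matrix",
    "centralities",
]

N_CLASSES = 5


@dataclass
class CompositionResult:
    """Per-node cycle-composition scores for one motif size k."""

    k: int
    table: pd.DataFrame  # columns: cycles_used, literal, alters_mean; NaN if undefined

    @property
    def defined(self) -> pd.DataFrame:
        return self.table.dropna(subset=["alters_mean"])


def cycle_composition(membership: list[tuple], wealth, k: int, nodes=None) -> CompositionResult:
    """Score each node's k-cycle composition from canonical cycle sequences.

    Parameters
    ----------
    membership : list of canonical vertex sequences of length k
        As produced by ``cycle_census(..., with_membership=True)``.
    wealth : mapping node -> numeric wealth (class or score)
    k : motif size
    nodes : optional iterable fixing the output index (defaults to the
        union of cycle members)
    """
    alter_sum: dict = {}
    count: dict = {}
    for seq in membership:
        if len(seq) != k:
            raise ValueError(f"cycle of length {len(seq)} passed to k={k} composition")
        try:
            total = sum(wealth[v] for v in seq)
        except KeyError as exc:
            raise KeyError(f"wealth missing for cycle member {exc.args[0]!r}") from None
        for v in seq:
            alter_sum[v] = alter_sum.get(v, 0.0) + (total - wealth[v])
            count[v] = count.get(v, 0) + 1
    if nodes is None:
        nodes = sorted(alter_sum, key=str)
    rows = []
    for v in nodes:
        c = count.get(v, 0)
        if c == 0:
            rows.append((0, np.nan, np.nan))
        else:
            s = alter_sum[v]
            rows.append((c, s / (k * c), s / ((k - 1) * c)))
    table = pd.DataFrame(rows, index=pd.Index(nodes), columns=["cycles_used", "literal", "alters_mean"])
    return CompositionResult(k=k, table=table)


def composition_table(census: CensusResult, wealth, nodes=None) -> pd.DataFrame:
    """Long-format composition for every k in a census with membership."""
    if census.cycle_membership is None:
        raise ValueError("census was run without with_membership=True")
    frames = []
    for k in census.k_range:
        res = cycle_composition(census.cycle_membership[k], wealth, k, nodes=nodes)
        t = res.table.copy()
        t["k"] = k
        t["node"] = t.index
        frames.append(t.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


@dataclass
class AssortativityMatrix:
    """Wealth-class mixing matrix: share of edges per unordered class pair."""

    matrix: pd.DataFrame          # symmetric 5x5, unordered-pair shares
    marginals: pd.Series          # share of edge endpoints per class
    n_edges: int

    def row_normalized(self) -> pd.DataFrame:
        m = self.matrix.copy()
        return m.div(m.sum(axis=1), axis=0)

    def off_diagonal_mass(self) -> float:
        m = self.matrix.to_numpy()
        return float(m[~np.eye(m.shape[0], dtype=bool)].sum() / 2.0)


def assortativity_matrix(graph: nx.Graph, classes) -> AssortativityMatrix:
    """Fraction of edges joining each unordered wealth-class pair.

    Each undirected edge is counted once under its unordered class pair
    {a, b}; the matrix is stored symmetrically, so the shares of
    unordered pairs (diagonal plus upper triangle) sum to 1.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("assortativity undefined for an empty edge set")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=float)
    endpoint = np.zeros(N_CLASSES, dtype=float)
    for u, v in graph.edges():
        a, b = int(classes[u]) - 1, int(classes[v]) - 1
        counts[a, b] += 1.0
        if a != b:
            counts[b, a] += 1.0
        endpoint[a] += 1.0
        endpoint[b] += 1.0
    m = graph.number_of_edges()
    labels = list(range(1, N_CLASSES + 1))
    return AssortativityMatrix(
        matrix=pd.DataFrame(counts / m, index=labels, columns=labels),
        marginals=pd.Series(endpoint / (2 * m), index=labels),
        n_edges=m,
    )


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, eigenvector, and betweenness centralities per node.

    Eigenvector centrality is computed per connected component (power
    iteration, tolerance 1e-10), zero for isolated nodes, then scaled to
    unit maximum across the graph.  Betweenness is the standard
    normalized shortest-path betweenness.
    """
    try:
        nodes = sorted(graph.nodes())
    except TypeError:
        nodes = sorted(graph.nodes(), key=str)
    deg = pd.Series(dict(graph.degree()), dtype=float).reindex(nodes)
    eig = pd.Series(0.0, index=nodes)
    for comp in nx.connected_components(graph):
        comp = list(comp)
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        ec = nx.eigenvector_centrality(sub, max_iter=10_000, tol=1e-10)
        for v, x in ec.items():
            eig[v] = x
    if eig.max() > 0:
        eig = eig / eig.max()
    btw = pd.Series(nx.betweenness_centrality(graph, normalized=True)).reindex(nodes)
    return pd.DataFrame({"degree": deg, "eigenvector": eig, "betweenness": btw})
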