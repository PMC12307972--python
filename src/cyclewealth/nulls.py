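"""Degree-preserving null ensembles, Z-scores, and cyclic/path densities.

The null model holds the number of nodes, number of edges, and the full
degree sequence fixed while randomising which dyads are connected, via
repeated double-edge swaps: pick two edges (a,b), (c,d) and rewire to
(a,d), (c,b), rejecting any swap that would create a self-loop or a
multi-edge.  The k-cyclic density of a graph is

    C_k(G) = ln( max(1, |P_k(G)|) / max(1, E|P_k(G_R)|) )

i.e. the log-ratio of the observed k-cycle count to its null
expectation, with a max(1, .) guard on both numerator and denominator
(the observed-zero case is flagged rather than sent to -inf).  The
overall cyclic density C(G) is the arithmetic mean of C_k over k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .census import cycle_census, full_census, path_census

__all__ = [
    "NullEnsembleStats",
    "rewire_degree_preserving",
    "null_ensemble",
    "significance_threshold",
]


@dataclass
class NullEnsembleStats:
    """Null-model summary for one graph: per-k means, SDs, Z, densities."""

    k_range: list[int]
    replicates: int
    seed: int
    swap_multiplier: float
    observed_cycles: dict[int, int]
    observed_paths: dict[int, int]
    null_mean_cycles: dict[int, float]
    null_sd_cycles: dict[int, float]
    null_mean_paths: dict[int, float]
    null_sd_paths: dict[int, float]
    z_cycles: dict[int, float]
    z_paths: dict[int, float]
    cyclic_density: dict[int, float]
    path_density: dict[int, float]
    overall_cyclic_density: float
    flags: dict[int, list[str]] = field(default_factory=dict)


def rewire_degree_preserving(graph: nx.Graph, seed: int, swap_multiplier: float = 10.0) -> nx.Graph:
    """Randomise a simple undirected graph by accepted double-edge swaps.

    Performs ``swap_multiplier * |E|`` accepted swaps (self-loop or
    multi-edge proposals are rejected and retried).  The output has the
    input's exact degree sequence.  Graphs with no swappable edge pair
    (e.g. stars) are returned unchanged with ``graph.graph['rewire_warning']``
    set.
    """
    m = graph.number_of_edges()
    if m < 2:
        raise ValueError("rewiring requires at least 2 edges")
    rng = np.random.default_rng(seed)
    g = graph.copy()
    nodes = list(g.nodes())
    edges = [tuple(e) for e in g.edges()]
    target = max(1, int(round(swap_multiplier * m)))
    accepted = 0
    tries = 0
    max_tries = 200 * target
    adj = {v: set(g.neighbors(v)) for v in nodes}
    chunk = max(64, 2 * target)
    buf_ij = rng.integers(0, m, size=(chunk, 2))
    buf_flip = rng.integers(0, 2, size=chunk)
    pos = 0
    while accepted < target and tries < max_tries:
        if pos >= chunk:
            buf_ij = rng.integers(0, m, size=(chunk, 2))
            buf_flip = rng.integers(0, 2, size=chunk)
            pos = 0
        tries += 1
        i, j = buf_ij[pos]
        flip = buf_flip[pos]
        pos += 1
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if d in adj[a] or b in adj[c]:
            continue
        adj[a].discard(b); adj[b].discard(a)
        adj[c].discard(d); adj[d].discard(c)
        adj[a].add(d); adj[d].add(a)
        adj[c].add(b); adj[b].add(c)
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from(edges)
    if accepted == 0:
        out = graph.copy()
        out.graph["rewire_warning"] = "no swappable edge pair; returned input unchanged"
        warnings.warn("graph admits no double-edge swap; returning input unchanged")
    return out


def _guarded_log_ratio(observed: int, null_mean: float) -> tuple[float, list[str]]:
    flags = []
    if observed == 0:
        flags.append("observed_zero")
    return math.log(max(1.0, observed) / max(1.0, null_mean)), flags


def null_ensemble(
    graph: nx.Graph,
    K: int = 5,
    replicates: int = 50,
    seed: int = 0,
    swap_multiplier: float = 10.0,
) -> NullEnsembleStats:
    """Cycle/path Z-scores and densities against a degree-preserving ensemble.

    Z is reported as NaN (flagged ``null_sd_zero``), never 0, when the
    null SD vanishes.  Expected counts are ensemble means.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates for an SD")
    obs = full_census(graph, K)
    k_range = obs.k_range
    null_c = {k: [] for k in k_range}
    null_p = {k: [] for k in k_range}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(replicates)
    for r in range(replicates):
        g_r = rewire_degree_preserving(graph, int(child_seeds[r] % (2**31)), swap_multiplier)
        cen = full_census(g_r, K)
        for k in k_range:
            null_c[k].append(cen.graph_cycle_totals[k])
            null_p[k].append(cen.graph_path_totals[k])

    mean_c, sd_c, mean_p, sd_p = {}, {}, {}, {}
    z_c, z_p, dens_c, dens_p = {}, {}, {}, {}
    flags: dict[int, list[str]] = {}
    for k in k_range:
        arr_c = np.asarray(null_c[k], dtype=float)
        arr_p = np.asarray(null_p[k], dtype=float)
        mean_c[k], sd_c[k] = float(arr_c.mean()), float(arr_c.std(ddof=1))
        mean_p[k], sd_p[k] = float(arr_p.mean()), float(arr_p.std(ddof=1))
        fl: list[str] = []
        oc = obs.graph_cycle_totals[k]
        op = obs.graph_path_totals[k]
        if sd_c[k] > 0:
            z_c[k] = (oc - mean_c[k]) / sd_c[k]
        else:
            z_c[k] = float("nan")
            fl.append("null_sd_zero")
        z_p[k] = (op - mean_p[k]) / sd_p[k] if sd_p[k] > 0 else float("nan")
        dens_c[k], f2 = _guarded_log_ratio(oc, mean_c[k])
        dens_p[k], _ = _guarded_log_ratio(op, mean_p[k])
        flags[k] = fl + f2

    return NullEnsembleStats(
        k_range=k_range,
        replicates=replicates,
        seed=seed,
        swap_multiplier=swap_multiplier,
        observed_cycles={k: obs.graph_cycle_totals[k] for k in k_range},
        observed_paths={k: obs.graph_path_totals[k] for k in k_range},
        null_mean_cycles=mean_c,
        null_sd_cycles=sd_c,
        null_mean_paths=mean_p,
        null_sd_paths=sd_p,
        z_cycles=z_c,
        z_paths=z_p,
        cyclic_density=dens_c,
        path_density=dens_p,
        overall_cyclic_density=float(np.mean([dens_c[k] for k in k_range])),
        flags=flags,
    )


def significance_threshold(alpha: float = 0.05, two_sided: bool = True) -> float:
    """Standard-normal critical value; two-sided alpha=0.05 gives 1.96."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    q = 1 - alpha / 2 if two_sided else 1 - alpha
    return float(stats.norm.ppf(q))
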