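"""Cycle composition, assortativity, and centralities."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclewealth import (assortativity_matrix, centralities, composition_table,
                         cycle_census, cycle_composition)


def census_membership(g, k):
    return cycle_census(g, K=k, with_membership=True).cycle_membership[k]


def test_single_triangle_composition():
    g = nx.Graph([(1, 2), (2, 3), (1, 3)])
    comp = cycle_composition(census_membership(g, 3), {1: 1, 2: 2, 3: 3}, 3)
    assert comp.table.loc[1, "literal"] == pytest.approx((2 + 3) / (3 * 1))
    assert comp.table.loc[1, "alters_mean"] == pytest.approx(2.5)
    # constant wealth exposes the divisor difference between the variants
    const = cycle_composition(census_membership(g, 3), {1: 4, 2: 4, 3: 4}, 3)
    assert const.table["alters_mean"].eq(4.0).all()
    assert const.table["literal"].eq(4.0 * 2 / 3).all()


def test_two_shared_triangles_hand_enumeration():
    g = nx.Graph([("n", "a1"), ("a1", "a2"), ("a2", "n"),
                  ("n", "b1"), ("b1", "b2"), ("b2", "n")])
    w = {"n": 1, "a1": 2, "a2": 3, "b1": 4, "b2": 5}
    comp = cycle_composition(census_membership(g, 3), w, 3)
    assert comp.table.loc["n", "alters_mean"] == pytest.approx((2 + 3 + 4 + 5) / 4)
    assert comp.table.loc["n", "literal"] == pytest.approx(14 / 6)
    assert comp.table.loc["n", "cycles_used"] == 2


def test_acyclic_nodes_undefined_not_zero():
    g = nx.Graph([(1, 2), (2, 3), (1, 3), (3, 4)])  # node 4 dangles
    comp = cycle_composition(census_membership(g, 3), {1: 1, 2: 2, 3: 3, 4: 4}, 3,
                             nodes=[1, 2, 3, 4])
    assert np.isnan(comp.table.loc[4, "alters_mean"])
    assert comp.table.loc[4, "cycles_used"] == 0
    assert 4 not in comp.defined.index


def test_missing_wealth_raises_with_node_name():
    g = nx.complete_graph(3)
    with pytest.raises(KeyError, match="2"):
        cycle_composition(census_membership(g, 3), {0: 1, 1: 2}, 3)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=5_000),
       st.floats(min_value=0.1, max_value=4.0),
       st.floats(min_value=-3.0, max_value=3.0))
def test_affine_equivariance(seed, b, a):
    """alters-mean composition maps w -> a + b*w to a + b*(old value)."""
    g = nx.gnp_random_graph(10, 0.4, seed=seed)
    mem = census_membership(g, 3)
    if not mem:
        return
    rng = np.random.default_rng(seed)
    w = {v: float(rng.integers(1, 6)) for v in g.nodes()}
    w2 = {v: a + b * x for v, x in w.items()}
    c1 = cycle_composition(mem, w, 3).table["alters_mean"].dropna()
    c2 = cycle_composition(mem, w2, 3).table["alters_mean"].dropna()
    assert np.allclose(c2, a + b * c1, rtol=1e-9, atol=1e-7)


def test_assortativity_limit_cases():
    ga = nx.Graph([(1, 2), (3, 4)])
    cls = {1: 2, 2: 2, 3: 4, 4: 4}
    am = assortativity_matrix(ga, cls)
    assert am.off_diagonal_mass() == 0.0
    gb = nx.complete_bipartite_graph(2, 3)
    am2 = assortativity_matrix(gb, {0: 1, 1: 1, 2: 5, 3: 5, 4: 5})
    assert am2.matrix.loc[1, 5] == pytest.approx(1.0)
    assert am2.matrix.equals(am2.matrix.T)
    # unordered-pair shares sum to 1
    m = am2.matrix.to_numpy()
    assert np.triu(m).sum() == pytest.approx(1.0)
    with pytest.raises(ValueError, match="empty"):
        assortativity_matrix(nx.empty_graph(3), {0: 1, 1: 1, 2: 1})


def test_centralities_star_cycle_and_isolates():
    star = nx.star_graph(5)
    c = centralities(star)
    assert c.loc[0].eq(c.max()).all()
    assert c.loc[0, "eigenvector"] == pytest.approx(1.0)
    ring = centralities(nx.cycle_graph(6))
    assert ring["degree"].nunique() == 1
    assert ring["eigenvector"].round(8).nunique() == 1
    assert ring["betweenness"].round(8).nunique() == 1
    g = nx.star_graph(3)
    g.add_node("iso")
    assert centralities(g).loc["iso"].eq(0).all()


def brute_betweenness(g):
    """Exhaustive shortest-path betweenness (normalized), small graphs only."""
    nodes = list(g.nodes())
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for p in paths:
            for v in p[1:-1]:
                score[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: x / norm for v, x in score.items()}


def test_betweenness_matches_exhaustive_oracle():
    g = nx.gnp_random_graph(12, 0.3, seed=6)
    c = centralities(g)
    oracle = brute_betweenness(g)
    for v in g.nodes():
        assert c.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-10)


def test_composition_table_covers_all_k(small_cohort):
    from cyclewealth import build_layers
    vid = small_cohort.village_ids()[0]
    roster = small_cohort.roster(vid, 1)
    g = build_layers(small_cohort.village_ties(vid), roster, 1)["borrow_lend"]
    cen = cycle_census(g, K=4, with_membership=True)
    wealth = dict(zip(roster["person_id"], roster["wealth_class"].astype(float)))
    tab = composition_table(cen, wealth, nodes=list(roster["person_id"]))
    assert set(tab["k"].unique()) == {3, 4}
    assert len(tab) == 2 * len(roster)
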