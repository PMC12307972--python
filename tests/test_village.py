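"""Village summaries, regressions, and the label-permutation null."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cyclewealth import (build_quality_cache, cycle_census, permutation_null_quality,
                         village_regressions, village_summaries)


def triangle_cache(wealth=(1, 2, 3)):
    g = nx.Graph([(0, 1), (1, 2), (0, 2)])
    cen = cycle_census(g, K=3, with_membership=True)
    cache = build_quality_cache(cen, [0, 1, 2])
    return cache, {i: float(w) for i, w in enumerate(wealth)}


def test_single_triangle_mean_quality():
    """Wealth (1,2,3): per-node alters-means 2.5, 2.0, 1.5 -> village mean 2.0."""
    cache, wealth = triangle_cache()
    w = np.array([wealth[v] for v in cache.nodes])
    assert cache.mean_quality(w, 3) == pytest.approx(2.0)


def test_triangle_quality_invariant_under_all_permutations():
    """Relabelling the one triangle never changes mean quality -> degenerate flag."""
    cache, wealth = triangle_cache()
    vals = {cache.mean_quality(np.array(p), 3) for p in itertools.permutations([1.0, 2.0, 3.0])}
    assert vals == {2.0}
    res = permutation_null_quality([("v", cache, wealth)], B=120, seed=0, K=3)
    assert res.per_village.iloc[0]["flag"] == "degenerate"
    assert np.isnan(res.per_village.iloc[0]["z"])


def test_constant_wealth_is_degenerate():
    cache, _ = triangle_cache()
    res = permutation_null_quality([("v", cache, {0: 3, 1: 3, 2: 3})], B=120, seed=0, K=3)
    assert res.per_village.iloc[0]["flag"] == "degenerate"


def test_cached_recomputation_equals_direct(small_cohort):
    from cyclewealth import build_layers, cycle_composition
    vid = small_cohort.village_ids()[0]
    roster = small_cohort.roster(vid, 1)
    g = build_layers(small_cohort.village_ties(vid), roster, 1)["borrow_lend"]
    cen = cycle_census(g, K=4, with_membership=True)
    cache = build_quality_cache(cen, list(roster["person_id"]))
    wealth = dict(zip(roster["person_id"], roster["wealth_class"].astype(float)))
    w = np.array([wealth[v] for v in cache.nodes])
    for k in (3, 4):
        direct = cycle_composition(cen.cycle_membership[k], wealth, k).table["alters_mean"]
        if len(direct.dropna()):
            assert cache.mean_quality(w, k) == pytest.approx(direct.dropna().mean())
        else:
            assert np.isnan(cache.mean_quality(w, k))


def test_village_with_no_cycles_excluded_from_pooling():
    g = nx.path_graph(5)
    cen = cycle_census(g, K=3, with_membership=True)
    cache = build_quality_cache(cen, list(g.nodes()))
    res = permutation_null_quality([("v", cache, {i: i + 1 for i in range(5)})],
                                   B=120, seed=0, K=3)
    assert res.per_village.iloc[0]["flag"] == "no_cycles"
    assert res.pooled.iloc[0]["n_villages"] == 0


def test_pooled_statistic_invariant_to_village_order():
    rng = np.random.default_rng(0)
    entries = []
    for vid in ("a", "b", "c"):
        g = nx.gnp_random_graph(25, 0.2, seed=ord(vid))
        cen = cycle_census(g, K=3, with_membership=True)
        cache = build_quality_cache(cen, list(g.nodes()))
        wealth = {v: float(rng.integers(1, 6)) for v in g.nodes()}
        entries.append((vid, cache, wealth))
    fwd = permutation_null_quality(entries, B=150, seed=4, K=3)
    rev = permutation_null_quality(entries[::-1], B=150, seed=4, K=3)
    assert fwd.pooled["pooled_z"].tolist() == pytest.approx(rev.pooled["pooled_z"].tolist())


def test_permutation_guard():
    cache, wealth = triangle_cache()
    with pytest.raises(ValueError, match="100"):
        permutation_null_quality([("v", cache, wealth)], B=10, seed=0)


def make_summaries(n=20, slope=1.0, seed=0, waves=(1, 2)):
    rng = np.random.default_rng(seed)
    rows = []
    for v in range(n):
        q = rng.normal()
        for wave in waves:
            rows.append(dict(village_id=f"v{v}", wave=wave, size=rng.integers(50, 150),
                             mean_wealth=3 + slope * 0.3 * q + rng.normal(0, 0.3),
                             **{f"mean_quality_{k}": q + rng.normal(0, 0.1) for k in (3, 4, 5)},
                             **{f"cyclic_density_{k}": rng.normal() for k in (3, 4, 5)},
                             **{f"path_density_{k}": rng.normal() for k in (3, 4, 5)},
                             **{f"total_cycles_{k}": rng.integers(0, 50) for k in (3, 4, 5)}))
    return pd.DataFrame(rows)


def test_village_regressions_recover_quality_slope_sign():
    res = village_regressions(make_summaries(slope=1.0, n=40))
    qual = res[res.model == "wealth~quality"]
    assert (qual["coef"] > 0).all()
    assert (qual["p"] < 0.05).all()


def test_village_regressions_reject_single_village():
    one = make_summaries(n=1)
    with pytest.raises(ValueError, match="2 villages"):
        village_regressions(one)


def test_village_summaries_missing_quality_reported_as_nan():
    long = pd.DataFrame({
        "village_id": ["v1"] * 3, "wave": [1] * 3, "person_id": ["a", "b", "c"],
        "wealth_class": [1, 2, 3], "k": [3, 3, 3],
        "cycles": [0, 0, 0], "quality": [np.nan] * 3,
    })
    s = village_summaries(long)
    assert np.isnan(s.loc[0, "mean_quality_3"])
    assert s.loc[0, "size"] == 3
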