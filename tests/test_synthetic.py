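"""Synthetic cohort generator: contracts, determinism, planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cyclewealth import (VillageSpec, assortativity_matrix, build_layers,
                         generate_cohort, generate_village, generate_wave2,
                         tie_overlap_summary)
from cyclewealth.synthetic import read_cohort, write_cohort


def test_spec_validation():
    with pytest.raises(ValueError, match="wealth_class_probs"):
        VillageSpec(wealth_class_probs=(0.5, 0.5, 0.1, 0.0, 0.0))
    with pytest.raises(ValueError, match="overlap_target"):
        VillageSpec(overlap_target=1.5)
    with pytest.raises(ValueError, match="homophily"):
        VillageSpec(homophily_strength=-1)


def test_same_seed_reproduces_byte_identical_tables(tmp_path):
    spec = VillageSpec(n_households=8)
    a = generate_cohort(2, spec, seed=9)
    b = generate_cohort(2, spec, seed=9)
    pa = write_cohort(a, tmp_path / "a")
    pb = write_cohort(b, tmp_path / "b")
    assert pa["ties"].read_bytes() == pb["ties"].read_bytes()
    assert pa["persons"].read_bytes() == pb["persons"].read_bytes()
    back = read_cohort(tmp_path / "a")
    assert len(back.persons) == len(a.persons)


def test_tie_endpoints_in_roster_and_no_household_ties():
    v = generate_village(VillageSpec(seed=5))
    persons = set(v.persons["person_id"])
    assert set(v.ties["ego_id"]) <= persons and set(v.ties["alter_id"]) <= persons
    hh = dict(zip(v.persons["person_id"], v.persons["household_id"]))
    assert all(hh[a] != hh[b] for a, b in zip(v.ties["ego_id"], v.ties["alter_id"]))


def test_wealth_class_frequencies_converge():
    probs = (0.35, 0.25, 0.2, 0.12, 0.08)
    co = generate_cohort(30, VillageSpec(wealth_class_probs=probs), seed=2, two_wave=False)
    hh = co.persons.drop_duplicates("household_id")
    freq = hh["wealth_class"].value_counts(normalize=True).reindex(range(1, 6), fill_value=0)
    assert np.abs(freq.to_numpy() - np.array(probs)).max() < 3 / np.sqrt(len(hh))


def test_extreme_homophily_kills_off_diagonal_mixing():
    spec = VillageSpec(homophily_strength=50.0, seed=3, friendship_mean_degree=6)
    v = generate_village(spec)
    g = build_layers(v.ties, v.persons, 1)["friendship"]
    cls = dict(zip(v.persons["person_id"], v.persons["wealth_class"]))
    am = assortativity_matrix(g, cls)
    assert am.off_diagonal_mass() == pytest.approx(0.0)


def test_random_mixing_matches_margin_product():
    spec = VillageSpec(homophily_strength=0.0, degree_wealth_effect=0.0,
                       n_households=60, friendship_mean_degree=10)
    co = generate_cohort(12, spec, seed=4, two_wave=False)
    counts = np.zeros((5, 5))
    marg = np.zeros(5)
    n_edges = 0
    for vid in co.village_ids():
        roster = co.roster(vid, 1)
        g = build_layers(co.village_ties(vid), roster, 1)["friendship"]
        cls = dict(zip(roster["person_id"], roster["wealth_class"]))
        am = assortativity_matrix(g, cls)
        counts += am.matrix.to_numpy() * am.n_edges
        marg += am.marginals.to_numpy() * am.n_edges
        n_edges += am.n_edges
    assert n_edges >= 10_000
    mix = counts / n_edges
    margins = marg / n_edges
    expected = 2 * np.outer(margins, margins)
    np.fill_diagonal(expected, np.diag(np.outer(margins, margins)))
    tv = np.abs(np.triu(mix) - np.triu(expected)).sum()
    assert tv < 0.05


def test_overlap_target_zero_and_infeasible():
    v = generate_village(VillageSpec(overlap_target=0.0, seed=6))
    layers = build_layers(v.ties, v.persons, 1)
    assert tie_overlap_summary(layers).iloc[0].n_shared == 0
    bad = VillageSpec(friendship_mean_degree=0.2, borrow_lend_mean_degree=6,
                      overlap_target=1.0, seed=1)
    with pytest.raises(ValueError, match="overlap"):
        generate_village(bad)


def test_realized_overlap_near_target():
    co = generate_cohort(40, VillageSpec(overlap_target=0.76), seed=7, two_wave=False)
    graphs = [build_layers(co.village_ties(v), co.roster(v, 1), 1) for v in co.village_ids()]
    pooled = tie_overlap_summary(graphs).iloc[0]
    assert abs(pooled.pct_of_borrow_lend / 100 - 0.76) < 0.02


def test_full_persistence_keeps_wave1_edges():
    spec = VillageSpec(persistence=1.0, seed=8)
    v2 = generate_wave2(generate_village(spec), spec)
    for layer in ("friendship", "borrow_lend"):
        e1 = build_layers(v2.ties, v2.persons[v2.persons.wave == 1], 1)[layer]
        e2 = build_layers(v2.ties, v2.persons[v2.persons.wave == 2], 2)[layer]
        assert set(map(frozenset, e1.edges())) == set(map(frozenset, e2.edges()))


def test_wave2_requires_wave1_and_rejects_rerun():
    spec = VillageSpec(seed=1)
    v = generate_village(spec)
    v2 = generate_wave2(v, spec)
    with pytest.raises(ValueError, match="wave-2"):
        generate_wave2(v2, spec)
    empty = dataclasses.replace(v, persons=v.persons.iloc[0:0])
    with pytest.raises(ValueError, match="wave-1"):
        generate_wave2(empty, spec)


def test_no_planted_effect_means_gain_independent_of_quality():
    """With gain_effect_quality = 0, household gains are uncorrelated with quality."""
    from scipy import stats
    spec = VillageSpec(gain_effect_quality=0.0, move_prob=0.5)
    co = generate_cohort(20, spec, seed=13)
    w1 = co.persons[co.persons.wave == 1].drop_duplicates("household_id")
    w2 = co.persons[co.persons.wave == 2].drop_duplicates("household_id")
    merged = w1.merge(w2, on="household_id", suffixes=("_1", "_2"))
    moved = merged[merged.wealth_class_1 != merged.wealth_class_2]
    gained = (moved.wealth_class_2 > moved.wealth_class_1)
    # up/down should be a fair coin away from the class boundaries
    interior = moved[(moved.wealth_class_1 > 1) & (moved.wealth_class_1 < 5)]
    up = (interior.wealth_class_2 > interior.wealth_class_1).sum()
    p = stats.binomtest(int(up), len(interior), 0.5).pvalue
    assert p > 0.001


def test_truth_records_planted_parameters():
    spec = VillageSpec(gain_effect_quality=1.5)
    co = generate_cohort(1, spec, seed=0)
    assert co.truth["gain_effect_quality"] == 1.5
    assert co.truth["master_seed"] == 0
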