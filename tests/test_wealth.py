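"""MCA wealth index: geometry, invariances, and weighted quintiles."""

import numpy as np
import pandas as pd
import pytest

from cyclewealth import assign_wealth_classes, binarize_items, fit_mca, validate_index


def two_block_assets(n_per=20):
    """Two household groups with perfectly anti-correlated binary assets."""
    rich = pd.DataFrame({"electricity": 1, "radio": 1, "television": 1},
                        index=[f"r{i}" for i in range(n_per)])
    poor = pd.DataFrame({"electricity": 0, "radio": 0, "television": 0},
                        index=[f"p{i}" for i in range(n_per)])
    return pd.concat([rich, poor])


def test_block_structure_separates_groups_exactly():
    model = fit_mca(two_block_assets())
    rich = model.scores[[i for i in model.scores.index if i.startswith("r")]]
    poor = model.scores[[i for i in model.scores.index if i.startswith("p")]]
    assert rich.std() == pytest.approx(0, abs=1e-10)
    assert poor.std() == pytest.approx(0, abs=1e-10)
    assert rich.iloc[0] > poor.iloc[0]  # anchored: electricity=1 is the rich pole


def test_label_permutation_changes_scores_only_up_to_sign():
    rng = np.random.default_rng(0)
    assets = pd.DataFrame({
        "electricity": rng.integers(0, 2, 60),
        "water_source": rng.integers(0, 3, 60),
        "radio": rng.integers(0, 2, 60),
    })
    base = fit_mca(assets).scores
    relabeled = assets.copy()
    relabeled["water_source"] = relabeled["water_source"].map({0: 2, 1: 0, 2: 1})
    other = fit_mca(relabeled).scores
    agree = np.allclose(base, other, atol=1e-9)
    flipped = np.allclose(base, -other, atol=1e-9)
    assert agree or flipped


def test_duplicating_every_household_leaves_model_unchanged():
    assets = two_block_assets(10)
    jitter = assets.copy()
    jitter.iloc[0, 1] = 0  # break perfect blocks a little
    doubled = pd.concat([jitter, jitter.set_index(jitter.index + "_copy")])
    m1, m2 = fit_mca(jitter), fit_mca(doubled)
    assert np.allclose(m1.inertia_shares, m2.inertia_shares)
    assert np.allclose(m1.scores.to_numpy(), m2.scores.to_numpy()[: len(jitter)])


def test_constant_item_dropped_and_all_constant_fails():
    assets = two_block_assets(5)
    assets["windows"] = 1
    with pytest.warns(UserWarning, match="constant"):
        model = fit_mca(assets)
    assert model.dropped_items == ["windows"]
    allconst = pd.DataFrame({"a": [1, 1, 1], "b": [0, 0, 0]})
    with pytest.raises(ValueError, match="constant"):
        with pytest.warns(UserWarning):
            fit_mca(allconst)


def test_inertia_shares_are_a_distribution():
    model = fit_mca(two_block_assets(8))
    assert (model.inertia_shares >= 0).all()
    assert model.inertia_shares.sum() == pytest.approx(1.0)
    assert 0 < model.pct_inertia_dim1 <= 100


def test_quintiles_distinct_unit_households():
    scores = pd.Series(np.arange(10, dtype=float), index=[f"h{i}" for i in range(10)])
    sizes = pd.Series(1, index=scores.index)
    classes, _ = assign_wealth_classes(scores, sizes)
    assert classes[scores.sort_values().index].tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]


def test_large_household_dominates_breakpoints():
    scores = pd.Series([0.0, 1, 2, 3, 4, 5], index=list("abcdef"))
    sizes = pd.Series([100, 1, 1, 1, 1, 1], index=scores.index)
    classes, share = assign_wealth_classes(scores, sizes)
    assert classes["a"] == 1          # the big household fills classes 1-5's breakpoints
    assert (classes[list("bcdef")] == 5).all()


def test_monotone_in_score_and_tie_block_to_lower_class():
    scores = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0], index=list("abcde"))
    sizes = pd.Series(1, index=scores.index)
    classes, _ = assign_wealth_classes(scores, sizes)
    srt = scores.sort_values().index
    assert (classes[srt].diff().dropna() >= 0).all()
    assert classes["a"] == classes["b"] == classes["c"] == 1  # tied block, lower class


def test_person_weighted_quintile_shares():
    rng = np.random.default_rng(3)
    n = 5000
    scores = pd.Series(rng.random(n), index=[f"h{i}" for i in range(n)])
    sizes = pd.Series(1 + rng.poisson(3.0, n), index=scores.index)
    _, share = assign_wealth_classes(scores, sizes)
    assert np.allclose(share, 0.2, atol=0.02)


def test_validate_index_limits_and_guard():
    scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    assert validate_index(scores, scores)["spearman"] == pytest.approx(1.0)
    assert validate_index(scores, -scores)["pearson"] == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="3 overlapping"):
        validate_index(scores, pd.Series([1.0], index=["a"]))


def test_binarize_default_marks_top_categories_high():
    assets = pd.DataFrame({"electricity": [0, 1, 1], "floor_material": [0, 1, 2]})
    b = binarize_items(assets)
    assert b["electricity"].tolist() == [0, 1, 1]
    assert b["floor_material"].tolist() == [0, 0, 1]
    custom = binarize_items(assets, {"floor_material": {1, 2}})
    assert custom["floor_material"].tolist() == [0, 1, 1]
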