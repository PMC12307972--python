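"""Association batteries: arithmetic helpers, BH, invariances, contracts."""

import numpy as np
import pandas as pd
import pytest

from cyclewealth import (ModelSpec, benchmark_with_centrality, bh_adjust,
                         fit_individual_model, odds_multiplier, run_battery,
                         stratified_gain_loss)


def test_odds_multiplier_worked_example():
    """beta=0.1 with 10 extra cycles multiplies the odds by e ~ 2.72."""
    assert round(odds_multiplier(0.1, 10), 2) == 2.72
    assert odds_multiplier(0.0, 100) == 1.0


def direct_step_up(p, alpha=0.05):
    """Reference BH rejection set: largest i with p_(i) <= alpha*i/m."""
    p = np.asarray(p)
    order = np.argsort(p)
    m = len(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    k = passed.max() + 1 if len(passed) else 0
    rejected = np.zeros(m, bool)
    rejected[order[:k]] = True
    return rejected


def test_bh_q_matches_direct_step_up_and_is_monotone():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = np.concatenate([rng.random(15), rng.random(5) * 1e-3])
        rng.shuffle(p)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        # q monotone in p
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        # thresholding q < alpha equals the step-up rejection set
        assert ((q < 0.05) == direct_step_up(p, 0.05)).all()


def test_battery_deterministic_and_has_expected_cells(small_table):
    a = run_battery(small_table, families=("quantity_cross",), K=(3,))
    b = run_battery(small_table, families=("quantity_cross",), K=(3,))
    pd.testing.assert_frame_equal(a, b)
    assert len(a) == 8  # 8 wealth outcomes x one k
    assert set(a["link"]) == {"linear", "logistic"}
    assert a["n_villages"].min() >= 2


def test_longitudinal_specs_control_for_wave1_outcome(small_table):
    spec = ModelSpec(family="quality_long", outcome="wealth_index", k=3)
    from cyclewealth.models import _design
    _, X, _, _, _ = _design(small_table, spec)
    assert "wealth_index_w1" in X.columns


def test_standardization_makes_scale_irrelevant(small_table):
    spec = ModelSpec(family="quality_cross", outcome="wealth_index", k=3)
    base = fit_individual_model(small_table, spec)
    rescaled = small_table.copy()
    rescaled["quality_3_w1"] = rescaled["quality_3_w1"] * 1000 + 7
    again = fit_individual_model(rescaled, spec)
    assert again.coef == pytest.approx(base.coef, rel=1e-6)
    assert again.p == pytest.approx(base.p, rel=1e-4)


def test_duplicate_control_raises_rank_deficiency(small_table):
    spec = ModelSpec(family="quantity_cross", outcome="electricity", k=3,
                     extra_controls=("cycles_3",))
    with pytest.raises(ValueError, match="rank deficient"):
        fit_individual_model(small_table, spec)


def test_benchmark_with_uncorrelated_control_barely_moves_coef(small_table):
    rng = np.random.default_rng(5)
    t = small_table.copy()
    t["noise_ctrl_w1"] = rng.normal(size=len(t))
    base = fit_individual_model(t, ModelSpec("quantity_cross", "wealth_index", 3))
    aug = fit_individual_model(
        t, ModelSpec("quantity_cross", "wealth_index", 3, extra_controls=("noise_ctrl",)))
    assert abs(aug.coef - base.coef) < 2 * base.se


def test_benchmark_report_compares_significance(small_table):
    rng = np.random.default_rng(6)
    t = small_table.copy()
    t["eigenvector_w1"] = rng.random(len(t))
    out = benchmark_with_centrality(t, families=("quantity_cross",), K=(3,),
                                    outcomes=("wealth_index", "electricity"))
    assert {"significant_base", "significant_ctrl", "significance_changed"} <= set(out.columns)
    assert len(out) == 2


def test_stratified_gain_loss_contract(small_table):
    tab = stratified_gain_loss(small_table, metric="quality", K=(3,))
    assert set(tab["stratum"]) == {1, 2, 3, 4, 5}
    # the ceiling stratum uses the non-loss boundary rule
    assert (tab.loc[tab.stratum == 5, "note"] == "gain=non-loss (ceiling)").all()
    small = tab[~tab["estimable"]]
    assert small["p"].isna().all()  # not-estimable strata report NaN, no exception
    with pytest.raises(ValueError, match="metric"):
        stratified_gain_loss(small_table, metric="bogus")


def test_vif_reported(small_table):
    res = fit_individual_model(small_table, ModelSpec("quantity_cross", "wealth_index", 3))
    assert np.isfinite(res.max_vif)
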