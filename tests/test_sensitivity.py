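"""Tornado, threshold, probabilistic sensitivity and structure search."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pancea import (
    CE_CT,
    CE_MR_CT,
    PSASpec,
    StructureFlags,
    default_params,
    one_way,
    run_psa,
    run_strategy,
    structure_search,
    threshold_resectability,
    tornado,
)
from pancea.sensitivity import (
    NoCrossoverError,
    _incremental_nmb,
    nmb_difference_curve,
    set_parameter,
)


def test_degenerate_range_gives_zero_width(params):
    e = one_way(params, "cost_mri", low=615.0, high=615.0)
    assert e.width == 0.0
    assert e.outcome_low == e.outcome_base == e.outcome_high


def test_mri_cost_shifts_incremental_cost_one_for_one(params):
    e = one_way(params, "cost_mri", low=0.0, high=1_230.0)
    # cost_mri enters the CE-MR/CT arm once, undiscounted, so the
    # incremental NMB falls by exactly the cost increase
    assert e.outcome_low - e.outcome_high == pytest.approx(1_230.0)
    for v in (0.0, 1_230.0):
        q = set_parameter(params, "cost_mri", v)
        assert run_strategy(CE_CT, q).total_qaly == pytest.approx(
            run_strategy(CE_CT, params).total_qaly
        )
        assert run_strategy(CE_MR_CT, q).total_qaly == pytest.approx(
            run_strategy(CE_MR_CT, params).total_qaly
        )


def test_out_of_range_base_rejected(params):
    with pytest.raises(ValueError, match="outside"):
        one_way(params, "cost_mri", low=1_000.0, high=2_000.0)
    with pytest.raises(Exception, match="not_a_param"):
        one_way(params, "not_a_param", low=0.0, high=1.0)


def test_tornado_endpoints_bracket_base_for_monotone_parameters(params):
    frame = tornado(params, rel_range=0.25,
                    parameters=["cost_mri", "u_m1_no_surgery", "cost_m1_therapy"])
    for _, row in frame.iterrows():
        lo = min(row["inmb_low"], row["inmb_high"])
        hi = max(row["inmb_low"], row["inmb_high"])
        assert lo - 1e-6 <= row["inmb_base"] <= hi + 1e-6


def test_full_default_tornado_schema(params):
    frame = tornado(params, rel_range=0.10)
    assert {"parameter", "inmb_low", "inmb_high", "icer_low", "width"} <= set(
        frame.columns
    )
    assert (np.diff(frame["width"]) <= 1e-9).all()  # sorted by influence
    assert "p_ct_fp" in set(frame["parameter"])
    assert "p_ct_tp" not in set(frame["parameter"])


def test_threshold_bisection_agrees_with_dense_grid(params):
    crossover = threshold_resectability(params, lo=0.90, hi=1.0, tol=1e-6)
    grid = np.arange(0.97, 1.0, 1e-4)
    diffs = np.array(
        [_incremental_nmb(set_parameter(params, "p_ct_tp", float(p)),
                          params.wtp)[0] for p in grid]
    )
    sign_change = np.nonzero(np.diff(np.sign(diffs)))[0]
    assert len(sign_change) == 1
    bracket = (grid[sign_change[0]], grid[sign_change[0] + 1])
    assert bracket[0] - 1e-6 <= crossover <= bracket[1] + 1e-6


def test_preference_direction_around_crossover(params):
    crossover = threshold_resectability(params)
    below = _incremental_nmb(
        set_parameter(params, "p_ct_tp", crossover - 0.005), params.wtp
    )[0]
    above = _incremental_nmb(
        set_parameter(params, "p_ct_tp", crossover + 0.005), params.wtp
    )[0]
    assert below > 0 > above  # CE-MR/CT preferred below, CE-CT above


def test_perfect_classification_prefers_ct_alone(params):
    d = _incremental_nmb(set_parameter(params, "p_ct_tp", 1.0), params.wtp)[0]
    assert d == pytest.approx(-params.cost_mri)


def test_no_crossover_bracket_reported(params):
    with pytest.raises(NoCrossoverError, match="same sign"):
        threshold_resectability(params, lo=0.85, hi=0.95)


def test_nmb_difference_curve_consistent_with_threshold(params):
    curve = nmb_difference_curve(params, grid=np.array([0.95, 0.99, 1.0]))
    assert curve["nmb_difference"].iloc[0] > 0
    assert curve["nmb_difference"].iloc[-1] < 0


def test_degenerate_psa_reproduces_base_case_exactly(params, base_case):
    results, _ = base_case
    spec = PSASpec(n_iterations=5, seed=9, prob_se_frac=0.0, cost_se_frac=0.0)
    psa = run_psa(params, spec)
    it = psa.iterations
    assert (it["cost_ce_ct"] == results["CE-CT"].total_cost).all()
    assert (it["qaly_ce_mr_ct"] == results["CE-MR/CT"].total_qaly).all()


def test_psa_fixed_seed_bit_reproducible(params):
    spec = PSASpec(n_iterations=200, seed=1234)
    a = run_psa(params, spec)
    b = run_psa(params, spec)
    pd.testing.assert_frame_equal(a.iterations, b.iterations)
    np.testing.assert_array_equal(a.acceptability, b.acceptability)
    c = run_psa(params, PSASpec(n_iterations=200, seed=1235))
    assert not a.iterations.equals(c.iterations)


def test_psa_acceptability_bounds_and_grid(params):
    psa = run_psa(params, PSASpec(n_iterations=300, seed=5))
    assert np.all((psa.acceptability >= 0) & (psa.acceptability <= 1))
    assert np.all(np.diff(psa.wtp_grid) > 0)
    assert psa.acceptability_at(100_000.0) == psa.acceptability[
        list(psa.wtp_grid).index(100_000.0)
    ]


def test_psa_override_with_wrong_mean_rejected(params):
    spec = PSASpec(n_iterations=5, seed=0,
                   overrides={"cost_mri": ("gamma", 2.0, 1.0)})  # mean 2 != 615
    with pytest.raises(ValueError, match="cost_mri"):
        run_psa(params, spec)


def test_psa_fixed_override_accepted(params):
    spec = PSASpec(n_iterations=5, seed=0,
                   overrides={"cost_mri": ("fixed", 615.0)})
    psa = run_psa(params, spec)
    assert len(psa.iterations) == 5


def test_structure_search_recovers_known_configuration():
    known = StructureFlags(
        accrual="end",
        terminal_stage=False,
        utility_set="table1",
        r1_cost_schedule="flat",
        met_cost_schedule="flat",
        surgery_cost_scope="operated",
    )
    p = default_params(structure=known)
    targets = {
        "cost_ce_ct": run_strategy(CE_CT, p).total_cost,
        "qaly_ce_ct": run_strategy(CE_CT, p).total_qaly,
        "cost_ce_mr_ct": run_strategy(CE_MR_CT, p).total_cost,
        "qaly_ce_mr_ct": run_strategy(CE_MR_CT, p).total_qaly,
    }
    result = structure_search(targets=targets)
    assert result.best == known
    assert result.best_error == pytest.approx(0.0, abs=1e-12)


def test_structure_search_reports_all_combinations_ranked():
    result = structure_search(tol=np.inf)
    report = result.report
    assert len(report) == 192
    assert (np.diff(report["max_rel_error"]) >= 0).all()
    assert report["within_tol"].all()  # tol = inf filters nothing
    # published totals are matched well by the selected configuration
    assert result.best_error < 0.01


def test_structure_search_missing_target_key_rejected():
    with pytest.raises(ValueError, match="missing"):
        structure_search(targets={"cost_ce_ct": 1.0})
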