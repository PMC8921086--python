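"""Transition matrices, discounting and cohort accumulation."""

import dataclasses

import numpy as np
import pytest

from pancea import (
    CE_CT,
    CE_MR_CT,
    StructureFlags,
    allocate,
    build_transition_matrix,
    default_params,
    discount_factor,
    perturb_params,
    run_cohort,
    run_strategy,
    with_structure,
)
from pancea.decision_tree import InitialAllocation
from pancea.states import DEAD, N_STATES, NONRES, RES_MET, RES_NED


def _plain_flags(**kw):
    """End-of-cycle accrual without the terminal stage (text-book convention)."""
    return StructureFlags(accrual="end", terminal_stage=False, **kw)


def _point_allocation(state, upfront=0.0):
    probs = np.zeros(N_STATES)
    probs[state] = 1.0
    return InitialAllocation(
        strategy=CE_CT,
        initial_state_probs=probs,
        upfront_cost=upfront,
        upfront_cost_by_state=np.full(N_STATES, upfront),
        operated_fraction=1.0,
    )


def test_nonresectable_row_uses_m1_mortality(params):
    M = build_transition_matrix(params)
    np.testing.assert_allclose(M[NONRES], [0.4926, 0, 0, 0, 0.5074], atol=1e-12)


def test_death_first_composition_for_metastasis_after_resection(params):
    M = build_transition_matrix(params)
    assert M[RES_NED, RES_MET] == pytest.approx((1 - 0.029) * 0.38, abs=1e-12)


@pytest.mark.parametrize("seed", range(30))
def test_rows_stochastic_and_death_absorbing(params, seed):
    q = perturb_params(params, 0.4, seed=seed)
    M = build_transition_matrix(q)
    assert np.all(M >= 0) and np.all(M <= 1)
    np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(M[DEAD], np.eye(N_STATES)[DEAD], atol=0)


def test_annual_r1_split_moves_hazard_into_matrix(params):
    annual = with_structure(
        params, dataclasses.replace(params.structure, r1_split_timing="annual")
    )
    M = build_transition_matrix(annual)
    surv = 1 - 0.029
    assert M[RES_NED, 2] == pytest.approx(surv * (1 - 0.38) * 0.8)
    np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)


def test_age_dependent_mortality_hook(params):
    hazard = lambda age: 0.01 * (age - 69)  # noqa: E731
    M1 = build_transition_matrix(params, cycle=1, m0_hazard=hazard)
    M3 = build_transition_matrix(params, cycle=3, m0_hazard=hazard)
    assert M1[RES_NED, DEAD] == pytest.approx(0.01)
    assert M3[RES_NED, DEAD] == pytest.approx(0.03)


@pytest.mark.parametrize(
    "rate, cycle, expected",
    [(0.03, 0, 1.0), (0.03, 1, 1 / 1.03), (0.0, 7, 1.0)],
)
def test_discount_factor_closed_form(rate, cycle, expected):
    assert discount_factor(rate, cycle) == pytest.approx(expected, abs=1e-9)


def test_all_dead_cohort_accrues_only_upfront_cost(params):
    res = run_cohort(_point_allocation(DEAD, upfront=43_561.0), params)
    assert res.total_qaly == 0.0
    assert res.total_cost == pytest.approx(43_561.0)


def test_undiscounted_single_state_qalys_scale_with_reward_points():
    # an immortal metastatic-after-surgery patient accrues u = 0.6 per year
    immortal = default_params(
        _plain_flags(),
        p_death_m1=0.0,
        p_death_m0=0.0,
        p_surgery_death=0.0,
        discount_rate=0.0,
    )
    res = run_cohort(_point_allocation(RES_MET), immortal)
    assert res.total_qaly == pytest.approx(5 * 0.6, abs=1e-12)

    # the default convention counts the terminal stage as well: 6 points
    inclusive = default_params(
        p_death_m1=0.0, p_death_m0=0.0, p_surgery_death=0.0, discount_rate=0.0
    )
    res6 = run_cohort(_point_allocation(RES_MET), inclusive)
    assert res6.total_qaly == pytest.approx(6 * 0.6, abs=1e-12)


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("strategy", [CE_CT, CE_MR_CT])
def test_occupancy_conservation_and_monotone_death(params, strategy, seed):
    q = perturb_params(params, 0.35, seed=seed)
    res = run_cohort(allocate(strategy, q), q)
    occ = res.trace.occupancy
    np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(np.diff(occ[:, DEAD]) >= -1e-12)


@pytest.mark.parametrize("field", ["p_death_m1", "p_death_m0", "p_surgery_death"])
def test_qalys_weakly_decrease_with_mortality(params, field):
    grid = np.linspace(0.0, 1.0, 6)
    for strategy in (CE_CT, CE_MR_CT):
        qalys = [
            run_strategy(
                strategy, dataclasses.replace(params, **{field: float(v)})
            ).total_qaly
            for v in grid
        ]
        assert np.all(np.diff(qalys) <= 1e-9)


def test_totals_non_increasing_in_discount_rate(params):
    rates = [0.0, 0.01, 0.03, 0.05, 0.10]
    res = [
        run_strategy(CE_CT, dataclasses.replace(params, discount_rate=r))
        for r in rates
    ]
    costs = [r.total_cost for r in res]
    qalys = [r.total_qaly for r in res]
    assert np.all(np.diff(costs) <= 1e-9)
    assert np.all(np.diff(qalys) <= 1e-9)


def test_trace_frame_reconciles_with_totals(params, tmp_path):
    res = run_strategy(CE_MR_CT, params)
    frame = res.trace.to_frame()
    assert frame["cum_cost"].iloc[-1] == pytest.approx(res.total_cost)
    assert frame["cum_qaly"].iloc[-1] == pytest.approx(res.total_qaly)
    assert frame["cycle"].iloc[0] == 0
    path = tmp_path / "trace.csv"
    res.trace.to_csv(path)
    assert path.read_text().startswith("cycle,")


def test_state_entry_reference_matches_global_without_first_year_variants(params):
    # when no reward distinguishes the first year in a state, the two
    # "first year" conventions must coincide exactly
    flat = default_params(
        StructureFlags(
            r1_cost_schedule="flat", met_cost_schedule="flat",
            first_year_reference="global",
        ),
        cost_post_surgery_y1=1_126.0,
        u_m0_post_surgery_y1=0.797,
    )
    entry = with_structure(
        flat, dataclasses.replace(flat.structure, first_year_reference="state_entry")
    )
    for strategy in (CE_CT, CE_MR_CT):
        a = run_strategy(strategy, flat)
        b = run_strategy(strategy, entry)
        assert b.total_cost == pytest.approx(a.total_cost, abs=1e-9)
        assert b.total_qaly == pytest.approx(a.total_qaly, abs=1e-12)


def test_state_entry_reference_repays_first_year_followup_on_recurrence(params):
    entry = with_structure(
        params,
        dataclasses.replace(params.structure, first_year_reference="state_entry"),
    )
    # recurrent metastases enter their own first year, so the follow-up
    # add-on is paid again and total cost strictly exceeds the global case
    assert (
        run_strategy(CE_CT, entry).total_cost
        > run_strategy(CE_CT, params).total_cost
    )
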