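"""Individual-level Monte Carlo simulator mirroring the cohort engine.

Each simulated patient draws a diagnostic/surgical outcome from the
decision tree and then walks the Markov states cycle by cycle, using the
*same* transition matrices, reward schedules, accrual timing and
discounting as :func:`pancea.markov.run_cohort`.  By the law of large
numbers the per-patient means converge to the cohort-model expectations,
so the simulator serves as a brute-force oracle for the deterministic
engine: disagreement beyond Monte Carlo error isolates accumulation or
discounting bugs rather than probability bugs.

It doubles as the stress-test scenario generator for the property suite
(:func:`generate_test_scenarios`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .decision_tree import Strategy, allocate, get_strategy
from .markov import (
    _EXPANDED_TO_PUBLIC,
    _expand_matrix,
    _expand_rewards,
    build_transition_matrix,
    discount_factor,
    reward_schedule,
)
from .parameters import ModelParams, StructureFlags, default_params, with_structure
from .states import DEAD, N_STATES, NONRES

__all__ = ["MicrosimSummary", "simulate_patients", "generate_test_scenarios"]

_TRAJECTORY_SAMPLE = 100


@dataclass(frozen=True)
class MicrosimSummary:
    """Per-patient means with Monte Carlo standard errors."""

    strategy: Strategy
    n: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    trajectory_sample: np.ndarray  # (min(n, 100), horizon + 1) public StateIds


def simulate_patients(
    strategy: Strategy | str,
    params: ModelParams,
    n: int,
    seed: int,
    return_patients: bool = False,
):
    """Simulate ``n`` individual patients under one staging strategy.

    Returns a :class:`MicrosimSummary`; with ``return_patients=True`` a
    tuple ``(summary, costs, qalys)`` including the per-patient discounted
    totals.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    rng = np.random.default_rng(seed)
    flags = params.structure
    expand = flags.first_year_reference == "state_entry"
    alloc = allocate(strategy, params)
    rewards = reward_schedule(params)
    H = params.horizon

    # initial state draw (in the engine's internal state space)
    probs = alloc.initial_state_probs
    if expand:
        init_probs = np.zeros(7)
        init_probs[[0, 1, 2, 4, 6]] = probs[[0, 1, 2, 3, 4]]
        to_public = _EXPANDED_TO_PUBLIC
    else:
        init_probs = probs
        to_public = np.arange(N_STATES)
    states = np.searchsorted(np.cumsum(init_probs), rng.random(n), side="right")
    states = np.minimum(states, len(init_probs) - 1)

    costs = alloc.upfront_cost_by_state[to_public[states]].astype(float).copy()
    qalys = np.zeros(n)
    n_sample = min(n, _TRAJECTORY_SAMPLE)
    trajectories = np.empty((n_sample, H + 1), dtype=np.int8)
    trajectories[:, 0] = to_public[states[:n_sample]]

    def reward_vectors(cycle: int):
        if expand:
            c = _expand_rewards(rewards["cost_first"], rewards["cost_later"], cycle)
            u = _expand_rewards(
                rewards["utility_first"], rewards["utility_later"], cycle
            )
        else:
            c = rewards["cost_first"] if cycle == 1 else rewards["cost_later"]
            u = rewards["utility_first"] if cycle == 1 else rewards["utility_later"]
        return c, u

    for k in range(1, H + 1):
        M = build_transition_matrix(params, cycle=k)
        P = _expand_matrix(M) if expand else M
        cum = np.cumsum(P, axis=1)
        u01 = rng.random(n)
        # vectorized categorical draw: count how many cumulative bounds lie
        # below each uniform variate
        nxt = (u01[:, None] > cum[states]).sum(axis=1)
        nxt = np.minimum(nxt, P.shape[0] - 1)

        c_vec, u_vec = reward_vectors(k)
        if flags.half_cycle_correction:
            c_k = 0.5 * (c_vec[states] + c_vec[nxt])
            u_k = 0.5 * (u_vec[states] + u_vec[nxt])
        elif flags.accrual == "begin":
            c_k, u_k = c_vec[states], u_vec[states]
        else:
            c_k, u_k = c_vec[nxt], u_vec[nxt]
        d = discount_factor(params.discount_rate, k)
        costs += c_k * d
        qalys += u_k * d
        states = nxt
        trajectories[:, k] = to_public[states[:n_sample]]

    if flags.terminal_stage and flags.accrual == "begin" and not flags.half_cycle_correction:
        c_vec, u_vec = reward_vectors(H + 1)
        d = discount_factor(params.discount_rate, H + 1)
        costs += c_vec[states] * d
        qalys += u_vec[states] * d

    ddof = 1 if n > 1 else 0
    summary = MicrosimSummary(
        strategy=strategy,
        n=n,
        mean_cost=float(costs.mean()),
        mean_qaly=float(qalys.mean()),
        se_cost=float(costs.std(ddof=ddof) / np.sqrt(n)),
        se_qaly=float(qalys.std(ddof=ddof) / np.sqrt(n)),
        trajectory_sample=trajectories,
    )
    if return_patients:
        return summary, costs, qalys
    return summary


# ---------------------------------------------------------------------------
# stress-test scenario generation
# ---------------------------------------------------------------------------

_EDGE_OVERRIDES = (
    {"p_ct_fp": 0.0, "p_ct_tp": 1.0},
    {"p_death_m1": 1.0},
    {"discount_rate": 0.0},
    {"p_surgery_death": 0.0},
    {"p_met_after_resection": 1.0},
    {"p_r1": 1.0},
    {"cost_m1_therapy": 0.0},
    {"p_death_m0": 0.0},
)

_EDGE_STRUCTURES = (
    StructureFlags(),
    StructureFlags(accrual="end", terminal_stage=False),
    StructureFlags(half_cycle_correction=True, terminal_stage=False),
    StructureFlags(first_year_reference="state_entry"),
    StructureFlags(r1_split_timing="annual"),
)


def generate_test_scenarios(n_scenarios: int, seed: int) -> list[ModelParams]:
    """Valid, seeded random parameter sets spanning edge regions.

    The first scenarios pin stipulated corners (no false positives,
    certain metastatic mortality, zero discounting, ...), and structural
    configurations rotate across scenarios so the cohort-vs-microsim
    comparison exercises every accrual convention.
    """
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be >= 1")
    from .parameters import perturb_params

    scenarios = []
    for i in range(n_scenarios):
        child_seed = int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        )
        p = perturb_params(default_params(), relative_width=0.3, seed=child_seed)
        p = with_structure(p, _EDGE_STRUCTURES[i % len(_EDGE_STRUCTURES)])
        if i < len(_EDGE_OVERRIDES):
            p = replace(p, **_EDGE_OVERRIDES[i])
        scenarios.append(p.validate())
    return scenarios
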