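"""Five-state annual-cycle Markov cohort engine.

The cohort is propagated through the states ``{NONRES, RES_NED, RES_LOC,
RES_MET, DEAD}`` with a row-stochastic transition matrix built from the
annual probabilities in :class:`~pancea.parameters.ModelParams`.  Competing
risks are composed death-first: the annual death probability is applied
first and the non-death transitions act on survivors, which keeps rows
stochastic for any valid parameter set (including perturbed ones in the
sensitivity analyses).

Reward accrual follows the structural flags: cycle-k rewards use the state
distribution at the start of the cycle (``accrual="begin"``), at the end
(``"end"``), or their average (half-cycle correction), discounted by
``1/(1+r)^k``.  With ``terminal_stage`` on (begin accrual), stage counting
is inclusive of the terminal stage, so an H-year horizon carries H+1 reward
points.  One-time decision-tree costs enter undiscounted at cycle 0.

When ``first_year_reference="state_entry"`` the engine expands the two
states with first-year reward variants reachable after cycle 0 (RES_LOC and
RES_MET) into internal one-cycle tunnel states, and collapses them again in
the reported trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .decision_tree import InitialAllocation, Strategy, allocate, get_strategy
from .parameters import ModelParams
from .states import DEAD, N_STATES, NONRES, RES_LOC, RES_MET, RES_NED, STATE_NAMES

__all__ = [
    "build_transition_matrix",
    "discount_factor",
    "reward_schedule",
    "run_cohort",
    "run_strategy",
    "CohortTrace",
    "StrategyResult",
]

# expanded internal state order used for time-since-entry rewards:
# NONRES, RES_NED, RES_LOC (first cycle), RES_LOC, RES_MET (first cycle),
# RES_MET, DEAD
_EXPANDED_TO_PUBLIC = np.array([0, 1, 2, 2, 3, 3, 4])
_N_EXPANDED = 7


def discount_factor(rate: float, cycle: int) -> float:
    """Present-value factor ``1/(1+rate)^cycle``."""
    if rate < 0 or cycle < 0:
        raise ValueError("rate and cycle must be non-negative")
    return 1.0 / (1.0 + rate) ** cycle


def build_transition_matrix(
    params: ModelParams,
    cycle: int = 1,
    m0_hazard: Callable[[float], float] | None = None,
) -> np.ndarray:
    """Per-cycle 5x5 transition matrix (death-first composition).

    ``m0_hazard`` is an optional hook replacing the constant metastasis-free
    death probability with an age-dependent one, evaluated at
    ``start_age + cycle - 1``; it defaults to off (the constant annual
    probability stands in for the life table).
    """
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    p_m0 = params.p_death_m0
    if m0_hazard is not None:
        p_m0 = float(m0_hazard(params.start_age + cycle - 1))
    p_m1 = params.p_death_m1
    p_met = params.p_met_after_resection
    p_r1_death = (
        params.p_death_m0
        if params.structure.r1_mortality == "m0"
        else float(params.structure.r1_mortality)
    )
    if m0_hazard is not None and params.structure.r1_mortality == "m0":
        p_r1_death = p_m0

    M = np.zeros((N_STATES, N_STATES))
    M[NONRES, DEAD] = p_m1
    M[NONRES, NONRES] = 1.0 - p_m1
    M[RES_MET, DEAD] = p_m1
    M[RES_MET, RES_MET] = 1.0 - p_m1

    surv = 1.0 - p_m0
    M[RES_NED, DEAD] = p_m0
    M[RES_NED, RES_MET] = surv * p_met
    if params.structure.r1_split_timing == "annual":
        M[RES_NED, RES_LOC] = surv * (1.0 - p_met) * params.p_r1
        M[RES_NED, RES_NED] = surv * (1.0 - p_met) * (1.0 - params.p_r1)
    else:
        M[RES_NED, RES_NED] = surv * (1.0 - p_met)

    surv_r1 = 1.0 - p_r1_death
    M[RES_LOC, DEAD] = p_r1_death
    M[RES_LOC, RES_MET] = surv_r1 * p_met
    M[RES_LOC, RES_LOC] = surv_r1 * (1.0 - p_met)

    M[DEAD, DEAD] = 1.0

    rowsum = M.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-12):
        raise RuntimeError(f"transition rows sum to {rowsum}, expected 1")
    return M


def reward_schedule(params: ModelParams) -> dict[str, np.ndarray]:
    """Per-state annual cost and utility, first-year and later variants.

    The R1/local-recurrence state has no published utility; it reuses the
    active M0 post-surgery pair (it describes patients without metastases).
    Its cost and the resected-metastatic cost depend on the structural cost
    schedule flags.
    """
    s = params.structure
    c_first = np.zeros(N_STATES)
    c_later = np.zeros(N_STATES)
    u_first = np.zeros(N_STATES)
    u_later = np.zeros(N_STATES)

    c_first[NONRES] = c_later[NONRES] = params.cost_m1_therapy
    u_first[NONRES] = u_later[NONRES] = params.u_m1_no_surgery

    c_first[RES_NED] = params.cost_post_surgery_y1
    c_later[RES_NED] = params.cost_post_surgery_later
    u_first[RES_NED] = params.u_m0_post_surgery_y1
    u_later[RES_NED] = params.u_m0_post_surgery_later

    if s.r1_cost_schedule == "flat":
        c_first[RES_LOC] = c_later[RES_LOC] = params.cost_local_recurrence
    elif s.r1_cost_schedule == "first_year_replaced":
        c_first[RES_LOC] = params.cost_post_surgery_y1
        c_later[RES_LOC] = params.cost_local_recurrence
    else:  # plus_followup
        c_first[RES_LOC] = params.cost_local_recurrence + params.cost_post_surgery_y1
        c_later[RES_LOC] = params.cost_local_recurrence + params.cost_post_surgery_later
    u_first[RES_LOC] = params.u_m0_post_surgery_y1
    u_later[RES_LOC] = params.u_m0_post_surgery_later

    c_first[RES_MET] = c_later[RES_MET] = params.cost_m1_after_surgery
    if s.met_cost_schedule == "plus_followup":
        c_first[RES_MET] += params.cost_post_surgery_y1
        c_later[RES_MET] += params.cost_post_surgery_later
    u_first[RES_MET] = u_later[RES_MET] = params.u_m1_post_surgery

    # DEAD stays at 0 cost / 0 utility (u_dead is validated to 0)
    return {
        "cost_first": c_first,
        "cost_later": c_later,
        "utility_first": u_first,
        "utility_later": u_later,
    }


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle record of one cohort run.

    ``occupancy`` rows are the true state distribution at cycle starts
    0..H; ``accrual_cycles`` lists the discounting cycle of every reward
    accrual with the membership vector it used and the discounted cost and
    QALY increments it produced.
    """

    occupancy: np.ndarray          # (H+1, 5)
    accrual_cycles: np.ndarray     # (K,)
    accrual_occupancy: np.ndarray  # (K, 5)
    disc_cost: np.ndarray          # (K,)
    disc_qaly: np.ndarray          # (K,)
    upfront_cost: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cycle": 0,
                **dict(zip(STATE_NAMES, self.occupancy[0])),
                "disc_cost": self.upfront_cost,
                "disc_qaly": 0.0,
            }
        ]
        for i, k in enumerate(self.accrual_cycles):
            rows.append(
                {
                    "cycle": int(k),
                    **dict(zip(STATE_NAMES, self.accrual_occupancy[i])),
                    "disc_cost": self.disc_cost[i],
                    "disc_qaly": self.disc_qaly[i],
                }
            )
        frame = pd.DataFrame(rows)
        frame["cum_cost"] = frame["disc_cost"].cumsum()
        frame["cum_qaly"] = frame["disc_qaly"].cumsum()
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class StrategyResult:
    """Discounted totals of one staging strategy."""

    strategy: Strategy
    total_cost: float
    total_qaly: float
    trace: CohortTrace

    def nmb(self, wtp: float) -> float:
        return wtp * self.total_qaly - self.total_cost


def _expand_matrix(M: np.ndarray) -> np.ndarray:
    """Lift a 5-state matrix to the 7-state tunnel space."""
    P = np.zeros((_N_EXPANDED, _N_EXPANDED))
    P[0, 0] = M[NONRES, NONRES]
    P[0, 6] = M[NONRES, DEAD]
    P[1, 1] = M[RES_NED, RES_NED]
    P[1, 2] = M[RES_NED, RES_LOC]   # new entrants -> first-cycle tunnel
    P[1, 4] = M[RES_NED, RES_MET]
    P[1, 6] = M[RES_NED, DEAD]
    for src in (2, 3):  # RES_LOC tunnel and steady state
        P[src, 3] = M[RES_LOC, RES_LOC]
        P[src, 4] = M[RES_LOC, RES_MET]
        P[src, 6] = M[RES_LOC, DEAD]
    for src in (4, 5):  # RES_MET tunnel and steady state
        P[src, 5] = M[RES_MET, RES_MET]
        P[src, 6] = M[RES_MET, DEAD]
    P[6, 6] = 1.0
    return P


def _expand_rewards(first: np.ndarray, later: np.ndarray, cycle: int) -> np.ndarray:
    """Reward vector over the tunnel space for one accrual cycle."""
    v = np.empty(_N_EXPANDED)
    v[0] = first[NONRES] if cycle == 1 else later[NONRES]
    v[1] = first[RES_NED] if cycle == 1 else later[RES_NED]  # entered at cycle 0
    v[2] = first[RES_LOC]
    v[3] = later[RES_LOC]
    v[4] = first[RES_MET]
    v[5] = later[RES_MET]
    v[6] = 0.0
    return v


def run_cohort(
    alloc: InitialAllocation,
    params: ModelParams,
    m0_hazard: Callable[[float], float] | None = None,
) -> StrategyResult:
    """Propagate the cohort over the horizon and accumulate discounted rewards."""
    H = params.horizon
    if H < 1:
        raise ValueError(f"horizon must be >= 1, got {H}")
    flags = params.structure
    expand = flags.first_year_reference == "state_entry"
    rewards = reward_schedule(params)

    if expand:
        x = np.zeros(_N_EXPANDED)
        probs = alloc.initial_state_probs
        x[0] = probs[NONRES]
        x[1] = probs[RES_NED]
        x[2] = probs[RES_LOC]   # initial occupants are in their first year
        x[4] = probs[RES_MET]
        x[6] = probs[DEAD]
        collapse = np.zeros((_N_EXPANDED, N_STATES))
        collapse[np.arange(_N_EXPANDED), _EXPANDED_TO_PUBLIC] = 1.0
    else:
        x = alloc.initial_state_probs.astype(float).copy()
        collapse = np.eye(N_STATES)

    occupancy = [x @ collapse]
    accrual_cycles: list[int] = []
    accrual_occ: list[np.ndarray] = []
    disc_cost: list[float] = []
    disc_qaly: list[float] = []

    def accrue(cycle: int, membership: np.ndarray) -> None:
        if expand:
            c = _expand_rewards(rewards["cost_first"], rewards["cost_later"], cycle)
            u = _expand_rewards(
                rewards["utility_first"], rewards["utility_later"], cycle
            )
        else:
            c = rewards["cost_first"] if cycle == 1 else rewards["cost_later"]
            u = rewards["utility_first"] if cycle == 1 else rewards["utility_later"]
        d = discount_factor(params.discount_rate, cycle)
        accrual_cycles.append(cycle)
        accrual_occ.append(membership @ collapse)
        disc_cost.append(float(membership @ c) * d)
        disc_qaly.append(float(membership @ u) * d)

    for k in range(1, H + 1):
        M = build_transition_matrix(params, cycle=k, m0_hazard=m0_hazard)
        P = _expand_matrix(M) if expand else M
        x_next = x @ P
        if flags.half_cycle_correction:
            accrue(k, 0.5 * (x + x_next))
        elif flags.accrual == "begin":
            accrue(k, x)
        else:
            accrue(k, x_next)
        x = x_next
        occupancy.append(x @ collapse)

    if flags.terminal_stage and flags.accrual == "begin" and not flags.half_cycle_correction:
        accrue(H + 1, x)

    trace = CohortTrace(
        occupancy=np.array(occupancy),
        accrual_cycles=np.array(accrual_cycles),
        accrual_occupancy=np.array(accrual_occ),
        disc_cost=np.array(disc_cost),
        disc_qaly=np.array(disc_qaly),
        upfront_cost=alloc.upfront_cost,
    )
    return StrategyResult(
        strategy=alloc.strategy,
        total_cost=alloc.upfront_cost + float(np.sum(disc_cost)),
        total_qaly=float(np.sum(disc_qaly)),
        trace=trace,
    )


def run_strategy(
    strategy: Strategy | str,
    params: ModelParams,
    m0_hazard: Callable[[float], float] | None = None,
) -> StrategyResult:
    """Decision tree + cohort run for one strategy."""
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    return run_cohort(allocate(strategy, params), params, m0_hazard=m0_hazard)
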