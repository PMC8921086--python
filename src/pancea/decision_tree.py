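"""Diagnostic decision tree mapping a staging strategy to the Markov start.

The modelled cohort is the set of patients whom contrast-enhanced CT
classifies as resectable.  Under CE-CT alone every one of them is operated;
the false-positive fraction carries occult metastases and is resected
futilely.  Under the combined CE-MR/CT strategy the added liver MRI
reclassifies false positives to non-resectable (with probability
``p_mri_detect``), sparing them surgery.  Perioperative mortality applies
once, at model entry, to operated patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParams
from .states import DEAD, N_STATES, NONRES, RES_LOC, RES_MET, RES_NED

__all__ = ["Strategy", "CE_CT", "CE_MR_CT", "STRATEGIES", "get_strategy",
           "InitialAllocation", "allocate"]


@dataclass(frozen=True)
class Strategy:
    """One of the two staging strategies under comparison."""

    name: str
    uses_mri: bool


CE_CT = Strategy("CE-CT", uses_mri=False)
CE_MR_CT = Strategy("CE-MR/CT", uses_mri=True)
STRATEGIES = (CE_CT, CE_MR_CT)


def get_strategy(name: str) -> Strategy:
    for s in STRATEGIES:
        if s.name == name:
            return s
    raise ValueError(
        f"unknown strategy {name!r}; expected one of "
        f"{[s.name for s in STRATEGIES]}"
    )


@dataclass(frozen=True)
class InitialAllocation:
    """Cycle-0 state distribution and expected one-time cost per patient.

    ``upfront_cost_by_state`` carries the one-time cost conditional on the
    initial state (it differs between operated and non-operated patients
    when ``surgery_cost_scope = "operated"``); ``upfront_cost`` is its
    expectation under ``initial_state_probs``.
    """

    strategy: Strategy
    initial_state_probs: np.ndarray
    upfront_cost: float
    upfront_cost_by_state: np.ndarray
    operated_fraction: float

    def __post_init__(self):
        p = np.asarray(self.initial_state_probs, dtype=float)
        if p.shape != (N_STATES,) or np.any(p < -1e-15):
            raise ValueError("initial_state_probs must be 5 non-negative values")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"initial_state_probs sum to {p.sum()!r}, expected 1")


def allocate(strategy: Strategy, params: ModelParams) -> InitialAllocation:
    """Resolve the decision tree for one strategy.

    Returns the initial Markov state distribution over
    ``{NONRES, RES_NED, RES_LOC, RES_MET, DEAD}`` and the expected one-time
    diagnostic/surgical cost.
    """
    if strategy not in STRATEGIES:
        strategy = get_strategy(getattr(strategy, "name", str(strategy)))

    diag_cost = params.cost_ct + (params.cost_mri if strategy.uses_mri else 0.0)
    reclassified = params.p_ct_fp * params.p_mri_detect if strategy.uses_mri else 0.0
    operated = 1.0 - reclassified
    residual_fp = params.p_ct_fp - reclassified

    perioperative_dead = operated * params.p_surgery_death
    survivors_m0 = params.p_ct_tp * (1.0 - params.p_surgery_death)
    survivors_met = residual_fp * (1.0 - params.p_surgery_death)

    probs = np.zeros(N_STATES)
    probs[NONRES] = reclassified
    if params.structure.r1_split_timing == "at_entry":
        probs[RES_NED] = survivors_m0 * (1.0 - params.p_r1)
        probs[RES_LOC] = survivors_m0 * params.p_r1
    else:  # annual hazard handled inside the transition matrix
        probs[RES_NED] = survivors_m0
    probs[RES_MET] = survivors_met
    probs[DEAD] = perioperative_dead

    upfront_by_state = np.full(N_STATES, diag_cost + params.cost_surgery)
    if params.structure.surgery_cost_scope == "operated":
        upfront_by_state[NONRES] = diag_cost
    upfront = float(probs @ upfront_by_state)

    return InitialAllocation(
        strategy=strategy,
        initial_state_probs=probs,
        upfront_cost=upfront,
        upfront_cost_by_state=upfront_by_state,
        operated_fraction=operated,
    )
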