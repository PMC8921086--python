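"""Cost-effectiveness metrics: ICER, net monetary benefit, dominance.

The decision rule throughout the package is net monetary benefit,
``NMB = WTP x QALY - cost``: in the dominant quadrant (cheaper *and* more
effective) the ICER is negative and its magnitude carries no decision
information, whereas NMB orders strategies unambiguously at a given
willingness-to-pay.  The ICER is still reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .decision_tree import CE_CT, CE_MR_CT
from .markov import StrategyResult, run_strategy
from .parameters import ModelParams

__all__ = ["CEAComparison", "compute_nmb", "compare", "run_base_case"]


def compute_nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit ``wtp * total_qaly - total_cost``."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * result.total_qaly - result.total_cost


@dataclass(frozen=True)
class CEAComparison:
    """Incremental comparison of strategy ``a`` against comparator ``b``.

    ``icer`` is ``None`` when the QALY difference is zero.  ``dominance``
    classifies ``a``: *dominant* (cheaper, more effective), *dominated*
    (costlier, less effective) or *tradeoff*.
    """

    a_name: str
    b_name: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    nmb_by_strategy: dict[str, float]
    dominance: str
    wtp: float

    @property
    def preferred(self) -> str:
        """Strategy with the higher NMB at this willingness-to-pay."""
        return max(self.nmb_by_strategy, key=self.nmb_by_strategy.get)

    def to_dict(self) -> dict:
        return {
            "comparison": f"{self.a_name} vs {self.b_name}",
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "nmb": dict(self.nmb_by_strategy),
            "dominance": self.dominance,
            "preferred": self.preferred,
            "wtp": self.wtp,
        }


def compare(a: StrategyResult, b: StrategyResult, wtp: float) -> CEAComparison:
    """Incremental cost-effectiveness of ``a`` relative to ``b``."""
    delta_cost = a.total_cost - b.total_cost
    delta_qaly = a.total_qaly - b.total_qaly
    icer = delta_cost / delta_qaly if delta_qaly != 0.0 else None
    if delta_cost < 0 and delta_qaly > 0:
        dominance = "dominant"
    elif delta_cost > 0 and delta_qaly < 0:
        dominance = "dominated"
    else:
        dominance = "tradeoff"
    return CEAComparison(
        a_name=a.strategy.name,
        b_name=b.strategy.name,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        nmb_by_strategy={
            a.strategy.name: compute_nmb(a, wtp),
            b.strategy.name: compute_nmb(b, wtp),
        },
        dominance=dominance,
        wtp=wtp,
    )


def run_base_case(params: ModelParams, wtp: float | None = None):
    """Run both staging strategies and compare them.

    Returns ``(results, comparison)`` where ``results`` maps strategy name
    to :class:`StrategyResult` and the comparison is CE-MR/CT vs CE-CT at
    ``wtp`` (default: the parameter set's willingness-to-pay).
    """
    wtp = params.wtp if wtp is None else wtp
    res_ct = run_strategy(CE_CT, params)
    res_mr = run_strategy(CE_MR_CT, params)
    comparison = compare(res_mr, res_ct, wtp)
    return {CE_CT.name: res_ct, CE_MR_CT.name: res_mr}, comparison
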