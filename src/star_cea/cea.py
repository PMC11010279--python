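"""Cost-effectiveness summaries: incremental outcomes, iNMB, ICER, dominance.

Conventions: deltas are intervention minus comparator; positive incremental
net monetary benefit (iNMB = lambda * dQ - dC) favours the intervention.  The
ICER dC/dQ is reported only on the trade-off quadrants of the cost-
effectiveness plane (NE: more effective and more costly; SW: less effective
and less costly); when one strategy strictly dominates, the ICER is
meaningless and left undefined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .markov_engine import ArmResult

__all__ = ["Dominance", "CEResult", "compare_arms", "budget_impact"]


class Dominance(enum.Enum):
    INTERVENTION_DOMINANT = "intervention_dominant"  # more QALYs, lower cost
    COMPARATOR_DOMINANT = "comparator_dominant"      # fewer QALYs, higher cost
    TRADE_OFF_NE = "trade_off_NE"                    # more QALYs, higher cost
    TRADE_OFF_SW = "trade_off_SW"                    # fewer QALYs, lower cost


@dataclass(frozen=True)
class CEResult:
    delta_qalys: float
    delta_costs: float
    threshold: float
    inmb: float
    dominance: Dominance
    icer: float | None  # None when dominance holds or dQ == 0 (flagged, not infinite)
    icer_undefined_zero_dq: bool = False

    def as_dict(self) -> dict:
        return {
            "delta_qalys": self.delta_qalys,
            "delta_costs": self.delta_costs,
            "threshold": self.threshold,
            "inmb": self.inmb,
            "dominance": self.dominance.value,
            "icer": self.icer,
        }


def compare_arms(
    intervention: ArmResult, comparator: ArmResult, threshold: float
) -> CEResult:
    """Compare two arm results at a willingness-to-pay threshold (GBP/QALY)."""
    dq = intervention.total_qalys - comparator.total_qalys
    dc = intervention.total_costs - comparator.total_costs
    inmb = threshold * dq - dc

    if dq > 0 and dc < 0:
        dominance = Dominance.INTERVENTION_DOMINANT
    elif dq < 0 and dc > 0:
        dominance = Dominance.COMPARATOR_DOMINANT
    elif dc >= 0:
        dominance = Dominance.TRADE_OFF_NE
    else:
        dominance = Dominance.TRADE_OFF_SW

    icer = None
    zero_dq = False
    if dominance in (Dominance.TRADE_OFF_NE, Dominance.TRADE_OFF_SW):
        if dq == 0:
            zero_dq = True
        else:
            icer = dc / dq
    return CEResult(
        delta_qalys=dq,
        delta_costs=dc,
        threshold=threshold,
        inmb=inmb,
        dominance=dominance,
        icer=icer,
        icer_undefined_zero_dq=zero_dq,
    )


def budget_impact(
    annual_surgeries: float, cp_rate: float, per_patient_saving: float
) -> float:
    """National budget impact: surgeries/year x chronic-pain rate x per-patient saving."""
    if annual_surgeries < 0 or per_patient_saving < 0:
        raise ValueError("inputs must be non-negative")
    if not (0.0 <= cp_rate <= 1.0):
        raise ValueError("cp_rate must be a fraction in [0, 1]")
    return annual_surgeries * cp_rate * per_patient_saving
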