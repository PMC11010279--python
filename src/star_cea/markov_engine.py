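"""Two-state cohort Markov engine.

The cohort starts from an initial state distribution and is pushed through one
transition matrix per annual cycle.  Payoffs (a QALY weight and an annual cost
per state) are attributed by END-of-cycle state membership, with no half-cycle
correction; this is the convention under which the published totals are
reproduced from the published inputs.  Discounting starts in the second year:
the factor for cycle t is (1 + r)^-(t-1), so year 1 is undiscounted.  A one-off
cost (the intervention delivery cost) is charged undiscounted in cycle 1.

There is no death state: the horizon is short and the intervention is assumed
not to affect mortality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import STATES, PainState, ParameterSet

__all__ = ["CohortTrace", "ArmResult", "run_trace", "accrue", "run_arm"]

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class CohortTrace:
    """End-of-cycle state membership fractions, shape (horizon, 2), (CP, NCP)."""

    membership: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.membership, dtype=float)
        object.__setattr__(self, "membership", m)
        if m.ndim != 2 or m.shape[1] != 2:
            raise ValueError(f"membership must be (horizon, 2), got {m.shape}")
        if not np.allclose(m.sum(axis=1), 1.0, atol=_MASS_TOL):
            raise ValueError("cohort mass not conserved: a cycle's fractions do not sum to 1")

    @property
    def horizon(self) -> int:
        return self.membership.shape[0]

    def fraction(self, year: int, state: PainState) -> float:
        return float(self.membership[year - 1, state.index])


@dataclass(frozen=True)
class ArmResult:
    """Discounted and undiscounted per-cycle QALYs and costs for one arm."""

    per_cycle_qalys: np.ndarray
    per_cycle_costs: np.ndarray
    per_cycle_qalys_undiscounted: np.ndarray
    per_cycle_costs_undiscounted: np.ndarray

    @property
    def total_qalys(self) -> float:
        return float(self.per_cycle_qalys.sum())

    @property
    def total_costs(self) -> float:
        return float(self.per_cycle_costs.sum())

    @property
    def total_qalys_undiscounted(self) -> float:
        return float(self.per_cycle_qalys_undiscounted.sum())

    @property
    def total_costs_undiscounted(self) -> float:
        return float(self.per_cycle_costs_undiscounted.sum())


def run_trace(
    initial_distribution: np.ndarray | dict[PainState, float],
    matrices: np.ndarray | dict[int, "object"],
    horizon: int,
) -> CohortTrace:
    """Propagate the cohort through ``horizon`` annual cycles.

    ``matrices`` may be an array of shape (horizon, 2, 2) or a mapping
    year -> TransitionMatrix covering years 1..horizon.  Membership at the end
    of cycle t is membership(t-1) left-multiplied by the matrix of year t.
    """
    if isinstance(initial_distribution, dict):
        init = np.array([initial_distribution[s] for s in STATES], dtype=float)
    else:
        init = np.asarray(initial_distribution, dtype=float)
    if init.shape != (2,) or not np.isclose(init.sum(), 1.0, atol=_MASS_TOL):
        raise ValueError("initial distribution must be two fractions summing to 1")

    if isinstance(matrices, dict):
        try:
            stack = np.stack([np.asarray(matrices[y].p if hasattr(matrices[y], "p") else matrices[y], dtype=float) for y in range(1, horizon + 1)])
        except KeyError as exc:
            raise ValueError(f"missing transition matrix for year {exc}") from exc
    else:
        stack = np.asarray(matrices, dtype=float)
    if stack.shape != (horizon, 2, 2):
        raise ValueError(f"need one 2x2 matrix per year 1..{horizon}, got shape {stack.shape}")

    membership = np.empty((horizon, 2))
    m = init
    for t in range(horizon):
        m = m @ stack[t]
        membership[t] = m
    return CohortTrace(membership)


def accrue(
    trace: CohortTrace,
    qaly_payoffs: np.ndarray,
    cost_payoffs: np.ndarray,
    discount_rate: float,
    oneoff_year1_cost: float = 0.0,
) -> ArmResult:
    """Accrue discounted QALYs and costs along a cohort trace.

    ``qaly_payoffs`` and ``cost_payoffs`` have shape (horizon, 2) ordered
    (CP, NCP); costs are the summed annual state costs.  The one-off cost is
    added to cycle 1 at full (undiscounted) value regardless of membership.
    """
    q = np.asarray(qaly_payoffs, dtype=float)
    c = np.asarray(cost_payoffs, dtype=float)
    h = trace.horizon
    if q.shape != (h, 2) or c.shape != (h, 2):
        raise ValueError("payoff arrays must cover every year and state of the trace")

    qalys_und = (trace.membership * q).sum(axis=1)
    costs_und = (trace.membership * c).sum(axis=1)
    costs_und = costs_und.copy()
    costs_und[0] += oneoff_year1_cost

    # Year 1 undiscounted; year t divided by (1 + r)^(t-1).
    factors = (1.0 + discount_rate) ** (-np.arange(h, dtype=float))
    return ArmResult(
        per_cycle_qalys=qalys_und * factors,
        per_cycle_costs=costs_und * factors,
        per_cycle_qalys_undiscounted=qalys_und,
        per_cycle_costs_undiscounted=costs_und,
    )


def run_arm(params: ParameterSet, arm: str) -> ArmResult:
    """Run one arm of a ParameterSet end to end (trace + accrual)."""
    trace = run_trace(params.initial_array(), params.transition_array(arm), params.horizon)
    return accrue(
        trace,
        params.qaly_array(arm),
        params.cost_array(arm),
        params.discount_rate,
        oneoff_year1_cost=params.oneoff_cost(arm),
    )
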