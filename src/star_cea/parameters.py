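"""Model inputs for the two-state chronic-pain cost-utility model.

The decision problem compares two post-operative strategies after total knee
replacement — a structured pain-management care pathway ("star") delivered
during the first year, versus usual postoperative care ("usual_care") — for
patients who enter with chronic pain (CP), defined by an Oxford Knee Score
pain subscale (OKS-PS, 0–28) of 14 or less.  The model is a cohort Markov
simulation with two health states (CP / NCP), annual cycles, a five-year
horizon, and time-dependent transition probabilities.

This module defines the input bundle (:class:`ParameterSet`), its validation,
(de)serialisation to YAML/JSON, and the built-in base-case fixture holding the
published point estimates.
"""

from __future__ import annotations

import copy
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "PainState",
    "STATES",
    "OKS_PS_MAX",
    "CP_THRESHOLD",
    "CostComponents",
    "StateYearPayoff",
    "TransitionMatrix",
    "ParameterSet",
    "builtin_star_parameters",
    "load_parameters",
    "serialize_parameters",
    "save_parameters",
    "validate",
    "ValidationError",
]

#: Upper end of the OKS pain-subscale score range.
OKS_PS_MAX = 28
#: Scores at or below this are classified as chronic pain.
CP_THRESHOLD = 14

ARM_INTERVENTION = "star"
ARM_COMPARATOR = "usual_care"

_ROW_TOL = 1e-9


class PainState(enum.Enum):
    """Health state: chronic pain (CP) or no chronic pain (NCP)."""

    CP = "CP"
    NCP = "NCP"

    @property
    def index(self) -> int:
        return 0 if self is PainState.CP else 1


STATES: tuple[PainState, PainState] = (PainState.CP, PainState.NCP)


class ValidationError(ValueError):
    """Raised when a parameter document or bundle violates the schema."""


@dataclass(frozen=True)
class CostComponents:
    """Annual per-state healthcare costs in GBP (2019–2020 prices)."""

    prescriptions: float = 0.0
    consultations: float = 0.0
    hospital_admissions: float = 0.0

    @property
    def total(self) -> float:
        return self.prescriptions + self.consultations + self.hospital_admissions

    def violations(self, where: str) -> list[str]:
        out = []
        for name in ("prescriptions", "consultations", "hospital_admissions"):
            if getattr(self, name) < 0:
                out.append(f"{where}.{name}: cost component must be >= 0")
        return out


@dataclass(frozen=True)
class StateYearPayoff:
    """Per-cycle payoff for one state: a QALY weight and annual costs."""

    qaly: float
    costs: CostComponents

    def violations(self, where: str) -> list[str]:
        out = []
        if not (0.0 <= self.qaly <= 1.0):
            out.append(f"{where}.qaly: value {self.qaly} outside [0, 1]")
        out.extend(self.costs.violations(f"{where}.costs"))
        return out


class TransitionMatrix:
    """A 2x2 row-stochastic matrix indexed (from-state, to-state)."""

    __slots__ = ("p",)

    def __init__(self, p: Iterable[Iterable[float]]):
        arr = np.asarray(p, dtype=float)
        if arr.shape != (2, 2):
            raise ValidationError(f"transition matrix must be 2x2, got {arr.shape}")
        self.p = arr

    def __getitem__(self, key: tuple[PainState, PainState]) -> float:
        frm, to = key
        return float(self.p[frm.index, to.index])

    def __eq__(self, other) -> bool:
        return isinstance(other, TransitionMatrix) and np.array_equal(self.p, other.p)

    def __repr__(self) -> str:
        return f"TransitionMatrix({self.p.tolist()})"

    def violations(self, where: str) -> list[str]:
        out = []
        if ((self.p < 0) | (self.p > 1)).any():
            out.append(f"{where}: entries outside [0, 1]")
        for i, state in enumerate(STATES):
            s = self.p[i].sum()
            if not math.isclose(s, 1.0, abs_tol=_ROW_TOL):
                out.append(f"{where}[{state.value}]: row sums to {s}, expected 1")
        return out


@dataclass
class ParameterSet:
    """Complete input bundle for a two-arm cohort Markov run.

    ``arms`` orders the strategies as (intervention, comparator).  Schedules
    are keyed arm -> cycle year (1-based) -> value.  ``intervention_oneoff_cost``
    is the cost of delivering the care pathway, charged once, undiscounted, in
    cycle 1 of the intervention arm.  ``extra_arm_year1_cost`` is a documented
    calibration knob (default 0) for an additional year-1 intervention-arm cost
    that the published point estimates imply but do not itemise; see
    docs/methods.md.
    """

    arms: tuple[str, str] = (ARM_INTERVENTION, ARM_COMPARATOR)
    transition_schedule: dict[str, dict[int, TransitionMatrix]] = field(default_factory=dict)
    payoff_schedule: dict[str, dict[int, dict[PainState, StateYearPayoff]]] = field(default_factory=dict)
    intervention_oneoff_cost: float = 0.0
    extra_arm_year1_cost: float = 0.0
    discount_rate: float = 0.035
    horizon: int = 5
    initial_distribution: dict[PainState, float] = field(
        default_factory=lambda: {PainState.CP: 1.0, PainState.NCP: 0.0}
    )
    wtp_threshold: float = 20000.0

    # -- array views used by the engine -------------------------------------

    @property
    def intervention_arm(self) -> str:
        return self.arms[0]

    @property
    def comparator_arm(self) -> str:
        return self.arms[1]

    def years(self) -> range:
        return range(1, self.horizon + 1)

    def transition_array(self, arm: str) -> np.ndarray:
        """Transition matrices for ``arm`` stacked as (horizon, 2, 2)."""
        return np.stack([self.transition_schedule[arm][y].p for y in self.years()])

    def qaly_array(self, arm: str) -> np.ndarray:
        """QALY weights for ``arm`` as (horizon, 2) ordered (CP, NCP)."""
        return np.array(
            [[self.payoff_schedule[arm][y][s].qaly for s in STATES] for y in self.years()]
        )

    def cost_array(self, arm: str) -> np.ndarray:
        """Total annual state costs for ``arm`` as (horizon, 2)."""
        return np.array(
            [[self.payoff_schedule[arm][y][s].costs.total for s in STATES] for y in self.years()]
        )

    def initial_array(self) -> np.ndarray:
        return np.array([self.initial_distribution[s] for s in STATES])

    def oneoff_cost(self, arm: str) -> float:
        if arm == self.intervention_arm:
            return self.intervention_oneoff_cost + self.extra_arm_year1_cost
        return 0.0

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return serialize_parameters(self) == serialize_parameters(other)


# ---------------------------------------------------------------------------
# Built-in base-case fixture
# ---------------------------------------------------------------------------

# Published point estimates, stored exactly as printed (3 dp probabilities and
# utilities, whole pounds).  Year-1 intervention effects: the care pathway arm
# has a lower CP->CP probability, its own year-1 QALY anchors and hospital
# costs, and the one-off delivery cost.  Years 2-5 dynamics are common to both
# arms (cohort-derived), reflecting the assumption that the intervention acts
# only while active.
#
# The year-1 NCP row is structurally empty (the whole cohort enters in CP); it
# is stored as the identity row (0, 1) so that every row is a valid stochastic
# row without affecting results.

_UC_CP_STAY = (0.494, 0.368, 0.388, 0.400, 0.406)
_STAR_CP_STAY = (0.355, 0.368, 0.388, 0.400, 0.406)
_NCP_TO_CP = (0.000, 0.050, 0.042, 0.031, 0.037)

_UC_QALY_CP = (0.465, 0.556, 0.607, 0.642, 0.698)
_UC_QALY_NCP = (0.539, 0.730, 0.727, 0.716, 0.702)
_STAR_QALY_CP = (0.484, 0.572, 0.621, 0.654, 0.708)
_STAR_QALY_NCP = (0.560, 0.742, 0.739, 0.728, 0.714)

_PRESC_CP = (100, 88, 91, 91, 91)
_PRESC_NCP = (22, 18, 17, 17, 18)
_CONSULT_CP = (166, 143, 137, 137, 125)
_CONSULT_NCP = (62, 51, 48, 46, 48)
_UC_HOSP_CP = (2972, 898, 464, 65, 24)
_UC_HOSP_NCP = (1057, 386, 331, 82, 249)
_STAR_HOSP_CP = (1265, 898, 464, 65, 24)
_STAR_HOSP_NCP = (1302, 386, 331, 82, 249)

INTERVENTION_ONEOFF_COST = 191.0

# Scenario inputs (see star_cea.scenarios).
POOLED_QALY_CP = (0.477, 0.566, 0.616, 0.650, 0.704)
POOLED_QALY_NCP = (0.555, 0.739, 0.736, 0.725, 0.711)
S2_UC_CP_STAY_Y1 = 0.500
S2_STAR_CP_STAY_Y1 = 0.357
S2_STAR_NCP_TO_CP_Y1 = 0.222
S3_HOSP_CP_Y1 = 1935.0
S3_HOSP_NCP_Y1 = 1237.0


def _schedules() -> tuple[dict, dict]:
    transitions: dict[str, dict[int, TransitionMatrix]] = {}
    payoffs: dict[str, dict[int, dict[PainState, StateYearPayoff]]] = {}
    per_arm = {
        ARM_INTERVENTION: (_STAR_CP_STAY, _STAR_QALY_CP, _STAR_QALY_NCP, _STAR_HOSP_CP, _STAR_HOSP_NCP),
        ARM_COMPARATOR: (_UC_CP_STAY, _UC_QALY_CP, _UC_QALY_NCP, _UC_HOSP_CP, _UC_HOSP_NCP),
    }
    for arm, (cp_stay, q_cp, q_ncp, h_cp, h_ncp) in per_arm.items():
        transitions[arm] = {}
        payoffs[arm] = {}
        for i, year in enumerate(range(1, 6)):
            ncp_to_cp = _NCP_TO_CP[i]
            transitions[arm][year] = TransitionMatrix(
                [[cp_stay[i], 1.0 - cp_stay[i]], [ncp_to_cp, 1.0 - ncp_to_cp]]
            )
            payoffs[arm][year] = {
                PainState.CP: StateYearPayoff(
                    qaly=q_cp[i],
                    costs=CostComponents(_PRESC_CP[i], _CONSULT_CP[i], h_cp[i]),
                ),
                PainState.NCP: StateYearPayoff(
                    qaly=q_ncp[i],
                    costs=CostComponents(_PRESC_NCP[i], _CONSULT_NCP[i], h_ncp[i]),
                ),
            }
    return transitions, payoffs


def builtin_star_parameters() -> ParameterSet:
    """Return the built-in base-case parameter bundle (published point estimates)."""
    transitions, payoffs = _schedules()
    return ParameterSet(
        arms=(ARM_INTERVENTION, ARM_COMPARATOR),
        transition_schedule=transitions,
        payoff_schedule=payoffs,
        intervention_oneoff_cost=INTERVENTION_ONEOFF_COST,
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

_SETTING_DEFAULTS = {
    "intervention_oneoff_cost": 0.0,
    "extra_arm_year1_cost": 0.0,
    "discount_rate": 0.035,
    "horizon": 5,
    "wtp_threshold": 20000.0,
}


def serialize_parameters(params: ParameterSet) -> dict:
    """Render a ParameterSet as a plain nested dict (YAML/JSON friendly)."""
    doc: dict = {
        "arms": {"intervention": params.arms[0], "comparator": params.arms[1]},
        "settings": {
            "intervention_oneoff_cost": float(params.intervention_oneoff_cost),
            "extra_arm_year1_cost": float(params.extra_arm_year1_cost),
            "discount_rate": float(params.discount_rate),
            "horizon": int(params.horizon),
            "wtp_threshold": float(params.wtp_threshold),
            "initial_distribution": {
                s.value: float(params.initial_distribution[s]) for s in STATES
            },
        },
        "transitions": {},
        "payoffs": {},
    }
    for arm in params.arms:
        doc["transitions"][arm] = {
            year: {
                f"{frm.value}->{to.value}": float(params.transition_schedule[arm][year][frm, to])
                for frm in STATES
                for to in STATES
            }
            for year in params.years()
        }
        doc["payoffs"][arm] = {
            year: {
                s.value: {
                    "qaly": float(params.payoff_schedule[arm][year][s].qaly),
                    "costs": {
                        "prescriptions": float(params.payoff_schedule[arm][year][s].costs.prescriptions),
                        "consultations": float(params.payoff_schedule[arm][year][s].costs.consultations),
                        "hospital_admissions": float(params.payoff_schedule[arm][year][s].costs.hospital_admissions),
                    },
                }
                for s in STATES
            }
            for year in params.years()
        }
    return doc


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    doc = serialize_parameters(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def _require(doc: Mapping, key: str, where: str):
    if key not in doc:
        raise ValidationError(f"missing required field: {where}{key}")
    return doc[key]


def load_parameters(source: str | Path | Mapping) -> ParameterSet:
    """Build a validated ParameterSet from a YAML/JSON document or dict.

    Missing optional settings fall back to the documented defaults (3.5%
    discount rate, 5-year horizon, £20,000 willingness-to-pay threshold,
    100% CP initial distribution, zero extra costs).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        doc = yaml.safe_load(text)
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise ValidationError("parameter document must be a mapping")

    arms_doc = _require(doc, "arms", "")
    arms = (str(_require(arms_doc, "intervention", "arms.")),
            str(_require(arms_doc, "comparator", "arms.")))
    settings = dict(doc.get("settings", {}))
    merged = {**_SETTING_DEFAULTS, **{k: v for k, v in settings.items() if k != "initial_distribution"}}
    horizon = int(merged["horizon"])
    init_doc = settings.get("initial_distribution", {"CP": 1.0, "NCP": 0.0})
    try:
        initial = {s: float(init_doc[s.value]) for s in STATES}
    except KeyError as exc:
        raise ValidationError(f"settings.initial_distribution: missing state {exc}") from exc

    transitions_doc = _require(doc, "transitions", "")
    payoffs_doc = _require(doc, "payoffs", "")
    transition_schedule: dict[str, dict[int, TransitionMatrix]] = {}
    payoff_schedule: dict[str, dict[int, dict[PainState, StateYearPayoff]]] = {}
    for arm in arms:
        if arm not in transitions_doc:
            raise ValidationError(f"missing required field: transitions.{arm}")
        if arm not in payoffs_doc:
            raise ValidationError(f"missing required field: payoffs.{arm}")
        transition_schedule[arm] = {}
        payoff_schedule[arm] = {}
        for year in range(1, horizon + 1):
            tdoc = transitions_doc[arm]
            ydoc = tdoc.get(year, tdoc.get(str(year)))
            if ydoc is None:
                raise ValidationError(f"missing required field: transitions.{arm}.{year}")
            p = [[0.0, 0.0], [0.0, 0.0]]
            for frm in STATES:
                for to in STATES:
                    key = f"{frm.value}->{to.value}"
                    p[frm.index][to.index] = float(
                        _require(ydoc, key, f"transitions.{arm}.{year}.")
                    )
            tm = TransitionMatrix(p)
            bad = tm.violations(f"transitions.{arm}.{year}")
            if bad:
                raise ValidationError("; ".join(bad))
            transition_schedule[arm][year] = tm

            pdoc_all = payoffs_doc[arm]
            pdoc = pdoc_all.get(year, pdoc_all.get(str(year)))
            if pdoc is None:
                raise ValidationError(f"missing required field: payoffs.{arm}.{year}")
            payoff_schedule[arm][year] = {}
            for s in STATES:
                sdoc = _require(pdoc, s.value, f"payoffs.{arm}.{year}.")
                cdoc = _require(sdoc, "costs", f"payoffs.{arm}.{year}.{s.value}.")
                payoff_schedule[arm][year][s] = StateYearPayoff(
                    qaly=float(_require(sdoc, "qaly", f"payoffs.{arm}.{year}.{s.value}.")),
                    costs=CostComponents(
                        prescriptions=float(cdoc.get("prescriptions", 0.0)),
                        consultations=float(cdoc.get("consultations", 0.0)),
                        hospital_admissions=float(cdoc.get("hospital_admissions", 0.0)),
                    ),
                )

    params = ParameterSet(
        arms=arms,
        transition_schedule=transition_schedule,
        payoff_schedule=payoff_schedule,
        intervention_oneoff_cost=float(merged["intervention_oneoff_cost"]),
        extra_arm_year1_cost=float(merged["extra_arm_year1_cost"]),
        discount_rate=float(merged["discount_rate"]),
        horizon=horizon,
        initial_distribution=initial,
        wtp_threshold=float(merged["wtp_threshold"]),
    )
    bad = validate(params)
    if bad:
        raise ValidationError("; ".join(bad))
    return params


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(params: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty when the bundle is valid)."""
    out: list[str] = []
    if len(params.arms) != 2 or params.arms[0] == params.arms[1]:
        out.append("arms: exactly two distinct arm identifiers required")
    if params.horizon < 1:
        out.append(f"horizon: {params.horizon} must be >= 1")
    if params.discount_rate < 0:
        out.append(f"discount_rate: {params.discount_rate} must be >= 0")
    if params.intervention_oneoff_cost < 0:
        out.append("intervention_oneoff_cost: must be >= 0")
    if params.wtp_threshold < 0:
        out.append("wtp_threshold: must be >= 0")

    init = params.initial_distribution
    total = sum(init.get(s, 0.0) for s in STATES)
    if not math.isclose(total, 1.0, abs_tol=_ROW_TOL):
        out.append(f"initial_distribution: sums to {total}, expected 1")
    for s in STATES:
        if not (0.0 <= init.get(s, 0.0) <= 1.0):
            out.append(f"initial_distribution[{s.value}]: outside [0, 1]")

    for arm in params.arms:
        for year in params.years():
            tm = params.transition_schedule.get(arm, {}).get(year)
            if tm is None:
                out.append(f"transitions.{arm}.{year}: missing")
            else:
                out.extend(tm.violations(f"transitions.{arm}.{year}"))
            ydoc = params.payoff_schedule.get(arm, {}).get(year)
            if ydoc is None:
                out.append(f"payoffs.{arm}.{year}: missing")
                continue
            for s in STATES:
                payoff = ydoc.get(s)
                if payoff is None:
                    out.append(f"payoffs.{arm}.{year}.{s.value}: missing")
                else:
                    out.extend(payoff.violations(f"payoffs.{arm}.{year}.{s.value}"))
    return out
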