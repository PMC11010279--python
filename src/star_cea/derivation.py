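"""Parameter-derivation procedures.

These operations turn longitudinal patient-level panels into the model's
inputs:

* chronic-pain classification from the OKS pain subscale (score <= 14 -> CP);
* first-order transition-probability estimation between two assessment times;
* per-patient QALYs over year 1 by the trapezoidal area-under-the-curve
  method on utilities at baseline, 6 and 12 months;
* covariate adjustment of group mean QALYs for baseline utility (pooled-slope
  linear model, groups evaluated at the pooled mean baseline);
* projection of utilities beyond year 1 by the percentage-of-potential-change
  (PoPC) method, anchoring levels at the trial estimate and taking yearly
  change from a reference cohort;
* projection of costs beyond year 1 by annual percentage changes observed in
  a reference cohort.

PoPC detail: an observed cohort improvement is expressed as a fraction of the
potential improvement (distance to the scale maximum) and applied to the
anchor's own remaining headroom; an observed deterioration is expressed as a
fraction of the potential decline (distance to the scale minimum), which for a
zero minimum reduces to proportional change.  This signed, direction-aware
rule reproduces the published projected utility rows, including the declining
years, from their anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .parameters import (
    CP_THRESHOLD,
    OKS_PS_MAX,
    STATES,
    PainState,
    TransitionMatrix,
)

__all__ = [
    "classify_pain",
    "TransitionEstimate",
    "estimate_transition_matrix",
    "auc_qaly",
    "adjust_qalys_for_baseline",
    "popc_step",
    "popc_project",
    "pct_change_project",
    "derive_parameter_set",
]

log = logging.getLogger(__name__)


def classify_pain(oks_ps: int, threshold: int = CP_THRESHOLD) -> PainState:
    """Classify an OKS pain-subscale score (0–28) into CP (<= threshold) or NCP."""
    score = int(oks_ps)
    if score != oks_ps or not (0 <= score <= OKS_PS_MAX):
        raise ValueError(f"OKS-PS score must be an integer in [0, {OKS_PS_MAX}], got {oks_ps!r}")
    return PainState.CP if score <= threshold else PainState.NCP


@dataclass(frozen=True)
class TransitionEstimate:
    """A transition matrix with its underlying counts and exclusion tally."""

    matrix: TransitionMatrix
    counts: np.ndarray  # (2, 2) integer counts (from-state, to-state)
    n_excluded: int     # patients lacking a paired observation


def estimate_transition_matrix(
    panel: pd.DataFrame,
    from_time: float,
    to_time: float,
    arm: str | None = None,
    fill_empty: Mapping[PainState, Sequence[float]] | None = None,
) -> TransitionEstimate:
    """Estimate a 2x2 transition matrix from paired panel observations.

    Entry (i, j) is the fraction of patients observed in state i at
    ``from_time`` (months) who are in state j at ``to_time``.  Patients missing
    either observation are excluded (available-case) and counted in
    ``n_excluded``.  An origin state with an empty risk set raises, unless
    ``fill_empty`` supplies a structural row for it (e.g. the identity row for
    a state no patient occupies at model entry).
    """
    df = panel
    if arm is not None:
        df = df[df["arm"] == arm]
    at_from = df[df["time_months"] == from_time].dropna(subset=["oks_ps"]).set_index("patient_id")
    at_to = df[df["time_months"] == to_time].dropna(subset=["oks_ps"]).set_index("patient_id")
    paired = at_from.index.intersection(at_to.index)
    n_excluded = len(at_from.index.union(at_to.index)) - len(paired)
    if n_excluded:
        log.info(
            "transition %s -> %s months: excluded %d patients without paired observations",
            from_time, to_time, n_excluded,
        )

    s_from = at_from.loc[paired, "oks_ps"].map(classify_pain)
    s_to = at_to.loc[paired, "oks_ps"].map(classify_pain)
    counts = np.zeros((2, 2), dtype=int)
    for a, b in zip(s_from, s_to):
        counts[a.index, b.index] += 1

    p = np.empty((2, 2))
    for s in STATES:
        row_n = counts[s.index].sum()
        if row_n == 0:
            if fill_empty is not None and s in fill_empty:
                p[s.index] = np.asarray(fill_empty[s], dtype=float)
                continue
            raise ValueError(
                f"empty risk set: no patients observed in state {s.value} at t={from_time} months"
            )
        p[s.index] = counts[s.index] / row_n
    return TransitionEstimate(matrix=TransitionMatrix(p), counts=counts, n_excluded=n_excluded)


def auc_qaly(u0: float, u6: float, u12: float) -> float:
    """QALYs over one year from utilities at 0, 6 and 12 months (trapezoid rule)."""
    for u in (u0, u6, u12):
        if u > 1.0:
            raise ValueError(f"utility {u} exceeds the scale maximum of 1")
    return 0.25 * (u0 + u6) + 0.25 * (u6 + u12)


def adjust_qalys_for_baseline(
    per_patient: pd.DataFrame | Iterable[tuple[float, float, object]],
) -> dict:
    """Group mean QALYs adjusted for baseline utility.

    Fits QALY ~ group indicators + baseline utility (single pooled slope) by
    ordinary least squares and returns each group's predicted mean at the
    pooled mean baseline utility.  Requires >= 2 groups, >= 2 patients per
    group, and non-constant baseline utility.
    """
    if isinstance(per_patient, pd.DataFrame):
        df = per_patient[["qaly", "baseline", "group"]].copy()
    else:
        df = pd.DataFrame(per_patient, columns=["qaly", "baseline", "group"])
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups for covariate adjustment")
    if (df.groupby("group").size() < 2).any():
        raise ValueError("need at least two patients per group")
    if np.isclose(df["baseline"].var(ddof=0), 0.0):
        raise ValueError("baseline utility is constant; design matrix is singular")

    dummies = pd.get_dummies(df["group"], dtype=float)
    X = pd.concat([dummies, df["baseline"]], axis=1)  # cell-means coding, no intercept
    fit = sm.OLS(df["qaly"].to_numpy(), X.to_numpy()).fit()
    pooled_baseline = df["baseline"].mean()
    slope = fit.params[-1]
    return {
        g: float(fit.params[i] + slope * pooled_baseline)
        for i, g in enumerate(dummies.columns)
    }


def popc_step(
    current: float,
    cohort_from: float,
    cohort_to: float,
    scale_max: float = 1.0,
    scale_min: float = 0.0,
) -> float:
    """Advance ``current`` one step by the cohort's percentage of potential change.

    Improvement: popc = (to - from) / (scale_max - from), applied to the
    current value's remaining headroom.  Deterioration: the decline is scaled
    by the potential decline (from - scale_min) and applied to the current
    value's own distance above the minimum.
    """
    if current > scale_max:
        raise ValueError(f"current value {current} exceeds scale maximum {scale_max}")
    if cohort_to >= cohort_from:
        denom = scale_max - cohort_from
        if denom <= 0:
            raise ValueError("cohort value at the scale maximum: potential change undefined")
        popc = (cohort_to - cohort_from) / denom
        return current + popc * (scale_max - current)
    denom = cohort_from - scale_min
    if denom <= 0:
        raise ValueError("cohort value at the scale minimum: potential decline undefined")
    popc = (cohort_to - cohort_from) / denom  # negative
    return current + popc * (current - scale_min)


def popc_project(
    anchor: float,
    cohort_series: Sequence[float],
    scale_max: float = 1.0,
    scale_min: float = 0.0,
) -> list[float]:
    """Iterate :func:`popc_step` along a cohort series, starting from ``anchor``.

    The output has the same length as the cohort series; element 0 is the
    anchor itself (the trial level for year 1), and element t applies the
    cohort's year t -> t+1 change.
    """
    series = list(cohort_series)
    if len(series) < 2:
        raise ValueError("cohort series must contain at least two values")
    out = [float(anchor)]
    for frm, to in zip(series[:-1], series[1:]):
        out.append(popc_step(out[-1], frm, to, scale_max=scale_max, scale_min=scale_min))
    return out


def pct_change_project(anchor: float, cohort_costs: Sequence[float]) -> list[float]:
    """Project yearly costs from an anchor by the cohort's annual percentage changes.

    Equivalent to scaling the whole cohort series so that its first value
    equals the anchor: out[t] = anchor * cohort[t] / cohort[0].
    """
    series = [float(c) for c in cohort_costs]
    if any(c == 0 for c in series):
        raise ValueError("cohort cost of zero: relative change undefined")
    out = [float(anchor)]
    for frm, to in zip(series[:-1], series[1:]):
        out.append(out[-1] * (1.0 + (to - frm) / frm))
    return out


# ---------------------------------------------------------------------------
# Full derivation pipeline: panels -> ParameterSet
# ---------------------------------------------------------------------------

_COST_COLS = {
    "prescriptions": "cost_prescriptions",
    "consultations": "cost_consultations",
    "hospital_admissions": "cost_hospital",
}

_IDENTITY_NCP_ROW = {PainState.NCP: (0.0, 1.0)}


def _trial_groups(trial: pd.DataFrame) -> pd.DataFrame:
    """Wide per-patient trial table with year-1 state, utilities and costs."""
    wide = trial.pivot_table(index=["patient_id", "arm"], columns="time_months",
                             values="utility", aggfunc="first")
    missing = [t for t in (0, 6, 12) if t not in wide.columns]
    if missing:
        raise ValueError(f"trial panel lacks utility observations at months {missing}")
    wide = wide.rename(columns={0: "u0", 6: "u6", 12: "u12"})[["u0", "u6", "u12"]]
    end = trial[trial["time_months"] == 12].set_index(["patient_id", "arm"])
    wide["state12"] = end["oks_ps"].map(lambda s: classify_pain(s).value)
    for comp, col in _COST_COLS.items():
        wide[comp] = end[col] if col in end.columns else np.nan
    return wide.reset_index()


def derive_parameter_set(
    trial_panel: pd.DataFrame,
    cohort_panel: pd.DataFrame,
    arms: tuple[str, str] = ("star", "usual_care"),
    intervention_oneoff_cost: float = 191.0,
    horizon: int = 5,
    **settings,
):
    """Assemble a full ParameterSet from a trial-like and a cohort-like panel.

    Year-1 transition probabilities come from the trial per arm (baseline ->
    12 months); later years come from consecutive yearly cohort assessments
    and are shared by both arms.  Year-1 QALY anchors are baseline-adjusted
    AUC means per arm and 12-month state, projected forward by PoPC along the
    cohort's yearly state-mean utilities.  Year-1 costs come from the trial
    (hospital admissions per arm, prescriptions and consultations pooled
    across arms) and are projected by the cohort's annual percentage changes
    from pooled anchors.
    """
    from .parameters import CostComponents, ParameterSet, StateYearPayoff, validate

    cohort_times = [12 * t for t in range(1, horizon + 1)]

    # --- transitions -------------------------------------------------------
    transition_schedule: dict[str, dict[int, TransitionMatrix]] = {a: {} for a in arms}
    for arm in arms:
        est = estimate_transition_matrix(trial_panel, 0, 12, arm=arm,
                                         fill_empty=_IDENTITY_NCP_ROW)
        transition_schedule[arm][1] = est.matrix
    for year in range(2, horizon + 1):
        est = estimate_transition_matrix(cohort_panel, cohort_times[year - 2], cohort_times[year - 1])
        for arm in arms:
            transition_schedule[arm][year] = est.matrix

    # --- year-1 QALY anchors ------------------------------------------------
    wide = _trial_groups(trial_panel).dropna(subset=["u0", "u6", "u12"])
    wide["qaly"] = [auc_qaly(a, b, c) for a, b, c in zip(wide["u0"], wide["u6"], wide["u12"])]
    wide["group"] = list(zip(wide["arm"], wide["state12"]))
    adjusted = adjust_qalys_for_baseline(
        wide.rename(columns={"u0": "baseline"})[["qaly", "baseline", "group"]]
    )

    # --- cohort series ------------------------------------------------------
    coh = cohort_panel.copy()
    coh["state"] = coh["oks_ps"].map(lambda s: classify_pain(s).value)
    util_series = {
        s: [coh[(coh["time_months"] == t) & (coh["state"] == s.value)]["utility"].mean()
            for t in cohort_times]
        for s in STATES
    }
    cost_series = {
        s: {comp: [coh[(coh["time_months"] == t) & (coh["state"] == s.value)][col].mean()
                   for t in cohort_times]
            for comp, col in _COST_COLS.items()}
        for s in STATES
    }

    # --- anchors for costs --------------------------------------------------
    pooled_cost_anchor = {
        s: {comp: wide[wide["state12"] == s.value][comp].mean() for comp in _COST_COLS}
        for s in STATES
    }
    hosp_anchor_by_arm = {
        arm: {
            s: wide[(wide["arm"] == arm) & (wide["state12"] == s.value)]["hospital_admissions"].mean()
            for s in STATES
        }
        for arm in arms
    }

    # --- assemble payoffs ---------------------------------------------------
    payoff_schedule: dict[str, dict[int, dict[PainState, StateYearPayoff]]] = {a: {} for a in arms}
    for arm in arms:
        for s in STATES:
            anchor = min(max(adjusted[(arm, s.value)], 0.0), 1.0)
            qalys = popc_project(anchor, util_series[s])
            presc = pct_change_project(pooled_cost_anchor[s]["prescriptions"],
                                       cost_series[s]["prescriptions"])
            consult = pct_change_project(pooled_cost_anchor[s]["consultations"],
                                         cost_series[s]["consultations"])
            # hospital: per-arm anchor in year 1, pooled anchor drives years 2+
            hosp = pct_change_project(pooled_cost_anchor[s]["hospital_admissions"],
                                      cost_series[s]["hospital_admissions"])
            hosp[0] = hosp_anchor_by_arm[arm][s]
            for year in range(1, horizon + 1):
                payoff_schedule[arm].setdefault(year, {})[s] = StateYearPayoff(
                    qaly=min(max(qalys[year - 1], 0.0), 1.0),
                    costs=CostComponents(
                        prescriptions=max(presc[year - 1], 0.0),
                        consultations=max(consult[year - 1], 0.0),
                        hospital_admissions=max(hosp[year - 1], 0.0),
                    ),
                )

    params = ParameterSet(
        arms=arms,
        transition_schedule=transition_schedule,
        payoff_schedule=payoff_schedule,
        intervention_oneoff_cost=intervention_oneoff_cost,
        horizon=horizon,
        **settings,
    )
    problems = validate(params)
    if problems:
        raise ValueError("derived parameter set is invalid: " + "; ".join(problems))
    return params
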