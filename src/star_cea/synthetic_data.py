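"""Synthetic patient-level panels for the derivation pipeline.

The real data sources behind the model (a randomised trial with 12-month
follow-up, a five-year observational cohort, and a primary-care database
extract) are access-restricted.  This module generates panels with the same
statistical structure the derivation stages assume, so every stage is
testable end to end:

* pain states evolve first (first-order Markov dynamics on CP/NCP as defined
  by the OKS pain subscale), and scores, utilities and costs are drawn
  conditionally on state — matching the analysis's assumption that the
  OKS-defined state drives outcomes;
* OKS-PS scores are drawn uniformly on disjoint supports (CP on 0–14, NCP on
  15–28), so classification recovers the generating state exactly;
* utilities are Gaussian around state-conditional means, capped at the scale
  maximum of 1 (values below 0 are permitted, as on the EQ-5D-3L scale);
* annual costs are gamma-distributed around state-conditional component
  means with a configurable coefficient of variation, with an optional
  point mass at zero.

Trial-like panels observe utilities at 0/6/12 months with annual costs at 12
months; cohort-like panels observe yearly for five years.  The six-month
state is set equal to the twelve-month state — patients who leave chronic
pain are taken to have done so by mid-year, consistent with the faster
six-month exit reported for the intervention arm.

Defaults mirror the published year-1 point estimates (exit probabilities
0.645 / 0.506, state-mean utilities and costs near the published anchors);
see docs/methods.md for the rationale behind values the publication does not
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import (
    CP_THRESHOLD,
    OKS_PS_MAX,
    STATES,
    PainState,
)

__all__ = ["GeneratorConfig", "simulate_trial", "simulate_cohort", "implied_parameters"]

# Cohort dynamics for years 2-5 (shared by both arms in the base case).
_DEFAULT_COHORT_CP_STAY = (0.368, 0.388, 0.400, 0.406)
_DEFAULT_COHORT_NCP_TO_CP = (0.050, 0.042, 0.031, 0.037)


def _default_cohort_matrices() -> np.ndarray:
    out = np.empty((4, 2, 2))
    for i, (stay, back) in enumerate(zip(_DEFAULT_COHORT_CP_STAY, _DEFAULT_COHORT_NCP_TO_CP)):
        out[i] = [[stay, 1.0 - stay], [back, 1.0 - back]]
    return out


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic trial and cohort panels."""

    # sample sizes
    n_trial_per_arm: int = 2000
    n_cohort: int = 5000

    # trial dynamics: probability of leaving CP during year 1, per arm
    trial_cp_to_ncp: dict = field(
        default_factory=lambda: {"star": 0.645, "usual_care": 0.506}
    )
    # cohort dynamics: matrices for years 2..5 and the state mix at entry
    # The real cohort is a general post-replacement population with both pain
    # states represented at entry; an even split keeps both transition risk
    # sets well populated for estimation.
    cohort_matrices: np.ndarray = field(default_factory=_default_cohort_matrices)
    cohort_initial_cp: float = 0.5

    # observation models
    baseline_utility_mean: float = 0.45          # everyone enters the trial in CP
    trial_utility_mean: dict = field(
        default_factory=lambda: {"CP": 0.50, "NCP": 0.72}
    )
    cohort_utility_mean: dict = field(
        default_factory=lambda: {
            "CP": (0.465, 0.556, 0.607, 0.642, 0.698),
            "NCP": (0.539, 0.730, 0.727, 0.716, 0.702),
        }
    )
    utility_sd: float = 0.15
    trial_cost_mean: dict = field(
        default_factory=lambda: {
            "prescriptions": {"CP": 100.0, "NCP": 22.0},
            "consultations": {"CP": 166.0, "NCP": 62.0},
            "hospital_admissions": {
                "star": {"CP": 1265.0, "NCP": 1302.0},
                "usual_care": {"CP": 2972.0, "NCP": 1057.0},
            },
        }
    )
    cohort_cost_mean: dict = field(
        default_factory=lambda: {
            "prescriptions": {"CP": (100, 88, 91, 91, 91), "NCP": (22, 18, 17, 17, 18)},
            "consultations": {"CP": (166, 143, 137, 137, 125), "NCP": (62, 51, 48, 46, 48)},
            "hospital_admissions": {"CP": (2972, 898, 464, 65, 24), "NCP": (1057, 386, 331, 82, 249)},
        }
    )
    cost_cv: float = 0.5
    zero_cost_mass: float = 0.0                  # point mass at zero cost
    missing_utility_rate: float = 0.0

    def validated(self) -> "GeneratorConfig":
        for arm, p in self.trial_cp_to_ncp.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"trial_cp_to_ncp[{arm}]={p} is not a probability")
        mats = np.asarray(self.cohort_matrices, dtype=float)
        if mats.shape[1:] != (2, 2) or ((mats < 0) | (mats > 1)).any() \
                or not np.allclose(mats.sum(axis=2), 1.0):
            raise ValueError("cohort_matrices must be row-stochastic 2x2 matrices")
        if not (0.0 <= self.cohort_initial_cp <= 1.0):
            raise ValueError("cohort_initial_cp must be a fraction")
        if not (0.0 <= self.missing_utility_rate <= 1.0):
            raise ValueError("missing_utility_rate must be a fraction")
        if self.utility_sd < 0 or self.cost_cv < 0:
            raise ValueError("dispersions must be non-negative")
        if not (0.0 <= self.zero_cost_mass <= 1.0):
            raise ValueError("zero_cost_mass must be a fraction")
        return self


def _draw_oks(rng: np.random.Generator, states: np.ndarray) -> np.ndarray:
    """Uniform OKS-PS scores on the state's side of the classification threshold."""
    cp = rng.integers(0, CP_THRESHOLD + 1, size=states.shape)
    ncp = rng.integers(CP_THRESHOLD + 1, OKS_PS_MAX + 1, size=states.shape)
    return np.where(states == 0, cp, ncp)


def _draw_utility(rng, mean: np.ndarray, sd: float) -> np.ndarray:
    return np.minimum(mean + rng.normal(0.0, sd, size=mean.shape) if sd > 0 else mean.copy(), 1.0)


def _draw_cost(rng, mean: np.ndarray, cv: float, zero_mass: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if cv > 0:
        shape = 1.0 / cv**2
        out = rng.gamma(shape, mean * cv**2)  # shape * scale = mean
    else:
        out = mean.copy()
    if zero_mass > 0:
        out = np.where(rng.random(mean.shape) < zero_mass, 0.0, out)
    return out


def _mask(rng, values: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return values
    return np.where(rng.random(values.shape) < rate, np.nan, values)


def simulate_trial(config: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Trial-like panel: both arms, utilities at 0/6/12 months, costs at 12 months."""
    cfg = config.validated()
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for arm, p_exit in cfg.trial_cp_to_ncp.items():
        n = cfg.n_trial_per_arm
        ids = np.arange(offset, offset + n)
        offset += n
        state0 = np.zeros(n, dtype=int)                       # everyone enters in CP
        state12 = (rng.random(n) < p_exit).astype(int)        # 1 = NCP at 12 months
        state6 = state12                                       # transition by mid-year

        u_mean12 = np.where(state12 == 0, cfg.trial_utility_mean["CP"], cfg.trial_utility_mean["NCP"])
        u0 = _mask(rng, _draw_utility(rng, np.full(n, cfg.baseline_utility_mean), cfg.utility_sd),
                   cfg.missing_utility_rate)
        u6 = _mask(rng, _draw_utility(rng, u_mean12, cfg.utility_sd), cfg.missing_utility_rate)
        u12 = _mask(rng, _draw_utility(rng, u_mean12, cfg.utility_sd), cfg.missing_utility_rate)

        costs = {}
        for comp in ("prescriptions", "consultations"):
            means = np.where(state12 == 0, cfg.trial_cost_mean[comp]["CP"], cfg.trial_cost_mean[comp]["NCP"])
            costs[comp] = _draw_cost(rng, means, cfg.cost_cv, cfg.zero_cost_mass)
        hosp = cfg.trial_cost_mean["hospital_admissions"][arm]
        means = np.where(state12 == 0, hosp["CP"], hosp["NCP"])
        costs["hospital_admissions"] = _draw_cost(rng, means, cfg.cost_cv, cfg.zero_cost_mass)

        for t, states_t, util in ((0, state0, u0), (6, state6, u6), (12, state12, u12)):
            frames.append(pd.DataFrame({
                "patient_id": ids,
                "arm": arm,
                "time_months": t,
                "oks_ps": _draw_oks(rng, states_t),
                "utility": util,
                "cost_prescriptions": costs["prescriptions"] if t == 12 else np.nan,
                "cost_consultations": costs["consultations"] if t == 12 else np.nan,
                "cost_hospital": costs["hospital_admissions"] if t == 12 else np.nan,
            }))
    return pd.concat(frames, ignore_index=True).sort_values(
        ["patient_id", "time_months"], ignore_index=True
    )


def simulate_cohort(config: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Cohort-like panel: yearly assessments at months 12..60 for five years."""
    cfg = config.validated()
    rng = np.random.default_rng(seed)
    n = cfg.n_cohort
    mats = np.asarray(cfg.cohort_matrices, dtype=float)
    n_years = mats.shape[0] + 1

    states = np.empty((n_years, n), dtype=int)
    states[0] = (rng.random(n) >= cfg.cohort_initial_cp).astype(int)  # 0=CP, 1=NCP
    for y in range(1, n_years):
        p_to_ncp = mats[y - 1][states[y - 1], 1]
        states[y] = (rng.random(n) < p_to_ncp).astype(int)

    frames = []
    ids = np.arange(n)
    for y in range(n_years):
        s = states[y]
        u_mean = np.where(
            s == 0,
            cfg.cohort_utility_mean["CP"][y],
            cfg.cohort_utility_mean["NCP"][y],
        )
        utility = _mask(rng, _draw_utility(rng, u_mean, cfg.utility_sd), cfg.missing_utility_rate)
        row = {
            "patient_id": ids,
            "arm": "cohort",
            "time_months": 12 * (y + 1),
            "oks_ps": _draw_oks(rng, s),
            "utility": utility,
        }
        for comp, col in (("prescriptions", "cost_prescriptions"),
                          ("consultations", "cost_consultations"),
                          ("hospital_admissions", "cost_hospital")):
            means = np.where(s == 0, cfg.cohort_cost_mean[comp]["CP"][y],
                             cfg.cohort_cost_mean[comp]["NCP"][y])
            row[col] = _draw_cost(rng, means.astype(float), cfg.cost_cv, cfg.zero_cost_mass)
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True).sort_values(
        ["patient_id", "time_months"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Closed-form oracle: the parameters the generator implies
# ---------------------------------------------------------------------------

def _capped_normal_mean(mu: float, sd: float, cap: float = 1.0) -> float:
    """E[min(X, cap)] for X ~ Normal(mu, sd) — the generator caps utilities at 1."""
    if sd == 0:
        return min(mu, cap)
    z = (cap - mu) / sd
    return mu - sd * (stats.norm.pdf(z) - z * stats.norm.sf(z))


def implied_parameters(config: GeneratorConfig, arms: tuple[str, str] = ("star", "usual_care"),
                       intervention_oneoff_cost: float = 191.0):
    """The exact ParameterSet the generating process implies, in closed form.

    This is the oracle against which the derive-from-panels pipeline is
    checked: the derivation applied to infinitely many synthetic patients
    would converge to exactly this bundle.
    """
    from .derivation import pct_change_project, popc_project
    from .parameters import CostComponents, ParameterSet, StateYearPayoff, TransitionMatrix

    cfg = config.validated()
    sd = cfg.utility_sd

    transition_schedule = {a: {} for a in arms}
    for arm in arms:
        p = cfg.trial_cp_to_ncp[arm]
        transition_schedule[arm][1] = TransitionMatrix([[1.0 - p, p], [0.0, 1.0]])
    for year in range(2, 6):
        tm = TransitionMatrix(cfg.cohort_matrices[year - 2])
        for arm in arms:
            transition_schedule[arm][year] = tm

    # year-1 QALY anchors: AUC with u6 = u12 = state mean, u0 = baseline mean
    u_base = _capped_normal_mean(cfg.baseline_utility_mean, sd)
    anchors = {
        arm: {
            s: 0.25 * u_base + 0.75 * _capped_normal_mean(cfg.trial_utility_mean[s.value], sd)
            for s in STATES
        }
        for arm in arms
    }
    util_series = {
        s: [_capped_normal_mean(m, sd) for m in cfg.cohort_utility_mean[s.value]]
        for s in STATES
    }

    # pooled year-1 cost anchors, weighted by each arm's expected state mix
    state_w = {
        s: {arm: (1.0 - cfg.trial_cp_to_ncp[arm]) if s is PainState.CP else cfg.trial_cp_to_ncp[arm]
            for arm in arms}
        for s in STATES
    }
    scale = 1.0 - cfg.zero_cost_mass
    pooled = {}
    for s in STATES:
        w = state_w[s]
        total_w = sum(w.values())
        pooled[s] = {
            "prescriptions": scale * cfg.trial_cost_mean["prescriptions"][s.value],
            "consultations": scale * cfg.trial_cost_mean["consultations"][s.value],
            "hospital_admissions": scale * sum(
                w[arm] * cfg.trial_cost_mean["hospital_admissions"][arm][s.value] for arm in arms
            ) / total_w,
        }

    payoff_schedule = {a: {} for a in arms}
    for arm in arms:
        for s in STATES:
            qalys = popc_project(min(max(anchors[arm][s], 0.0), 1.0), util_series[s])
            series = {
                comp: pct_change_project(pooled[s][comp],
                                         [scale * v for v in cfg.cohort_cost_mean[comp][s.value]])
                for comp in ("prescriptions", "consultations", "hospital_admissions")
            }
            series["hospital_admissions"][0] = scale * cfg.trial_cost_mean["hospital_admissions"][arm][s.value]
            for year in range(1, 6):
                payoff_schedule[arm].setdefault(year, {})[s] = StateYearPayoff(
                    qaly=min(max(qalys[year - 1], 0.0), 1.0),
                    costs=CostComponents(
                        prescriptions=series["prescriptions"][year - 1],
                        consultations=series["consultations"][year - 1],
                        hospital_admissions=series["hospital_admissions"][year - 1],
                    ),
                )

    return ParameterSet(
        arms=arms,
        transition_schedule=transition_schedule,
        payoff_schedule=payoff_schedule,
        intervention_oneoff_cost=intervention_oneoff_cost,
    )
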