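"""Derivation stages: classification, transitions, AUC QALYs, PoPC, cost projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from star_cea import PainState, auc_qaly, classify_pain, pct_change_project, popc_project, popc_step
from star_cea.derivation import adjust_qalys_for_baseline, estimate_transition_matrix
from star_cea.synthetic_data import GeneratorConfig, simulate_trial

CP, NCP = PainState.CP, PainState.NCP

# Published utility rows: usual-care series (the cohort-anchored reference),
# the intervention-arm anchors, and the intervention-arm projected rows.
UC_CP = (0.465, 0.556, 0.607, 0.642, 0.698)
UC_NCP = (0.539, 0.730, 0.727, 0.716, 0.702)
STAR_CP = (0.484, 0.572, 0.621, 0.654, 0.708)
STAR_NCP = (0.560, 0.742, 0.739, 0.728, 0.714)
POOLED_CP = (0.477, 0.566, 0.616, 0.650, 0.704)
POOLED_NCP = (0.555, 0.739, 0.736, 0.725, 0.711)


# -- pain-state classification ----------------------------------------------

@pytest.mark.parametrize("score, state", [(0, CP), (14, CP), (15, NCP), (28, NCP)])
def test_classification_threshold(score, state):
    assert classify_pain(score) is state


@pytest.mark.parametrize("score", [-1, 29, 3.5])
def test_classification_rejects_out_of_range(score):
    with pytest.raises(ValueError):
        classify_pain(score)


# -- transition estimation ---------------------------------------------------

def _panel(states_t1, states_t2, arm="a"):
    n = len(states_t1)
    rows = []
    for t, states in ((0, states_t1), (12, states_t2)):
        for i, s in enumerate(states):
            rows.append({"patient_id": i, "arm": arm, "time_months": t,
                         "oks_ps": 10 if s == "CP" else 20})
    return pd.DataFrame(rows)


def test_transition_counts_direct_ratio():
    panel = _panel(["CP"] * 10, ["NCP"] * 6 + ["CP"] * 4)
    est = estimate_transition_matrix(panel, 0, 12, fill_empty={NCP: (0.0, 1.0)})
    assert est.matrix[CP, NCP] == pytest.approx(0.6)
    assert est.matrix[CP, CP] == pytest.approx(0.4)
    assert est.counts[0].sum() == 10
    assert est.n_excluded == 0


def test_transition_empty_risk_set_raises():
    panel = _panel(["CP"] * 5, ["CP"] * 5)
    with pytest.raises(ValueError, match="NCP"):
        estimate_transition_matrix(panel, 0, 12)


def test_transition_excludes_unpaired_patients():
    panel = _panel(["CP"] * 6, ["NCP"] * 6)
    panel = panel.drop(panel[(panel.patient_id == 0) & (panel.time_months == 12)].index)
    est = estimate_transition_matrix(panel, 0, 12, fill_empty={NCP: (0.0, 1.0)})
    assert est.n_excluded == 1
    assert est.counts[0].sum() == 5


def test_transition_recovery_within_binomial_interval():
    """Estimates from a synthetic trial fall in the exact binomial CI of the truth."""
    trial = simulate_trial(GeneratorConfig(n_trial_per_arm=2000), seed=42)
    est = estimate_transition_matrix(trial, 0, 12, arm="star", fill_empty={NCP: (0.0, 1.0)})
    k, n = est.counts[0, 1], est.counts[0].sum()
    lo = beta_dist.ppf(0.025, k, n - k + 1)
    hi = beta_dist.ppf(0.975, k + 1, n - k)
    assert lo <= 0.645 <= hi


# -- AUC QALYs ----------------------------------------------------------------

@pytest.mark.parametrize(
    "u0, u6, u12, expected",
    [(0.5, 0.5, 0.5, 0.5), (0.0, 1.0, 0.0, 0.5), (0.2, 0.6, 0.8, 0.55)],
)
def test_auc_trapezoid(u0, u6, u12, expected):
    assert auc_qaly(u0, u6, u12) == pytest.approx(expected)


def test_auc_rejects_utility_above_scale():
    with pytest.raises(ValueError):
        auc_qaly(0.5, 1.2, 0.5)


# -- baseline adjustment ------------------------------------------------------

def test_adjustment_is_noop_for_balanced_groups():
    baseline = np.tile(np.linspace(0.2, 0.8, 25), 2)
    qaly = np.concatenate([np.full(25, 0.5), np.full(25, 0.6)]) + 0.3 * baseline
    group = ["a"] * 25 + ["b"] * 25
    adj = adjust_qalys_for_baseline(pd.DataFrame({"qaly": qaly, "baseline": baseline, "group": group}))
    raw = pd.Series(qaly).groupby(group).mean()
    assert adj["a"] == pytest.approx(raw["a"], abs=1e-10)
    assert adj["b"] == pytest.approx(raw["b"], abs=1e-10)


def test_adjustment_matches_closed_form_least_squares():
    """Recover known group effects (0.46 vs 0.54) with baseline slope 0.5."""
    rng = np.random.default_rng(7)
    n = 400
    group = np.repeat(["a", "b"], n)
    baseline = rng.uniform(0.2, 0.9, 2 * n)
    effects = np.where(group == "a", 0.46, 0.54)
    qaly = effects + 0.5 * (baseline - baseline.mean()) + rng.normal(0, 0.05, 2 * n)
    df = pd.DataFrame({"qaly": qaly, "baseline": baseline, "group": group})
    adj = adjust_qalys_for_baseline(df)

    # independent route: normal equations on the same design
    X = np.column_stack([group == "a", group == "b", baseline]).astype(float)
    coef, *_ = np.linalg.lstsq(X, qaly, rcond=None)
    expected = {g: coef[i] + coef[2] * baseline.mean() for i, g in enumerate(["a", "b"])}
    assert adj["a"] == pytest.approx(expected["a"], abs=1e-10)
    assert adj["b"] == pytest.approx(expected["b"], abs=1e-10)

    resid_se = 0.05 * np.sqrt(2 / n)  # crude SE of a group-mean difference
    assert adj["b"] - adj["a"] == pytest.approx(0.08, abs=2 * resid_se)


def test_adjustment_with_zero_baseline_effect_matches_raw_means():
    rng = np.random.default_rng(11)
    n = 500
    group = np.repeat(["a", "b"], n)
    baseline = rng.uniform(0.2, 0.9, 2 * n)
    qaly = np.where(group == "a", 0.5, 0.6) + rng.normal(0, 0.03, 2 * n)
    adj = adjust_qalys_for_baseline(pd.DataFrame({"qaly": qaly, "baseline": baseline, "group": group}))
    raw = pd.Series(qaly).groupby(group).mean()
    assert adj["a"] == pytest.approx(raw["a"], abs=3 * 0.03 / np.sqrt(n))
    assert adj["b"] == pytest.approx(raw["b"], abs=3 * 0.03 / np.sqrt(n))


def test_adjustment_rejects_constant_baseline():
    df = pd.DataFrame({"qaly": [0.4, 0.5, 0.6, 0.7], "baseline": [0.5] * 4,
                       "group": ["a", "a", "b", "b"]})
    with pytest.raises(ValueError, match="singular|constant"):
        adjust_qalys_for_baseline(df)


# -- percentage of potential change -------------------------------------------

def test_popc_step_published_examples():
    assert popc_step(0.484, 0.465, 0.556) == pytest.approx(0.5718, abs=5e-5)
    assert popc_step(0.560, 0.539, 0.730) == pytest.approx(0.7423, abs=5e-5)


def test_popc_step_anchor_equal_to_cohort_returns_cohort():
    assert popc_step(0.465, 0.465, 0.556) == pytest.approx(0.556, abs=1e-12)
    assert popc_step(0.730, 0.730, 0.716) == pytest.approx(0.716, abs=1e-12)  # decline


def test_popc_step_rejects_cohort_at_scale_max():
    with pytest.raises(ValueError):
        popc_step(0.5, 1.0, 1.1)


@given(
    current=st.floats(0.05, 1.0),
    frm=st.floats(0.05, 0.99),
    to=st.floats(0.0, 1.0),
)
def test_popc_step_stays_on_scale(current, frm, to):
    out = popc_step(current, frm, to)
    assert out <= 1.0 + 1e-12
    if to >= frm:
        # the top of the scale is absorbing under improvement
        assert popc_step(1.0, frm, to) == pytest.approx(1.0, abs=1e-12)
    if current >= 0:
        assert out >= -1e-12 or to < frm  # declines keep sign of current


@pytest.mark.parametrize(
    "anchor, cohort, printed",
    [
        (0.484, UC_CP, STAR_CP),
        (0.560, UC_NCP, STAR_NCP),
        (0.477, UC_CP, POOLED_CP),
        (0.555, UC_NCP, POOLED_NCP),
    ],
)
def test_popc_projection_reproduces_published_utility_rows(anchor, cohort, printed):
    """Cross-arm construction: reference-series change applied to each anchor."""
    projected = popc_project(anchor, cohort)
    assert np.allclose(projected, printed, atol=1e-3)


def test_popc_projection_identity_path():
    series = popc_project(UC_CP[0], UC_CP)
    assert series == pytest.approx(list(UC_CP), abs=1e-12)


# -- percentage-change cost projection ----------------------------------------

@pytest.mark.parametrize(
    "anchor, cohort, expected",
    [
        (100, (100, 88, 91), [100, 88, 91]),
        (200, (100, 88), [200, 176]),
        (50, (100, 50, 25), [50, 25, 12.5]),
    ],
)
def test_pct_change_projection(anchor, cohort, expected):
    assert pct_change_project(anchor, cohort) == pytest.approx(expected)


def test_pct_change_rejects_zero_cohort_value():
    with pytest.raises(ValueError):
        pct_change_project(100, (100, 0, 50))


@given(
    anchor=st.floats(1, 1e4),
    scale=st.floats(0.1, 10),
    cohort=st.lists(st.floats(1, 1e4), min_size=2, max_size=6),
)
def test_pct_change_is_scale_equivariant(anchor, scale, cohort):
    base = pct_change_project(anchor, cohort)
    scaled = pct_change_project(anchor * scale, cohort)
    assert np.allclose(scaled, np.asarray(base) * scale, rtol=1e-9)
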