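"""PSA: moment matching, seeded reproducibility, CEAC, coverage ellipse."""

import numpy as np
import pytest

from star_cea import (
    ceac,
    compare_arms,
    confidence_ellipse,
    default_distributions,
    run_arm,
    run_psa,
)
from star_cea.psa import DistributionSpec, PsaDraws, default_ceac_grid


def _fixed_specs(params):
    return [
        DistributionSpec(s.path, "fixed", 0.0, 0.0, s.mean, 0.0)
        for s in default_distributions(params)
    ]


def _draws_from(dq, dc):
    dq = np.asarray(dq, dtype=float)
    dc = np.asarray(dc, dtype=float)
    return PsaDraws(n=len(dq), seed=0, delta_qalys=dq, delta_costs=dc,
                    arm_qalys={}, arm_costs={})


# -- distribution specs -------------------------------------------------------

def test_beta_moment_matching():
    spec = next(s for s in default_distributions(__import__("star_cea").builtin_star_parameters())
                if s.path == ("transition", "usual_care", 1, "CP"))
    assert spec.family == "beta"
    assert spec.mean == pytest.approx(0.494)
    assert spec.sd == pytest.approx(0.0741)
    m, v = 0.494, 0.0741**2
    k = m * (1 - m) / v - 1
    assert spec.a == pytest.approx(m * k)
    assert spec.b == pytest.approx((1 - m) * k)


def test_gamma_moment_matching(base_params):
    spec = next(s for s in default_distributions(base_params)
                if s.path == ("cost", "usual_care", 1, "CP", "hospital_admissions"))
    assert spec.family == "gamma"
    assert spec.a == pytest.approx(1 / 0.15**2)
    assert spec.b == pytest.approx(2972 * 0.15**2)
    assert spec.a * spec.b == pytest.approx(2972)


def test_structural_zero_is_fixed(base_params):
    spec = next(s for s in default_distributions(base_params)
                if s.path == ("transition", "star", 1, "NCP"))
    assert spec.family == "fixed" and spec.mean == 0.0


def test_moment_matching_round_trips_through_sampling(base_params):
    rng = np.random.default_rng(5)
    n = 100_000
    for path in [("transition", "usual_care", 1, "CP"),
                 ("qaly", "star", 2, "NCP"),
                 ("cost", "usual_care", 1, "CP", "hospital_admissions")]:
        spec = next(s for s in default_distributions(base_params) if s.path == path)
        x = spec.sample(rng, n)
        se_mean = spec.sd / np.sqrt(n)
        assert x.mean() == pytest.approx(spec.mean, abs=3 * se_mean)
        assert x.std() == pytest.approx(spec.sd, rel=0.02)


def test_dispersion_must_be_positive(base_params):
    with pytest.raises(ValueError):
        default_distributions(base_params, dispersion=0.0)


# -- PSA runs -----------------------------------------------------------------

def test_same_seed_gives_identical_draws(base_params):
    a = run_psa(base_params, n=50, seed=7)
    b = run_psa(base_params, n=50, seed=7)
    assert np.array_equal(a.delta_qalys, b.delta_qalys)
    assert np.array_equal(a.delta_costs, b.delta_costs)
    c = run_psa(base_params, n=50, seed=8)
    assert not np.array_equal(a.delta_qalys, c.delta_qalys)


def test_degenerate_psa_equals_deterministic(base_params):
    det = compare_arms(run_arm(base_params, "star"), run_arm(base_params, "usual_care"), 20000)
    draws = run_psa(base_params, specs=_fixed_specs(base_params), n=5, seed=3)
    assert draws.delta_qalys == pytest.approx([det.delta_qalys] * 5, abs=1e-12)
    assert draws.delta_costs == pytest.approx([det.delta_costs] * 5, abs=1e-9)


def test_psa_mean_tracks_deterministic_result(base_params):
    det = compare_arms(run_arm(base_params, "star"), run_arm(base_params, "usual_care"), 20000)
    draws = run_psa(base_params, n=4000, seed=2)
    se = draws.delta_qalys.std() / np.sqrt(draws.n)
    assert draws.delta_qalys.mean() == pytest.approx(det.delta_qalys, abs=3 * se)


def test_psa_rejects_empty_run(base_params):
    with pytest.raises(ValueError):
        run_psa(base_params, n=0, seed=1)


# -- CEAC ---------------------------------------------------------------------

def test_ceac_uniform_dominance_gives_probability_one():
    draws = _draws_from([0.1, 0.2, 0.05], [-100, -50, -10])
    curve = ceac(draws)
    assert (curve["probability"] == 1.0).all()


def test_ceac_definition_at_zero_and_large_threshold():
    rng = np.random.default_rng(0)
    draws = _draws_from(rng.normal(0.05, 0.2, 2000), rng.normal(-300, 800, 2000))
    curve = ceac(draws, thresholds=[0.0, 1e9])
    assert curve["probability"].iloc[0] == (draws.delta_costs < 0).mean()
    assert curve["probability"].iloc[1] == pytest.approx((draws.delta_qalys > 0).mean(), abs=1e-3)


def test_ceac_monotone_when_all_draws_gain_qalys():
    rng = np.random.default_rng(1)
    draws = _draws_from(rng.uniform(0.01, 0.3, 1000), rng.normal(0, 700, 1000))
    curve = ceac(draws)
    assert (np.diff(curve["probability"]) >= 0).all()


def test_default_grid_has_101_points():
    grid = default_ceac_grid()
    assert len(grid) == 101 and grid[0] == 0 and grid[-1] == 50000


# -- coverage ellipse ---------------------------------------------------------

def test_ellipse_coverage_on_known_bivariate_normal():
    rng = np.random.default_rng(9)
    n = 10000
    cov = np.array([[0.04, 0.5], [0.5, 400.0]])
    pts = rng.multivariate_normal([0.1, -300.0], cov, size=n)
    draws = _draws_from(pts[:, 0], pts[:, 1])
    ell = confidence_ellipse(draws, coverage=0.95)
    frac = ell.contains(draws.pairs).mean()
    se = np.sqrt(0.95 * 0.05 / n)
    assert frac == pytest.approx(0.95, abs=2 * se + 5e-3)


def test_ellipse_axes_equal_for_isotropic_draws():
    rng = np.random.default_rng(3)
    pts = rng.normal(0, 1.0, size=(20000, 2))
    ell = confidence_ellipse(_draws_from(pts[:, 0], pts[:, 1]))
    assert ell.semi_axes[0] == pytest.approx(ell.semi_axes[1], rel=0.05)


def test_ellipse_zero_coverage_degenerates_to_mean():
    rng = np.random.default_rng(4)
    pts = rng.normal(0, 1.0, size=(100, 2))
    ell = confidence_ellipse(_draws_from(pts[:, 0], pts[:, 1]), coverage=0.0)
    assert np.allclose(ell.semi_axes, 0.0)


def test_ellipse_rejects_singular_covariance():
    draws = _draws_from([0.1] * 10, [-100.0] * 10)
    with pytest.raises(ValueError, match="singular"):
        confidence_ellipse(draws)
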