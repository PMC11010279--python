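"""Probabilistic sensitivity analysis.

Each uncertain input receives a parametric distribution moment-matched to its
point estimate: beta for quantities bounded in [0, 1] (transition
probabilities and utility weights) and gamma for non-negative costs, with a
configurable dispersion (standard deviation as a fraction of the mean,
default 0.15).  The published analysis does not print its hyperparameters, so
dispersion is an explicit modelling choice here, not a reproduction.

Each two-state transition row is sampled through a single beta draw on the
probability of moving to CP, with the complement assigned to NCP (for two
states this is equivalent to a Dirichlet row).  Structural constants — the
discount rate, horizon, one-off intervention cost, and exact-zero or
exact-one probabilities — are held fixed.

All draws come from a single seeded generator in a stable parameter order, so
a PSA run is exactly reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import STATES, PainState, ParameterSet

__all__ = [
    "DistributionSpec",
    "PsaDraws",
    "Ellipse",
    "default_distributions",
    "run_psa",
    "ceac",
    "confidence_ellipse",
    "default_ceac_grid",
]

_COMPONENTS = ("prescriptions", "consultations", "hospital_admissions")


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one scalar model input.

    ``path`` addresses the input: ("transition", arm, year, from_state) for
    the to-CP probability of that row, ("qaly", arm, year, state), or
    ("cost", arm, year, state, component).  ``family`` is "beta", "gamma" or
    "fixed"; ``a``/``b`` are (alpha, beta) or (shape, scale); ``mean``/``sd``
    record the matched moments.
    """

    path: tuple
    family: str
    a: float
    b: float
    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.mean)
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=n)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=n)
        raise ValueError(f"unknown family {self.family!r}")


def _beta_spec(path: tuple, mean: float, dispersion: float) -> DistributionSpec:
    if not (0.0 <= mean <= 1.0):
        raise ValueError(f"{'/'.join(map(str, path))}: mean {mean} outside beta support")
    if mean in (0.0, 1.0):
        return DistributionSpec(path, "fixed", 0.0, 0.0, mean, 0.0)
    sd = dispersion * mean
    # keep the variance inside the feasible region of the beta family
    sd = min(sd, 0.95 * np.sqrt(mean * (1.0 - mean)))
    var = sd * sd
    k = mean * (1.0 - mean) / var - 1.0
    return DistributionSpec(path, "beta", mean * k, (1.0 - mean) * k, mean, sd)


def _gamma_spec(path: tuple, mean: float, dispersion: float) -> DistributionSpec:
    if mean < 0:
        raise ValueError(f"{'/'.join(map(str, path))}: mean {mean} outside gamma support")
    if mean == 0.0:
        return DistributionSpec(path, "fixed", 0.0, 0.0, 0.0, 0.0)
    shape = 1.0 / dispersion**2
    scale = mean * dispersion**2
    return DistributionSpec(path, "gamma", shape, scale, mean, dispersion * mean)


def default_distributions(
    params: ParameterSet, dispersion: float = 0.15
) -> list[DistributionSpec]:
    """Moment-matched specs for every transition probability, utility and cost."""
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    specs: list[DistributionSpec] = []
    for arm in params.arms:
        for year in params.years():
            tm = params.transition_schedule[arm][year]
            for frm in STATES:
                p_to_cp = tm[frm, PainState.CP]
                specs.append(_beta_spec(("transition", arm, year, frm.value), p_to_cp, dispersion))
            for s in STATES:
                payoff = params.payoff_schedule[arm][year][s]
                specs.append(_beta_spec(("qaly", arm, year, s.value), payoff.qaly, dispersion))
                for comp in _COMPONENTS:
                    specs.append(
                        _gamma_spec(("cost", arm, year, s.value, comp),
                                    getattr(payoff.costs, comp), dispersion)
                    )
    return specs


@dataclass
class PsaDraws:
    """Per-draw incremental and per-arm totals from a PSA run."""

    n: int
    seed: int
    delta_qalys: np.ndarray
    delta_costs: np.ndarray
    arm_qalys: dict[str, np.ndarray]
    arm_costs: dict[str, np.ndarray]
    n_resampled: int = 0

    @property
    def pairs(self) -> np.ndarray:
        return np.column_stack([self.delta_qalys, self.delta_costs])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "draw": np.arange(self.n),
            "delta_qalys": self.delta_qalys,
            "delta_costs": self.delta_costs,
        })
        for arm, q in self.arm_qalys.items():
            df[f"qalys_{arm}"] = q
        for arm, c in self.arm_costs.items():
            df[f"costs_{arm}"] = c
        return df


def _batch_totals(matrices, qalys, costs, initial, discount_rate, oneoff):
    """Vectorised engine over draws: arrays (n, H, 2, 2), (n, H, 2), (n, H, 2)."""
    n, horizon = qalys.shape[0], qalys.shape[1]
    m = np.broadcast_to(initial, (n, 2)).copy()
    factors = (1.0 + discount_rate) ** (-np.arange(horizon, dtype=float))
    tot_q = np.zeros(n)
    tot_c = np.zeros(n)
    for t in range(horizon):
        m = np.einsum("ni,nij->nj", m, matrices[:, t])
        tot_q += (m * qalys[:, t]).sum(axis=1) * factors[t]
        cyc_c = (m * costs[:, t]).sum(axis=1)
        if t == 0:
            cyc_c = cyc_c + oneoff
        tot_c += cyc_c * factors[t]
    return tot_q, tot_c


def run_psa(
    params: ParameterSet,
    specs: Sequence[DistributionSpec] | None = None,
    n: int = 10000,
    seed: int = 0,
    dispersion: float = 0.15,
) -> PsaDraws:
    """Run the model for ``n`` sampled parameter sets and record incremental outcomes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if specs is None:
        specs = default_distributions(params, dispersion=dispersion)
    rng = np.random.default_rng(seed)
    samples = {spec.path: spec.sample(rng, n) for spec in specs}

    horizon = params.horizon
    initial = params.initial_array()
    arm_qalys: dict[str, np.ndarray] = {}
    arm_costs: dict[str, np.ndarray] = {}
    for arm in params.arms:
        matrices = np.broadcast_to(params.transition_array(arm), (n, horizon, 2, 2)).copy()
        qalys = np.broadcast_to(params.qaly_array(arm), (n, horizon, 2)).copy()
        costs = np.broadcast_to(params.cost_array(arm), (n, horizon, 2)).copy()
        for year in params.years():
            t = year - 1
            for frm in STATES:
                key = ("transition", arm, year, frm.value)
                if key in samples:
                    p = samples[key]
                    matrices[:, t, frm.index, PainState.CP.index] = p
                    matrices[:, t, frm.index, PainState.NCP.index] = 1.0 - p
            for s in STATES:
                key = ("qaly", arm, year, s.value)
                if key in samples:
                    qalys[:, t, s.index] = samples[key]
                total = np.zeros(n)
                found = False
                for comp in _COMPONENTS:
                    ckey = ("cost", arm, year, s.value, comp)
                    if ckey in samples:
                        total += samples[ckey]
                        found = True
                if found:
                    costs[:, t, s.index] = total
        arm_qalys[arm], arm_costs[arm] = _batch_totals(
            matrices, qalys, costs, initial, params.discount_rate, params.oneoff_cost(arm)
        )

    intervention, comparator = params.arms
    return PsaDraws(
        n=n,
        seed=seed,
        delta_qalys=arm_qalys[intervention] - arm_qalys[comparator],
        delta_costs=arm_costs[intervention] - arm_costs[comparator],
        arm_qalys=arm_qalys,
        arm_costs=arm_costs,
    )


def default_ceac_grid(stop: float = 50000.0, step: float = 500.0) -> np.ndarray:
    """The default willingness-to-pay grid: 0 to 50,000 GBP/QALY in steps of 500."""
    return np.arange(0.0, stop + step / 2, step)


def ceac(draws: PsaDraws, thresholds: Sequence[float] | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: P(lambda * dQ - dC > 0) per threshold."""
    if draws.n < 1:
        raise ValueError("draws must be non-empty")
    grid = default_ceac_grid() if thresholds is None else np.asarray(thresholds, dtype=float)
    nmb = grid[:, None] * draws.delta_qalys[None, :] - draws.delta_costs[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"threshold": grid, "probability": prob})


@dataclass(frozen=True)
class Ellipse:
    """A bivariate-normal coverage ellipse on the cost-effectiveness plane."""

    center: np.ndarray        # (mean dQ, mean dC)
    semi_axes: np.ndarray     # lengths of the semi-axes
    orientation: float        # radians from the dQ axis to the major axis
    coverage: float
    covariance: np.ndarray = field(repr=False, default=None)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test via the Mahalanobis distance."""
        diff = np.atleast_2d(points) - self.center
        inv = np.linalg.inv(self.covariance)
        d2 = np.einsum("ni,ij,nj->n", diff, inv, diff)
        return d2 <= stats.chi2.ppf(self.coverage, df=2)

    def boundary(self, num: int = 200) -> np.ndarray:
        """Points on the ellipse boundary, for plotting."""
        theta = np.linspace(0, 2 * np.pi, num)
        circle = np.column_stack([self.semi_axes[0] * np.cos(theta),
                                  self.semi_axes[1] * np.sin(theta)])
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        return circle @ rot.T + self.center


def confidence_ellipse(draws: PsaDraws, coverage: float = 0.95) -> Ellipse:
    """Coverage ellipse for (dQ, dC) from the sample mean and covariance."""
    if draws.n < 3:
        raise ValueError("need at least three draws for a covariance estimate")
    pts = draws.pairs
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 0:
        raise ValueError("singular covariance: ellipse undefined")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = stats.chi2.ppf(coverage, df=2)
    return Ellipse(
        center=center,
        semi_axes=np.sqrt(np.maximum(evals, 0.0) * q),
        orientation=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        coverage=coverage,
        covariance=cov,
    )
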