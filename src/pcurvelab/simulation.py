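"""Monte Carlo simulation of p-hacking through omitted-variable bias.

The data-generating process is trivariate:

    y = beta_star * x + gamma * z + epsilon,

with (x, z) standard normal with covariance ``cov_xz``, epsilon standard
normal and independent of both (exogeneity holds by construction).  The
analyst's regression omits the confounder z and regresses y on x alone,
so the fitted slope carries an expected omitted-variable bias of

    E[bias] = gamma * Cov(x, z) / Var(x).

Each Monte Carlo iteration draws gamma ~ Uniform[0, gamma_max] and a
sample size n ~ discrete Uniform[n_min, n_max], then a fresh sample of
all variables (no re-use of a dataset across iterations — the
conservative design).  ``gamma_max`` is either given directly or
calibrated so that the maximum expected Pearson correlation between y
and x under the null equals ``rho_max``:

    rho_yx(gamma) = cov_xz * gamma / sqrt(gamma^2 + 1)

because Var(y) = gamma^2 + 1 under beta_star = 0 and unit variances,
hence gamma_max = rho_max / sqrt(cov_xz^2 - rho_max^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, InvalidParameterError, NoSolutionError
from .ols import OLSFit, simple_slope

__all__ = [
    "DGPSpec",
    "SimulatedSample",
    "expected_ovb",
    "calibrate_gamma_max",
    "draw_sample",
    "fit_omitted_regression",
    "run_monte_carlo",
    "monte_carlo_table",
    "significant_share",
]


def expected_ovb(gamma: float, cov_xz: float = 0.2, var_x: float = 1.0) -> float:
    """Expected omitted-variable bias of the short-regression slope."""
    if var_x <= 0.0:
        raise InvalidParameterError(f"var_x must be positive, got {var_x}")
    return gamma * cov_xz / var_x


def calibrate_gamma_max(rho_max: float, cov_xz: float = 0.2) -> float:
    """Solve rho_yx(gamma) = rho_max for gamma under the null DGP.

    rho_yx(gamma) = |cov_xz| * gamma / sqrt(gamma^2 + 1) is increasing in
    gamma and bounded by |cov_xz|, so a target at or beyond that bound has
    no solution.
    """
    if rho_max < 0.0:
        raise InvalidParameterError(f"rho_max must be >= 0, got {rho_max}")
    if rho_max == 0.0:
        return 0.0
    c = abs(cov_xz)
    if rho_max >= c:
        raise NoSolutionError(
            f"rho_max={rho_max} unattainable: correlation is bounded by |cov_xz|={c}"
        )
    return rho_max / math.sqrt(c * c - rho_max * rho_max)


@dataclass
class DGPSpec:
    """Parameters of the trivariate DGP and its bias calibration.

    Exactly one of ``gamma_max`` / ``rho_max`` should be given; if
    ``rho_max`` is given, ``gamma_max`` is calibrated from it.  With
    neither, the spec is an exact null (gamma_max = 0).
    """

    beta_star: float = 0.0
    cov_xz: float = 0.2
    gamma_max: float | None = None
    rho_max: float | None = None
    n_min: int = 50
    n_max: int = 1000
    intercept: bool = True

    def __post_init__(self) -> None:
        if not abs(self.cov_xz) < 1.0:
            raise InvalidParameterError(f"|cov_xz| must be < 1, got {self.cov_xz}")
        if not (0 < self.n_min <= self.n_max):
            raise InvalidParameterError(
                f"need 0 < n_min <= n_max, got ({self.n_min}, {self.n_max})"
            )
        if self.gamma_max is None:
            self.gamma_max = (
                calibrate_gamma_max(self.rho_max, self.cov_xz)
                if self.rho_max is not None
                else 0.0
            )
        elif self.rho_max is not None:
            raise InvalidParameterError("give gamma_max or rho_max, not both")
        if self.gamma_max < 0.0:
            raise InvalidParameterError(f"gamma_max must be >= 0, got {self.gamma_max}")

    def with_n_max(self, n_max: int) -> "DGPSpec":
        return replace(self, n_max=n_max)


@dataclass
class SimulatedSample:
    """One realized dataset from the DGP."""

    x: np.ndarray
    z: np.ndarray
    epsilon: np.ndarray
    y: np.ndarray
    gamma: float
    n: int


def draw_sample(
    spec: DGPSpec, gamma: float, n: int, rng: np.random.Generator
) -> SimulatedSample:
    """Draw (x, z, epsilon) jointly normal and build y elementwise.

    z is constructed as cov_xz * x + sqrt(1 - cov_xz^2) * w with w an
    independent standard normal, which gives the exact target covariance
    under unit variances.  epsilon is drawn independently of both.
    """
    if n < 3:
        raise DegenerateSampleError(f"need n >= 3, got {n}")
    if gamma < 0.0:
        raise InvalidParameterError(f"gamma must be >= 0, got {gamma}")
    nrm = rng.standard_normal((n, 3))
    x = nrm[:, 0]
    z = spec.cov_xz * x + math.sqrt(1.0 - spec.cov_xz**2) * nrm[:, 1]
    epsilon = nrm[:, 2]
    y = spec.beta_star * x + gamma * z + epsilon
    return SimulatedSample(x=x, z=z, epsilon=epsilon, y=y, gamma=gamma, n=n)


def fit_omitted_regression(
    sample: SimulatedSample, intercept: bool = True, model_id: str | None = None
) -> OLSFit:
    """Short regression of y on x alone (the confounder z omitted)."""
    return simple_slope(sample.x, sample.y, intercept=intercept, model_id=model_id)


def _iterate(spec: DGPSpec, iterations: int, seed):
    """Yield (i, n, gamma, fit) with draws a pure function of (seed, i).

    One SeedSequence child per iteration; within an iteration the sample
    size and gamma come from uniform deviates drawn before the normal
    block, so grids sharing a seed run under common random numbers.
    """
    if iterations < 1:
        raise InvalidParameterError(f"iterations must be >= 1, got {iterations}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    span = spec.n_max - spec.n_min + 1
    for i, child in enumerate(ss.spawn(iterations)):
        rng = np.random.default_rng(child)
        n = spec.n_min + min(int(rng.uniform() * span), span - 1)
        gamma = rng.uniform() * spec.gamma_max
        sample = draw_sample(spec, gamma, n, rng)
        fit = fit_omitted_regression(sample, intercept=spec.intercept, model_id=str(i))
        yield i, n, gamma, fit


def run_monte_carlo(spec: DGPSpec, iterations: int, seed) -> list[OLSFit]:
    """Run the omitted-variable Monte Carlo; returns one fit per iteration."""
    return [fit for _, _, _, fit in _iterate(spec, iterations, seed)]


def monte_carlo_table(spec: DGPSpec, iterations: int, seed) -> pd.DataFrame:
    """Like :func:`run_monte_carlo` but as a flat per-iteration table."""
    rows = [
        (i, n, gamma, f.coefficient, f.std_error, f.t_stat, f.p_value)
        for i, n, gamma, f in _iterate(spec, iterations, seed)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "iteration",
            "n",
            "gamma",
            "coefficient",
            "std_error",
            "t_stat",
            "p_value",
        ],
    )


def significant_share(p_values, alpha: float = 0.05) -> float:
    """Fraction of two-sided p-values strictly below ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidParameterError("no p-values given")
    return float(np.mean(p < alpha))
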