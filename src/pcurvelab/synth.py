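"""Synthetic growth-table generator.

Emulates the statistical structure the specification-search arm relies
on: a cross-country table with one outcome, one variable of interest
whose true coefficient is exactly zero, and 15 adjusting variables that
are mutually correlated and correlated with the variable of interest —
enough confounding for sub-models to pick up omitted-variable bias of a
known sign.

The default calibration (frozen; see docs/methods.md):

* 99 countries, 15 adjusters;
* exchangeable correlations — 0.2 between any two adjusters, 0.3
  between the interest variable and each adjuster;
* the first 8 adjusters carry nonzero coefficients with magnitudes
  decaying geometrically from 1.25 (factor 0.75) and negative signs, so
  sub-models omitting them bias the interest coefficient downward
  (mirroring a disease-prevalence variable entangled with conditions
  that depress growth); the leading magnitude is calibrated once so
  that bias dominates sampling noise at 50–99 rows — weak confounding
  at these sample sizes leaves significant estimates clustered just
  under the threshold instead of piling up near zero;
* residual noise sd 1, baseline level 1.8 (an ordinary annualized
  growth percentage).

Marginal distributions are all Gaussian: the pipeline is sensitive only
to the correlation structure, not to units or to the binary nature of
some real-world adjusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .growth import ADJUSTER_NAMES, GrowthTable

__all__ = ["SyntheticGrowthSpec", "generate_growth_table", "default_spec"]

_DELTA_LEAD = 1.25
_DELTA_DECAY = 0.75
_DELTA_NONZERO = 8


def _default_delta(n_adjusters: int, sign: float) -> tuple[float, ...]:
    delta = np.zeros(n_adjusters)
    k = min(_DELTA_NONZERO, n_adjusters)
    delta[:k] = sign * _DELTA_LEAD * _DELTA_DECAY ** np.arange(k)
    return tuple(delta)


@dataclass
class SyntheticGrowthSpec:
    """Parameters of the synthetic cross-country growth table."""

    n_countries: int = 99
    n_adjusters: int = 15
    rho_adj: float = 0.2  # adjuster-adjuster correlation
    rho_int: float = 0.3  # interest-adjuster correlation
    delta: tuple[float, ...] | None = None  # adjuster coefficients
    interest_coefficient: float = 0.0
    baseline: float = 1.8
    noise_sd: float = 1.0
    correlation: np.ndarray | None = None  # full override, interest first

    def __post_init__(self) -> None:
        if self.n_countries <= self.n_adjusters + 2:
            raise InvalidParameterError(
                f"{self.n_countries} countries cannot support "
                f"{self.n_adjusters} adjusters"
            )
        if self.noise_sd <= 0:
            raise InvalidParameterError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.delta is None:
            self.delta = _default_delta(self.n_adjusters, sign=-1.0)
        self.delta = tuple(float(d) for d in self.delta)
        if len(self.delta) != self.n_adjusters:
            raise InvalidParameterError(
                f"delta has {len(self.delta)} entries for "
                f"{self.n_adjusters} adjusters"
            )

    def correlation_matrix(self) -> np.ndarray:
        """(1 + n_adjusters) square correlation matrix, interest first."""
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
        else:
            p = self.n_adjusters + 1
            C = np.full((p, p), self.rho_adj)
            C[0, :] = C[:, 0] = self.rho_int
            np.fill_diagonal(C, 1.0)
        if C.shape != (self.n_adjusters + 1,) * 2 or not np.allclose(C, C.T):
            raise InvalidParameterError("correlation matrix has wrong shape/symmetry")
        return C

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.correlation_matrix())
        except np.linalg.LinAlgError as exc:
            raise InvalidParameterError(
                "correlation matrix is not positive definite"
            ) from exc

    def to_dict(self) -> dict:
        d = {
            "n_countries": self.n_countries,
            "n_adjusters": self.n_adjusters,
            "rho_adj": self.rho_adj,
            "rho_int": self.rho_int,
            "delta": list(self.delta),
            "interest_coefficient": self.interest_coefficient,
            "baseline": self.baseline,
            "noise_sd": self.noise_sd,
        }
        if self.correlation is not None:
            d["correlation"] = np.asarray(self.correlation).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticGrowthSpec":
        d = dict(d)
        if "correlation" in d and d["correlation"] is not None:
            d["correlation"] = np.asarray(d["correlation"], dtype=float)
        if "delta" in d and d["delta"] is not None:
            d["delta"] = tuple(d["delta"])
        return cls(**d)


def _column_names(n_adjusters: int) -> tuple[str, ...]:
    if n_adjusters == len(ADJUSTER_NAMES):
        return ADJUSTER_NAMES
    return tuple(f"A{i + 1:02d}" for i in range(n_adjusters))


def generate_growth_table(
    spec: SyntheticGrowthSpec, rng: np.random.Generator | int | None = None
) -> GrowthTable:
    """Draw one table from the spec: correlated regressors, known truth.

    Regressors are multivariate normal with the spec's correlation
    structure; the outcome is the linear predictor plus Gaussian noise.
    The full-model interest estimate is unbiased for
    ``interest_coefficient`` (zero by default).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    L = spec.cholesky()
    n = spec.n_countries
    Z = rng.standard_normal((n, spec.n_adjusters + 1)) @ L.T
    interest = Z[:, 0]
    adjusters = Z[:, 1:]
    outcome = (
        spec.baseline
        + spec.interest_coefficient * interest
        + adjusters @ np.asarray(spec.delta)
        + spec.noise_sd * rng.standard_normal(n)
    )
    names = _column_names(spec.n_adjusters)
    data = pd.DataFrame(adjusters, columns=list(names))
    data.insert(0, "MALARIA", interest)
    data.insert(0, "GR6096", outcome)
    data.index = pd.Index([f"C{i + 1:03d}" for i in range(n)], name="COUNTRY")
    return GrowthTable(data, outcome="GR6096", interest="MALARIA", adjusters=names)


def default_spec(flavor: str = "null-effect") -> SyntheticGrowthSpec:
    """Frozen study-condition specs.

    ``null-effect``
        The stand-in for the real table: zero true interest effect with
        negative confounding, so a specification search finds negative
        significant estimates at a nontrivial rate.
    ``no-negative-hit``
        Mirror-image confounding (all adjuster coefficients positive, so
        omitted-variable bias on the interest variable is strictly
        positive): negative significant hits are vanishingly rare.  The
        guaranteed-failure fixture for the search.
    """
    if flavor == "null-effect":
        return SyntheticGrowthSpec()
    if flavor == "no-negative-hit":
        return SyntheticGrowthSpec(delta=_default_delta(15, sign=+1.0))
    raise InvalidParameterError(f"unknown flavor {flavor!r}")
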