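"""Lightweight ordinary-least-squares fits.

The simulation and specification-search arms of this package each fit
regressions by the hundreds of thousands, so the slope of interest is
computed directly from the normal equations rather than through a
model-object API.  Two entry points cover both arms:

* :func:`simple_slope` — bivariate regression (optionally with intercept),
  used by the omitted-variable Monte Carlo.
* :func:`gram_interest_fit` — multiple regression expressed through a
  precomputed Gram matrix ``X'X`` so that all-subsets searches can reuse
  one cross-product accumulation per country sample.

Two-sided p-values come from the Student t distribution with the
residual degrees of freedom (``scipy.special.stdtr``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import stdtr

from .errors import CollinearityError, DegenerateSampleError

__all__ = ["OLSFit", "simple_slope", "gram_interest_fit", "ols_full"]


@dataclass(frozen=True)
class OLSFit:
    """One fitted regression coefficient of interest with its inference."""

    coefficient: float
    std_error: float
    t_stat: float
    p_value: float
    n: int
    df_resid: int
    model_id: str | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _t_inference(coef: float, se: float, df: int) -> tuple[float, float]:
    if se > 0.0:
        t = coef / se
        p = 2.0 * stdtr(df, -abs(t))
    else:  # perfect fit: the slope is exact
        t = math.inf if coef >= 0 else -math.inf
        p = 0.0
    return t, p


def simple_slope(
    x: np.ndarray,
    y: np.ndarray,
    intercept: bool = True,
    model_id: str | None = None,
) -> OLSFit:
    """OLS slope of ``y`` on ``x`` with textbook closed-form inference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise DegenerateSampleError(f"need >= 3 paired observations, got {n}")
    if intercept:
        xc = x - x.mean()
        yc = y - y.mean()
        df = n - 2
    else:
        xc, yc = x, y
        df = n - 1
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise CollinearityError("regressor is constant")
    coef = float(xc @ yc) / sxx
    resid = yc - coef * xc
    rss = max(float(resid @ resid), 0.0)
    se = math.sqrt(rss / df / sxx)
    t, p = _t_inference(coef, se, df)
    return OLSFit(coef, se, t, p, n, df, model_id)


def gram_interest_fit(
    G: np.ndarray,
    g: np.ndarray,
    yty: float,
    n: int,
    interest_index: int = 1,
    model_id: str | None = None,
) -> OLSFit:
    """Fit from the normal equations ``G b = g`` (``G = X'X``, ``g = X'y``).

    Only the coefficient at ``interest_index`` receives inference.  Exact
    singularity raises :class:`CollinearityError`; so does a non-positive
    diagonal of the unscaled covariance (a numerical rank-deficiency
    symptom).
    """
    p = G.shape[0]
    df = n - p
    if df <= 0:
        raise DegenerateSampleError(f"n={n} rows for {p} coefficients")
    rhs = np.zeros((p, 2))
    rhs[:, 0] = g
    rhs[interest_index, 1] = 1.0
    try:
        sol = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(f"singular design: {exc}") from exc
    beta = sol[:, 0]
    ginv_jj = sol[interest_index, 1]
    if not np.isfinite(ginv_jj) or ginv_jj <= 0.0 or not np.all(np.isfinite(beta)):
        raise CollinearityError("numerically rank-deficient design")
    rss = max(yty - float(g @ beta), 0.0)
    coef = float(beta[interest_index])
    se = math.sqrt(rss / df * ginv_jj)
    t, pval = _t_inference(coef, se, df)
    return OLSFit(coef, se, t, pval, n, df, model_id)


def ols_full(X: np.ndarray, y: np.ndarray):
    """Full multiple-OLS fit; returns ``(beta, se, resid, df)``.

    Used where every coefficient matters (null-outcome construction).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise DegenerateSampleError(f"n={n} rows for {p} coefficients")
    G = X.T @ X
    try:
        beta = np.linalg.solve(G, X.T @ y)
        ginv_diag = np.diag(np.linalg.inv(G))
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(f"singular design: {exc}") from exc
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * ginv_diag)
    return beta, se, resid, df
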