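"""Specification search on cross-country growth regressions.

This module implements the empirical arm of the package: the effect of
malaria prevalence in 1966 on annualized real GDP per-capita growth
1960–1996, regressed across countries with varying sets of adjusting
variables.  The stages are

1. null-outcome construction — refit the full model (outcome on the
   variable of interest plus all 15 adjusters), then rebuild the outcome
   with the interest coefficient forced to zero, so the truth is an
   exact null while the rest of the data's correlation structure
   survives;
2. model-space enumeration — all C(15, 6) = 5,005 subsets of six
   adjusters around the interest variable (the typical growth-regression
   model size);
3. vibration analysis — every model on many random country samples,
   classifying estimates by sign × significance;
4. p-hacking search — browse models in random order per country sample
   and harvest the first negative, significant estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.special import stdtr

from .errors import (
    CollinearityError,
    DegenerateSampleError,
    InvalidParameterError,
    SearchExhaustedError,
)
from .ols import OLSFit, gram_interest_fit, ols_full
from .pcurve import PCurve, build_pcurve

__all__ = [
    "ADJUSTER_NAMES",
    "GrowthTable",
    "ModelSpec",
    "NullOutcomeResult",
    "VibrationResult",
    "HackingConfig",
    "HackedEstimateSet",
    "construct_null_outcome",
    "enumerate_models",
    "fit_growth_model",
    "vibration_analysis",
    "phack_search",
]

#: Adjusting variables of the full growth model, in canonical order.
ADJUSTER_NAMES: tuple[str, ...] = (
    "OPEN",
    "FERTILITY",
    "GDP60",
    "HIGHER.EDU",
    "INV.PRICE",
    "LIFE.EXP",
    "PRIM.EDU",
    "POL.RIGHTS",
    "POP",
    "TROPICA",
    "TRADE",
    "BRIT.COL",
    "SPAIN.COL",
    "AREA.WATER",
    "PUBLIC.INV",
)


@dataclass
class GrowthTable:
    """Complete-case table: outcome + variable of interest + adjusters.

    ``data`` is indexed by country id; all used columns must be free of
    missing values.
    """

    data: pd.DataFrame
    outcome: str = "GR6096"
    interest: str = "MALARIA"
    adjusters: tuple[str, ...] = ADJUSTER_NAMES

    def __post_init__(self) -> None:
        self.adjusters = tuple(self.adjusters)
        used = [self.outcome, self.interest, *self.adjusters]
        if len(set(used)) != len(used):
            raise InvalidParameterError("column roles overlap")
        missing = [c for c in used if c not in self.data.columns]
        if missing:
            raise InvalidParameterError(f"columns absent from table: {missing}")
        if not self.data.index.is_unique:
            raise InvalidParameterError("country ids must be unique")
        if self.data[used].isna().any().any():
            raise InvalidParameterError("used columns contain missing values")
        if self.n <= len(self.adjusters) + 2:
            raise InvalidParameterError(
                f"{self.n} rows cannot support {len(self.adjusters)} adjusters"
            )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def country_ids(self) -> pd.Index:
        return self.data.index

    def outcome_values(self) -> np.ndarray:
        return self.data[self.outcome].to_numpy(dtype=float)

    def interest_values(self) -> np.ndarray:
        return self.data[self.interest].to_numpy(dtype=float)

    def full_design(self) -> np.ndarray:
        """[1, interest, all adjusters] column-wise."""
        return np.column_stack(
            [
                np.ones(self.n),
                self.interest_values(),
                self.data[list(self.adjusters)].to_numpy(dtype=float),
            ]
        )

    def with_outcome(self, values: np.ndarray) -> "GrowthTable":
        data = self.data.copy()
        data[self.outcome] = np.asarray(values, dtype=float)
        return GrowthTable(data, self.outcome, self.interest, self.adjusters)


@dataclass(frozen=True)
class ModelSpec:
    """One regression specification: k adjusters around the interest var."""

    adjusters: tuple[str, ...]
    indices: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.adjusters)

    @property
    def model_id(self) -> str:
        return "+".join(self.adjusters) if self.adjusters else "<none>"


def enumerate_models(adjusters, k: int) -> list[ModelSpec]:
    """All C(n, k) adjuster subsets in lexicographic index order.

    ``adjusters`` may be a count (columns then named A01, A02, ...) or a
    sequence of names.
    """
    names = (
        tuple(f"A{i + 1:02d}" for i in range(adjusters))
        if isinstance(adjusters, int)
        else tuple(adjusters)
    )
    if k < 0 or k > len(names):
        raise InvalidParameterError(f"k={k} outside [0, {len(names)}]")
    return [
        ModelSpec(adjusters=tuple(names[i] for i in idx), indices=tuple(idx))
        for idx in combinations(range(len(names)), k)
    ]


@dataclass
class NullOutcomeResult:
    """Outcome rebuilt with the interest coefficient forced to zero."""

    new_outcome: pd.Series
    full_fit: pd.Series  # all full-model coefficients, interest zeroed
    correlation_old_new: float
    beta_star_hat: float
    beta_star_p: float
    table: GrowthTable = field(repr=False)

    def table_with_null_outcome(self) -> GrowthTable:
        """The input table with its outcome replaced by the null outcome."""
        return self.table.with_outcome(self.new_outcome.to_numpy())


def _rank_check(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # QR with column pivoting: the trailing pivots are the dependent columns
        _, _, piv = qr(X, mode="economic", pivoting=True)
        offending = [names[j] for j in piv[rank:]]
        raise CollinearityError(
            f"design is rank deficient (rank {rank} of {X.shape[1]}); "
            f"offending columns: {offending}",
            columns=tuple(offending),
        )


def construct_null_outcome(table: GrowthTable) -> NullOutcomeResult:
    """Zero out the interest coefficient while keeping everything else.

    Fits the full model, then sets
    ``new_outcome = outcome - beta_star_hat * interest`` — identical to
    rebuilding the outcome from the intercept, adjuster terms, and
    residuals with the interest term dropped.  Refitting on the new
    outcome returns an interest coefficient of zero (to rounding) and
    unchanged adjuster estimates and residuals.
    """
    X = table.full_design()
    names = ["const", table.interest, *table.adjusters]
    _rank_check(X, names)
    y = table.outcome_values()
    beta, se, resid, df = ols_full(X, y)
    beta_star_hat = float(beta[1])
    t = beta_star_hat / se[1]
    beta_star_p = float(2.0 * stdtr(df, -abs(t)))
    new = y - beta_star_hat * table.interest_values()
    full_fit = pd.Series(beta, index=names)
    full_fit[table.interest] = 0.0
    corr = float(np.corrcoef(y, new)[0, 1])
    return NullOutcomeResult(
        new_outcome=pd.Series(new, index=table.country_ids, name=f"{table.outcome}_new"),
        full_fit=full_fit,
        correlation_old_new=corr,
        beta_star_hat=beta_star_hat,
        beta_star_p=beta_star_p,
        table=table,
    )


class _GramFitter:
    """Shared cross-product plumbing for all-subsets fits on row samples.

    For a fixed row sample the Gram matrix of the *full* design is
    accumulated once; each model then solves its normal equations on the
    relevant submatrix — numerically identical to refitting from the raw
    columns.  :meth:`fit_all` stacks those solves across all models
    (one batched LAPACK call), which is what makes 5,005-model sweeps
    over thousands of samples tractable.
    """

    def __init__(self, table: GrowthTable, models: list[ModelSpec]):
        self.table = table
        self.models = models
        self.M = table.full_design()
        self.y = table.outcome_values()
        self.index_arrays = [
            np.array((0, 1) + tuple(2 + j for j in m.indices), dtype=np.intp)
            for m in models
        ]
        # all models share one k, so the index arrays stack rectangularly
        self.IX = np.vstack(self.index_arrays)

    def sample(self, rows: np.ndarray | None):
        if rows is None:
            Ms, ys = self.M, self.y
        else:
            Ms, ys = self.M[rows], self.y[rows]
        G = Ms.T @ Ms
        g = Ms.T @ ys
        yty = float(ys @ ys)
        n = len(ys)
        return G, g, yty, n

    def fit(self, G, g, yty, n, model_pos: int) -> OLSFit:
        ix = self.index_arrays[model_pos]
        return gram_interest_fit(
            G[np.ix_(ix, ix)],
            g[ix],
            yty,
            n,
            interest_index=1,
            model_id=self.models[model_pos].model_id,
        )

    def fit_all(self, G, g, yty, n, which: np.ndarray | None = None):
        """Vectorized fits for ``which`` model positions (default: all).

        Returns ``(coef, se, p_value, valid)`` arrays; invalid entries
        mark rank-deficient submatrices (the caller's skip semantics).
        """
        IX = self.IX if which is None else self.IX[which]
        m, p = IX.shape
        df = n - p
        if df <= 0:
            raise DegenerateSampleError(f"n={n} rows for {p} coefficients")
        Gs = G[IX[:, :, None], IX[:, None, :]]
        gs = g[IX]
        rhs = np.zeros((m, p, 2))
        rhs[:, :, 0] = gs
        rhs[:, 1, 1] = 1.0
        try:
            sol = np.linalg.solve(Gs, rhs)
        except np.linalg.LinAlgError:
            return self._fit_all_fallback(G, g, yty, n, IX, df)
        beta = sol[:, :, 0]
        ginv_jj = sol[:, 1, 1]
        rss = np.clip(yty - np.einsum("mp,mp->m", gs, beta), 0.0, None)
        valid = (
            np.isfinite(beta).all(axis=1)
            & np.isfinite(ginv_jj)
            & (ginv_jj > 0.0)
            & np.isfinite(rss)
        )
        coef = beta[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(rss / df * ginv_jj)
            t = np.where(se > 0, coef / se, np.sign(coef) * np.inf)
            pv = np.where(se > 0, 2.0 * stdtr(df, -np.abs(t)), 0.0)
        return coef, se, pv, valid

    def _fit_all_fallback(self, G, g, yty, n, IX, df):
        # some submatrix is exactly singular: redo model-by-model
        m = len(IX)
        coef = np.full(m, np.nan)
        se = np.full(m, np.nan)
        pv = np.full(m, np.nan)
        valid = np.zeros(m, dtype=bool)
        for i, ix in enumerate(IX):
            try:
                fit = gram_interest_fit(
                    G[np.ix_(ix, ix)], g[ix], yty, n, interest_index=1
                )
            except CollinearityError:
                continue
            coef[i], se[i], pv[i], valid[i] = (
                fit.coefficient,
                fit.std_error,
                fit.p_value,
                True,
            )
        return coef, se, pv, valid


def fit_growth_model(
    table: GrowthTable, model: ModelSpec, rows: np.ndarray | None = None
) -> OLSFit:
    """OLS of the outcome on [1, interest, model adjusters] over ``rows``."""
    n_rows = table.n if rows is None else len(rows)
    if n_rows <= model.k + 2:
        raise DegenerateSampleError(
            f"{n_rows} rows cannot support {model.k} adjusters"
        )
    fitter = _GramFitter(table, [model])
    return fitter.fit(*fitter.sample(rows), model_pos=0)


@dataclass
class VibrationResult:
    """All estimates across country samples × model specifications."""

    records: pd.DataFrame  # sample_id, model_id, n, coefficient, p_value, transformed_p
    shares: dict
    quantiles: dict
    n_samples: int
    n_models: int
    n_skipped: int
    alpha: float

    @property
    def n_estimates(self) -> int:
        return len(self.records)

    @property
    def planned_fits(self) -> int:
        return self.n_samples * self.n_models


def _classify(coef: np.ndarray, p: np.ndarray, alpha: float) -> dict:
    neg = coef < 0
    sig = p < alpha
    total = len(coef)
    return {
        "negative_significant": float(np.sum(neg & sig) / total),
        "negative_insignificant": float(np.sum(neg & ~sig) / total),
        "positive_significant": float(np.sum(~neg & sig) / total),
        "positive_insignificant": float(np.sum(~neg & ~sig) / total),
    }


def vibration_analysis(
    table: GrowthTable,
    n_samples: int = 100,
    size_range: tuple[int, int] = (50, 99),
    k: int = 6,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> VibrationResult:
    """Fit every k-adjuster model on each of ``n_samples`` country samples.

    Country samples are drawn without replacement with sizes from a
    discrete uniform over ``size_range``.  Rank-deficient (sample, model)
    pairs are skipped and counted in ``n_skipped``.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if n_samples < 1:
        raise InvalidParameterError(f"n_samples must be >= 1, got {n_samples}")
    lo, hi = size_range
    if not (k + 3 <= lo <= hi <= table.n):
        raise InvalidParameterError(
            f"size_range {size_range} incompatible with table of {table.n} rows"
        )
    models = enumerate_models(table.adjusters, k)
    fitter = _GramFitter(table, models)
    all_ids = np.array([m.model_id for m in models])
    sample_ids, model_ids, ns, coefs, ps = [], [], [], [], []
    n_skipped = 0
    for s in range(n_samples):
        size = int(rng.integers(lo, hi + 1))
        rows = rng.choice(table.n, size=size, replace=False)
        G, g, yty, n = fitter.sample(rows)
        coef_s, _, pv_s, valid = fitter.fit_all(G, g, yty, n)
        n_skipped += int(np.sum(~valid))
        sample_ids.append(np.full(int(valid.sum()), s))
        model_ids.append(all_ids[valid])
        ns.append(np.full(int(valid.sum()), n))
        coefs.append(coef_s[valid])
        ps.append(pv_s[valid])
    sample_ids = np.concatenate(sample_ids)
    model_ids = np.concatenate(model_ids)
    ns = np.concatenate(ns)
    coefs = np.concatenate(coefs)
    ps = np.concatenate(ps)
    transformed = -np.log10(np.clip(ps, 1e-300, None))
    records = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "model_id": model_ids,
            "n": ns,
            "coefficient": coefs,
            "p_value": ps,
            "transformed_p": transformed,
        }
    )
    qs = [1, 50, 99]
    quantiles = {
        "coefficient": dict(zip(qs, np.percentile(coefs, qs))),
        "transformed_p": dict(zip(qs, np.percentile(transformed, qs))),
    }
    return VibrationResult(
        records=records,
        shares=_classify(coefs, ps, alpha),
        quantiles=quantiles,
        n_samples=n_samples,
        n_models=len(models),
        n_skipped=n_skipped,
        alpha=alpha,
    )


@dataclass
class HackingConfig:
    """Parameters of the sequential specification search."""

    alpha: float = 0.05
    target_sign: str = "negative"
    n_hacked: int = 100_000
    sample_size_range: tuple[int, int] = (50, 99)
    k: int = 6
    full_sample: bool = False
    max_attempts: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_hacked < 1:
            raise InvalidParameterError(f"n_hacked must be >= 1, got {self.n_hacked}")
        if self.target_sign not in ("negative", "positive"):
            raise InvalidParameterError(f"unknown target_sign {self.target_sign!r}")
        if self.max_attempts is None:
            self.max_attempts = 100 * self.n_hacked
        if self.max_attempts < self.n_hacked:
            raise InvalidParameterError("max_attempts must be >= n_hacked")


@dataclass
class HackedEstimateSet:
    """Harvest of the specification search: only sign-matching p < alpha."""

    records: pd.DataFrame  # hit_index, sample_id, model_id, n, coefficient, ...
    n_attempts: int
    config: HackingConfig

    @property
    def p_values(self) -> np.ndarray:
        return self.records["p_value"].to_numpy()

    @property
    def coefficients(self) -> np.ndarray:
        return self.records["coefficient"].to_numpy()

    def pcurve(self, n_bins: int = 5) -> PCurve:
        return build_pcurve(self.p_values, alpha=self.config.alpha, n_bins=n_bins)


def phack_search(
    table: GrowthTable,
    config: HackingConfig,
    rng: np.random.Generator | int | None = None,
) -> HackedEstimateSet:
    """Harvest significant, sign-matching estimates by specification search.

    Each attempt draws a country sample (or uses the full table when
    ``config.full_sample``), then browses the k-adjuster models in a
    fresh uniformly random order; the first estimate with the target
    sign and p < alpha is kept and a new sample is drawn.  Samples
    yielding no hit contribute nothing.  Raises
    :class:`SearchExhaustedError` (carrying the partial harvest) if
    ``max_attempts`` samples pass before ``n_hacked`` hits accumulate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = config.sample_size_range
    if not config.full_sample and not (config.k + 3 <= lo <= hi <= table.n):
        raise InvalidParameterError(
            f"sample_size_range {config.sample_size_range} incompatible "
            f"with table of {table.n} rows"
        )
    models = enumerate_models(table.adjusters, config.k)
    fitter = _GramFitter(table, models)
    negative = config.target_sign == "negative"
    full_gram = fitter.sample(None) if config.full_sample else None

    rows_out: list[tuple] = []
    attempts = 0
    scan = 32  # browse this many models one-by-one before batch-fitting the rest
    while len(rows_out) < config.n_hacked and attempts < config.max_attempts:
        attempts += 1
        if config.full_sample:
            G, g, yty, n = full_gram
        else:
            size = int(rng.integers(lo, hi + 1))
            rows = rng.choice(table.n, size=size, replace=False)
            G, g, yty, n = fitter.sample(rows)
        perm = rng.permutation(len(models))
        hit_fit = None
        for m in perm[:scan]:
            try:
                fit = fitter.fit(G, g, yty, n, int(m))
            except CollinearityError:
                continue  # treat as a non-hit and keep browsing
            if fit.p_value < config.alpha and (
                fit.coefficient < 0 if negative else fit.coefficient > 0
            ):
                hit_fit = (fit.model_id, fit.coefficient, fit.std_error, fit.p_value)
                break
        if hit_fit is None and len(perm) > scan:
            rest = perm[scan:]
            coef, se, pv, valid = fitter.fit_all(G, g, yty, n, which=rest)
            sign_ok = coef < 0 if negative else coef > 0
            winners = np.flatnonzero(valid & sign_ok & (pv < config.alpha))
            if winners.size:
                w = int(winners[0])  # first hit in browse order
                hit_fit = (
                    models[int(rest[w])].model_id,
                    float(coef[w]),
                    float(se[w]),
                    float(pv[w]),
                )
        if hit_fit is not None:
            model_id, coefficient, std_error, p_value = hit_fit
            rows_out.append(
                (
                    len(rows_out),
                    attempts - 1,
                    model_id,
                    n,
                    coefficient,
                    std_error,
                    p_value,
                )
            )

    records = pd.DataFrame(
        rows_out,
        columns=[
            "hit_index",
            "sample_id",
            "model_id",
            "n",
            "coefficient",
            "std_error",
            "p_value",
        ],
    )
    if len(rows_out) < config.n_hacked:
        raise SearchExhaustedError(
            f"only {len(rows_out)} of {config.n_hacked} hits after "
            f"{attempts} country samples",
            hits=records,
        )
    return HackedEstimateSet(records=records, n_attempts=attempts, config=config)
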