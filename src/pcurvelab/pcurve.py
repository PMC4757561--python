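"""p-curves: the distribution of statistically significant p-values.

A p-curve bins the p-values that fall strictly below a significance
threshold ``alpha`` into left-open, right-closed intervals partitioning
(0, alpha] — by default five bins of width 0.01 over (0, 0.05].  Under
an unbiased exact null the p-curve is flat (each bin holds 1/n_bins of
the significant mass); mass piling up near zero ("right skew") is the
pattern conventionally read as evidence of true effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError, UndefinedSkewError

__all__ = ["PCurve", "build_pcurve", "skew_summary"]


@dataclass(frozen=True)
class PCurve:
    bin_edges: np.ndarray  # length n_bins + 1, from 0 to alpha
    bin_counts: np.ndarray
    bin_shares: np.ndarray  # fractions of the *significant* mass
    n_significant: int
    n_total: int
    alpha: float

    @property
    def n_bins(self) -> int:
        return len(self.bin_counts)

    @property
    def share_significant(self) -> float:
        return self.n_significant / self.n_total

    @property
    def uniform_reference(self) -> float:
        """Bin share under a hypothetical uniform p-value distribution."""
        return 1.0 / self.n_bins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.bin_counts,
                "share": self.bin_shares,
                "uniform_reference": self.uniform_reference,
            }
        )


def build_pcurve(p_values, alpha: float = 0.05, n_bins: int = 5) -> PCurve:
    """Bin the significant part of ``p_values`` over (0, alpha].

    p-values at or above ``alpha`` are excluded from the bins but still
    count toward ``n_total`` (and hence ``share_significant``).  A
    p-value of exactly ``alpha`` is not significant (strict inequality).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise EmptyInputError("no p-values given")
    if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise InvalidParameterError("p-values must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    if n_bins < 2:
        raise InvalidParameterError(f"need at least 2 bins, got {n_bins}")
    edges = np.linspace(0.0, alpha, n_bins + 1)
    sig = p[p < alpha]
    # digitize(right=True): edges[i-1] < p <= edges[i]; p == 0 goes to bin 0
    idx = np.clip(np.digitize(sig, edges, right=True) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    shares = counts / sig.size if sig.size else np.zeros(n_bins)
    return PCurve(
        bin_edges=edges,
        bin_counts=counts,
        bin_shares=shares,
        n_significant=int(sig.size),
        n_total=int(p.size),
        alpha=alpha,
    )


def skew_summary(curve: PCurve, margin: float = 0.0) -> dict:
    """Descriptive skew classification of a p-curve.

    ``direction`` is "right" when the first bin outweighs the last by
    more than ``margin``, "left" in the mirror case, "flat" otherwise.
    ``monotone_decreasing`` flags non-increasing shares left to right.
    """
    if curve.n_significant == 0:
        raise UndefinedSkewError("no significant p-values: skew undefined")
    if curve.n_bins < 2:
        raise InvalidParameterError("need at least 2 bins to assess skew")
    first = float(curve.bin_shares[0])
    last = float(curve.bin_shares[-1])
    if first - last > margin:
        direction = "right"
    elif last - first > margin:
        direction = "left"
    else:
        direction = "flat"
    return {
        "direction": direction,
        "first_bin_share": first,
        "last_bin_share": last,
        "monotone_decreasing": bool(np.all(np.diff(curve.bin_shares) <= 1e-12)),
    }
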