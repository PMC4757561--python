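"""Optional figure rendering (the canonical exports are the CSVs)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .growth import VibrationResult
from .pcurve import PCurve

__all__ = ["plot_pcurve", "plot_vibration"]


def plot_pcurve(curve: PCurve, path, title: str = "") -> Path:
    """Bar chart of bin shares with the dashed uniform reference line."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    centers = (curve.bin_edges[:-1] + curve.bin_edges[1:]) / 2
    width = np.diff(curve.bin_edges)
    ax.bar(centers, curve.bin_shares, width=width * 0.9, color="#4477aa")
    ax.axhline(curve.uniform_reference, linestyle="--", color="grey")
    ax.set_xlabel("p-value")
    ax.set_ylabel("share of significant p-values")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_vibration(result: VibrationResult, path, title: str = "") -> Path:
    """Estimates vs -log10(p) with 1/50/99% quantile guides."""
    fig, ax = plt.subplots(figsize=(4.8, 3.6))
    r = result.records
    ax.scatter(r["coefficient"], r["transformed_p"], s=2, alpha=0.15, linewidths=0)
    ax.axhline(-np.log10(result.alpha), color="black", lw=1)
    for q in result.quantiles["coefficient"].values():
        ax.axvline(q, linestyle="--", color="grey", lw=0.8)
    for q in result.quantiles["transformed_p"].values():
        ax.axhline(q, linestyle="--", color="grey", lw=0.8)
    ax.set_xlabel("estimate")
    ax.set_ylabel("-log10(p)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
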