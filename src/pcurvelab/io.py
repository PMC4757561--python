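"""File I/O: growth-table CSVs, p-value files, result exports, manifests.

CSV dialect is fixed: comma-separated, header row, "." decimal, UTF-8.
Column headers are matched case-insensitively with "." and "_" treated
as equivalent, so ``HIGHER.EDU``, ``higher_edu`` and ``Higher.Edu`` all
resolve to the same role.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError
from .growth import ADJUSTER_NAMES, GrowthTable, VibrationResult
from .pcurve import PCurve

__all__ = [
    "DEFAULT_COLUMN_MAPPING",
    "read_growth_csv",
    "write_growth_csv",
    "read_pvalues_csv",
    "write_pcurve_csv",
    "write_json",
    "write_manifest",
]

DEFAULT_COLUMN_MAPPING = {
    "outcome": "GR6096",
    "interest": "MALARIA",
    "adjusters": list(ADJUSTER_NAMES),
    "country": "COUNTRY",
}


def _normalize(name: str) -> str:
    return name.strip().casefold().replace("_", ".")


def read_growth_csv(
    path,
    column_mapping: dict | None = None,
    min_rows: int = 20,
) -> GrowthTable:
    """Load a growth table, applying complete-case filtering.

    ``column_mapping`` maps roles to column names:
    ``{"outcome": ..., "interest": ..., "adjusters": [...], "country": ...}``
    (the ``country`` key is optional).  Rows with a missing value in any
    mapped column are dropped; fewer than ``min_rows`` survivors raise
    :class:`InsufficientDataError`.
    """
    mapping = dict(DEFAULT_COLUMN_MAPPING if column_mapping is None else column_mapping)
    df = pd.read_csv(path)
    lookup: dict[str, str] = {}
    for col in df.columns:
        lookup.setdefault(_normalize(col), col)

    def resolve(name: str, required: bool = True) -> str | None:
        actual = lookup.get(_normalize(name))
        if actual is None and required:
            raise SchemaError(
                f"column {name!r} not found; available headers: {list(df.columns)}"
            )
        return actual

    outcome = resolve(mapping["outcome"])
    interest = resolve(mapping["interest"])
    adjusters = [resolve(a) for a in mapping["adjusters"]]
    country = resolve(mapping.get("country", "COUNTRY"), required=False)
    if country is not None:
        df = df.set_index(country)
        df.index.name = "COUNTRY"
    used = [outcome, interest, *adjusters]
    complete = df.dropna(subset=used)
    n_dropped = len(df) - len(complete)
    if len(complete) < max(min_rows, len(adjusters) + 3):
        raise InsufficientDataError(
            f"only {len(complete)} complete rows after dropping {n_dropped}"
        )
    table = GrowthTable(
        complete[used].astype(float),
        outcome=outcome,
        interest=interest,
        adjusters=tuple(adjusters),
    )
    return table


def write_growth_csv(table: GrowthTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index_label="COUNTRY")
    return path


def read_pvalues_csv(path, column: str | None = None) -> np.ndarray:
    """Read p-values from a CSV: single column, or a named column."""
    df = pd.read_csv(path)
    if column is None:
        column = "p_value" if "p_value" in df.columns else df.columns[0]
    if column not in df.columns:
        raise SchemaError(
            f"column {column!r} not found; available headers: {list(df.columns)}"
        )
    return df[column].to_numpy(dtype=float)


def write_pcurve_csv(curve: PCurve, path) -> Path:
    """Bar-chart-ready export, including the uniform reference level."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curve.to_frame().to_csv(path, index=False)
    return path


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path


def _versions() -> dict:
    from . import __version__

    return {
        "pcurvelab": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }


def write_manifest(out_dir, command: str, config: dict, seed, counts: dict) -> Path:
    """Reproducibility manifest written beside every command's outputs."""
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "counts": counts,
        "versions": _versions(),
    }
    return write_json(manifest, Path(out_dir) / "manifest.json")


def vibration_to_csv(result: VibrationResult, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(path, index=False)
    return path
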