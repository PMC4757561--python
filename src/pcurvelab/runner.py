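"""Command runner: validated configs in, artifact files + manifest out.

Each command writes its result CSVs/JSON plus a ``manifest.json``
(config echo, seed, row counts, versions) into its output directory, so
every output file is reproducible from the manifest alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .errors import InvalidParameterError
from .growth import HackingConfig, construct_null_outcome, phack_search, vibration_analysis
from .pcurve import build_pcurve, skew_summary
from .simulation import DGPSpec, monte_carlo_table
from .synth import SyntheticGrowthSpec, default_spec, generate_growth_table

__all__ = ["RunConfig", "run_command", "COMMANDS"]

COMMANDS = ("simulate", "pcurve", "vibration", "phack", "synth")


@dataclass
class RunConfig:
    command: str
    out_dir: Path
    params: dict = field(default_factory=dict)
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise InvalidParameterError(
                f"unknown command {self.command!r}; expected one of {COMMANDS}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        self.out_dir = Path(self.out_dir)


def _spec_from_params(params: dict) -> DGPSpec:
    keys = ("beta_star", "cov_xz", "gamma_max", "rho_max", "n_min", "n_max", "intercept")
    return DGPSpec(**{k: params[k] for k in keys if k in params})


def _run_simulate(cfg: RunConfig) -> dict:
    iterations = int(cfg.params.get("iterations", 20_000))
    n_bins = int(cfg.params.get("n_bins", 5))
    spec = _spec_from_params(cfg.params)
    frame = monte_carlo_table(spec, iterations, cfg.seed)
    curve = build_pcurve(frame["p_value"], alpha=cfg.alpha, n_bins=n_bins)
    out = cfg.out_dir
    paths = {
        "iterations": out / "iterations.csv",
        "pcurve": out / "pcurve.csv",
        "summary": out / "summary.json",
    }
    out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(paths["iterations"], index=False)
    pio.write_pcurve_csv(curve, paths["pcurve"])
    pio.write_json(
        {
            "share_significant": curve.share_significant,
            "n_significant": curve.n_significant,
            "n_total": curve.n_total,
            "bin_shares": curve.bin_shares.tolist(),
            "gamma_max": spec.gamma_max,
        },
        paths["summary"],
    )
    pio.write_manifest(
        out,
        "simulate",
        {**cfg.params, "iterations": iterations, "alpha": cfg.alpha},
        cfg.seed,
        {"iterations": iterations, "n_significant": curve.n_significant},
    )
    return paths


def _run_pcurve(cfg: RunConfig) -> dict:
    path = cfg.params["input"]
    n_bins = int(cfg.params.get("n_bins", 5))
    p = pio.read_pvalues_csv(path, cfg.params.get("column"))
    curve = build_pcurve(p, alpha=cfg.alpha, n_bins=n_bins)
    out = cfg.out_dir
    paths = {"pcurve": out / "pcurve.csv", "summary": out / "summary.json"}
    pio.write_pcurve_csv(curve, paths["pcurve"])
    pio.write_json(
        {
            "share_significant": curve.share_significant,
            "n_significant": curve.n_significant,
            "n_total": curve.n_total,
            "bin_shares": curve.bin_shares.tolist(),
            "skew": skew_summary(curve) if curve.n_significant else None,
        },
        paths["summary"],
    )
    pio.write_manifest(
        out,
        "pcurve",
        {"input": str(path), "n_bins": n_bins, "alpha": cfg.alpha},
        cfg.seed,
        {"n_total": curve.n_total},
    )
    return paths


def _load_table(cfg: RunConfig):
    table = pio.read_growth_csv(cfg.params["table"], cfg.params.get("column_mapping"))
    if cfg.params.get("null_outcome", True):
        result = construct_null_outcome(table)
        return result.table_with_null_outcome(), result
    return table, None


def _run_vibration(cfg: RunConfig) -> dict:
    table, null_result = _load_table(cfg)
    result = vibration_analysis(
        table,
        n_samples=int(cfg.params.get("n_samples", 100)),
        size_range=tuple(cfg.params.get("size_range", (50, 99))),
        k=int(cfg.params.get("k", 6)),
        alpha=cfg.alpha,
        rng=cfg.seed,
    )
    out = cfg.out_dir
    paths = {"vibration": out / "vibration.csv", "summary": out / "summary.json"}
    pio.vibration_to_csv(result, paths["vibration"])
    summary = {
        "shares": result.shares,
        "quantiles": result.quantiles,
        "n_samples": result.n_samples,
        "n_models": result.n_models,
        "n_estimates": result.n_estimates,
        "n_skipped": result.n_skipped,
    }
    if null_result is not None:
        summary["beta_star_hat"] = null_result.beta_star_hat
        summary["correlation_old_new"] = null_result.correlation_old_new
    pio.write_json(summary, paths["summary"])
    pio.write_manifest(
        out,
        "vibration",
        {k: v for k, v in cfg.params.items() if k != "column_mapping"},
        cfg.seed,
        {"n_estimates": result.n_estimates, "rows": table.n},
    )
    return paths


def _run_phack(cfg: RunConfig) -> dict:
    table, null_result = _load_table(cfg)
    hack_cfg = HackingConfig(
        alpha=cfg.alpha,
        target_sign=cfg.params.get("target_sign", "negative"),
        n_hacked=int(cfg.params.get("n_hacked", 10_000)),
        sample_size_range=tuple(cfg.params.get("size_range", (50, 99))),
        k=int(cfg.params.get("k", 6)),
        full_sample=bool(cfg.params.get("full_sample", False)),
        max_attempts=cfg.params.get("max_attempts"),
    )
    harvest = phack_search(table, hack_cfg, rng=cfg.seed)
    curve = harvest.pcurve()
    out = cfg.out_dir
    paths = {
        "hacked": out / "hacked.csv",
        "pcurve": out / "pcurve.csv",
        "summary": out / "summary.json",
    }
    out.mkdir(parents=True, exist_ok=True)
    harvest.records.to_csv(paths["hacked"], index=False)
    pio.write_pcurve_csv(curve, paths["pcurve"])
    pio.write_json(
        {
            "n_hacked": len(harvest.records),
            "n_attempts": harvest.n_attempts,
            "bin_shares": curve.bin_shares.tolist(),
            "skew": skew_summary(curve),
            "full_sample": hack_cfg.full_sample,
        },
        paths["summary"],
    )
    pio.write_manifest(
        out,
        "phack",
        {k: v for k, v in cfg.params.items() if k != "column_mapping"},
        cfg.seed,
        {"n_hacked": len(harvest.records), "n_attempts": harvest.n_attempts},
    )
    return paths


def _run_synth(cfg: RunConfig) -> dict:
    spec_params = cfg.params.get("spec")
    if spec_params:
        spec = SyntheticGrowthSpec.from_dict(spec_params)
    else:
        spec = default_spec(cfg.params.get("flavor", "null-effect"))
    table = generate_growth_table(spec, rng=cfg.seed)
    out = cfg.out_dir
    paths = {"table": out / "synthetic_growth.csv"}
    pio.write_growth_csv(table, paths["table"])
    pio.write_manifest(
        out, "synth", {"spec": spec.to_dict()}, cfg.seed, {"rows": table.n}
    )
    return paths


_DISPATCH = {
    "simulate": _run_simulate,
    "pcurve": _run_pcurve,
    "vibration": _run_vibration,
    "phack": _run_phack,
    "synth": _run_synth,
}


def run_command(config: RunConfig) -> dict:
    """Validate, dispatch, and return the mapping of artifact paths."""
    return _DISPATCH[config.command](config)
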