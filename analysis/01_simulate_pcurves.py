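#!/usr/bin/env python
"""Monte Carlo grid: p-curves from omitted-variable bias alone.

Sweeps the maximum expected confounded correlation rho_max over
{0.01, 0.05, 0.1} and the maximum sample size n_max over
{100, 1000, 10000} (add 100000 with --full), with a true effect of
exactly zero throughout.  Writes one p-curve per cell plus a grid
summary, and reports how the share of significant results and the
right-skew of the p-curve grow with bias strength and sample size.
"""

import argparse
from pathlib import Path

import pandas as pd

import pcurvelab as pl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--iterations", type=int, default=20_000)
    ap.add_argument("--full", action="store_true",
                    help="paper-scale run: 500,000 iterations, n_max up to 100,000")
    ap.add_argument("--out-dir", type=Path, default=Path("results/simulation"))
    args = ap.parse_args()

    iterations = 500_000 if args.full else args.iterations
    n_maxes = (100, 1000, 10_000, 100_000) if args.full else (100, 1000, 10_000)
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for rho in (0.01, 0.05, 0.1):
        for n_max in n_maxes:
            spec = pl.DGPSpec(rho_max=rho, n_min=50, n_max=n_max)
            frame = pl.monte_carlo_table(spec, iterations, args.seed)
            curve = pl.build_pcurve(frame["p_value"])
            pl.write_pcurve_csv(curve, out / f"pcurve_rho{rho}_nmax{n_max}.csv")
            rows.append(
                {
                    "rho_max": rho,
                    "n_max": n_max,
                    "gamma_max": spec.gamma_max,
                    "share_significant": curve.share_significant,
                    **{f"bin{i + 1}": s for i, s in enumerate(curve.bin_shares)},
                }
            )
            print(
                f"rho_max={rho:<5} n_max={n_max:<7} gamma_max={spec.gamma_max:.4f} "
                f"significant={curve.share_significant:6.2%}  "
                f"first bin={curve.bin_shares[0]:.3f} last bin={curve.bin_shares[-1]:.3f}"
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "grid_summary.csv", index=False)
    print(f"\nwrote {out / 'grid_summary.csv'}")
    print(
        "Reading: with a true effect of exactly zero, the share of significant\n"
        "results and the pile-up of p-values near zero both grow with the\n"
        "confounding strength (rho_max) and the sample size — a right-skewed\n"
        "p-curve indistinguishable from one generated by a real effect."
    )


if __name__ == "__main__":
    main()
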