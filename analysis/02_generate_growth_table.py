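#!/usr/bin/env python
"""Generate the synthetic cross-country growth table.

Writes a 99-row table in the layout the specification-search pipeline
expects: GR6096 (outcome), MALARIA (variable of interest, true effect
zero) and 15 correlated adjusting variables.  Drop-in stand-in for a
real growth dataset placed at the same path.
"""

import argparse
from pathlib import Path

import pcurvelab as pl


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--flavor", choices=["null-effect", "no-negative-hit"],
                    default="null-effect")
    ap.add_argument("--out", type=Path, default=Path("results/growth/synthetic_growth.csv"))
    args = ap.parse_args()

    spec = pl.default_spec(args.flavor)
    table = pl.generate_growth_table(spec, rng=args.seed)
    pl.write_growth_csv(table, args.out)
    print(f"wrote {args.out}: {table.n} countries, "
          f"{len(table.adjusters)} adjusters, flavor={args.flavor}")
    print(table.data.describe().loc[["mean", "std"]].round(3).to_string())


if __name__ == "__main__":
    main()
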