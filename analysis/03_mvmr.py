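#!/usr/bin/env python
"""Multivariable MR on correlated exposures.

Two demonstrations, each against the diagnosed outcome:

1. A correlated lipid-like pair (cross-effect correlation 0.6) with direct
   effects (0.2, 0): the univariable estimate for the null exposure inherits
   its partner's effect, while the multivariable direct effect recovers ~0 --
   the reason correlated lipid fractions are analyzed jointly in restricted
   adjustment sets rather than one at a time.
2. A blood-pressure-like pair with opposing direct effects (+0.02, -0.07 per
   10-unit reporting scale), where mutual adjustment separates effects that
   partially cancel univariably.

Writes results/mvmr.tsv.
"""

from pathlib import Path

import pandas as pd

from mrkit.estimators import ivw, mvmr
from mrkit.harmonize import harmonize, merge_multivariable
from mrkit.report import tidy_row
from mrkit.simulate import SimConfig, simulate_mv_exposures

OUT = Path("results")


def scenario(tag, seed, names, direct, corr, n_snv=120):
    cfg = SimConfig(seed=seed, n_snv=n_snv)
    tables, outcome, _ = simulate_mv_exposures(
        cfg, len(names), direct, corr)
    for t, name in zip(tables, names):
        t.trait_name = name
    rows = []
    for t, name, d in zip(tables, names, direct):
        est = ivw(harmonize(t, outcome))
        row = tidy_row(name, "ad_diagnosed", est)
        row.update(analysis=tag, model="univariable", true_direct=d)
        rows.append(row)
    res = mvmr(merge_multivariable(tables, outcome))
    for est, name, d in zip(res.exposures, names, direct):
        row = tidy_row(name, "ad_diagnosed", est)
        row.update(analysis=tag, model="multivariable", true_direct=d)
        rows.append(row)
    return rows


def main() -> None:
    rows = []
    rows += scenario("lipid_pair", 2101, ["hdl_like", "tg_like"], (0.2, 0.0), 0.6)
    rows += scenario("bp_pair", 2102, ["sbp_like", "dbp_like"], (0.02, -0.07), 0.7)
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "mvmr.tsv", sep="\t", index=False)
    print(f"wrote {len(df)} rows -> {OUT}/mvmr.tsv\n")
    for _, r in df.iterrows():
        print(f"  {r['analysis']:<11s} {r['model']:<14s} {r['exposure']:<10s} "
              f"b = {r['b']:+.3f} ({r['lo95']:+.3f}, {r['up95']:+.3f})  "
              f"[true direct {r['true_direct']:+.2f}]")
    print("\nthe univariable estimate for the null lipid exposure is biased "
          "toward its correlated partner; the multivariable direct effect "
          "brackets zero.")


if __name__ == "__main__":
    main()
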