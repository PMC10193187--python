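#!/usr/bin/env python
"""GWAS-by-proxy ascertainment bias demonstration.

Simulates an education-like exposure with a protective effect on diagnosed
disease (true OR 0.83 per SD) alongside a proxy outcome built from parental
disease reports, where the respondent's own education raises the probability
of reporting. Across seeded replicates the diagnosed-outcome IVW estimate
stays protective while the proxy-outcome estimate flips harmful -- the
direction reversal that motivates caution with proxy-phenotype outcome sets.
Also shows the dilution-only regime (no reporting channel): attenuated but
same-signed. Writes results/proxy_bias.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mrkit.estimators import ivw
from mrkit.harmonize import harmonize
from mrkit.simulate import ProxySimConfig, simulate_proxy_pair

OUT = Path("results")
N_REP = 25


def replicate_block(tag, **overrides):
    rows = []
    for r in range(N_REP):
        cfg = ProxySimConfig(seed=3000 + r, **overrides)
        exposure, diagnosed, proxy, truth = simulate_proxy_pair(cfg)
        est_d = ivw(harmonize(exposure, diagnosed))
        est_p = ivw(harmonize(exposure, proxy))
        rows.append({"scenario": tag, "replicate": r,
                     "beta_diagnosed": est_d.beta, "se_diagnosed": est_d.se,
                     "beta_proxy": est_p.beta, "se_proxy": est_p.se,
                     "sign_flip": est_d.beta < 0 < est_p.beta})
    return rows


def main() -> None:
    rows = replicate_block("reporting_channel")          # default calibration
    rows += replicate_block("dilution_only", reporting_effect=0.0)
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "proxy_bias.tsv", sep="\t", index=False,
              float_format="%.6g")
    for tag, sub in df.groupby("scenario"):
        print(f"{tag}: mean diagnosed beta {sub['beta_diagnosed'].mean():+.3f}, "
              f"mean proxy beta {sub['beta_proxy'].mean():+.3f}, "
              f"sign flip in {sub['sign_flip'].mean():.0%} of {N_REP} replicates")
    print(f"\nwrote {len(df)} rows -> {OUT}/proxy_bias.tsv")


if __name__ == "__main__":
    main()
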