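"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

The global test asks whether the harmonized instrument set is more
heterogeneous than its sampling error allows. The observed statistic is the
leave-one-out weighted residual sum of squares

    RSS_obs = sum_j (beta_out_j - theta_hat(-j) * beta_exp_j)^2 / se_out_j^2,

where theta_hat(-j) is the fixed-effect IVW estimate with variant j held out
(so each variant is scored against an estimate it did not influence). Its null
distribution is built by parametric simulation: in each replicate
beta_out*_j ~ N(theta_hat(-j) * beta_exp_j, se_out_j) and
beta_exp*_j ~ N(beta_exp_j, se_exp_j), scored by the same statistic. Empirical
p-values follow the add-one rule, so the smallest attainable value is
1/(n_sim+1) and is reported as "< 1/(n_sim+1)".

The per-variant outlier test compares each observed squared residual with the
simulated distribution of the same variant's squared residual, Bonferroni
multiplies by n_snv, and flags values below ``outlier_alpha``. The corrected
estimate is IVW on the non-outliers, and the distortion test locates the
observed relative change (corrected - raw)/|raw| within the distribution of
changes obtained by removing random pseudo-outlier sets of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, ivw
from .harmonize import HarmonizedSet


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outlier_pvals_bonferroni: dict[str, float]
    outliers: list[str]
    raw_estimate: MREstimate
    corrected_estimate: MREstimate | None
    distortion_pval: float | None
    n_sim: int
    seed: int
    all_flagged: bool = False
    p_floor: float = field(init=False)

    def __post_init__(self):
        self.p_floor = 1.0 / (self.n_sim + 1)

    def format_pval(self, p: float) -> str:
        """Floor-aware display: empirical p at the attainable minimum is a bound."""
        return f"< {self.p_floor:.3g}" if p <= self.p_floor else f"{p:.3g}"

    def outlier_frame(self) -> pd.DataFrame:
        rows = [{"variant_id": v, "pval": p,
                 "pval_bonferroni": self.outlier_pvals_bonferroni[v],
                 "pval_display": self.format_pval(p),
                 "flagged": v in set(self.outliers)}
                for v, p in self.outlier_pvals.items()]
        return pd.DataFrame(rows, columns=["variant_id", "pval", "pval_bonferroni",
                                           "pval_display", "flagged"])


def _loo_ivw(beta_exp: np.ndarray, beta_out: np.ndarray, se_out: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, one per variant (vectorizable
    over a leading simulation axis)."""
    w = beta_exp**2 / se_out**2
    wt = beta_exp * beta_out / se_out**2
    sw = w.sum(axis=-1, keepdims=True)
    swt = wt.sum(axis=-1, keepdims=True)
    return (swt - wt) / (sw - w)


def presso(hset: HarmonizedSet, n_sim: int = 2000, seed: int | None = None,
           outlier_alpha: float = 0.05) -> PressoResult:
    """Run the global, outlier, and distortion tests on a harmonized set.

    Requires at least 4 instruments and ``n_sim >= 100``; deterministic under a
    fixed ``seed`` (mandatory). Note the outlier test's resolution: the smallest
    attainable Bonferroni-adjusted p is n_snv/(n_sim+1), so ``n_sim`` must
    comfortably exceed n_snv/outlier_alpha for flagging to be possible at all.
    """
    n = len(hset)
    if n < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {n}")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if seed is None:
        raise ValueError("presso requires an explicit seed")

    bx, sx = hset.beta_exp, hset.se_exp
    by, sy = hset.beta_out, hset.se_out
    theta_loo = _loo_ivw(bx, by, sy)
    resid2 = (by - theta_loo * bx) ** 2 / sy**2
    rss_obs = float(resid2.sum())

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, n))
    by_s = rng.normal(theta_loo * bx, sy, size=(n_sim, n))
    theta_loo_s = _loo_ivw(bx_s, by_s, sy)
    resid2_s = (by_s - theta_loo_s * bx_s) ** 2 / sy**2
    rss_s = resid2_s.sum(axis=1)
    global_pval = float((1 + np.count_nonzero(rss_s >= rss_obs)) / (n_sim + 1))

    out_p = (1 + np.count_nonzero(resid2_s >= resid2, axis=0)) / (n_sim + 1)
    out_p_bonf = np.minimum(1.0, out_p * n)
    flagged = out_p_bonf < outlier_alpha
    ids = hset.variant_ids
    outliers = [v for v, f in zip(ids, flagged) if f]

    raw = ivw(hset)
    all_flagged = bool(flagged.all())
    corrected = None
    distortion_pval = None
    if not all_flagged:
        keep = [inst for inst, f in zip(hset.instruments, flagged) if not f]
        kept_set = HarmonizedSet(hset.exposure_name, hset.outcome_name, instruments=keep)
        corrected = ivw(kept_set)
        corrected.method = "mr_presso_corrected"
        k = len(outliers)
        if k > 0 and raw.beta != 0:
            d_obs = (corrected.beta - raw.beta) / abs(raw.beta)
            d_null = np.empty(n_sim)
            idx = np.arange(n)
            for s in range(n_sim):
                drop = rng.choice(idx, size=k, replace=False)
                mask = np.ones(n, dtype=bool)
                mask[drop] = False
                b, _, _ = _ivw_beta(bx[mask], by[mask], sy[mask])
                d_null[s] = (b - raw.beta) / abs(raw.beta)
            distortion_pval = float(
                (1 + np.count_nonzero(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))
    raw.method = "mr_presso_raw"

    return PressoResult(
        rss_obs=rss_obs, global_pval=global_pval,
        outlier_pvals=dict(zip(ids, out_p.tolist())),
        outlier_pvals_bonferroni=dict(zip(ids, out_p_bonf.tolist())),
        outliers=outliers, raw_estimate=raw, corrected_estimate=corrected,
        distortion_pval=distortion_pval, n_sim=n_sim, seed=seed,
        all_flagged=all_flagged,
    )


def _ivw_beta(bx, by, sy):
    w = bx**2 / sy**2
    wt = bx * by / sy**2
    sw = w.sum()
    return wt.sum() / sw, sw, None
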