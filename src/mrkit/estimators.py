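"""Causal-effect estimators for two-sample Mendelian randomization.

Given harmonized per-variant association pairs (beta_exp_j, se_exp_j,
beta_out_j, se_out_j), each estimator targets the causal effect theta of the
exposure on the outcome (log odds per exposure unit for a binary outcome):

* Wald ratio: theta_j = beta_out_j / beta_exp_j for a single variant, with
  first-order delta-method SE se_out_j / |beta_exp_j| (the second-order term
  adding exposure-side error is available by flag).
* IVW: the precision-weighted mean of Wald ratios with weights
  w_j = beta_exp_j^2 / se_out_j^2, algebraically identical to zero-intercept
  weighted regression of beta_out on beta_exp with weights 1/se_out^2. The
  default multiplicative random-effects model scales the fixed-effect SE by
  sqrt(max(1, Q/(n-1))) so it is never anti-conservative; Cochran's Q is
  reported alongside.
* MR-Egger: the same regression with a free intercept. The slope is a
  pleiotropy-adjusted causal estimate (valid under InSIDE); the intercept
  estimates the mean directional pleiotropic effect. Instruments are recoded
  so beta_exp_j >= 0 before fitting, which makes the intercept interpretable
  and the slope invariant to allele-coding flips.
* Weighted median: the 50% point of the inverse-variance-weighted empirical
  distribution of Wald ratios; consistent when valid instruments carry more
  than half the weight. Its SE comes from a parametric bootstrap.
* Multivariable MR: zero-intercept weighted multiple regression of beta_out
  on the matrix of exposure effects, giving each exposure's direct effect
  conditional on the others.

Confidence intervals use the normal multiplier 1.959964 throughout (the
summary-data MR convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, MulticollinearityError, UndefinedRatioError
from .harmonize import HarmonizedInstrument, HarmonizedSet, MVHarmonizedSet

Z95 = 1.959964


@dataclass
class MREstimate:
    """A causal-effect estimate on the outcome scale per exposure unit."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snv: int
    q_stat: float | None = None
    q_pval: float | None = None

    def __post_init__(self):
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


@dataclass
class EggerResult(MREstimate):
    intercept: float = 0.0
    intercept_se: float = float("nan")
    intercept_pval: float = float("nan")

    @property
    def intercept_ci(self) -> tuple[float, float]:
        return (self.intercept - Z95 * self.intercept_se,
                self.intercept + Z95 * self.intercept_se)


@dataclass
class MVMRResult:
    """Per-exposure direct effects from multivariable MR."""

    exposures: list[MREstimate]  # one per exposure, method tag "mvmr"
    n_snv: int
    conditioning: list[str] = field(default_factory=list)

    def by_name(self, name: str) -> MREstimate:
        for est in self.exposures:
            if est.method == f"mvmr:{name}":
                return est
        raise KeyError(name)


def _zp(beta: float, se: float) -> float:
    if se == 0 or not np.isfinite(se):
        return 1.0 if (beta == 0 or not np.isfinite(se)) else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _estimate(method: str, beta: float, se: float, n_snv: int,
              q: float | None = None, q_df: int | None = None) -> MREstimate:
    q_pval = float(stats.chi2.sf(q, q_df)) if (q is not None and q_df and q_df > 0) else None
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
                      pval=_zp(beta, se), n_snv=n_snv,
                      q_stat=None if q is None else float(q), q_pval=q_pval)


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-variant causal estimate beta_out/beta_exp.

    ``second_order=True`` adds the exposure-side term
    beta_out^2 * se_exp^2 / beta_exp^4 under the square root of the variance.
    """
    if inst.beta_exp == 0:
        raise UndefinedRatioError(f"zero exposure effect at {inst.variant_id}")
    beta = inst.beta_out / inst.beta_exp
    var = inst.se_out**2 / inst.beta_exp**2
    if second_order:
        var += inst.beta_out**2 * inst.se_exp**2 / inst.beta_exp**4
    return _estimate("wald", beta, np.sqrt(var), 1)


def _ivw_core(beta_exp: np.ndarray, se_out: np.ndarray, beta_out: np.ndarray):
    """Weighted-mean-of-ratios sums; avoids explicit division by beta_exp."""
    w = beta_exp**2 / se_out**2
    wt = beta_exp * beta_out / se_out**2  # = w * theta_j
    sw, swt = w.sum(), wt.sum()
    beta = swt / sw
    q = float(np.sum((beta_out - beta * beta_exp) ** 2 / se_out**2))
    return beta, sw, q


def ivw(hset: HarmonizedSet, model: str = "multiplicative_random",
        second_order: bool = False) -> MREstimate:
    """Inverse-variance weighted estimate (the primary analysis).

    ``model`` is ``"fixed"`` or ``"multiplicative_random"`` (default; the SE
    is scaled by sqrt(max(1, Q/(n-1))) and so never narrower than fixed).
    A single-instrument set degenerates to the Wald ratio.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown model {model!r}")
    n = len(hset)
    if n == 0:
        raise InsufficientInstrumentsError("empty instrument set")
    if n == 1:
        est = wald_ratio(hset.instruments[0], second_order=second_order)
        est.method = f"ivw_{'fe' if model == 'fixed' else 'mre'}"
        return est
    if np.any(hset.beta_exp == 0):
        raise UndefinedRatioError("zero exposure effect in instrument set")
    beta, sw, q = _ivw_core(hset.beta_exp, hset.se_out, hset.beta_out)
    se = sw**-0.5
    if model == "multiplicative_random":
        se *= np.sqrt(max(1.0, q / (n - 1)))
        tag = "ivw_mre"
    else:
        tag = "ivw_fe"
    return _estimate(tag, beta, se, n, q=q, q_df=n - 1)


def egger(hset: HarmonizedSet) -> EggerResult:
    """MR-Egger regression with multiplicative overdispersion.

    Fits beta_out_j = intercept + slope * beta_exp_j by weighted least squares
    (weights 1/se_out_j^2) after orienting every instrument to beta_exp >= 0.
    Both SEs are scaled by sqrt(max(1, RSS_w/(n-2))).
    """
    n = len(hset)
    if n < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {n}")
    sign = np.where(hset.beta_exp < 0, -1.0, 1.0)
    x = sign * hset.beta_exp
    y = sign * hset.beta_out
    w = 1.0 / hset.se_out**2
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    if det <= 0:
        raise MulticollinearityError("no spread in instrument strengths")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    rss = float(np.sum(w * (y - intercept - slope * x) ** 2))
    scale = max(1.0, rss / (n - 2))
    se_slope = np.sqrt(scale * sw / det)
    se_int = np.sqrt(scale * swxx / det)
    q_pval = float(stats.chi2.sf(rss, n - 2))
    return EggerResult(
        method="egger", beta=float(slope), se=float(se_slope),
        ci_low=float(slope - Z95 * se_slope), ci_high=float(slope + Z95 * se_slope),
        pval=_zp(slope, se_slope), n_snv=n, q_stat=rss, q_pval=q_pval,
        intercept=float(intercept), intercept_se=float(se_int),
        intercept_pval=_zp(intercept, se_int),
    )


def weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of order statistics.

    With normalized weights w_(j) in ratio-sorted order, the estimate is the
    interpolation of theta_(j) against standardized cumulative weight
    s_j = (cum_j - w_(j)/2) / sum(w), evaluated at 0.5.
    """
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, th))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Weights are the first-order inverse variances of the Wald ratios,
    beta_exp^2/se_out^2. The bootstrap redraws beta_exp_j and beta_out_j from
    their normal sampling distributions ``n_boot`` times with a fixed seed
    (mandatory for reproducibility).
    """
    n = len(hset)
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 instruments, got {n}")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    bx, sx = hset.beta_exp, hset.se_exp
    by, sy = hset.beta_out, hset.se_out
    if np.any(bx == 0):
        raise UndefinedRatioError("zero exposure effect in instrument set")
    theta = by / bx
    w = bx**2 / sy**2
    beta = weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_boot, n))
    by_s = rng.normal(by, sy, size=(n_boot, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        th_s = by_s / bx_s
        w_s = bx_s**2 / sy**2
    # vectorized weighted median per bootstrap row
    order = np.argsort(th_s, axis=1, kind="stable")
    th_sorted = np.take_along_axis(th_s, order, axis=1)
    w_sorted = np.take_along_axis(w_s, order, axis=1)
    w_sorted = w_sorted / w_sorted.sum(axis=1, keepdims=True)
    s = np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted
    boots = np.empty(n_boot)
    for i in range(n_boot):  # np.interp is 1-D; rows are small
        boots[i] = np.interp(0.5, s[i], th_sorted[i])
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny  # degenerate distribution: all ratios equal
    return _estimate("weighted_median", beta, se, n)


def mvmr(mset: MVHarmonizedSet) -> MVMRResult:
    """Multivariable MR: per-exposure direct effects by zero-intercept WLS.

    Solves beta_out = B @ theta with weights 1/se_out^2, B the (n_snv x k)
    exposure-effect matrix. SEs are scaled by sqrt(max(1, RSS_w/(n-k))).
    Perfectly collinear exposure columns raise naming the offending pair --
    the reason correlated lipid fractions are analyzed in restricted
    adjustment sets. A zero-signal column (an exposure with no instrument
    effect at all) is solved at minimum norm: direct effect 0 with infinite SE.
    """
    B = mset.beta_exp
    y = mset.beta_out
    n, k = B.shape
    if k < 2:
        raise ValueError("multivariable MR needs >= 2 exposures")
    if n < k + 1:
        raise InsufficientInstrumentsError(
            f"multivariable MR needs >= {k + 1} instruments for {k} exposures, got {n}")
    norms = np.linalg.norm(B, axis=0)
    nonzero = norms > 0
    Bn = B[:, nonzero] / norms[nonzero]
    cos = Bn.T @ Bn
    for i in range(cos.shape[0]):
        for j in range(i + 1, cos.shape[0]):
            if abs(cos[i, j]) > 1 - 1e-10:
                names = [mset.exposure_names[idx] for idx in np.where(nonzero)[0][[i, j]]]
                raise MulticollinearityError(
                    f"exposure effects perfectly collinear: {names[0]} vs {names[1]}")
    w = 1.0 / mset.se_out**2
    Bw = B * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    xtx = Bw.T @ Bw
    xty = Bw.T @ yw
    theta = np.linalg.pinv(xtx) @ xty
    rss = float(np.sum((yw - Bw @ theta) ** 2))
    scale = max(1.0, rss / (n - k))
    cov = scale * np.linalg.pinv(xtx)
    ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    ests = []
    for name, b, se, dead in zip(mset.exposure_names, theta, ses, ~nonzero):
        if dead:
            ests.append(_estimate(f"mvmr:{name}", 0.0, np.inf, n))
        else:
            ests.append(_estimate(f"mvmr:{name}", b, se, n))
    return MVMRResult(exposures=ests, n_snv=n, conditioning=list(mset.exposure_names))
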