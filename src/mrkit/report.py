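"""Effect scaling, per-method FDR, instrument diagnostics, and power.

The power model is the standard binary-outcome two-sample MR approximation:
the IVW estimate of an effect b (log odds per exposure unit) is asymptotically
normal with standard error 1/sqrt(N * R2 * phi * (1 - phi)), where N is the
outcome sample size, phi the case fraction, and R2 the variance of the
exposure explained by the instruments. Power at two-sided level alpha is

    Phi(ncp - z_{1-alpha/2}) + Phi(-ncp - z_{1-alpha/2}),
    ncp = sqrt(N * R2 * phi * (1 - phi)) * |b|,

and the minimum detectable effect inverts this numerically for the target
power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

Z95 = 1.959964


def scale_and_convert(beta: float, se: float, unit_multiplier: float = 1.0
                      ) -> tuple[float, float, float]:
    """Rescale a log-odds effect to its reporting unit and exponentiate.

    E.g. a per-mm-Hg blood-pressure effect with ``unit_multiplier=10`` becomes
    an OR per 10 mm Hg. Returns ``(or, ci_low, ci_high)``.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if unit_multiplier <= 0:
        raise ValueError("unit multiplier must be positive")
    b = beta * unit_multiplier
    s = se * unit_multiplier
    return (float(np.exp(b)), float(np.exp(b - Z95 * s)), float(np.exp(b + Z95 * s)))


def bh_fdr(pvals, groups=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, computed within groups.

    ``groups`` labels each p-value with its MR method (and outcome data set);
    the correction is applied separately per label and never pooled across
    methods. Without ``groups`` all p-values form one family.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if groups is None:
        return multipletests(p, method="fdr_bh")[1]
    groups = np.asarray(groups)
    q = np.empty_like(p)
    for g in pd.unique(groups):
        mask = groups == g
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def variance_explained(beta: float, maf: float) -> float:
    """Per-instrument variance explained: beta^2 * 2 * MAF * (1 - MAF).

    ``beta`` is the per-allele effect on an SD-scaled trait; ``maf`` the minor
    allele frequency. A frequency above 0.5 is folded to the minor allele with
    a warning. Summing over an instrument set gives its total R2.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError("maf must be in [0, 1]")
    if maf > 0.5:
        warnings.warn(f"allele frequency {maf:.3f} > 0.5 folded to minor allele")
        maf = 1.0 - maf
    return float(beta**2 * 2.0 * maf * (1.0 - maf))


@dataclass
class PowerSpec:
    """Inputs to the binary-outcome power calculation."""

    n_case: int
    n_control: int
    r2: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self):
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target power must be in (0, 1)")

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control

    @property
    def case_fraction(self) -> float:
        return self.n_case / self.n_total


def power_at(spec: PowerSpec, b: float) -> float:
    """Two-sided power to detect a log-odds change ``b`` per exposure unit."""
    phi = spec.case_fraction
    ncp = np.sqrt(spec.n_total * spec.r2 * phi * (1.0 - phi)) * abs(b)
    zc = stats.norm.isf(spec.alpha / 2.0)
    return float(stats.norm.cdf(ncp - zc) + stats.norm.cdf(-ncp - zc))


def power_min_detectable(spec: PowerSpec) -> float:
    """Smallest detectable |b| at the target power, in percent change of log odds.

    Numerically inverts :func:`power_at`; monotone decreasing in R2 and N.
    """
    if spec.r2 == 0:
        raise ValueError("r2 = 0: no detectable effect at any size")
    f = lambda b: power_at(spec, b) - spec.target_power
    b = optimize.brentq(f, 1e-12, 50.0, xtol=1e-14, rtol=1e-15)
    return float(100.0 * b)


def min_detectable_table(n_case: int, n_control: int, r2_by_exposure: dict[str, float],
                         alpha: float = 0.05, target_power: float = 0.80) -> pd.DataFrame:
    """Per-exposure minimum detectable effects (the power-curve table)."""
    rows = []
    for name, r2 in r2_by_exposure.items():
        spec = PowerSpec(n_case, n_control, r2, alpha, target_power)
        rows.append({"exposure": name, "r2": r2,
                     "min_detectable_pct": power_min_detectable(spec)})
    return pd.DataFrame(rows).sort_values("min_detectable_pct").reset_index(drop=True)


RESULT_COLUMNS = ["exposure", "outcome", "method", "nsnp", "b", "se", "lo95", "up95",
                  "pval", "or_", "or_lo95", "or_up95", "q", "q_pval",
                  "intercept", "intercept_se", "intercept_pval", "qval"]


def tidy_row(exposure: str, outcome: str, est, unit_multiplier: float = 1.0) -> dict:
    """One tidy results-table row from an estimate (unit scaling applied to OR)."""
    or_, lo, hi = scale_and_convert(est.beta, est.se, unit_multiplier) \
        if np.isfinite(est.se) and est.se > 0 else (np.nan, np.nan, np.nan)
    row = {"exposure": exposure, "outcome": outcome, "method": est.method,
           "nsnp": est.n_snv, "b": est.beta, "se": est.se,
           "lo95": est.ci_low, "up95": est.ci_high, "pval": est.pval,
           "or_": or_, "or_lo95": lo, "or_up95": hi,
           "q": est.q_stat, "q_pval": est.q_pval,
           "intercept": getattr(est, "intercept", None),
           "intercept_se": getattr(est, "intercept_se", None),
           "intercept_pval": getattr(est, "intercept_pval", None),
           "qval": np.nan}
    return row


def add_fdr(df: pd.DataFrame, by: tuple[str, ...] = ("method", "outcome")) -> pd.DataFrame:
    """Fill the ``qval`` column, correcting within ``by`` strata (never pooled
    across MR methods or outcome data sets)."""
    df = df.copy()
    labels = df[list(by)].astype(str).agg("||".join, axis=1)
    ok = df["pval"].notna() & (df["pval"] > 0)
    df.loc[ok, "qval"] = bh_fdr(df.loc[ok, "pval"].to_numpy(), labels[ok].to_numpy())
    return df


def forest_format(df: pd.DataFrame) -> pd.DataFrame:
    """Long forest-plot-ready layout: one labeled OR (CI) line per estimate."""
    out = df[["outcome", "exposure", "method", "nsnp", "or_", "or_lo95", "or_up95",
              "pval", "qval"]].copy()
    out["label"] = out.apply(
        lambda r: f"{r['or_']:.2f} ({r['or_lo95']:.2f}-{r['or_up95']:.2f})"
        if np.isfinite(r["or_"]) else "NA", axis=1)
    return out.sort_values(["outcome", "method", "exposure"]).reset_index(drop=True)
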