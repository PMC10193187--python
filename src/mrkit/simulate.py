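"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of the study data this package analyzes:
a large continuous-exposure GWAS (effects in SD units per allele) and a binary
Alzheimer-disease-like outcome GWAS (log odds per allele) from a case-control
sample of realistic size, linked by a controlled causal effect theta.

Summary statistics are simulated directly at the summary level -- per-variant
estimates drawn around their true values with the analytic standard errors

    se_exp = 1 / sqrt(2 * N_exp * maf * (1 - maf))          (SD-scaled trait)
    se_out = 1 / sqrt(N * phi * (1 - phi) * 2 * maf * (1 - maf))   (log odds)

-- except for the GWAS-by-proxy outcome, which requires an individual-level
family model because the bias operates through parental genotype: the
respondent's parent carries a correlated genotype (transmission coefficient
0.5), parental disease follows the parent's exposure, and the respondent's own
exposure shifts the probability that parental disease is reported. With a
negative true effect and a positive reporting effect the proxy-based estimate
reverses sign relative to the diagnosed-based estimate.

Pleiotropy modes plant violations of the exclusion restriction: ``balanced``
(zero-mean direct effects), ``directional`` (nonzero mean), and
``inside_violating`` (direct effects correlated with instrument strength,
breaking the InSIDE assumption). Gross outliers and LD blocks can be planted
on top. Every generator is a pure function of its config (seed mandatory).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .summary_io import SummaryRecord, SummaryTable
from . import study

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class PleiotropySpec:
    """Direct (pleiotropic) variant-outcome effects planted on the generator.

    ``invalid_fraction`` of variants receive a direct effect drawn
    N(mean, sd); in ``inside_violating`` mode the draw is correlated
    (``inside_corr``) with standardized instrument strength.
    """

    mode: str = "none"  # none | balanced | directional | inside_violating
    mean: float = 0.0
    sd: float = 0.001
    invalid_fraction: float = 1.0
    inside_corr: float = 0.7

    def __post_init__(self):
        if self.mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy mode {self.mode!r}")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if self.mode == "balanced" and self.mean != 0.0:
            raise ValueError("balanced pleiotropy must have zero mean")

    @classmethod
    def balanced(cls, sd: float = 0.001, invalid_fraction: float = 1.0):
        return cls(mode="balanced", mean=0.0, sd=sd, invalid_fraction=invalid_fraction)

    @classmethod
    def directional(cls, mean: float = 0.02, sd: float = 0.005,
                    invalid_fraction: float = 1.0):
        return cls(mode="directional", mean=mean, sd=sd, invalid_fraction=invalid_fraction)

    @classmethod
    def inside(cls, mean: float = 0.02, sd: float = 0.005,
               invalid_fraction: float = 1.0, inside_corr: float = 0.7):
        return cls(mode="inside_violating", mean=mean, sd=sd,
                   invalid_fraction=invalid_fraction, inside_corr=inside_corr)


@dataclass
class SimConfig:
    """Generative description of one synthetic two-sample MR scenario.

    Defaults follow the emulated study: a consortium-scale outcome (39,106 diagnosed
    cases / 401,577 controls), a 400k-sample exposure GWAS, and strong
    instruments (per-allele effects ~N(0.03, 0.01) SD, so ~50 instruments
    explain ~1.6% of exposure variance; scale ``n_snv`` up for the
    Table-2-like magnitudes).
    """

    seed: int
    n_snv: int = 50
    theta: float = 0.0
    beta_exp_mean: float = 0.03
    beta_exp_sd: float = 0.01
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 400_000
    n_out_case: int = study.N_CASE_DIAGNOSED
    n_out_control: int = study.N_CONTROL
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    outliers: tuple[tuple[float, float], ...] = ()  # (wald ratio, se_out) pairs
    outlier_beta_exp: float = 0.1  # planted outliers are strong instruments
    ld_blocks: tuple[tuple[int, float], ...] | None = None  # (block size, r2)
    frac_palindromic: float = 0.0
    frac_swapped: float = 0.0
    frac_flipped: float = 0.0
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_snv < 1:
            raise ValueError("n_snv must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5 "
                             "(degenerate frequencies have no association signal)")
        if min(self.n_exp, self.n_out_case, self.n_out_control) <= 0:
            raise ValueError("sample sizes must be positive")


@dataclass
class ProxySimConfig(SimConfig):
    """Adds the GWAS-by-proxy family model to :class:`SimConfig`.

    ``reporting_effect`` is the log-odds shift in the probability of reporting
    parental disease per SD of the respondent's own exposure: the channel that
    violates the independence assumption. Report rates given diseased/healthy
    parents set the strength of the true proxy signal. Calibration rationale
    is documented in the methods note.
    """

    theta: float = -0.18
    n_families: int = 100_000
    prevalence: float = 0.15
    transmission: float = 0.5
    reporting_effect: float = 0.25
    report_rate_diseased: float = 0.30
    report_rate_healthy: float = 0.02
    proxy_weight: float = 1.0

    def __post_init__(self):
        super().__post_init__()
        for name in ("prevalence", "report_rate_diseased", "report_rate_healthy"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 <= self.transmission <= 0.5:
            raise ValueError("transmission must be in [0, 0.5]")
        if not 0.0 < self.proxy_weight <= 1.0:
            raise ValueError("proxy_weight must be in (0, 1]")
        if self.outliers:
            raise ValueError("planted outliers are not supported in the proxy model")


@dataclass
class TruthRecord:
    """Every latent quantity needed to recompute expected estimates."""

    theta: float
    maf: np.ndarray
    beta_true: np.ndarray
    pleio: np.ndarray
    invalid_mask: np.ndarray
    se_exp: np.ndarray
    se_out: np.ndarray
    outlier_ids: list[str]
    r2_total: float
    config: SimConfig
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif f.name == "config":
                v = _config_to_dict(v)
            d[f.name] = v
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=str)


def _config_to_dict(config) -> dict:
    d = dataclasses.asdict(config)
    d["type"] = type(config).__name__
    return d


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), 1e-300)


def _draw_latents(rng: np.random.Generator, config: SimConfig):
    n = config.n_snv
    maf = rng.uniform(*config.maf_range, n)
    beta_true = rng.normal(config.beta_exp_mean, config.beta_exp_sd, n)
    spec = config.pleiotropy
    invalid = np.zeros(n, dtype=bool)
    pleio = np.zeros(n)
    if spec.mode != "none" and spec.invalid_fraction > 0:
        k = int(round(spec.invalid_fraction * n))
        invalid[rng.choice(n, size=k, replace=False)] = True
        z = rng.normal(size=k)
        if spec.mode == "inside_violating":
            strength = beta_true[invalid]
            zb = (strength - strength.mean()) / (strength.std() or 1.0)
            z = spec.inside_corr * zb + np.sqrt(1 - spec.inside_corr**2) * z
        pleio[invalid] = spec.mean + spec.sd * z
    return maf, beta_true, pleio, invalid


def _draw_alleles(rng: np.random.Generator, config: SimConfig, n: int):
    """Exposure-coded allele pairs plus the outcome-side recoding plan."""
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), n)
    pairs = [_NONPALINDROMIC_PAIRS[i] for i in pair_idx]
    u = rng.random(n)
    palindromic = u < config.frac_palindromic
    swapped = (u >= config.frac_palindromic) & \
              (u < config.frac_palindromic + config.frac_swapped)
    flipped = (u >= config.frac_palindromic + config.frac_swapped) & \
              (u < config.frac_palindromic + config.frac_swapped + config.frac_flipped)
    for i in np.where(palindromic)[0]:
        pairs[i] = _PALINDROMIC_PAIRS[rng.integers(0, len(_PALINDROMIC_PAIRS))]
    return pairs, swapped, flipped


def _records(ids, chroms, pairs, eaf, beta, se, n_sample) -> list[SummaryRecord]:
    pv = _pvals(beta, se)
    return [SummaryRecord(variant_id=v, chrom=c, effect_allele=ea, other_allele=oa,
                          eaf=float(f), beta=float(b), se=float(s), pval=float(p),
                          n=int(n_sample))
            for v, c, (ea, oa), f, b, s, p in zip(ids, chroms, pairs, eaf, beta, se, pv)]


def outcome_se(maf: np.ndarray, n_case: int, n_control: int) -> np.ndarray:
    """Log-odds-scale SE approximation 1/sqrt(N*phi*(1-phi)*2*maf*(1-maf))."""
    n = n_case + n_control
    phi = n_case / n
    return 1.0 / np.sqrt(n * phi * (1 - phi) * 2 * maf * (1 - maf))


def ld_matrix(variant_ids: list[str],
              ld_blocks: tuple[tuple[int, float], ...] | None) -> pd.DataFrame:
    """Block-diagonal r2 matrix: consecutive variants share a block.

    ``ld_blocks`` cycles through (block_size, r2) descriptions; ``None`` gives
    the identity (all variants mutually independent).
    """
    n = len(variant_ids)
    m = np.eye(n)
    if ld_blocks:
        start, b = 0, 0
        while start < n:
            size, r2 = ld_blocks[b % len(ld_blocks)]
            stop = min(start + size, n)
            blk = slice(start, stop)
            m[blk, blk] = r2
            np.fill_diagonal(m[blk, blk], 1.0)
            start, b = stop, b + 1
    return pd.DataFrame(m, index=variant_ids, columns=variant_ids)


def simulate_two_sample(config: SimConfig):
    """Draw one (exposure, outcome, truth) triple.

    The outcome effect of variant j is theta * beta_true_j + pleio_j, observed
    with case-control log-odds noise; the exposure effect is beta_true_j
    observed with SD-trait noise. Planted outliers are appended as extra
    variants whose observed outcome effect equals ratio * observed exposure
    effect exactly, with the stated (small) se_out.
    """
    rng = np.random.default_rng(config.seed)
    maf, beta_true, pleio, invalid = _draw_latents(rng, config)
    return _summary_pair(rng, config, maf, beta_true, pleio, invalid)


def _summary_pair(rng, config, maf, beta_true, pleio, invalid,
                  aligned_outcome: bool = False):
    n = config.n_snv
    ids = [f"rs{i + 1:06d}" for i in range(n)]
    chroms = [str(i % 22 + 1) for i in range(n)]
    pairs, swapped, flipped = _draw_alleles(rng, config, n)

    se_exp = 1.0 / np.sqrt(2 * config.n_exp * maf * (1 - maf))
    beta_exp_hat = rng.normal(beta_true, se_exp)
    se_out = outcome_se(maf, config.n_out_case, config.n_out_control)
    beta_out_hat = rng.normal(config.theta * beta_true + pleio, se_out)

    outlier_ids = []
    maf_l, se_exp_l, bexp_l, se_out_l, bout_l = (maf.tolist(), se_exp.tolist(),
                                                 beta_exp_hat.tolist(), se_out.tolist(),
                                                 beta_out_hat.tolist())
    for k, (ratio, o_se) in enumerate(config.outliers, start=1):
        vid = f"outlier_{k}"
        m = rng.uniform(*config.maf_range)
        s_exp = 1.0 / np.sqrt(2 * config.n_exp * m * (1 - m))
        # a gross (influential) outlier: strong instrument, discordant ratio
        b_exp = rng.normal(config.outlier_beta_exp, config.beta_exp_sd)
        ids.append(vid)
        chroms.append(str(len(ids) % 22 + 1))
        pairs.append(_NONPALINDROMIC_PAIRS[rng.integers(0, len(_NONPALINDROMIC_PAIRS))])
        maf_l.append(m); se_exp_l.append(s_exp); bexp_l.append(b_exp)
        se_out_l.append(float(o_se)); bout_l.append(ratio * b_exp)
        outlier_ids.append(vid)
    maf_a, se_exp_a, bexp_a = map(np.array, (maf_l, se_exp_l, bexp_l))
    se_out_a, bout_a = map(np.array, (se_out_l, bout_l))
    swapped = np.concatenate([swapped, np.zeros(len(outlier_ids), dtype=bool)])
    flipped = np.concatenate([flipped, np.zeros(len(outlier_ids), dtype=bool)])

    exposure = SummaryTable(config.exposure_name, "continuous", "SD",
                            _records(ids, chroms, pairs, maf_a, bexp_a, se_exp_a,
                                     config.n_exp))
    out_pairs, out_beta, out_eaf = _recode_outcome(pairs, bout_a, maf_a,
                                                   swapped, flipped, aligned_outcome)
    outcome = SummaryTable(config.outcome_name, "binary", "log odds",
                           _records(ids, chroms, out_pairs, out_eaf, out_beta, se_out_a,
                                    config.n_out_case + config.n_out_control))
    truth = TruthRecord(theta=config.theta, maf=maf, beta_true=beta_true, pleio=pleio,
                        invalid_mask=invalid, se_exp=se_exp, se_out=se_out,
                        outlier_ids=outlier_ids,
                        r2_total=float(np.sum(beta_true**2 * 2 * maf * (1 - maf))),
                        config=config)
    return exposure, outcome, truth


def _recode_outcome(pairs, beta, eaf, swapped, flipped, aligned):
    """Apply the harmonization-exercise recodings to the outcome table."""
    out_pairs, out_beta, out_eaf = [], [], []
    for (ea, oa), b, f, sw, fl in zip(pairs, beta, eaf, swapped, flipped):
        if not aligned and sw:
            ea, oa, b, f = oa, ea, -b, 1 - f
        if not aligned and fl:
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        out_pairs.append((ea, oa))
        out_beta.append(b)
        out_eaf.append(f)
    return out_pairs, np.array(out_beta), np.array(out_eaf)


def simulate_mv_exposures(config: SimConfig, n_exposures: int = 2,
                          direct_effects=(0.2, 0.0),
                          cross_effect_correlation: float = 0.6):
    """Correlated multi-exposure scenario for multivariable MR.

    Per-variant true effect vectors are drawn from a multivariate normal with
    the univariable marginal mean/sd and equicorrelation
    ``cross_effect_correlation``; the outcome is built from ``direct_effects``
    only, so the univariable estimate for a null exposure is confounded by its
    correlated partner while multivariable MR recovers ~0.
    """
    direct_effects = np.asarray(direct_effects, dtype=float)
    if len(direct_effects) != n_exposures:
        raise ValueError("need one direct effect per exposure")
    if abs(cross_effect_correlation) >= 1.0:
        raise ValueError("|cross_effect_correlation| must be < 1")
    if n_exposures == 1:
        exp_t, out_t, truth = simulate_two_sample(
            replace(config, theta=float(direct_effects[0])))
        return [exp_t], out_t, truth

    rng = np.random.default_rng(config.seed)
    n, k = config.n_snv, n_exposures
    maf = rng.uniform(*config.maf_range, n)
    cov = config.beta_exp_sd**2 * (
        (1 - cross_effect_correlation) * np.eye(k)
        + cross_effect_correlation * np.ones((k, k)))
    beta_true = config.beta_exp_mean + rng.multivariate_normal(np.zeros(k), cov, size=n)

    _, _, pleio, invalid = _draw_latents(rng, config)
    ids = [f"rs{i + 1:06d}" for i in range(n)]
    chroms = [str(i % 22 + 1) for i in range(n)]
    pairs, _, _ = _draw_alleles(rng, replace(config, frac_swapped=0.0, frac_flipped=0.0), n)

    se_exp = 1.0 / np.sqrt(2 * config.n_exp * maf * (1 - maf))
    tables = []
    for j in range(k):
        bhat = rng.normal(beta_true[:, j], se_exp)
        tables.append(SummaryTable(f"{config.exposure_name}_{j + 1}", "continuous", "SD",
                                   _records(ids, chroms, pairs, maf, bhat, se_exp,
                                            config.n_exp)))
    se_out = outcome_se(maf, config.n_out_case, config.n_out_control)
    bout = rng.normal(beta_true @ direct_effects + pleio, se_out)
    outcome = SummaryTable(config.outcome_name, "binary", "log odds",
                           _records(ids, chroms, pairs, maf, bout, se_out,
                                    config.n_out_case + config.n_out_control))
    truth = TruthRecord(theta=float("nan"), maf=maf, beta_true=beta_true, pleio=pleio,
                        invalid_mask=invalid, se_exp=se_exp, se_out=se_out,
                        outlier_ids=[],
                        r2_total=float(np.sum(beta_true[:, 0]**2 * 2 * maf * (1 - maf))),
                        config=config,
                        extras={"direct_effects": direct_effects.tolist(),
                                "cross_effect_correlation": cross_effect_correlation})
    return tables, outcome, truth


def simulate_proxy_pair(config: ProxySimConfig):
    """Exposure GWAS plus diagnosed and proxy outcome GWAS with shared truth.

    The diagnosed outcome is summary-level with the true theta. The proxy
    outcome is computed from an individual-level family model: respondents'
    case status is an affirmative parental-disease report, whose probability
    rises with the respondent's own exposure (``reporting_effect``), while the
    true signal is diluted through the parent's correlated genotype.
    """
    rng = np.random.default_rng(config.seed)
    maf, beta_true, pleio, invalid = _draw_latents(rng, config)
    exposure, diagnosed, truth = _summary_pair(rng, config, maf, beta_true, pleio,
                                               invalid, aligned_outcome=True)
    diagnosed = replace(diagnosed, trait_name=f"{config.outcome_name}_diagnosed")

    F, n = config.n_families, config.n_snv
    gp = rng.binomial(2, maf, size=(F, n)).astype(np.int8)
    inherit = rng.random((F, n)) < 2 * config.transmission
    a1 = np.where(inherit,
                  rng.random((F, n)) < gp / 2.0,
                  rng.random((F, n)) < maf)
    a2 = rng.random((F, n)) < maf
    go = a1.astype(np.int8) + a2.astype(np.int8)

    var_g = float(np.sum(beta_true**2 * 2 * maf * (1 - maf)))
    env_sd = np.sqrt(max(1.0 - var_g, 0.05))
    x_parent = (gp - 2 * maf) @ beta_true + rng.normal(0.0, env_sd, F)
    x_off = (go - 2 * maf) @ beta_true + rng.normal(0.0, env_sd, F)

    d_parent = rng.random(F) < expit(logit(config.prevalence) + config.theta * x_parent)
    base = logit(config.report_rate_healthy)
    signal = logit(config.report_rate_diseased) - base
    p_report = expit(base + signal * d_parent + config.reporting_effect * x_off)
    y = (rng.random(F) < p_report).astype(float)

    gof = go.astype(float)
    g_mean = gof.mean(axis=0)
    gc = gof - g_mean
    var_snv = (gc**2).mean(axis=0)
    ybar = y.mean()
    beta_lin = (gc * (y - ybar)[:, None]).mean(axis=0) / var_snv
    se_lin = np.sqrt(ybar * (1 - ybar) / (F * var_snv))
    denom = ybar * (1 - ybar)
    beta_log = beta_lin / denom
    se_log = se_lin / denom

    if config.proxy_weight < 1.0:
        # crude fixed-effect blend of the diagnosed and proxy channels
        bd = np.array([r.beta for r in diagnosed.records])
        sd_ = np.array([r.se for r in diagnosed.records])
        w_d = (1 - config.proxy_weight) / sd_**2
        w_p = config.proxy_weight / se_log**2
        beta_log = (w_d * bd + w_p * beta_log) / (w_d + w_p)
        se_log = 1.0 / np.sqrt(w_d + w_p)

    ids = exposure.variant_ids
    chroms = [r.chrom for r in exposure.records]
    pairs = [(r.effect_allele, r.other_allele) for r in exposure.records]
    proxy = SummaryTable(f"{config.outcome_name}_proxy", "binary", "log odds",
                         _records(ids, chroms, pairs, g_mean / 2.0, beta_log, se_log, F))
    truth.extras.update({
        "report_prevalence": float(ybar),
        "parent_disease_prevalence": float(np.mean(d_parent)),
        "offspring_parent_genotype_corr": float(np.mean([
            np.corrcoef(gof[:, j], gp[:, j].astype(float))[0, 1] for j in range(n)])),
    })
    return exposure, diagnosed, proxy, truth


def simulate_study_grid(out_dir, seed: int, snv_scale: float = 1.0,
                        pleiotropy: PleiotropySpec | None = None) -> dict:
    """Materialize the full emulated study data set under ``out_dir``.

    One exposure summary table per study exposure (instrument counts and
    variance explained mirroring the published grid, down-scalable via
    ``snv_scale``), each paired with two binary-outcome tables: the diagnosed
    case-control set and a smaller diagnosed set excluding one biobank. True
    causal effects come from :data:`mrkit.study.SYNTHETIC_TRUE_OR`. Per-allele
    exposure effects are calibrated so the realized instrument R2 matches each
    exposure's variance explained. Returns a manifest of written paths.
    """
    from pathlib import Path
    from . import study
    from .summary_io import write_summary

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict[str, dict] = {}
    # mean of 2*maf*(1-maf) over the default U(0.05, 0.5) frequency range
    het = 0.357
    for design in study.EXPOSURES:
        n_snv = max(5, int(round(design.n_snv * snv_scale)))
        beta_mean = float(np.sqrt(design.variance_explained / (n_snv * het)))
        theta = float(np.log(study.SYNTHETIC_TRUE_OR[design.name])
                      / design.unit_multiplier)
        base = SimConfig(
            seed=int(rng.integers(2**31)), n_snv=n_snv, theta=theta,
            beta_exp_mean=beta_mean, beta_exp_sd=beta_mean / 3,
            n_exp=design.gwas_n,
            pleiotropy=pleiotropy or PleiotropySpec(),
            exposure_name=design.name, outcome_name="ad_diagnosed")
        exposure, outcome, truth = simulate_two_sample(base)
        # same exposure GWAS against a smaller diagnosed set (biobank excluded):
        # re-draw only the outcome estimates with ~2/3 of cases and controls,
        # reusing the exposure table's variant coding
        rng_ex = np.random.default_rng(int(rng.integers(2**31)))
        n_case_ex = int(base.n_out_case * 2 / 3)
        n_ctrl_ex = int(base.n_out_control * 2 / 3)
        se_out_ex = outcome_se(truth.maf, n_case_ex, n_ctrl_ex)
        bout_ex = rng_ex.normal(theta * truth.beta_true + truth.pleio, se_out_ex)
        ids = exposure.variant_ids
        chroms = [r.chrom for r in exposure.records]
        pairs = [(r.effect_allele, r.other_allele) for r in exposure.records]
        outcome_exukb = SummaryTable(
            "ad_diagnosed_exukb", "binary", "log odds",
            _records(ids, chroms, pairs, truth.maf, bout_ex, se_out_ex,
                     n_case_ex + n_ctrl_ex))
        paths = {}
        for tag, table in (("exposure", exposure), ("ad_diagnosed", outcome),
                           ("ad_diagnosed_exukb", outcome_exukb)):
            path = out / f"{design.name}.{tag}.tsv"
            write_summary(table, path)
            paths[tag] = str(path)
        truth_path = out / f"{design.name}.truth.json"
        truth.to_json(truth_path)
        paths["truth"] = str(truth_path)
        manifest[design.name] = paths
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig`/:class:`ProxySimConfig` from plain mappings
    (the declarative scenario-file form)."""
    d = dict(d)
    kind = d.pop("kind", "two_sample")
    if "pleiotropy" in d and isinstance(d["pleiotropy"], dict):
        d["pleiotropy"] = PleiotropySpec(**d["pleiotropy"])
    if "outliers" in d:
        d["outliers"] = tuple(tuple(o) for o in d["outliers"])
    if "ld_blocks" in d and d["ld_blocks"] is not None:
        d["ld_blocks"] = tuple(tuple(b) for b in d["ld_blocks"])
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    cls = ProxySimConfig if kind == "proxy" else SimConfig
    return cls(**d)


def run_scenario(scenario: dict, out_dir) -> list:
    """Materialize a scenario: summary tables, optional LD matrix, and the
    truth sidecar, all tab-delimited/JSON under ``out_dir``.

    ``scenario`` has a ``kind`` (two_sample | multivariable | proxy), a
    ``config`` mapping, and for multivariable runs ``n_exposures``,
    ``direct_effects`` and ``cross_effect_correlation``.
    """
    from pathlib import Path
    from .summary_io import write_summary

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kind = scenario.get("kind", "two_sample")
    config = config_from_dict({**scenario.get("config", {}), "kind": kind})
    written = []

    def _write(table, name):
        path = out / f"{name}.tsv"
        write_summary(table, path)
        written.append(path)

    if kind == "two_sample":
        exp_t, out_t, truth = simulate_two_sample(config)
        _write(exp_t, "exposure")
        _write(out_t, "outcome")
    elif kind == "multivariable":
        tables, out_t, truth = simulate_mv_exposures(
            config, n_exposures=scenario.get("n_exposures", 2),
            direct_effects=scenario.get("direct_effects", (0.2, 0.0)),
            cross_effect_correlation=scenario.get("cross_effect_correlation", 0.6))
        for i, t in enumerate(tables, start=1):
            _write(t, f"exposure_{i}")
        _write(out_t, "outcome")
    elif kind == "proxy":
        exp_t, diag_t, proxy_t, truth = simulate_proxy_pair(config)
        _write(exp_t, "exposure")
        _write(diag_t, "outcome_diagnosed")
        _write(proxy_t, "outcome_proxy")
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")

    if config.ld_blocks:
        ld = ld_matrix(exp_t.variant_ids if kind != "multivariable"
                       else tables[0].variant_ids, config.ld_blocks)
        ld_path = out / "ld.tsv"
        ld.to_csv(ld_path, sep="\t")
        written.append(ld_path)
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    written.append(truth_path)
    return written
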