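# Methods

This note documents the statistical models implemented in `mrkit`, the
assumptions they rest on, the calibration of the synthetic data generator,
and the numerical choices that a user auditing results will want to know.

## Two-sample MR model

Genetic variants serve as instrumental variables for a modifiable exposure.
Validity of a variant $j$ requires (i) association with the exposure, (ii)
independence from exposure–outcome confounders, and (iii) the exclusion
restriction: no path to the outcome except through the exposure. Under these,
with summary associations $(\hat\beta_{Xj},\sigma_{Xj})$ and
$(\hat\beta_{Yj},\sigma_{Yj})$ from two non-overlapping samples, the Wald
ratio $\hat\beta_{Yj}/\hat\beta_{Xj}$ estimates the causal effect $\theta$
(log odds of outcome per exposure unit for binary outcomes).

### Instrument selection and harmonization

Instruments are variants below a genome-wide significance threshold (strict
`p < 5e-8`), greedily pruned for LD against a caller-supplied r² matrix —
smallest p first, dropping everything above the r² threshold to a kept
variant, ties broken on variant id for determinism. Real reference panels are
out of scope; the generator emits matching block matrices, which keeps the
study's per-trait thresholds (0.001 / 0.05 / 0.1) exercisable offline. A
chromosome-wide exclusion (chromosome 19) is available to sever the dominant
APOE region in sensitivity runs.

Harmonization aligns both tables on one effect allele: direct match, allele
swap (sign and frequency flip), and strand complement are resolved;
palindromic (A/T, C/G) variants are excluded unconditionally by default
because strand cannot be inferred from alleles alone — the common
allele-frequency rescue is opt-in (`palindromic_maf_window`). Variants
missing from either table are dropped (no LD-proxy lookup) and every
exclusion is written to an audit table with a fixed reason vocabulary.
Frequency discordance is warned about, never filtered on.

### Estimators

| method | estimator | assumption protecting against pleiotropy |
|---|---|---|
| `ivw_fe` / `ivw_mre` | precision-weighted mean of Wald ratios, weights $\hat\beta_{Xj}^2/\sigma_{Yj}^2$ | none (all instruments valid) |
| `egger` | weighted regression with free intercept, instruments oriented to $\hat\beta_{Xj}\ge 0$ | InSIDE: pleiotropy independent of instrument strength |
| `weighted_median` | weight-standardized 50% ratio quantile, parametric-bootstrap SE | >50% of weight on valid instruments |
| `mr_presso` | IVW after simulation-based outlier removal | outliers are the invalid instruments |
| `mvmr` | zero-intercept weighted multiple regression | pleiotropy acts through the modeled co-exposures |

Choices the literature leaves open, fixed here:

- IVW defaults to **multiplicative random effects** (SE × $\sqrt{\max(1,
  Q/(n-1))}$, never narrower than fixed-effect); fixed-effect by flag.
  Results label which was used.
- Wald-ratio SEs are **first-order** ($\sigma_{Yj}/|\hat\beta_{Xj}|$) by
  default — appropriate for strong instruments — with the second-order
  exposure-error term by flag.
- Egger SEs (slope and intercept) carry the same multiplicative
  overdispersion factor $\sqrt{\max(1, RSS_w/(n-2))}$; the $\beta_X\ge0$
  orientation makes the intercept interpretable as mean directional
  pleiotropy and the slope invariant to allele-coding flips.
- Weighted-median bootstrap: 1,000 draws by default, explicit seed required.
- All CIs use the normal multiplier 1.959964, the summary-data convention;
  at the instrument counts in view the difference from t-quantiles is
  negligible.
- Multivariable MR errors on perfectly collinear exposure columns (naming
  the pair — the reason lipid fractions are analyzed in restricted
  adjustment sets), while an all-zero column (no instrument signal for one
  exposure) is solved at minimum norm: direct effect 0, infinite SE, so the
  nested-model identity with univariable IVW holds exactly.

### MR-PRESSO

The observed statistic is the leave-one-out weighted RSS
$\sum_j (\hat\beta_{Yj}-\hat\theta^{(-j)}\hat\beta_{Xj})^2/\sigma_{Yj}^2$;
residuals are weighted by inverse outcome variance, the regression-natural
choice. The null is simulated parametrically (both sides redrawn from their
sampling distributions around the leave-one-out fit); empirical p-values use
the add-one rule so the attainable floor is $1/(n_{sim}+1)$ and floor values
are displayed as bounds ("< 1/(n_sim+1)"). Outlier flags compare
Bonferroni-multiplied per-variant empirical tails to `outlier_alpha` (0.05).
**Resolution constraint:** flagging is possible only if
$n_{snv}/(n_{sim}+1) < \alpha$; the default is therefore `n_sim = 2000`,
which resolves sets of up to ~100 instruments at α = 0.05 (1,000 simulations
would already be blind at 51 instruments). The distortion test compares the
observed relative change (corrected − raw)/|raw| against changes from
removing random pseudo-outlier sets of the observed size.

### Inference report

FDR is Benjamini–Hochberg, applied within (method × outcome data set ×
direction) strata and never pooled across methods. Effects are scaled to
reporting units before exponentiation (e.g. ×10 for per-10-mm-Hg). Instrument
variance explained uses $\beta^2\cdot 2\,\mathrm{MAF}(1-\mathrm{MAF})$, with
frequencies above 0.5 folded to the minor allele under a warning. Binary
exposures report OR of outcome per unit log odds of exposure; no
liability-scale conversion is attempted.

### Power

Power for a binary outcome uses the normal approximation with noncentrality
$\sqrt{N R^2 \varphi(1-\varphi)}\,|b|$ and two-sided level α; the minimum
detectable $|b|$ is found by Brent inversion (xtol 1e-14; forward power at
the returned bound reproduces the target to <1e-6). Applied to the emulated
study grid — 39,106 cases, 401,577 controls, per-exposure $R^2$ from 0.7% to
19% (education's published 12–16% range is carried at its lower bound; the
minimum is attained at 19% regardless) — the smallest minimum detectable
change in outcome log odds is 3.40%, i.e. 3% to the nearest whole percent.
The per-exposure curve is emitted alongside the headline number.

## The synthetic generator

`simulate_two_sample` draws true per-allele effects $b_j\sim N(0.03, 0.01^2)$
(SD-trait units), frequencies $\mathrm{MAF}\sim U(0.05, 0.5)$, and observes

- exposure: $\hat\beta_{Xj}\sim N(b_j, \sigma_{Xj}^2)$,
  $\sigma_{Xj} = (2 N_X \mathrm{MAF}(1-\mathrm{MAF}))^{-1/2}$;
- outcome: $\hat\beta_{Yj}\sim N(\theta b_j + \alpha_j, \sigma_{Yj}^2)$,
  $\sigma_{Yj} = (N\varphi(1-\varphi)\cdot 2\mathrm{MAF}(1-\mathrm{MAF}))^{-1/2}$
  on the log-odds scale.

Defaults emulate the study regime: exposure GWAS of 400k, outcome of 39,106
cases / 401,577 controls, 50 instruments — strong instruments (per-variant
F ≫ 100), jointly explaining ~1.6% of exposure variance; the study-grid
driver scales counts and calibrates $b$ to the published per-exposure
variance explained. A truth record carries every latent quantity, so any
expected estimate can be recomputed by an independent oracle.

Pleiotropy $\alpha_j$ is planted on an `invalid_fraction` of variants:

- **balanced** — zero mean, default sd 0.001: an order of magnitude below
  the outcome-association SE at study scale (~0.009), i.e. weak ubiquitous
  pleiotropy inflating per-variant variance by only a few percent. This is
  deliberately a *near-null* condition: it is the regime in which the IVW
  z-test and the PRESSO global test should still hold their size, and the
  calibration tests verify exactly that.
- **directional** — default mean 0.02, sd 0.005 (InSIDE holds): the regime
  for Egger-intercept recovery.
- **inside_violating** — pleiotropy correlated (0.7) with instrument
  strength, breaking InSIDE.

Two scenario calibrations were fixed by forward error analysis (not by
adjusting to observed test outcomes):

- *Robustness ordering* (40% invalid instruments): IVW's ratio-scale bias is
  ≈ `fraction × mean(α)/E[b]` while the weighted median's is bounded by the
  valid instruments' ratio noise ≈ $\sigma_Y/b$; the two coincide when
  mean(α) ≈ 2.4 σ_Y (~0.02 here), making the ordering a coin flip. The
  scenario therefore plants gross directional pleiotropy, mean 0.05 ≈ 6 σ_Y,
  where IVW's bias is ~2.5× the weighted median's.
- *Planted outliers* are created as strong instruments (per-allele exposure
  effect 0.1, the top of the strength distribution, via `outlier_beta_exp`)
  with outcome effect exactly `ratio × exposure effect` at a small stated
  SE. A weak outlier is both hard to flag (residual z ~ 4) and too light to
  distort IVW beyond its own sampling noise, so "outlier correction reduces
  error" would be undecidable; a gross one (residual z ≈ 18, ~40% of IVW
  weight) makes both halves of the claim testable.

`simulate_mv_exposures` draws per-variant effect vectors from a multivariate
normal with the univariable marginals and equicorrelation ρ; the outcome uses
the stated direct effects only. With direct effects (0.2, 0) and ρ = 0.6 the
univariable estimate for the null exposure converges to
$0.2\cdot\mathrm{E}[b_1 b_2]/\mathrm{E}[b_2^2] \approx 0.19$ (the shared
positive effect mean dominates), while multivariable MR recovers ~0 with
honestly wide intervals — the deconfounding contrast.

### The GWAS-by-proxy family model

Proxy case status cannot be expressed at summary level because the bias runs
through parental genotype, so `simulate_proxy_pair` uses an individual-level
family model (default 100,000 respondent–parent pairs): parent genotypes
$g_p\sim\mathrm{Bin}(2,\mathrm{MAF})$; one respondent allele transmitted from
the parent (transmission coefficient 0.5 ⇒ genotype correlation 0.5, checked
empirically); exposures are genetic value + environment, standardized;
parental disease follows a logistic model in the parent's exposure
(prevalence 0.15, same θ as the diagnosed outcome); and the respondent
*reports* parental disease with probability
$\mathrm{expit}(\mathrm{logit}(r_{D_p}) + \lambda X_{\mathrm{offspring}})$,
report rates 0.30 (diseased parent) vs 0.02 (healthy), reporting effect
λ = 0.25 per SD of the respondent's own exposure. Per-variant associations
with the report are computed by vectorized linear regression and transformed
to the log-odds scale by $1/\bar y(1-\bar y)$.

Linearizing, the per-allele proxy effect is
$b_j\,[c\,p(1-p)\,\theta\,t + \lambda]$ with $c = \mathrm{logit}(0.30)-
\mathrm{logit}(0.02) \approx 3.04$, $p = 0.15$, $t = 0.5$: a dilution channel
of −0.034 (for θ = −0.18) against a reporting channel of +0.25. λ = 0.25 was
chosen so the reporting channel dominates decisively (IVW z ≈ 2 at the
default sizes), reproducing the qualitative reversal — protective on the
diagnosed outcome, apparently harmful on the proxy outcome. With λ = 0 the
model shows the dilution-only regime: attenuated toward zero, same sign.
`proxy_weight < 1` blends the diagnosed and proxy channels by precision, as
a mixed outcome set would.

### What the generator does not emulate

Summary statistics are simulated directly (no genome-wide LD structure;
the block r² matrices drive clumping only and do not correlate the effect
estimates), populations are unstructured, exposure and outcome samples never
overlap, and allele codings across co-generated tables are consistent by
construction. Passing tests therefore demonstrate correctness of the
estimators and the stated bias mechanisms under clean sampling assumptions —
not robustness to cryptic sample overlap, stratification, or real LD. The
published odds ratios of the emulated study are direction-setting context
only; its input summary statistics are not public, so no test asserts them.

## Problem sizes used by the statistical test suite

Null calibration uses 1,000 replicates (PRESSO global with 500 simulations,
ample resolution at α = 0.05); parameter recovery 500; robustness ordering
and MVMR deconfounding 200 each (PRESSO at its 2,000-simulation default);
the proxy reversal 100 replicates of the 100,000-family model; oracle
equivalence 100 random instrument sets at relative tolerance 1e-10
(weighted median 1e-6). The whole suite runs in a few minutes on one core.

## Known limitations

- Greedy clumping against a supplied r² matrix cannot reproduce published
  instrument counts that depended on reference-panel windows.
- First-order Wald SEs understate uncertainty for weak instruments; use the
  second-order flag when instrument F-statistics are modest.
- The Egger intercept CI relies on the multiplicative-overdispersion
  variance model; when pleiotropy variance is large relative to outcome
  sampling variance its weights are misspecified and coverage runs ~2–5
  points below nominal (visible in the recovery test, which sits just above
  its 90% bar).
- Empirical PRESSO p-values are bounded below by the simulation count;
  interpret floor values as bounds, and size `n_sim` to the instrument
  count.
- No liability-scale conversion for binary exposures; estimates are per
  unit log odds of the exposure.
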