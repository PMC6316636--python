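# Methods

## Model

For SNP j let βˣⱼ be its per-allele effect on the exposure (here natural-log
serum 25-hydroxyvitamin D) and βʸⱼ its per-allele log odds ratio for the
outcome (major depression), with standard errors σˣⱼ and σʸⱼ from two
non-overlapping GWAS. If SNP j is a valid instrument, βʸⱼ = θ·βˣⱼ where θ is
the causal log-OR per unit exposure, so each SNP supplies a ratio estimate

    θ̂ⱼ = βʸⱼ / βˣⱼ,   SE(θ̂ⱼ) = σʸⱼ / |βˣⱼ|.

The SE is first order: uncertainty in βˣⱼ is ignored, the standard
approximation in two-sample MR where the exposure GWAS is much more precise
than the outcome GWAS (here σˣ/|βˣ| ≤ 18% per SNP, and the neglected variance
term is smaller than the retained one by a factor of roughly θ̂²·(σˣ/βˣ)² —
negligible for the shipped data). A second-order SE is deliberately not the
default because the shipped analysis's published interval is reproduced with
the first-order form.

### Estimators

- **IVW**: θ̂ = Σwⱼθ̂ⱼ / Σwⱼ with wⱼ = SE(θ̂ⱼ)⁻²; fixed-effect
  SE = (Σwⱼ)^(−1/2), algebraically identical to the zero-intercept weighted
  regression of βʸ on βˣ with weights 1/σʸ². The multiplicative
  random-effects option inflates the SE by √(Q/df) floored at 1, so it can
  never be anti-conservative relative to fixed-effect; with Q < df the two
  coincide.
- **Weighted median**: sort θ̂ⱼ; with normalized weights w′ⱼ compute midpoint
  cumulative fractions pₖ = Σ_{i≤k} w′ᵢ − w′ₖ/2 and linearly interpolate θ̂
  at p = 0.5 (boundary value taken outside [p₁, pₙ]). Ties are broken by a
  stable sort on (θ̂, rsID) for determinism. The SE is a parametric
  bootstrap: θ̂ⱼ* ~ N(θ̂ⱼ, SE(θ̂ⱼ)) redrawn n_boot times (default 10,000,
  default seed 20181987), taking the SD of the recomputed medians. The
  replicate count is a bias/runtime compromise: at 10,000 the SE is stable to
  well under 5% between independent halves.
- **MR-Egger**: weighted least squares of βʸ on βˣ *with* intercept, weights
  1/σʸ², all instruments oriented so βˣ > 0. The intercept estimates average
  directional pleiotropy; the slope is a pleiotropy-adjusted causal estimate
  valid under InSIDE (pleiotropic effects independent of instrument
  strengths). Standard errors carry the residual-dispersion factor
  max(1, √(RSS_w/(n−2))). p-values default to the t distribution on n−2 df —
  with n = 6 instruments the normal would be anti-conservative — with
  `use_t=False` available for the normal convention used by some
  implementations. Confidence intervals use the normal multiplier 1.959964
  for uniformity across methods; with few instruments the Egger p-value is
  therefore the more conservative of the two summaries.
- **Heterogeneity**: Cochran's Q = Σwⱼ(θ̂ⱼ − θ̂)² on n−1 df,
  I² = max(0, (Q − df)/Q)·100.

### Reporting scale

Estimates are pooled per unit of the oriented exposure and rescaled to an
odds ratio per SD via OR = exp(θ̂·SD). The shipped S-25OHD SD of 0.33
ln-nmol/L (descriptively, about 18 nmol/L) is a configuration default taken
from an external clinical cohort, not a constant of the method; the
"18 nmol/L" label never enters computation. Direction "decrease" reports the
OR per SD *fall* in the exposure; "increase" is its exact reciprocal with
swapped CI bounds. Text output rounds ORs/CIs/p to two decimals
(half-away-from-zero); JSON/TSV output carries full precision.

### Orientation

The shipped instrument set codes every effect allele as S-25OHD-*lowering*,
and results are quoted per SD decrease. Harmonization therefore defines the
oriented exposure as "exposure decrease": any SNP whose raw exposure beta is
positive has both betas negated, then the exposure beta's sign is reversed
once more, so β_exposure = |βˣ| > 0 while β_outcome keeps its sign per the
exposure-lowering allele. This is the only orientation consistent with the
shipped data's published intercept sign (−0.006); the mirror coding
("exposure_increase") is available and simply negates the causal estimand.

### Power

The causal log-OR per exposure SD is estimated with approximate variance
1/(N·R²·K·(1−K)) — N outcome sample size, K case fraction, R² exposure
variance explained by the instruments — giving noncentrality
z\* = √(N·R²·K·(1−K))·|ln OR| and two-sided power
Φ(z\*−z₁₋α/₂) + Φ(−z\*−z₁₋α/₂). An `or_minus_1` effect-scale variant
replaces |ln OR| with |OR−1|; for the shipped design (N = 173,005,
K = 0.346, R² = 0.075, OR = 1.09) both round to 100% power at whole-percent
precision, so the choice is immaterial there. `min_detectable_or` inverts
the formula by bisection on ln OR over (0, ln 10] to 1e−8.

## Harmonization rules

Records join strictly on rsID (no positional matching — the intended inputs
key on rsID only). When the outcome's effect allele differs from the
exposure's, the outcome beta is sign-flipped and EAF complemented; reports on
the opposite strand are recognized via base complement when a second allele
is available. Palindromic SNPs (A/T, C/G) with EAF within 0.08 of 0.5
(configurable) are ambiguous and excluded with a warning, or raise in strict
mode; the shipped instrument set prints no second allele, so it is treated
as pre-harmonized and palindromic screening applies only when both alleles
are supplied. Missing optional fields (EAF, p, counts) stay absent — never
imputed. GWAS p-values below the smallest positive double (e.g. 1e−343) are
floored there rather than read as zero.

## Synthetic data

The generator emulates two independent GWAS at the summary level: true
per-allele exposure effects γⱼ with uniform magnitudes and random signs,
direct (pleiotropic) outcome effects αⱼ ~ N(mean, sd) drawn independently of
γⱼ (InSIDE holds by construction, applied per the exposure-raising allele),
and observed effects with Gaussian noise at the reported SEs. Defaults
mirror the shipped instrument set: 6 SNPs, per-allele effects 0.017–0.089,
exposure SEs 0.002–0.003, outcome SEs 0.008–0.011, null causal effect, no
pleiotropy. `simulate_at_fixture_strength` holds the exposure side at the
shipped values exactly and redraws only outcome betas — the configuration
used for type-I-error calibration at the real instrument strength.

What the simulator does *not* model: linkage disequilibrium between
instruments, winner's curse in instrument selection, case-control sampling
at the individual level, sample overlap between the two GWAS, and
InSIDE-violating (correlated) pleiotropy. Passing recovery and coverage
tests on these simulations therefore validates the estimators under their
own assumptions; they say nothing about robustness to correlated pleiotropy
or weak-instrument bias in real data.

## Test problem sizes

Stochastic calibration tests run at: 500 datasets of 50 instruments for IVW
bias/coverage and for Egger intercept recovery; 200 seeds of 100–200
instruments for consistency and pleiotropy-ordering checks; 1000 seeds for
the null rejection rate at the shipped instrument strength. The consistency
check uses SE scales of 1e−3–2e−4 because it asserts a 0.01 bracket on three
estimators at once and the Egger slope converges slowest over a narrow
instrument-strength range. All complete in seconds; Monte-Carlo acceptance
bands (coverage 92–98%, type-I 3–7%) come from binomial noise at those
replicate counts.

## Known limitations

- No mode-based estimators, MR-PRESSO, multivariable MR, Steiger filtering,
  or weak-instrument (F-statistic) diagnostics.
- No GWAS-VCF/.sumstats readers, LD clumping, proxy lookup, or liftover;
  multi-allelic variants are out of scope.
- Exact bit-level agreement with other MR implementations (e.g. Stata's
  mrrobust) is not claimed: df conventions and dispersion floors differ
  between packages; published two-decimal results for the shipped data are
  reproduced under the conventions above.
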