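# Methods

This note documents the statistical model behind `mrkit`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Two-sample summary-data MR

The package assumes the standard instrumental-variable structure: each SNP
*j* affects the exposure X (per-allele effect γⱼ), is independent of
confounders, and affects the outcome Y only through X, except where a
direct ("horizontally pleiotropic") effect αⱼ is being tested for. With
summary statistics (γ̂ⱼ, σ_Xⱼ) and (Γ̂ⱼ, σ_Yⱼ) from two non-overlapping
samples of the same ancestry, the true outcome association is
Γⱼ = βγⱼ + αⱼ, where β is the causal log-odds effect per unit exposure.

The per-SNP Wald ratio β̂ⱼ = Γ̂ⱼ/γ̂ⱼ uses the first-order standard error
σ_Yⱼ/|γ̂ⱼ|. This convention (shared by the mainstream summary-MR tools)
ignores the exposure-side sampling noise; its consequences are quantified
under *Validation experiments* below.

## Instrument selection

1. **Significance filter** — keep SNPs with exposure p < 5×10⁻⁸ (strict
   inequality; thresholds 0 and 1 act as "keep none"/"keep all").
2. **LD clumping** — greedy by ascending p-value (ties broken by rsid so
   the result is independent of input order); a candidate is rejected if
   it has r² ≥ 0.1 with an already-accepted SNP within a 10,000 kb window.
   When the LD reference has no positions the window is skipped, and pairs
   absent from the reference are treated as unlinked (both are logged);
   this lets a plain rsid/r² table serve as the reference.
3. **MAF filter** — drop minor-allele frequency below 5%; the boundary is
   kept (the removal rule is "< 5%"), and SNPs with missing frequency are
   retained with a warning since they cannot be assessed.
4. **Proxies** — an instrument absent from the outcome study is replaced by
   the available SNP with the highest r² strictly above 0.9 (ties broken
   lexicographically). The proxy must be present in *both* studies so that
   exposure and outcome effects refer to the same variant; cross-variant
   allele bridging is deliberately not attempted.

## Harmonization

Outcome effects are re-expressed on the exposure's effect allele: direct
match → unchanged; swapped alleles → negate beta, complement the allele
frequency; otherwise the outcome alleles are strand-complemented
(A↔T, C↔G) and the two rules retried; irreconcilable sets are dropped.
Palindromic SNPs (A/T, C/G) cannot be strand-resolved from labels, so they
are kept only when both allele frequencies exist, both are farther than
*w* = 0.08 from 0.5, and they point to the same allele after label
alignment; anything else is dropped as ambiguous. The window is
configurable and *w* = ∞ reproduces a strict always-exclude policy; 0.08
is the common operating point for frequency-based orientation. Missing
frequency on a palindromic SNP always drops it. Indels and multi-allelic
records are rejected at parse time — the instrument sets this package
targets are biallelic SNPs.

Harmonization is involutive in the outcome's reported orientation and
never changes effect magnitudes or standard errors (property-tested).

## Estimators

* **IVW**: β̂ = Σwⱼβ̂ⱼ/Σwⱼ, algebraically identical to through-origin WLS
  of Γ̂ on γ̂ with weights 1/σ_Yⱼ² (tested to 10⁻¹⁰). The multiplicative
  random-effects variant scales the SE by max(1, √(Q/(n−1))) —
  underdispersion never shrinks the fixed-effect SE. Normal reference for
  p-values and 1.96-SE confidence intervals.
* **MR-Egger**: instruments are oriented so γ̂ⱼ > 0 (the Wald ratio is
  invariant to joint negation), then WLS with a free intercept, weights
  1/σ_Yⱼ². Inference uses t(n−2) with the residual scale estimated from
  the fit, since two parameters are estimated from few points and
  overdispersion should widen the intervals. An exact fit (weighted RSS at
  floating-point noise) is treated as degenerate: the t statistic would be
  a ratio of rounding errors, so the p-value is 1 for a zero coefficient
  and 0 otherwise.
* **Weighted median**: linear interpolation of sorted ratios against the
  standardized cumulative weights sⱼ = (Σ_{i≤j}wᵢ − wⱼ/2)/Σw at s = 0.5.
* **Weighted mode**: normal-kernel weighted density of the ratios,
  bandwidth h = 0.9·min(sd, mad/0.6745)·n^(−1/5) times a configurable
  factor (default 1), argmax over a 512-point grid spanning
  [min−3h, max+3h], ties broken toward the smaller value. All ratios
  identical (h = 0) returns the common value with the fixed-effect IVW SE.
* Median and mode SEs come from a seeded parametric bootstrap (resample
  each ratio from N(β̂ⱼ, seⱼ²), default 1000 replicates); the replicate
  count and bandwidth are not pinned down by any convention stronger than
  the original methods' defaults, so both are configurable.

## Diagnostics and method choice

Cochran's Q about the IVW estimate (χ², n−1 df) and Rücker's Q′ about the
Egger fit (n−2 df) measure heterogeneity; Q ≥ Q′ always, and Q equals the
through-origin weighted RSS identity. "Detected" means p < 0.05 for both
tests (configurable α). The flowchart: no pleiotropy and no heterogeneity
→ fixed-effect IVW; heterogeneity only → multiplicative-random-effects IVW,
with the outlier test also run — if it flags instruments, the
outlier-corrected IVW becomes primary, since the outlier machinery exists
to correct rather than merely detect; pleiotropy → MR-Egger. The flowchart
consumes the IVW Q (matching the candidate primary method); Q′ is reported
alongside.

The outlier test follows the simulation-based residual framework: the
observed statistic is the sum of weighted squared leave-one-out residuals
Σⱼ wⱼ(Γ̂ⱼ − γ̂ⱼβ̂₋ⱼ)²; the null distribution resamples both effect sets
parametrically (default 1000 draws); per-SNP empirical p-values are
Bonferroni-corrected and flagged below α; the distortion test compares the
estimate shift after removing flagged SNPs with 1000 random same-size
removals. Empirical p-values use the (r+1)/(n+1) convention so they are
never zero. Leave-one-out marks a SNP influential when its exclusion makes
the CI cross the null while the full-set CI does not.

## Reporting, scaling and power

Estimates are log-odds per unit (1 SD of the log exposure). For reporting
they are rescaled and exponentiated. Two modes exist because "per 10%
increase" conversions appear in the literature in two forms: a plain
multiplier (default 1.1) applied to the log-scale estimate, and the
conventional ln(1.1) ≈ 0.0953 per-10%-of-raw-scale conversion
(`scale_mode: log`). The default replicates the multiplier form; the
choice only rescales the log-estimate and leaves p-values untouched.

Binary-outcome power uses the non-centrality approximation: with case
fraction K and alternative odds ratio OR, b = K(OR/(1+K(OR−1)) − 1),
v = (K(1−K) − b²)/(N·r²), and power is the upper tail of χ²(1, b²/v)
beyond the central critical value; OR = 1 returns exactly α. Power is
evaluated at two alternatives (default OR 1.1 and 1.3, inverted for
protective estimates) with r² defaulting to 0.0265, the variance explained
in the emulated exposure GWAS. Bonferroni across outcomes divides α by the
number of outcomes (0.05/6 ≈ 0.0083 for the six-cancer layout).

Instrument strength is reported in both conventions in circulation: the
variance-explained form F = (R²/k)/((1−R²)/(n−k−1)) and the mean per-SNP
Wald form mean((γ̂/σ_X)²). The two can differ substantially (at R² = 2.65%,
k = 8, n = 7827 the first is ≈ 26.6 while per-SNP values depend on how the
variance is spread), which is why both are emitted rather than guessing
which one a given report used. I²-GX is computed from the heterogeneity of
the positively-oriented γ̂ with inverse-variance weights,
(Q_GX − (k−1))/Q_GX floored at 0 — the Egger regression-dilution
diagnostic.

## Synthetic generator

`simulate_study` works at the summary level: maf ~ U(0.1, 0.5); raw
effects ~ N(0,1) rescaled so Σ2p(1−p)γ² equals the target r² exactly
(the exposure is a variance-1 log-scale trait, so γ is in SD units);
σ_X = 1/√(2p(1−p)·n_exp); observed effects are drawn around the truth;
outcome SEs use the case/control effective size 4/(1/cases+1/controls).
Pleiotropic effects are defined relative to the exposure-increasing allele
(αⱼ = sign(γⱼ)·(μ + σ·zⱼ)), so a directional mean pushes all oriented
instruments the same way; an InSIDE violation correlates the oriented αⱼ
with |γⱼ| at ρ = 0.8. Outliers displace chosen observed outcome effects by
a fixed multiple of their SE. Defaults mirror the emulated study pair:
8 instruments, r² = 2.65%, n_exp = 7827, 6,000 cases / 195,000 controls
(biobank magnitude — the exact published counts live in a supplement that
is not redistributed here), and the shipped fixture adds a protective
causal effect of gastric-cancer size (OR ≈ 0.88 per 10% increase).

What the generator does *not* emulate: LD between instruments (identity by
default; `simulate_block_ld_study` adds block correlation solely to
exercise clumping), winner's-curse inflation from genome-wide selection,
mixed-model association artifacts, sample overlap, and population
stratification. Passing tests therefore demonstrate correctness of the
estimators and diagnostics under the assumed generative model, not
robustness to those real-data complications.

## Validation experiments

`mrkit.validation` runs the Monte-Carlo studies reported by
`scripts/acceptance.py`. Problem sizes are desk-scale by design: 200
replicates for recovery, 200–300 for calibration, 100 for outlier
detection, 1000 simulation draws inside each outlier test.

* **Recovery** (50 instruments, β = 0.2, n_exp = 8000, 10k/10k outcome):
  all four estimators' means land within ±0.02 of the truth. The
  experiment uses r² = 0.70 (per-SNP F ≈ 112) so that what is measured is
  the estimators, not weak-instrument attenuation. Even with arbitrarily
  strong instruments, the first-order ratio SE omits the exposure-noise
  variance fraction β²·n_eff/n_exp ≈ 10% under these sample sizes, which
  caps true IVW 95% CI coverage near 0.93–0.94 (large-replicate runs give
  ≈ 0.932); single 200-replicate measurements scatter around that value
  by ±0.018. This is a documented property of the standard first-order
  convention, not an implementation artifact — with exposure noise removed
  the measured coverage is 0.95.
* **Egger intercept calibration**: balanced (mean-zero) pleiotropy,
  sd = 0.005, 50 strong instruments — rejection near the nominal 5%.
* **Global outlier-test calibration**: homogeneous data with a real causal
  effect — rejection near 5%; a single instrument displaced by 10 SE among
  10 is flagged in essentially every run.

## Known limitations

Only biallelic SNPs keyed by rsid (no coordinates, liftover or indels);
proxies require presence in both studies; no Steiger filtering, radial MR
or multivariable extensions; power assumes the non-centrality
approximation rather than simulating the full two-stage design; the
first-order ratio SE undercovers when the outcome study is much larger
than the exposure study and the true effect is sizeable (see above).
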