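# Methods

This note documents the statistical models, default parameters, numerical
choices and known limitations of `drugtarget-mr`.

## Setting and notation

A drug-target MR analysis asks whether lifelong genetic perturbation of a
drug target's activity — proxied by variants in or near the encoding gene
that shift a biomarker the target controls — changes disease risk. The
package's running example is LDL cholesterol (mmol/L) as the exposure and a
case-control inflammatory-disease outcome on the log-odds scale. For score
variant j we write β_Xj ± σ_Xj for the per-allele exposure effect,
β_Yj ± σ_Yj for the per-allele outcome log-odds, ρ_jk for the signed LD
correlation, and θ_j = β_Yj/β_Xj for the per-SNP Wald ratio.

**Orientation convention.** Every score stores positive exposure-lowering
weight magnitudes together with the allele whose inheritance lowers the
exposure. After harmonization bx_j = |β_Xj| > 0 and by_j is sign-consistent,
so every pooled estimate is natively a log-odds per 1 mmol/L exposure
*decrease* and odds ratios below 1 mean protection. When a counted allele
switches relative to the LD matrix's coding, the corresponding row and
column of ρ flip sign. This convention makes orientation invariance testable:
flipping the counted allele of any SNP and re-harmonizing leaves every
estimator's output unchanged (a property test enforces this).

## Instrument construction

- **Cis scores**: variants within the gene body ± 100 kb (1-based hg19
  coordinates), exposure association p < 5×10⁻⁸, pairwise r² ≤ 0.2.
  Selection is greedy by ascending p-value with ties broken by variant id;
  a candidate is accepted only if it passes the prune threshold against all
  previously accepted variants in *every* supplied LD panel (so "weak LD in
  both populations" is an AND over panels).
- **Polygenic score**: no region filter, r² < 0.001 (effectively
  independent instruments).
- **Proxies**: when an outcome cohort lacks a score variant, the candidate
  with the highest r² ≥ 0.9 substitutes; ties go to the lexicographically
  smallest id so runs are deterministic.
- **Harmonization**: alleles match directly or via strand complement;
  the outcome beta's sign flips when its effect allele is the counted
  allele's partner. Palindromic (A/T, C/G) variants are dropped when the
  effect-allele frequency is missing or within 0.08 of 0.5 (default band;
  strand unresolvable), a conservative configurable policy.
- **Strength**: per-SNP F = (β_X/σ_X)²; a variant with F ≤ 10 is flagged
  weak. Selection at genome-wide significance already implies F above the
  χ²₁ quantile at 5×10⁻⁸ (≈ 29.7), which the report includes for context.
- **Cross-cohort pooling** of outcome effects is fixed-effect
  inverse-variance meta-analysis per SNP, applied after each cohort is
  oriented to the score's counted alleles.

## Estimators

**Correlated-variant IVW.** GLS of by on bx without intercept under
Ω = outer(sy, sy)·ρ: β̂ = (bxᵀΩ⁻¹bx)⁻¹ bxᵀΩ⁻¹by, SE = (bxᵀΩ⁻¹bx)^(−1/2).
With ρ = I this is exactly inverse-variance pooling of the per-SNP ratios.
Heterogeneity: Q = residᵀΩ⁻¹resid against χ²_{k−1}; I² = max(0, (Q−(k−1))/Q).
The multiplicative random-effects variant multiplies the SE by
max(1, √(Q/(k−1))) and leaves the point estimate unchanged; it is the
default for the polygenic score, fixed-effects for cis scores. Ω with a
condition number above 10⁸ is refused (prune harder) rather than silently
inverted. One caveat worth recording: the IVW SE is monotone non-decreasing
in positive LD only for exchangeable instruments (equal standardized
strengths bx_j/sy_j); with heterogeneous strengths, strong correlation can
*add* GLS information (a control-variate effect), which is expected
behavior, not a bug.

**MR-Egger.** Correlation-aware GLS of by on bx *with* intercept. The slope
is the causal estimate under InSIDE; a nonzero intercept indicates
directional pleiotropy. Standard errors carry the multiplicative
overdispersion factor max(1, √(Q/(k−2))) and inference uses t_{k−2}, the
standard random-effects Egger treatment — without it the intercept test is
badly anticonservative whenever balanced pleiotropy inflates residual
variance beyond the outcome SEs. An optional bootstrap resamples SNPs with
replacement (seeded) and reports a percentile CI for the slope. Egger is
sensitive to exposure measurement error: with the exposure GWAS at the
n ≈ 1.9×10⁵ scale the package targets, the attenuation reliability of the
effect spread is ≈ 0.98 and the intercept test is near-nominal; at much
smaller exposure samples the known NOME-violation intercept bias appears
(we measured ≈ 11% type-I error at n = 20,000 in scratch experiments), so
the calibration suite fixes the exposure scan at 188,578.

**Weighted median.** Per-SNP ratios ordered, inverse-variance weights
normalized, cumulative p_j = S_j − w_j/2 interpolated at ½; SE from a
seeded parametric bootstrap (default 5,000 draws of bx, by around their
observed values). Consistent while valid instruments carry ≥ 50% of weight.

**Profile maximum likelihood.** Observed (bx_j, by_j) are modeled as normal
around (ξ_j, βξ_j) with SDs (sx_j, sy_j); the nuisance ξ_j profile out
analytically, leaving ℓ(β) = −½ Σ (by_j − β bx_j)²/(sy_j² + β² sx_j²),
maximized by Brent's method from the IVW start with widening brackets; the
SE is the inverse square root of the numerical profile curvature
(central difference, step 10⁻⁴(1+|β|)). Assumes independent instruments — the setting
where it is used here (the r² < 0.001 polygenic score); it reduces to IVW
as sx → 0 and to the Wald ratio at k = 1.

**MR-PRESSO.** Observed statistic: weighted leave-one-out residual sum of
squares Σ_j w_j (by_j − β̂_{−j} bx_j)², w_j = 1/sy_j². Null distribution:
n_sim parametric draws bx* ~ N(bx, sx), by* ~ N(bx*·β̂_{−j}, sy), identical
functional applied; the global p is the exceedance fraction (with the +1
correction). Per-SNP outlier p-values come from each SNP's simulated squared
residual distribution, thresholded at 0.05/k (Bonferroni). The corrected
estimate is IVW on the surviving SNPs; flagging every SNP is an error, not a
silent empty answer. Defaults: n_sim = 5,000; tests use smaller n_sim, which
only coarsens p-value resolution.

**Multivariable GLS.** Joint regression of by on several exposures' SNP
effects under the same Ω, no intercept; column 0 is the primary exposure and
its coefficient is the pleiotropy-adjusted effect. An all-zero covariate
column is treated as a nested model (null estimate, p = 1) rather than a
rank error; genuinely collinear columns are refused. Risk-factor screening
(`score_trait_association`) flags a candidate pathway when the pooled score
effect on that trait has p strictly below 0.05, feeding the covariate list.

## Colocalization

Per-SNP Wakefield log approximate Bayes factors,
log ABF = ½[log(1−r) + z²r], r = W/(V+W), V = se². Prior effect SDs default
to 0.20 per standardized unit for the quantitative trait (W₁ = 0.04) and
0.15 log-odds for the binary trait (W₂ = 0.0225), the conventional choices
for these scales. Conditional on one shared causal variant in the region,
PPA_j = softmax(labf1_j + labf2_j) under equal per-SNP priors; variants
above a reporting threshold (default 0.01) are flagged. The five-hypothesis
region-level decomposition is deliberately out of scope: the package reports
the per-SNP shared-variant posterior only, which is shift-invariant in the
log Bayes factors and flattens to uniform as either W → 0.

## Dose-response and power

The individual-level dose-response remodels the case/control logistic
regression on a restricted cubic spline (Harrell parameterization: linear
beyond boundary knots) of the weighted score, with 4 knots at the 5/35/65/95
percentiles by default (3- and 5-knot placements available; n_knots = 0
degenerates to the ordinary linear logistic fit). Odds-ratio curves are
normalized to OR = 1 at a reference score (median by default) so the
intercept cancels in the contrast; CIs come from the delta method on the
basis-difference contrast. Trend tests are logistic score
(Cochran–Armitage-type) tests on the integer exposure-allele count and on
the score value. Quintile strata compare Q2–4 and Q5 against Q1. At least 50
cases are required, and detected separation is an error (penalized
regression is out of scope).

Analytic power for binary-outcome MR uses the normal approximation
power = Φ(|log OR|·√(N·R²·K(1−K)) − z_{1−α/2}). At N = 33,998,
K = 12,596/33,998, R² = 0.004, OR = 0.5, α = 0.05 it gives 97.4%. The
Monte-Carlo cross-check in the test suite simulates score → exposure →
logistic outcome and counts Wald rejections; agreement is within 3
percentage points at the tested configurations, with the caveat that for
strong effects (OR ≲ 0.6) logistic noncollapsibility attenuates the marginal
slope and the approximation becomes optimistic by several points — the
tested configurations use moderate odds ratios where the approximation is
accurate.

## Synthetic studies

The generator emulates the two-sample design end to end:

- **Dosages**: two latent multivariate-normal haplotypes per individual are
  thresholded at Φ⁻¹(MAF) and summed; the latent pairwise correlation is
  calibrated by root-finding so the *dosage* correlation hits the target LD
  (dosage correlation equals the haplotype-indicator correlation because
  haplotypes are i.i.d.). Unattainable targets (Fréchet-bound violations for
  rare-rare pairs) are an error; slightly non-PSD latent matrices are
  eigenvalue-clipped, with a hard error if repair moves the matrix by more
  than 0.1.
- **Exposure cohort**: X·β + N(0, σ²) with σ = 0.85 mmol/L (a typical
  population SD for LDL cholesterol); per-SNP simple linear regressions give
  the exposure scan.
- **Outcome cohort**: logistic disease model with linear predictor
  logit(K) + causal_beta·(exposure − E[exposure]) + direct·(dosage −
  E[dosage]); centering makes K the *marginal* prevalence whether or not
  effects are null. Default prospective sampling of n individuals at
  prevalence K; a designed case/control split (e.g. 497/4,416) is obtained
  by simulating a larger base population and sampling the designed counts.
  Per-SNP logistic maximum likelihood (vectorized 2-parameter Newton,
  identical to the textbook MLE) gives the outcome scan on the case-control
  log-odds scale. Fewer than 10 realized cases or controls is an error.
- **Seeds**: one global seed expands through a fixed
  `numpy.random.SeedSequence.spawn` rule into per-component streams
  (exposure dosages / exposure noise / outcome dosages / outcome phenotype),
  so all outputs are byte-reproducible and `simulate_cohort` returns exactly
  the cohort embedded in the full two-sample study.

Defaults mirror the target study's conditions: 4 variants with per-allele
effects (−0.073, −0.057, −0.042, −0.035) mmol/L, causal log-odds
−log(0.57) per mmol/L decrease, outcome cohort 4,913 at prevalence 0.101
(a 497/4,416 case-control collection), exposure cohort 50,000 (a scaled-down
exposure GWAS; the calibration suites raise it to 188,578 where Egger's
exposure-error sensitivity matters). MAFs default to (0.35, 0.12, 0.22,
0.16) — common-variant frequencies chosen once as realistic; the source
table does not publish them.

**What the synthetic studies do not capture**: genome-wide realistic LD
(only the specified pairwise targets), population structure and
relatedness, allele-frequency differences between cohorts, genotyping or
imputation error, and real pleiotropy architectures beyond the
normal/constant direct-effect models. Passing calibration on these studies
therefore demonstrates correctness of the estimators under their stated
assumptions, not robustness to the full messiness of real cohort data.

## Calibration-study designs in the test suite

Chosen once as the package's own designs and documented here:

- **CI coverage** (IVW and profile ML): 500 replicates of the default
  4-variant study with true OR 0.57 per mmol/L decrease, exposure n = 50,000,
  outcome n = 8,000 at prevalence 0.101; coverage must land in [0.93, 0.97].
- **Egger intercept type-I error**: 300 replicates, m = 50 exchangeable
  instruments (constant MAF 0.3 so outcome SEs are homoscedastic — with
  heterogeneous SEs the multiplicative-overdispersion weighting is itself
  misspecified, a separate known phenomenon), balanced pleiotropy
  N(0, 0.04²), exposure n = 188,578, outcome n = 10,000; the rejection rate
  must sit within 5% ± 2%.
- **MR-PRESSO detection**: 200 summary-level sets of 11 SNPs on θ = −0.5
  with one outcome effect displaced by 10 outcome-SEs; the planted outlier
  must be flagged in ≥ 95% of runs (n_sim = 600, Bonferroni 0.05/11).
- **Power formula vs Monte Carlo**: four configurations with moderate odds
  ratios (0.75–0.85) and mid-range power, 1,500 replicates each, agreement
  within 3 percentage points.

Replicate counts and cohort sizes are the package's own scaled-down choices
that keep each suite's Monte-Carlo error well inside the asserted bands.

## Known limitations

- No Steiger directionality filtering, mode-based estimators, MR-RAPS or
  multi-causal-variant colocalization (out of scope by design).
- The maximum-likelihood and MR-PRESSO procedures assume independent
  instruments; they are applied to the r² < 0.001 polygenic score, where the
  assumption is by construction nearly exact.
- Wald-ratio SEs are first-order by default (sy/bx); the second-order term
  is available behind a flag and matters only for weak instruments, which
  the F > 10 screen excludes.
- LD matrices are inputs: the package performs no reference-panel
  computation, genome-build conversion or VCF/BGEN parsing.
- The file formats are deliberately minimal TSVs with a strict header
  synonym table; unknown columns are an error rather than a guess.
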