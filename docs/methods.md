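# Methods

## The model

`mrmediate` implements two-sample Mendelian randomization (MR) with a
mediation layer. Genetic variants G serve as instruments for an exposure
X (here, gut microbial traits), a candidate mediator M (a blood
metabolite or cytokine), and a disease outcome Y (rheumatoid arthritis).
Writing θ1 for the causal effect X→M, θ2 for M→Y and θ3 for the direct
path X→Y, the structural model is

    M = θ1·X + ε_M
    Y = θ3·X + θ2·M + ε_Y

so the total causal effect of X on Y is θ3 + θ1·θ2 and the indirect
(mediated) effect is θ1·θ2. All estimation is summary-level: the only
inputs are per-SNP GWAS coefficients (β, se) for each trait.

Two decompositions of the indirect effect are computed:

* **product of coefficients (two-step MR)** — θ̂1·θ̂2, where θ̂1 is the
  IVW estimate of X→M using X's instruments and θ̂2 the IVW estimate of
  M→Y using M's instruments; the standard error is first-order delta
  method, sqrt(θ2²·se1² + θ1²·se2²) (the exact-variance cross term
  se1²·se2² is available via `exact=True`);
* **difference in coefficients (MVMR)** — total effect minus the direct
  effect θ̂3 from a multivariable IVW regression that includes both X's
  and M's per-SNP effects; its SE conservatively adds the two variances.

The proportion mediated is 100·indirect/total, reported only when the
two agree in sign; otherwise it is NA with reason `inconsistent-sign`
(this is how published mediation tables in this literature handle
sign-discordant pairs). Proportions above 100% are flagged, not
truncated — they can arise from estimation noise.

## Estimators

* **IVW (multiplicative random effects)** — weighted regression of
  outcome betas on exposure betas through the origin, weights 1/se_out².
  Cochran's Q is the weighted residual sum; the fixed-effect SE is
  multiplied by max(1, √(Q/df)). The factor never shrinks the SE, which
  makes the test mildly conservative under homogeneity (measured
  type-I error ≈ 0.043 at α = 0.05 with 50 instruments).
* **Wald ratio** — by/bx with first-order SE sy/|bx|; used automatically
  when only one instrument survives.
* **Maximum likelihood** — bivariate-normal model with per-SNP true
  exposure effects as nuisance parameters; profiling them gives the
  concentrated objective ½Σ(by−β·bx)²/(sy²+β²·sx²), minimized by bounded
  scalar search around the IVW start; SE from the numerical curvature at
  the optimum. Falls back to IVW with a logged warning on failure.
* **Weighted median** — weighted 50th percentile of per-SNP Wald ratios
  (weights bx²/sy², cumulative-weight interpolation at the
  (cum−w/2)/W midpoints); SE by seeded parametric bootstrap
  (default 1000 draws; the seed is a mandatory argument so results are
  reproducible).
* **MR-Egger** — weighted regression *with* intercept after orienting
  all bx ≥ 0; the intercept is the directional-pleiotropy test, the
  slope the adjusted effect. P-values use the t distribution with
  n−2 df; Rucker's Q′ applies the same overdispersion rule.
* **MVMR-IVW** — no-intercept WLS of outcome betas on the exposure-beta
  matrix; per-coefficient SEs carry overdispersion with df = n−k.
  The conditional F of each exposure is the mean chi-square of its
  instrument signal after projecting out the other exposures' betas
  (equal to the mean per-SNP F when there is one exposure). The pipeline
  warns rather than fails below the conventional threshold of 10,
  since conditional F just above 9 was accepted in the motivating
  analyses.

Odds-ratio reporting is exp(β) per unit exposure; when the outcome GWAS
is a 0/1-coded trait analysed on the linear probability scale (as for
biobank-scale RA), betas are of order 1e-4 and ORs sit near 1 — the
tables preserve this convention.

## Instrument selection

Significance thresholding is strict (< threshold), defaulting to
1×10⁻⁵ for microbial traits (genome-wide hits are scarce at microbiome
GWAS sample sizes) and 5×10⁻⁸ for metabolites, cytokines and the
outcome. LD clumping is greedy PLINK-style: sort by p (ties broken by
rsID), accept the best remaining SNP, discard same-chromosome SNPs
within 10,000 kb at r² ≥ 0.01. SNPs missing from the LD matrix are
retained with a warning. Weak instruments are removed at per-SNP
F = (β/se)² < 10; the R²(n−2)/(1−R²) form with R² = 2·maf·(1−maf)·β² is
available as an option.

## Harmonization

Exposure and outcome effects are aligned by rsID to the exposure's
effect allele: identical orientation is kept, swapped alleles negate the
outcome beta and complement its frequency, palindromic (A/T, C/G)
variants are aligned by which side of 0.5 each trait's frequency falls
on when MAF ≤ 0.3 and dropped as ambiguous above that, and incompatible
allele sets are dropped. Duplicated rsIDs keep the record with the
lowest p-value. Every drop is recorded as (rsID, reason) for the audit
log. Strand issues beyond palindromes are assumed pre-resolved.

## Sensitivity suite

* **MR-PRESSO** — the global statistic is the sum of squared
  leave-one-out residuals (by_j − β̂₍₋ⱼ₎bx_j)²; its null distribution
  comes from parametric resampling of (bx, by) under the fitted
  no-pleiotropy model (empirical p with the +1 correction, so p ≥
  1/(nSim+1)). Per-SNP squared residuals are compared with their own
  simulated distributions and Bonferroni-adjusted over the instrument
  count; adjusted p < 0.05 flags an outlier. A refinement pass then
  re-tests all SNPs against a null fitted *without* the first-pass
  outliers — a flagged SNP drags the leave-one-out slopes of its
  neighbours, and without the second pass clean SNPs are occasionally
  co-flagged. The distortion test compares the all-SNP and
  outlier-removed estimates against the shift produced by removing
  random same-size subsets in the resampled data.
* **Steiger directionality** — per-trait instrument r² sums
  t²/(t²+n−2); the z statistic compares Fisher-transformed √r² scaled by
  the two sample sizes. Exact ties report "forward" with p = 1 and an
  `inconclusive` flag.
* **Colocalization** — per-SNP Wakefield approximate Bayes factors with
  prior effect SD 0.15 (quantitative) and 0.2 (binary), combined under
  per-SNP priors p1 = p2 = 1e-4, p12 = 1e-5 into PP.H0–H4 (log-space
  throughout; the H3 cross term uses log-diff-exp). A single causal
  variant per region is assumed. PP.H4 > 0.8 is the conventional gate
  for a shared variant; the pipeline reports the value without encoding
  any further interpretation.

## Pipeline gates and multiple testing

The forward screen runs every exposure through selection →
harmonization → estimator battery → sensitivity suite, then
Benjamini–Hochberg-adjusts the primary (IVW/Wald) p-values within the
exposure family; BH is applied per family (microbial traits,
metabolites, cytokines run as separate screens) as mediation studies in
this area adjust per panel. An exposure is excluded from mediation only
when Cochran's Q p < 0.05 **and** the MR-PRESSO global test is
significant **and** outlier removal does not restore homogeneity —
heterogeneity alone is not treated as disqualifying, because at
biobank-scale outcome precision the Q test detects benign
measurement-error overdispersion (the NOME approximation) that carries
no pleiotropy signal. Diagnostics (Steiger, coloc) annotate rather than
gate; BH runs first. Reverse MR reuses the same machinery with the
outcome instrumented at 5×10⁻⁸ and reports "not-assessable" when no
instruments or no matching SNPs exist.

### Step-2 instruments in two-step MR

SNPs that pass the exposure's own significance threshold are excluded
from the mediator's instrument set for step 2. An exposure instrument
affects the outcome through the direct path as well, so its Wald ratio
for M→Y converges to θ2 + θ3/θ1 rather than θ2; at strong instrument
strength this bias is visible. Filtering exposure-associated SNPs from
step 2 is standard two-step-MR practice and restores unbiasedness of
θ̂2 under the structural model.

## Synthetic data generator

`simulate(SimTruth(...))` draws summary statistics directly (no
individual-level genotypes): per-SNP standard errors follow the analytic
form 1/√(2·maf·(1−maf)·n) for a unit-variance trait, observed betas are
true effects plus normal noise at that SE, and p-values come from the
normal z. Exposure instruments carry per-SNP explained variance drawn
from `instrument_r2_range` (default 0.002–0.01, which reproduces the
F-statistic span of real microbiome-GWAS instruments at n ≈ 9000);
the mediator inherits θ1·γ and adds its own instruments; the outcome
receives (θ3+θ1θ2)·γ, θ2·α, and optional pleiotropy δ ~ N(mean, sd) on
a configurable fraction of SNPs, oriented per exposure-increasing
allele so a nonzero mean is genuinely directional. LD is
block-exchangeable (blocks separated by 20 Mb so they never co-clump).
Default sample sizes mirror the real study classes: exposure 8,956,
mediator 7,824, outcome 463,010; calibration studies in the tests use
n = 50,000 for all three so instruments are strong in every trait.

What the generator does *not* emulate: realistic LD decay, allele
frequency spectra, population stratification, sample overlap between
GWAS, binary-trait liability-scale effects (outcome betas are
linear-probability), or selection-on-significance winner's curse.
Passing tests therefore demonstrate correctness of the estimators and
pipeline under the stated structural model, not robustness to those
real-data complications.

## Numerical choices and edge cases

* Empirical p-values use the +1 correction and are never 0; analytic
  p-values are floored at the smallest positive double.
* Clumping ties in p are broken lexicographically by rsID, making every
  pipeline stage deterministic for a fixed seed.
* The weighted-median bootstrap, MR-PRESSO resampling, and all
  simulation draws take explicit seeds; identical config + seed gives
  byte-identical report tables.
* IVW with one SNP delegates to the Wald ratio; MVMR with one exposure
  equals univariable IVW to numerical precision.
* Steiger r² sums are clipped just below 1 with a warning; zero-length
  SNP intersections, zero exposure betas, rank-deficient MVMR designs
  and all-flagged PRESSO runs raise typed errors.

## Problem sizes used in the checks

Calibration studies run at sizes chosen to keep sampling error well
below the effects being measured: 300 replicates for decomposition
coverage, 2000 for null type-I error, 500 for IVW bias, 21 instruments
for the outlier-detection scenario (displacing the strongest instrument
by 10 outcome SEs — the worst case for estimate distortion, and the
configuration where outlier correction must help), and 60-SNP regions
for colocalization.

## Known limitations

* Single-causal-variant colocalization only (no SuSiE-style multi-signal
  decomposition).
* One mediator at a time; no joint multi-mediator decomposition.
* No Egger weak-instrument (SIMEX/I²GX) correction.
* IVW/MVMR carry the usual O(1/F) weak-instrument attenuation; the
  product and difference decompositions inherit small opposite-signed
  finite-sample biases (≈0.4% of the indirect effect at F ≈ 100–500),
  so the two methods agree in expectation only up to that order.
* Proxy-SNP lookup, liftover and VCF input are out of scope; inputs are
  delimited text with a configurable column map.
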