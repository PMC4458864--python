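# Methods

## Model and assumptions

The structural model is linear on the latent scale: for centred, scaled
exposure *x* and outcome *y*, *y* = α·*x* + η, where η absorbs confounding
(and is therefore correlated with *x*). A genetic variant with allele-dosage
effect γᵢ on *x* and βᵢ on *y* identifies α through the Wald ratio
αᵢ = βᵢ/γᵢ provided the three instrumental-variable conditions hold:
association with the exposure, independence from confounders, and no effect
on the outcome except through the exposure (exclusion restriction). Only
summary effects enter the computation; dosages are never materialized.

The first-order variance vᵢ = s(βᵢ)²/γᵢ² treats γᵢ as known. This is the
standard two-sample approximation and is adequate when instruments reach
genome-wide significance (|γᵢ|/s(γᵢ) ≳ 5.5); with weak instruments it
understates vᵢ. The package stores s(γᵢ) on every instrument record so the
approximation is auditable, but does not propagate it.

Pooling treats the αᵢ exactly as study estimates in a meta-analysis.
The random-effects estimator is DerSimonian–Laird (method of moments),
chosen as the standard estimator of the summary-MR literature's era; its
truncation at τ² = 0 makes the random- and fixed-effects results coincide
exactly for homogeneous sets, a behaviour the reported analyses rely on
(the screened FG set pools with I² = 0). The fixed-effects estimate is
algebraically the zero-intercept weighted least-squares regression of βᵢ on
γᵢ with weights s(βᵢ)⁻²; the test suite verifies this equivalence against
an independent WLS fit to 10 significant digits.

I² = max(0, (Q − df)/Q)·100 with a test-based 95% CI (Higgins–Thompson) on
ln H, H² = Q/df:

* Q > df:  se(ln H) = (ln Q − ln df) / (2(√(2Q) − √(2df−1)))
* Q ≤ df:  se(ln H) = √(1/(2(df−1))·(1 − 1/(3(df−1)²)))

mapped back through I² = (H²−1)/H² and truncated to [0, 100]. The
test-based CI need not contain the point estimate, and with df = 1 the
homogeneous-case SE is undefined, so the CI degrades to (0, 100). All CIs
use the multiplier 1.959964; pooled P values are two-sided normal Wald
tests on the log-odds scale.

## Standard-error reconstruction and imputation

Published tables print effects (often ORs to 2 decimals) and P values (2
significant figures) but no SEs. Under the two-sided Wald-test assumption,
SE = |effect|/z with z = Φ⁻¹(1 − P/2), evaluated through the
survival-function inverse so that P values as extreme as 1×10⁻²¹⁵ (the
smallest in the bundled tables) invert without underflow. Round-tripping
P → SE → P is verified to 6 significant digits across P ∈ [10⁻²¹⁵, 0.99].

An outcome OR printed as 1.00 has zero log-effect and no recoverable SE.
The default policy imputes the median of the defined SEs *within the
analysis set being pooled* and flags the record; this keeps the instrument
with αᵢ = 0 and preserves the published instrument counts (n = 26 and
n = 24). `mean` and `drop` policies are available. Because the median is
taken per analysis set, a flat-OR SNP's imputed SE can differ slightly
between the candidate-set and instrument-set analyses; rows with defined
SEs are identical across the two. How the original analysis handled these
rows is not documented; the policy is explicit and configurable.

## Harmonization

Records are rsID-keyed and position-free. Outcome effects are re-expressed
per copy of the exposure's effect allele: direct match keeps the sign, a
swapped match negates it, and strand-complement pairs (A/G vs T/C) are
matched after complementing. Palindromic SNPs (A/T, C/G) are strand
ambiguous; the default policy keeps them with a warning (`flag`), since the
bundled tables are pre-aligned; `drop` is available for generic inputs.
Allele frequencies are not used to resolve palindromes (not printed in the
source tables).

## CPMA pleiotropy screening

Under the null of no confounder association, a SNP's P values across
confounder traits are Uniform(0,1), so xⱼ = −ln pⱼ ~ Exponential(1). CPMA
is the likelihood-ratio test of rate 1 against the MLE λ̂ = n/Σxⱼ,

    CPMA = −2[ℓ(1) − ℓ(λ̂)],   ℓ(λ) = Σⱼ(ln λ − λxⱼ),

referred to χ²₁. The statistic is zero iff λ̂ = 1 and is permutation
invariant; type-I error at the 0.05 level is verified at ≈5% by Monte
Carlo. The default screen flags cpma_p < 0.05 over the five canonical
confounder traits (LDL-C, triglycerides, systolic BP, diastolic BP, BMI),
jointly in one omnibus test per SNP. No multiple-testing correction is
applied across SNPs: over-exclusion of instruments can only bias toward
the null, which is the conservative direction for a screening step.
Reproduction runs use the pleiotropy labels printed in the bundled tables
(`screening: fixture_labels`) because the underlying confounder GWAS
P values are not republished there.

## Combinatorial heterogeneity decomposition

All subsets obtained by removing 0…k instruments are re-pooled (random
effects) and ranked, by ascending remaining-set I² (default) or by drop in
Q; ties break toward fewer removals then lexicographic SNP IDs, making the
ranking fully deterministic. Exhausting all 2ⁿ subsets is infeasible at
n ≈ 26, and every reported finding involves at most three removals, so the
default bound is k = 3 (≈3,000 subsets at n = 26, well under a second)
with an explicit enumeration budget that refuses larger requests with
guidance. The minimal-I² ranking criterion is an implementation choice;
the source analyses describe the enumeration but not a formal selection
rule.

## Subgroups

Instruments are grouped by the Dimas et al. physiologic clustering of T2D
loci (BC beta-cell, IR insulin resistance, PI pro-insulin, HG
hyperglycemia, UC unclassified, NA unavailable). After pleiotropy
screening the IR cluster is empty and PI/HG retain one member each, so the
`bc_vs_rest` grouping pools the 8 beta-cell instruments against the 18
remaining instruments (UC + NA + the HG and PI singletons) — the only
partition consistent with the published group sizes; whether the two
singletons belonged to the published "no clear effect" group is inferred,
not stated. Groups below `min_size` (default 3) are reported as skipped
with their membership rather than pooled.

## Synthetic data

`generate_study` draws, per SNP: true γᵢ ~ N(0.10, 0.025) (per-allele
exposure ORs ≈ 1.05–1.16), observed γ̂ᵢ and β̂ᵢ with Gaussian noise at fixed
SEs (defaults 0.015, matching the magnitudes reconstructed from the bundled
CHD table), βᵢ = α·γᵢ + δᵢ·1[pleiotropic] with δᵢ ~ N(0, 0.02) for a
configurable fraction of SNPs, and a confounder P-value matrix that is
uniform for clean SNPs and derived from |z| shifted by ±3 for pleiotropic
ones. Defaults: 26 SNPs, α = ln 1.11, no pleiotropy. The generator is
Gaussian-on-summary-statistics by construction — the regime every formula
above assumes — so passing recovery tests demonstrate internal consistency
of the estimator chain, not robustness to liability-scale binary-trait
effects, LD between instruments, winner's curse, or sample overlap, none
of which are modelled. Identical seeds give byte-identical tables.

`recovery_experiment` replicates the full pipeline (optionally with CPMA
screening) and reports bias, RMSE, 95% CI coverage and mean I² with
Monte-Carlo SEs. Under the defaults coverage is slightly above nominal
(≈96% at 1,000 replicates) because the DL weights absorb the γ-noise the
Wald variance ignores.

## Numerical choices

* All pooling on the natural-log scale; exponentiation only for reporting.
* Ratios are summed in canonical snp_id order, so pooled results are
  bit-identical under permutation of the input.
* Human-readable reports round ORs/CIs to 2 decimals and I² to 1 decimal;
  `report.json` keeps full precision.
* Degenerate inputs fail loudly and early: empty sets, γ = 0 (weak
  instrument), all-undefined SEs, all P values = 1, removals that would
  leave fewer than two instruments.

## Problem sizes used in validation

The published-estimate checks run the actual analyses (n = 37/26 and
33/24 instruments; subset scan to k = 3). Calibration checks use 1,000
random instances for the WLS equivalence, 10,000 Monte-Carlo replicates
for CPMA type-I error, and 1,000 replicates at the 26-SNP default profile
for bias/coverage — sizes at which the Monte-Carlo error is well inside
the asserted bands and a full run completes in seconds on one core.

## Known limitations

* No MR-Egger, weighted-median or modal estimators; directional pleiotropy
  that survives screening biases the estimate.
* The Wald variance ignores s(γᵢ); fine at genome-wide significance, wrong
  for weak instruments.
* SE reconstruction inherits the rounding of printed effects and P values:
  pooled ORs reproduce published values to about ±0.02.
* CPMA here is a reconstruction of the cross-phenotype test from its
  description (uniformity of P values under the null); the reference
  implementation was not available for comparison.
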