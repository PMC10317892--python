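# Methods

`targetmr` implements a drug-target Mendelian randomisation (MR) workflow:
genetic variants in and around the gene encoding a drug's protein target are
used as proxies for pharmacological perturbation of that target, and their
effects on disease outcomes are combined into a causal estimate. The design
it replicates is a glucose-lowering drug-target study: instruments selected
from a type 2 diabetes GWAS, re-expressed on the HbA1c biomarker scale, and
tested against cancer outcomes, with colocalisation and conditional analysis
as exclusion-restriction diagnostics.

## Instrument construction

For a gene region (GRCh37, 1-based inclusive coordinates) with a flanking
window (default ±500 kb), candidate instruments are variants associated with
the selection trait at genome-wide significance (default p < 5×10⁻⁸). The
closed interval convention means a variant exactly at `start − window` is
retained. Candidates are greedily pruned in ascending p-value order: a
variant is kept iff its squared LD correlation with every already-kept
variant is below the threshold (default r² < 0.20, which trades a small
amount of correlation for instrument strength). Ties in p break by position
then identifier, so pruning is deterministic. The greedy p-ordered rule is
equivalent to the lexicographically first maximal admissible subset, which
is what the exhaustive-search oracle in the tests enumerates.

Each surviving variant must carry a scaling-trait (biomarker, here IRNT
HbA1c) estimate on the same effect allele. Variants whose biomarker effect
opposes their selection-trait effect (or is exactly zero, leaving direction
undefined) are removed as likely pleiotropic. The final instrument stores
the biomarker per-allele effects; under the default `lowering` orientation,
exposure and outcome effects are jointly negated downstream so the causal
slope reads "per 1-unit biomarker lowering". Joint negation leaves the IVW
slope magnitude invariant; only the sign convention changes.

Harmonisation of any two summary-statistic tables aligns outcome records to
the exposure's effect allele, negating betas and mirroring frequencies for
swapped coding. Palindromic (A/T, C/G) variants are aligned by effect-allele
frequency only when both frequencies lie outside [0.42, 0.58] and are
dropped otherwise; frequency cannot resolve strand near 50%. This is a
documented convention, not something the replicated design specifies.

### Instrument strength

On a variance-1 (IRNT) trait, a variant's marginal explained variance is
2·eaf·(1−eaf)·β². Because marginal effects of correlated variants
double-count shared signal, the instrument-level r² uses standardized
effects w (wᵢ = βᵢ·√(2·eafᵢ(1−eafᵢ))) in the quadratic form **w′R⁻¹w** —
the joint-model R² implied by the marginal estimates — which reduces to the
naive sum Σwᵢ² when R = I. The naive sum remains available via
`ld_corrected=False`. Instrument-level F uses the k-instrument formula
F = (n−k−1)/k · r²/(1−r²); per-variant F = (β/se)² is also reported because
conventions differ between publications. Fixed variants (eaf ∈ {0,1}) are
rejected at instrument entry.

## IVW estimation with correlated variants

With exposure effects ω, outcome effects γ, outcome SEs s and LD matrix R,
the outcome covariance is Σᵢⱼ = sᵢsⱼRᵢⱼ and the causal slope is the GLS fit

    β̂ = (ω′Σ⁻¹ω)⁻¹ ω′Σ⁻¹γ.

Overdispersion (multiplicative random effects) is estimated as
φ_raw = (γ−ωβ̂)′Σ⁻¹(γ−ωβ̂)/(k−1) and floored at 1: under-dispersed
instruments fall back to the fixed-effect variance (model label `fe`),
over-dispersed ones scale the variance linearly in φ_raw (`re_floored`).
A single variant reduces exactly to the Wald ratio γ/ω with first-order
delta-method SE s/|ω| and φ = 1. Confidence intervals and p-values use
normal quantiles by default (t with k−1 df behind a flag); at the
instrument strengths involved the difference is negligible, and normal
theory is the convention. Σ is solved directly with a condition-number
guard of 10¹²: with pairwise r² < 0.20 the covariance is always
well-conditioned, so failure indicates malformed input.

Leave-one-out analysis refits the estimator k times, each omitting one
variant, to expose single-variant influence. Evidence labelling applies the
Bonferroni heuristic for 27 primary analyses (3 targets × 9 endpoints):
`strong` below 0.05/27 ≈ 0.00185, `weak` below 0.05, `none` otherwise.

## Colocalisation

Per-variant Wakefield approximate Bayes factors,
log ABF = ½·log(1−r) + z²r/2 with r = W/(V+W), summarise evidence against
the null under a N(0, W) effect prior. Prior SDs default to 0.15 for
quantitative traits and 0.20 (log-odds) for binary traits — the established
defaults for this family of methods; binary effects are used on the
log-odds scale directly, with no liability conversion. Assuming at most one
causal variant per trait, the five configuration likelihoods are

    L0 = 1,  L1 = p1·Σeᵃ,  L2 = p2·Σeᵇ,
    L3 = p1p2·(Σeᵃ·Σeᵇ − Σeᵃ⁺ᵇ),  L4 = p12·Σeᵃ⁺ᵇ,

with priors p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵ (sensitivity grid 5×10⁻⁶ and
5×10⁻⁵ at fixed p1/p2). All accumulation uses log-sum-exp; the L3
subtraction is done as a log-space difference, so a single-variant region
yields PP3 = 0 exactly and p12 = 0 yields PP4 = 0 exactly. A configuration
is called "supported" when its posterior exceeds 50%.

## Conditional decomposition (pairwise conditional colocalisation)

Regression moments are reconstructed from summary data:
(X′X)ⱼₖ ≈ n·√(vⱼvₖ)·rⱼₖ with vⱼ = 2·eafⱼ(1−eafⱼ), (X′y)ⱼ ≈ n·vⱼ·βⱼ, with
phenotypic variance 1 and the implied y′y refit as the median across
variants of the per-variant value from the marginal fits. Forward stepwise
selection adds the variant with the smallest conditional p below the entry
threshold (default 5×10⁻⁸) each round, skipping candidates with r² > 0.9 to
any selected index (collinearity guard); both defaults follow established
summary-level conditional-analysis practice. Ties break by position then
identifier, making selection deterministic. Binary traits are conditioned
on the log-odds scale with effective sample size
n_eff = 4/(1/n_cases + 1/n_controls). A variant inside its own
conditioning set is reported with conditional beta 0 and its marginal SE
retained — "no residual association" while preserving the positive-SE
invariant. The same reference LD is used for selection, conditioning and
colocalisation; mixing panels is unsupported.

Pairwise conditional colocalisation builds, per trait, the marginal
dataset plus (when ≥2 signals exist) one conditional dataset per signal
(conditioning on all the trait's other signals), then colocalises every
cross pair and reports the grid with the maximal-PP4 pair. With one signal
per trait this degenerates to the single marginal×marginal analysis.

## Power

For a binary outcome, the asymptotic SE of the IVW log-odds slope is
se∞ = 1/√(N·r²·φ(1−φ)) with case fraction φ. Power at odds ratio OR uses
the one-tailed rejection approximation Φ(|log OR|/se∞ − z₁₋α/₂), standard
for MR power calculators (exact two-tailed available by flag); under it
power at OR = 1 equals α/2 and the detectable-OR inversion
|log OR| = (z₁₋α/₂+z_power)·se∞ round-trips exactly.

## Synthetic data generator

The generator emulates the statistical structure of consortium inputs so
every stage is testable offline. Genotypes: each variant's two haplotype
alleles are Bernoulli(MAF) indicators from thresholding a latent Gaussian
vector (Hardy–Weinberg {0,1,2} dosages). Thresholding attenuates
correlation, so latent pairwise correlations are tetrachorically adjusted —
Owen's-T-based bivariate-normal CDF inverted per pair — so realized dosage
Pearson LD matches the target AR(1) or block matrix; the adjusted latent
matrix is eigenvalue-clipped back to PSD if needed. Dosage correlations
are Fréchet-bounded, so a high target r is only achievable between
variants of comparable frequency; preset scenarios keep MAF ranges
accordingly. The region (MAFs, LD, causal truth) is fixed by the config
seed; replicate loops redraw non-overlapping cohorts over that fixed
region.

Quantitative traits are linear in genotype with residual variance set to
1 − (genetic variance) (floored at 0.05), giving an approximately
variance-1 IRNT-like scale. Binary traits use a liability threshold at the
configured prevalence (default 0.10, diabetes-like), with marginal effects
re-estimated by per-variant logistic regression so binary summary
statistics carry realistic finite-sample noise. The logistic fits use a
vectorised two-parameter Newton solver (all variants simultaneously),
verified against a reference implementation in the tests. The causal
model routes the outcome through the exposure trait with a configurable
slope, plus optional direct (pleiotropic) per-variant outcome effects.

Preset scenarios fix the study conditions: the five colocalisation
configurations use 50-variant AR(1) ρ=0.6 regions, 50,000-sample cohorts
(20,000 under the null) and causal effects sized for per-trait z ≈ 8; MR
scenarios use 5 instrument variants in AR(1) ρ=0.3, per-allele biomarker
effects of 0.020–0.035 on the variance-1 scale (the upper part of the
published per-allele range, giving per-variant F ≈ 40–200 so that
weak-instrument dilution stays inside Monte-Carlo error at the replicate
counts used), a 400,000-sample exposure GWAS (matching the scale of a
biobank biomarker GWAS), a 100,000-sample outcome cohort and true slope
0.5. The secondary-sharing scenario plants two conditionally independent
signals in trait 1 of which trait 2 shares only the secondary, the case
pairwise conditional colocalisation exists to detect.

What the generator does **not** emulate: haplotype-scale recombination
structure, allele-frequency/LD coupling beyond the Fréchet bound,
population stratification, sample overlap between cohorts, case–control
ascertainment beyond the liability threshold, and genotyping error.
Passing tests therefore demonstrate correctness of the estimators under
the stated sampling models, not robustness to those real-data features.

## Problem sizes and numerical choices

Simulation-backed checks use 500 replicates for IVW recovery/coverage,
200 null regions for coloc calibration, and 100 replicates (n = 8,000,
5 variants) for conditional-reconstruction agreement — sizes at which
Monte-Carlo error is small relative to the tolerances asserted. LD
matrices are accepted as PSD down to eigenvalue −10⁻⁸, repaired by
eigenvalue clipping (with rescaling, which preserves PSD) down to −10⁻⁶,
and rejected below that as malformed. Posterior arithmetic never
exponentiates z²/2 terms directly. Degenerate inputs — monomorphic
variants, empty instruments, missing LD coverage, misaligned variant
sets — raise typed errors named in each module.

## Known limitations

- The instrument-level F formula is one of several conventions; published
  instrument F ranges cannot generally be reproduced from rounded
  per-variant tables, so per-variant (β/se)² is reported alongside.
- The published instrument table carries no positions or LD; the packaged
  fixture assigns synthetic in-gene positions and a synthetic constant
  weak-LD matrix (r = 0.1) that satisfies the r² < 0.20 construction
  constraint. Replays on this fixture validate the cascade's logic, not
  the original panel's LD.
- Summary-level conditional estimates inherit the usual reference-LD
  approximation error; agreement with exact least squares is demonstrated
  when the LD comes from the same cohort.
- Colocalisation assumes at most one causal variant per trait per dataset;
  multi-causal regions are handled only through the conditional
  decomposition.
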