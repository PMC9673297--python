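# Methods

This note documents the statistical models, algorithms and numerical choices in
`lcsgwas`, and what the synthetic-data generator does and does not emulate.

## The multi-trait linear mixed model

For one trait measured at `t` time points on `n` individuals, the stacked model is

    y = (I_t ⊗ X) b + u + e,
    u ~ N(0, Σu ⊗ K),   e ~ N(0, Σe ⊗ I_n),

where `X` (n×p) holds the intercept, sex, and house dummies (first level as
reference), `K` is the VanRaden genomic relationship matrix, and `Σu`, `Σe` are t×t
covariance matrices of the additive-polygenic and residual effects. The narrow-sense
heritability at time point i is `h²ᵢ = Σu,ii / (Σu,ii + Σe,ii)`; genetic correlations
come from the off-diagonals of `Σu`.

### REML algorithm

`K = UΛU′` is eigendecomposed once; rotating phenotypes and design by `U′` makes the
tn×tn covariance block-diagonal with per-individual blocks `V_i = λ_i Σu + Σe`, so
every likelihood evaluation is O(n·t³) instead of O((tn)³). The restricted
log-likelihood is

    logL = −½ [ log|V| + log|X̄′V⁻¹X̄| + y′Py + (tn − tp)·log 2π ],   X̄ = I_t ⊗ X,

and is verified in the test suite against a brute-force dense-matrix evaluation.

Optimization is average-information (AI) REML over the unique elements of `(Σu, Σe)`:

- AI step with up to six step-halvings; a step is accepted only if the restricted
  likelihood does not decrease.
- EM-REML fallback (`Σu ← Σu + Σu S Σu / n` with S the score statistic) whenever no
  AI step is acceptable; EM is monotone and stays in the PSD cone.
- After every update each matrix is projected to PSD by eigenvalue clipping at
  `max(1e-6·trace/t, 1e-10)`.
- Starting values: `Σu = Σe = ½·cov(Y)` over complete cases.
- Convergence: `|Δ logL| < 1e-8` **and** maximum relative parameter change `< 1e-6`;
  the default iteration cap is 1000 because boundary solutions (an eigenvalue of `Σu`
  pinned near zero) converge by a slow crawl along the cone boundary. Non-convergence
  is flagged, never silently ignored.
- If `K`'s eigenvalues are (near-)constant (e.g. `K = I`), only `Σu + Σe` is
  identified; the fit warns and flags `identifiable=False`.

Missing phenotypes/covariates are handled by complete-case analysis at model-frame
construction (count reported); `K` is subset and reordered to match.

### GWAS

Each SNP enters as `(I_t ⊗ w)α` with one allele-substitution effect per time point.
`α̂` and `var(α̂)` are computed by GLS with `(Σu, Σe)` **fixed at the null-model REML
estimates** (per-SNP refitting would multiply the cost by the iteration count and is
not part of the procedure being implemented). The Wald statistic
`W = α̂′var(α̂)⁻¹α̂` is referred to χ²(t). Dosages (0–2) are accepted as `w`
directly. Missing genotypes are mean-imputed per SNP; SNPs with MAF < 1e-6 or a
singular effect covariance are skipped and counted. The scan is vectorized over SNPs
(einsum over per-individual t×t inverse blocks), which makes the drop-log(P)
simulations cheap.

Conditional GWAS appends the lead SNP's genotype column to `X` (t coefficients, one
per trait), excludes the lead itself and skips test SNPs with |r| > 0.9999 to the lead.

The genome-wide threshold is `0.05/N` with `N` the number of SNPs retained by
sliding-window LD pruning (window 50 SNPs, step 5, r² > 0.2 removes the
smaller-MAF member, tie → larger position). Note: `0.05/391,976 = 1.28×10⁻⁷`; the
package reports what the formula gives.

### Drop-log(P) confidence intervals

For a QTL with lead SNP effect `α̂_lead` (region = cluster bounds ± 1 Mb):

1. Remove the lead effect from the phenotypes: `y_res = y − (I_t ⊗ w_lead)α̂_lead`.
2. For each of S simulations, pick a causal SNP from the region's testable SNPs
   (without replacement while the region holds ≥ S SNPs, else with replacement), add
   `(I_t ⊗ w_causal)α̂_lead` to `y_res`, and rescan the region with variance
   components still fixed at the null fit.
3. Record `Δ_s = max −log₁₀P − (−log₁₀P at the causal SNP) ≥ 0`. The drop is measured
   against the simulated scan's own best SNP, which may or may not be the causal one.
4. `D` = 95th percentile of `{Δ_s}`; the CI is the span of region SNPs whose observed
   −log₁₀P is within `D` of the observed lead, width = end − start + 1 (1-based,
   inclusive). The CI always contains the lead; a single-SNP region degenerates to
   width 1 with a warning.

Fixed effects are re-estimated in every simulated scan (the GLS solves for them
jointly). The whole procedure is reproducible bit-for-bit under a fixed seed.
−log₁₀P is computed from the χ² log-survival function, so extreme peaks do not
underflow.

### QTL heritability

`h²_QTL,i = h²ᵢ − h′²ᵢ`, where `h′²` comes from a full REML refit with the lead SNP
appended to the fixed effects. Negative differences (sampling noise) are clamped to 0
with a warning. Two caveats documented here because they matter when interpreting
recovery simulations: (i) the adjusted fit's phenotypic variance excludes the QTL
variance, so for a QTL explaining fraction f the expected difference is
`f·(1 − h′²)`, slightly below f; (ii) the unadjusted `h²` captures the QTL variance
only insofar as the GRM tags the causal SNP, so sparse or low-LD panels bias
`h²_QTL` further down.

## Imputation-accuracy metrics

Sites are shared iff (chrom, pos, ref, alt) match exactly (a ref/alt swap is not a
match). GC per cell is 1 iff the hard-called test genotype equals truth; per-site GC
averages over samples with both calls present, and the headline mean is the
unweighted mean over evaluable sites (both per-site and pooled views are available).
Hard calls from probability triples use the argmax (tie → heterozygote); bare dosages
round to the nearest integer (.5 → 1). GA is the per-site Pearson correlation between
dosage and truth code; sites with < 3 paired observations or zero variance are
skipped and counted. MAF bins (width 0.05, binned by truth-set MAF, last bin closed
at 0.5) and (sample size × depth) grids reuse the same per-site machinery.

## Population-genetics windows

Windows are anchored at position 1 per chromosome, advance by the step, and trailing
partial windows are kept but flagged. Per-site π = 2ab/(N(N−1)) over the N
non-missing alleles; the window value divides the site sum by the *nominal* window
size in bp. F_ST uses the Weir–Cockerham (1984) per-site components (a, b, c) with
ratio-of-sums windowing Σa/Σ(a+b+c) — the weighted estimator; negative values are
legitimate and kept. Outlier selection takes windows at or above a quantile cutoff
(the quantile is always a parameter — different analyses use top 1% or top 5%),
optionally after z-scoring, and merges overlapping/adjacent selected windows into
regions.

## The synthetic-data generator

The generator emulates the statistical structure of an LCS-genotyped livestock
cohort; its defaults are the study conditions used throughout the tests:

- **Genotypes.** 10 founder haplotypes; founder alleles follow a Markov retention
  chain (retention probability `exp(−gap/150 kb)`) over per-site frequencies drawn
  from U(0.05, 0.5), giving ancestral LD; sample haplotypes copy founders with a
  0.02/SNP switch rate, giving mosaic relatedness. The combination was calibrated to
  the strong LD reported for such closed, artificially inseminated populations
  (r² ≈ 0.5 for adjacent sites, decaying over hundreds of kb) — not to any test
  outcome. Default 600 individuals, 5000 SNPs on 5 chromosomes at ~1 kb mean spacing.
  Founder quantization means a small tail of sites drifts below MAF 0.05 or to
  monomorphism, as in real data before QC.
- **Phenotypes.** `u` is drawn from N(0, Σu ⊗ K) using the realized GRM of the
  simulated genotypes (matrix square roots of Σu and K), `e` from N(0, Σe ⊗ I); sex
  (Bernoulli ½) and five house levels add fixed effects; default Σu/Σe give unit
  phenotypic variance with h² = (0.10, 0.25, 0.40) and genetic correlation 0.5
  (residual correlation 0.3). QTL effects solve `2p(1−p)β² = f·σ²_P` with
  `σ²_P = (Σu,kk+Σe,kk)/(1−f)` so the injected fraction is exact.
- **Low-coverage dosages.** Per cell, reads ~ Poisson(depth), alternate-supporting
  reads ~ Binomial(reads, f_g) with `f_g = (g/2)(1−ε) + (1−g/2)ε`; the genotype
  posterior uses a Hardy–Weinberg prior at the site's true allele frequency and the
  dosage is the posterior mean. This is an *idealized single-site genotyper*: it
  deliberately uses no LD information, so its absolute GC/GA (≈75%/0.59 at 1X) sit
  well below what haplotype-based imputation reaches on real data (≈99%); only the
  qualitative behaviour (monotone improvement with depth and sample information,
  MAF dependence) transfers. Cells with zero reads return the prior mean and are
  flagged in `zero_read_mask`.

What passing tests therefore show: the estimators are correct against dense-matrix
and enumeration oracles, calibrated under the null, and recover simulated truth at
realistic cohort sizes. What they do not show: performance of any real imputation
engine, or real-data effect sizes.

## Problem sizes used by the checks

Chosen as the smallest sizes at which the statistical behaviour under test is
expressed cleanly: REML oracle equivalence at n=8, t=2; Wald calibration on a
400-individual, 2000-SNP null cohort (the calibration cohort uses an LD-free SNP
panel because the binomial envelope and KS test presuppose near-independent tests,
while the cohort keeps its family structure); heritability recovery at n=500,
m=2000, t=3 over 10 seeds; QTL-heritability recovery at n=500, m=1500, t=2 with a
10% QTL on traits of h² 0.15/0.25 (typical of the moderately heritable traits this
design targets); drop-log(P) coverage over 100 replicates of a 400-individual
cohort with a 5%-variance QTL in a ~500-SNP region, 200 simulations per CI.

## Known limitations

- Fixed-effect SNP tests in strongly related, high-LD cohorts are conservative
  because the tested SNP's direction is partly absorbed by `Σu ⊗ K` (proximal
  contamination); leave-one-chromosome-out GRMs would mitigate this but are outside
  the implemented procedure, which fixes one genome-wide GRM.
- The HWE exact test assumes autosomal biallelic diploid counts.
- `Σu` boundary solutions slow AI-REML to EM-like crawls; the iteration cap (1000)
  is generous but finite, and non-convergence surfaces in `converged`.
- The LD pruner approximates, and is not guaranteed to bit-match, the reference
  tool's `--indep-pairwise` output; its rules (drop smaller-MAF member, tie → larger
  position, pairs scanned in index order) are fixed for determinism.
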