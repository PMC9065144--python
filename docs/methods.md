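# Methods

This note documents the statistical model behind `voxelgwas`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## The discovery statistic

Let Y be the n × V subject-by-voxel phenotype matrix for one tissue
feature. A thin SVD of the column-centered Y yields orthonormal voxel
eigenvectors v_k, eigenvalues λ_k (score variances, divisor n − 1), and
subject scores s_k. Column signs are fixed by making the
largest-magnitude loading of each eigenvector positive, so the
decomposition is deterministic.

For SNP j and PC k, both the mean-imputed dosage g_j and the score s_k
are residualized on the covariate design Z (intercept, age, sex,
global-volume analog, dummy-coded batch, ancestry axes). By the
Frisch–Waugh theorem the simple-regression slope of the residualized
score on the residualized dosage, its standard error with n − p − 1
degrees of freedom (p = columns of Z), and the Wald ratio W = β/se equal
the full-design multiple-regression quantities; this is verified against
an independent full-design OLS fit in the tests. The marginal statistic
is also direction-invariant: regressing dosage on score gives the same
|W|.

Because PC scores are mutually orthogonal in-sample, under the null the
omnibus statistic T = Σ_k W_k² is χ²_K to the accuracy of the normal
approximation of W (each W² is exactly t²-distributed; at the sample
sizes used the difference is negligible and the null-calibration test
bounds it empirically). The global–local rule at cut point C computes
p_head = P(χ²_C > Σ_{k≤C} W_k²) and p_tail on the remaining K − C
components, then X = −2(ln p_head + ln p_tail) ~ χ²₄ (Fisher's method on
two independent p-values). The exact head/tail construction is one
faithful instantiation of a family of global–local combinations; it is
isolated behind a single function so alternatives can be swapped.

Missing Wald entries (e.g., a PC dropped for a flagged SNP) are removed
with the degrees of freedom reduced accordingly. Underflowed head/tail
p-values are clipped at the smallest positive double before the
logarithm.

**Significance.** With cut points scanned and several tissue features
analysed, the auto threshold is 5×10⁻⁸ / (n_rules × n_features). Only the
cut-point rules count as candidates when any are given — the full sum is
always reported but is not a significance candidate — so 4 cut points × 3
features gives α = 4.2×10⁻⁹. The per-SNP call uses the smallest candidate
p-value ("best rule").

**K.** The default is desk-scale (K = 20–50; configurable). K bounds the
rank of every downstream object: back-projected maps, polyvoxel scores,
and per-PC heritabilities all live in the span of the retained
eigenvectors.

## Quality control and loci

Variants are kept iff MAF ≥ 0.005, Hardy–Weinberg χ² (1 df, no continuity
correction) p ≥ 1e-10, and missingness ≤ 0.05; boundaries are inclusive
on the keep side. Monomorphic SNPs are HWE-untestable (p set to 1) and
fall to the MAF filter. LD is the squared Pearson correlation of dosages
over pairwise-complete subjects (composite LD; phase is unavailable from
dosages).

Clumping is greedy: the unassigned significant SNP with the smallest p
(ties by position, then id) leads a locus, absorbing every unassigned
significant SNP on the same chromosome that is either in LD with the lead
(r² > 0.1) or within 250 kb of it. The OR of the two conditions — rather
than AND — is used because LD pruning and positional clumping act jointly
to collapse one signal; the window is lead-to-member. The locus span is
the min/max member position; loci with overlapping [start, end] on a
chromosome are merged across features, the merged lead being the member
with the smallest p.

## Polyvoxel validation

The score for a discovered SNP in a new sample is
score_i = Σ_k β_k v_kᵀ(x_i − x̄_disc), centering by the *discovery* voxel
means so no validation-sample statistics leak into the weights. All K
discovery PCs enter by default (K_use exposed). In the covariate-free
discovery sample the identity cov(g, score) = var(g) Σ_k β_k² holds
exactly because β_k = cov(s_k, g)/var(g) and the PCs are uncorrelated
in-sample; this is the consistency anchor for the confirmatory test. The
test itself is the correlation t-statistic between the
covariate-residualized dosage and score with n − p − 1 df, with a
per-locus Bonferroni threshold of 0.05 / n_loci. Family relatedness
(mixed-effects) is not modelled; the validation regression is
fixed-effects with covariates — a documented limitation for family-based
validation cohorts.

## Regional enrichment

For one SNP, per-PC coefficients are back-projected,
β̂_i = Σ_{k≤K} β_k v_ki, and scored against each region probability map as
the weighted mean Σ P_i β̂_i / Σ P_i (invariant to rescaling P). Signed
coefficients are used as-is by default; |β̂| and β̂² weightings are exposed
because signed weighting can cancel spatially alternating effects. The
null is empirical: each of B bootstrap draws resamples one whole
association map from the non-significant SNPs (≥ 50 required) and scores
it, so μ₀ and σ₀ describe the score of a typical null SNP while
preserving spatial correlation; z = (score − μ₀)/σ₀ with a two-sided
normal p. One shared seed drives all regions' draws, so identical
probability maps tie exactly. B defaults to 1000 at desk scale
(configurable). Null SNPs are taken genome-wide without allele-frequency
matching. Note the z-score ranking standardizes by each region's own null
variability: a region overlapping high-variance latent structure needs a
larger raw score to rank first.

## Genome-wide summaries

LD scores are ℓ_j = 1 + Σ r²(j, ·) over windowed neighbors (self
included; window 0 gives ℓ = 1). The heritability regression fits
χ²_j = a + b ℓ_j by unweighted least squares with a free intercept and
converts the slope by h² = b·M/n; the free intercept (rather than fixing
a = 1) keeps the slope identified purely by ℓ variation and absorbs
uniform inflation, and constant ℓ is correctly reported as
unidentifiable. Standard errors are delete-one-block jackknife over LD
blocks. The full iterative weighting of production LDSC software is
deliberately out of scope.

The average heritability of the multivariate phenotype is the
eigenvalue-weighted mean Σ λ_k h²_k / Σ λ_k over the retained K PCs. This
is not the same number as the voxel-average variance fraction recorded by
the generator's ground truth: the weighted average lives in the retained
PC subspace and weights high-variance components, so the two agree only
in the full-rank, equal-weight limit.

The multivariate χ² is rescaled as T/K — unit null mean, matching the
convention of a 1-df χ² in LDSC-style regressions; 1/K is one defensible
convention among several, isolated in a single function.

Signal overlap between two traits: per-LD-block means of −log₁₀ p (capped
at 320 to absorb underflow; the combined CPC p per SNP is used), compared
by Spearman correlation with mid-ranked ties and a t-approximation
p-value. Blocks are the generative blocks for synthetic data; a BED file
of approximately independent blocks is accepted for real data (0-based
half-open converted to 1-based inclusive on read).

## The synthetic-data generator

The generative model per subject i, voxel v is

    y_iv = Σ_c γ_c z_ic + Σ_q β_q g_iq w_qv + Σ_l u_il b_lv + ε_iv

with standardized covariates z (effects uniform across voxels), causal
dosages g, region probability maps w, smooth unit-RMS latent maps b with
loadings u ~ N(0, latent_sd²), and white noise ε ~ N(0, noise_sd²).
Spatially correlated noise is exposed as an option
(`noise_smoothness`); the default is white noise, since the voxel noise
structure is otherwise unconstrained.

Genotypes: allele frequencies uniform in `maf_range`; two independent
haplotypes per subject, each a thresholded latent Gaussian with AR(1)
correlation within blocks of `ld_block_size` SNPs (blocks independent).
Thresholding attenuates Pearson correlation, so the latent correlation is
inflated by sin(πr/2); the realized adjacent-dosage correlation
approximates the target for common variants (e.g., ~0.7 realized at a
0.8 target) rather than matching it exactly for every MAF. Independent
haplotypes guarantee Hardy–Weinberg proportions. Missingness is
completely at random. Positions are evenly spaced (`bp_spacing`,
default 10 kb) on one chromosome.

The region atlas tiles the grid into near-disjoint boxes (corners
jittered by ≤ 1 voxel, seeded), optionally Gaussian-blurred to peak-1
probability blobs. Heavier smoothing increases inter-region overlap,
which dilutes enrichment-ranking specificity — the recovery tests use
σ = 0.5 for compact, well-separated blobs.

Discovery and validation cohorts share all population-level draws
(frequencies, LD structure, latent maps, effect maps) and differ only in
subject-level draws via distinct sub-seeds, mirroring a temporal sample
split. All randomness flows from the config seed through named
spawn-keyed streams; identical configs reproduce byte-identical data.

**Default conditions.** n = 500 subjects, 200 SNPs in blocks of 20 with
adjacent-r target 0.5, MAF ∈ (0.05, 0.5), 1% missingness, a 10×10×2 voxel
grid, 5 latent components of unit SD, unit noise SD, and age/sex/volume
covariate effects of 0.1/0.1/0.2 SD — small enough to run interactively
while preserving the qualitative structure (block LD, low-rank spatial
signal, covariate confounding) of a population imaging cohort.
Parameter-recovery runs use n = 2000, MAF ∈ (0.2, 0.5), and a per-allele
effect of 0.8 phenotype SDs: with var(g) ≥ 2·0.2·0.8 = 0.32 the
per-voxel association noncentrality at a full-probability voxel is
n β² var(g) ≈ 410, giving per-voxel power ≈ 1 at α = 4.2×10⁻⁹, so
recovery failures would indicate pipeline defects rather than sampling
noise.

**What the generator does not emulate:** realistic LD from reference
panels (haplotype blocks are AR(1) copulas), relatedness or family
structure, ancestry-linked allele-frequency gradients, scanner/site
effects beyond a categorical batch shift, non-Gaussian phenotype tails,
and realistic dMRI signal formation. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not robustness to all structure found in real cohort data.

## Tissue fractions

N0 = |c_r0| / ‖c‖, ND = ‖(c_r2, c_r4)‖ / ‖c‖, NF = |c_f0| / ‖c‖ with ‖c‖
the Euclidean norm over all model coefficients (restricted orders 0/2/4,
hindered, free water). The order-2/4 aggregate is the Euclidean norm, not
the algebraic sum: the norm is invariant under within-order rotations of
the voxel frame and keeps ND in [0, 1], whereas a signed sum is neither.
Zeroth-order coefficients enter as absolute values. Voxels with an
all-zero coefficient vector are masked invalid; no division by zero
occurs.

## Numerical choices

- Residualization uses a rank-revealing pivoted QR; rank deficiency
  raises an error naming the collinear columns (tolerance
  max|diag R| · max(n, p) · eps).
- SNPs whose residualized dosage sum of squares falls below n·10⁻¹² are
  flagged untested (NaN statistics) rather than producing unstable
  ratios; regression sums of squares are clipped at zero against
  cancellation.
- PCA requires K ≤ min(n − 1, V) and reports variance-explained fractions
  against the total variance from the full spectrum.
- Clumping ties in p are broken by position then id, making output
  invariant to input row order.
- −log₁₀ p is capped at 320; Fisher inputs are clipped at the smallest
  positive double.
- Bootstrap draws, simulation streams, and pipeline stages all take
  explicit seeds; there is no global RNG state.

## Problem sizes

Tests and the reproduction script run at desk scale by design: grids of
10×10×2 voxels, K = 20 PCs, 80–500 SNPs, n = 300–2000 subjects, B = 1000
bootstrap draws, and 20–50 replicates per rate estimate. These sizes were
chosen so the full suite completes in minutes while every statistical
property under test (null calibration, power at the stated effect sizes,
jackknife SE coverage) is already in its asymptotic regime.
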