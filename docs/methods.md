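# Methods

## Variance-component model for multidimensional traits

A quantitative trait vector of dimension M observed on N samples is
collected in the matrix Y (N×M) and modelled as Y = G + C + E with

    vec(G) ~ N(0, Σ_A ⊗ K),  vec(C) ~ N(0, Σ_C ⊗ Λ),  vec(E) ~ N(0, Σ_E ⊗ I).

K encodes genetic similarity between samples: the allele-frequency
standardized SNP cross-product matrix for unrelated population samples
(so Σ_A is the genetic covariance tagged by common genotyped variants,
and the resulting h² is a lower bound on narrow-sense heritability), or
twice the kinship matrix for family samples. Λ encodes shared
environment (1 within a household, 0 elsewhere) and vanishes for
unrelated designs. Heritability is defined as the trace ratio
h² = tr[Σ_A]/tr[Σ_P], Σ_P = Σ_A + Σ_C + Σ_E. Two consequences drive the
whole package:

* **Rotation invariance.** For orthogonal T, the trait YT has genetic
  covariance TᵀΣ_A T and the trace ratio is unchanged. PCA is such a
  rotation, so per-PC heritabilities, combined with variance weights,
  reproduce the multivariate estimate exactly — `pcmodes` asserts this
  identity to 1e-8 on every input rather than assuming it.
* **Weighted-average decomposition.** h² = Σ_m γ_m h²_m with
  γ_m = (Σ_P)_mm / tr[Σ_P]: the multivariate heritability is the
  variance-weighted average of component heritabilities.

## Moment-matching estimator (unrelated samples)

E[y_r y_sᵀ] = (Σ_A)_rs K + (Σ_E)_rs I, so regressing each empirical
cross-product matrix elementwise on (K, I) and solving the 2×2 normal
equations gives

    Σ̂_A = Yᵀ(K − k̄I)Y / v_K,   Σ̂_E = Yᵀ(κI − k̄K)Y / v_K,

k̄ = tr[K]/N, κ = tr[K²]/N, v_K = tr[K²] − tr²[K]/N. For M = 1 this is
classical Haseman–Elston regression; the test suite keeps the O(N²M²)
elementwise OLS as an independent oracle and checks agreement to 1e-8.
The estimator is unbiased (verified by simulation at 500 replicates) but
not constrained to the parameter space: ĥ² is clamped to [0, 1] for
reporting, while the unclamped statistic feeds inference, where the
boundary-aware null handles negative excursions.

v_K measures the relatedness contrast in K; when v_K/N < 1e-8·κ (e.g.
K ∝ I) the regression is singular and the estimator raises rather than
returning noise.

### Sampling variance

The delta method on f(t) = t_A/(t_A + t_E), with two standard
simplifications — off-diagonal entries of K are small (K ≈ I), and Σ_P
is replaced by its empirical estimate — yields

    var(ĥ²) ≈ (2 / v_K) · tr[Σ_P²] / tr²[Σ_P].

Given K, this depends only on sample size and the phenotypic correlation
structure, not on the point estimate. Writing λ_m for the eigenvalues of
Σ_P, tr[Σ_P²]/tr²[Σ_P] = Σλ²/(Σλ)² ≤ 1 with equality iff rank(Σ_P) = 1:
a multidimensional trait can only reduce the variance relative to a
scalar trait, by exactly 1/M for independent equal-variance components.
For M = 1 the expression reduces to 2/v_K ≈ 2/(N² var_offdiag(K)), the
standard result for SNP-heritability standard errors. Calibration is
checked by simulation: the Monte-Carlo sd of ĥ² over replicates matches
the mean analytic s.e. within a few percent at N = 500.

### Covariates

Fixed effects XB (X: N×q, full rank, intercept included) are removed by
an orthonormal basis U of the null space of Xᵀ: Ỹ = UᵀY, K̃ = UᵀKU, an
(N−q)-dimensional problem of the same form. Any valid basis gives the
same estimate (proved by invariance, asserted to 1e-10); rank-deficient X
is rejected with the collinear columns named. Trait rows with missing
values are dropped listwise before projection — the model has no
missingness mechanism.

### Inference

* **Wald.** The null h² = 0 sits on the parameter-space boundary, so
  W = (ĥ²/se)² is compared to a half–half mixture of χ²₀ and χ²₁:
  p = 0.5·P(χ²₁ ≥ W) for positive estimates, p = 0.5 at the boundary.
* **Permutation.** Rows and columns of K̃ are jointly permuted (traits
  fixed) and the unclamped statistic recomputed; p uses the add-one
  convention (1 + #{ĥ²_perm ≥ ĥ²})/(n_perm + 1), which never returns 0
  and is super-uniform under the null. Permutation happens after
  covariate projection — the permuted quantity is the projected
  similarity matrix itself — which keeps the cost at O(n_perm·N²) via a
  contraction against the fixed trait cross-product matrix. Default
  10,000 permutations; the RNG seed is a required, recorded parameter.
* **FDR.** Benjamini–Hochberg step-up across structures (statsmodels
  implementation), default q = 0.05.

On well-powered simulated data the Wald and permutation p values agree
closely (median gap well under 0.05 at 1,000 permutations), which is the
practical check that the analytic s.e. is trustworthy.

## Familial ACE estimation

For twin/family designs the moment estimator loses efficiency because K
and Λ are strongly collinear, so each trait component is fitted by REML
under cov[y] = σ²_A K_ped + σ²_C Λ + σ²_E I with fixed effects profiled
out, and components are combined by the γ-weighted average above (weights
from the fitted per-component phenotypic variances).

Numerical choices: the restricted likelihood is evaluated blockwise by
family (relatives never span families), batched over families of equal
size, making a fit O(Σ n_f³) ≈ milliseconds; optimization is L-BFGS-B on
log-variances from three starts, so degenerate components drift to a
lower bound of 1e-8 (then snapped to 0) instead of stalling against the
zero boundary; designs with no relatedness contrast (all singletons) are
flagged unidentifiable rather than fitted. Household sharing defaults to
"1 within a family" — twins and their non-twin siblings share an
environment — and is configurable through the pedigree table.

Uncertainty comes from a family-block bootstrap: families resampled with
replacement to the original family count (members move together), the
entire per-component fit + combination re-run, sd over replicates
reported. Default 1,000 replicates; replicates whose REML fails are
dropped and counted. Against an exhaustive enumeration at two families
and against the across-study sd in nested simulations, the bootstrap
s.e. is calibrated to well within 30%.

## GRM construction and QC

K_ij = (1/S)·Σ_s (x_is − 2p_s)(x_js − 2p_s)/(2p_s(1−p_s)) with in-sample
allele frequencies; missing genotypes are mean-imputed per variant. The
in-sample centering forces the mean off-diagonal entry to −1/(N−1) and
the off-diagonal sd to ≈ 1/√S for unrelated panels — both asserted in
tests. Variant QC precedes GRM construction: call rate ≥ 0.97, MAF
≥ 0.01, and a Levene–Haldane exact Hardy–Weinberg test (mid-p, better
calibrated at low counts) at p ≥ 1e-6; all thresholds configurable.
Autosomal biallelic variants are assumed. I/O covers PLINK 1 binary
(bed/bim/fam), the GCTA binary GRM dialect (lower-triangle float32 +
ID file) and plain-text matrices; round-trips are bit-faithful at
float32 precision. Top GRM eigenvectors are exposed as stratification
covariates.

## Shape descriptors

Pipeline per structure: marching-cubes isosurface of the binary label
map (volume padded so border-touching structures stay closed) → 3
iterations of Taubin smoothing (λ = 0.5, ν = 0.53; two-step smoothing
limits the shrinkage of plain Laplacian averaging) → linear FEM spectrum
(cotangent stiffness, consistent mass matrix; lumped mass available
behind a flag) → drop the zero mode of the closed surface (threshold
1e-8 relative to the spectrum's median) → re-weight λ_m/m → scale by
V^(2/3) → concatenate left/right descriptors and average their volumes.
Defaults: 50 eigenvalues, 3 smoothing iterations; which structures are
bilateral is configuration, not assumption.

Why λ_m/m: eigenvalues of a 2D surface grow linearly in the index
(Weyl's law) and their variance quadratically, so without re-weighting
the highest modes would dominate the phenotypic covariance. Why V^(2/3):
scaling a surface by s multiplies eigenvalues by 1/s²; fixing enclosed
volume to 1 (s = V^(−1/3)) multiplies them by V^(2/3). The full pipeline
is verified to produce identical descriptors for a shape and a rigidly
moved, uniformly scaled copy (relative deviations at machine precision: smoothing and normalization commute with rigid motion and uniform scaling),
and the FEM spectrum converges to the analytic sphere spectrum l(l+1)
with multiplicities 2l+1 (first nonzero eigenvalue within 0.04% at 10k
vertices). Because shape is normalized for size, the structure's volume
is carried alongside the descriptor as a covariate for the heritability
analysis.

## Synthetic data

Generators emulate every study design with known truth: independent-site
binomial genotypes with uniform allele-frequency ranges; matrix-normal
traits with exact covariance Σ_A⊗K + Σ_C⊗Λ + Σ_E⊗I sampled as
L_K Z L_Σᵀ (never assembling the NM×NM covariance); MZ/DZ/sibling/
singleton pedigree designs; analytic icosphere/ellipsoid/box meshes.
What the generators deliberately lack: linkage disequilibrium,
population stratification, assortative mating, measurement error and
realistic anatomy. Passing tests therefore demonstrate correctness of
the estimators under their own model assumptions — not robustness to the
confounders of real cohorts, where stratification covariates and QC
carry that burden.

Problem sizes in tests and the acceptance script (N = 500 samples,
5,000 SNPs, M = 5; 100–500 replicates; 100 MZ + 100 DZ pairs) were
chosen as the smallest designs at which the targeted properties are
well-resolved; trait replicates are drawn conditional on one simulated
GRM, since both the estimator's sampling distribution and its analytic
standard error are defined given K.

## Known limitations

* No REML for multivariate unrelated-sample models (the moment estimator
  exists precisely because that is expensive); no genetic correlation
  between two multidimensional traits.
* ACE models cover twin/sibling structures only — no extended pedigrees,
  dominance, or multivariate REML.
* The GRM module does no imputation, LD pruning or X-chromosome
  handling; ancestry outlier detection is limited to providing GRM PCs.
* The permutation test permutes the projected similarity matrix; the
  alternative (permute, then re-project per draw) would cost a full
  projection per permutation and is not implemented.
* Mesh handling rejects degenerate faces but does not repair
  non-manifold input.
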