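# Methods

This note documents the models behind `subgrad`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical and design choices made where several defensible options
existed.  Nothing stated here goes beyond what the test suite and
`scripts/acceptance.py` actually compute.

## The twin ACE model

A phenotype measured on twins decomposes as variance
`σ²_A + σ²_C + σ²_E`: additive genetics (A), environment shared within a
family (C), and subject-unique environment plus measurement error (E).
Monozygotic (MZ) co-twins share A fully; dizygotic (DZ) co-twins and
non-twin full siblings share it with expected correlation 0.5; any
co-resident pair shares C.  The cross-twin covariance is therefore
`ρ σ²_A + σ²_C` with `ρ = 1` (MZ) or `0.5` (DZ/SIB), and heritability is
`h² = σ²_A / (σ²_A + σ²_C + σ²_E)`.

**Estimation.**  Full maximum likelihood on the bivariate-normal pair
likelihood.  Because pair members are exchangeable, the likelihood depends
on the data only through per-group sufficient statistics (pair count, sum
of squared deviations, sum of within-pair cross-products), so a voxelwise
map of fits costs one scalar optimization per voxel.  Details:

- The mean is profiled out as the grand mean over analyzed subjects (the
  phenotypes entering the model are covariate-residualized and effectively
  centered); group-specific or GLS means are not modelled.
- Optimization runs over standard deviations, so nonnegativity of the
  variance components is structural rather than enforced by constraints.
  L-BFGS-B, likelihood tolerance 1e-8, from three deterministic starts: a
  Falconer/method-of-moments point (`Â = 2(r_MZ − r_DZ)` clipped to the
  interior) and two fixed interior points.  σ_E is floored at 1e-6 of the
  search scale because σ_E = 0 makes the MZ pair covariance singular.
- DZ and SIB pairs are pooled at ρ = 0.5; singletons contribute univariate
  terms.  Both inclusions are flags on `ACEModel`.
- Significance of A uses the likelihood-ratio statistic against the
  σ²_A = 0 null.  Because the null pins the parameter to the boundary, T is
  referred to a 50:50 mixture of a point mass at zero and χ²(1):
  p = 1 when T = 0, else 0.5·Pr(χ²₁ ≥ T).  Voxelwise p-values get
  Benjamini–Hochberg FDR control (the step-up procedure, via statsmodels).
- The validation studies show the estimator is approximately unbiased at
  interior parameters (mean ĥ² over 200 replicates at a2 = 0.4 within
  ±0.03) and the mixture LRT is calibrated-to-conservative (rejection rate
  ≤ 0.06 at α = 0.05 over 2000 null simulations of 300 + 300 pairs).

**Bivariate fits.**  Cholesky-parameterized 2×2 A, C, E blocks (9
parameters); the cross-pair covariance applies ρ to the A block only.
Starts seed the cross-terms of every block with the phenotypic correlation
of the two traits, plus three fixed alternatives.  The genetic correlation
is `rG = A₁₂ / √(A₁₁ A₂₂)`, and the coheritability of the standardized
traits is `h_xy = A₁₂ / √(W₁₁ W₂₂)` with `W = A + C + E`, so
`rG = h_xy / √(h²_x h²_y)` holds as an identity of the fit.  Exactly
collinear traits make the joint likelihood unbounded at the boundary; that
degenerate case is detected and returns rG = ±1 with duplicated univariate
blocks.  rG values are reported without multiple-comparison correction,
mirroring common practice for this estimator.

**"Bootstrap" network distributions.**  Replicates draw half of the
families without replacement, refit the ACE model per voxel on their
members, and average h² per network; replicates violating the pair floor
(default 20 MZ and 20 DZ/SIB pairs) are redrawn.  This is literally a
half-sample subsampling scheme, kept under the conventional name.  Network
contrasts run a one-way ANOVA across the seven network columns and a
two-sample two-tailed t-test of per-replicate transmodal means against
unimodal means.

## Gradients

FC rows are compared by cosine similarity clipped at zero (negative
cosines would break the nonnegative-affinity requirement of the graph
Laplacian; clipping is the documented convention).  The embedding
diagonalizes the symmetric normalized Laplacian, drops the trivial
eigenpair, back-transforms eigenvectors by `D^(−1/2)` (the random-walk
convention), scales each component to unit norm, and fixes signs so the
largest-magnitude loading is positive.  Group-level components are
additionally oriented to correlate positively with the first spatial axis;
individuals inherit orientation through alignment.  A dense solver is used
below 500 voxels and shift-invert Lanczos (shift −0.01, since L is
singular at 0) above; tests verify equivalence against a dense oracle to
1e-8.  A second-smallest eigenvalue below 1e-10 is reported as a
disconnected graph with the advice to relax the sparsification threshold.

**Variance explained** has no canonical definition for a Laplacian
embedding; the convention here maps eigenvalue λ to spectral weight
`max(0, 1 − λ)` — the corresponding eigenvalue of the normalized affinity
operator — and normalizes the retained weights to proportions.  The number
is descriptive, not an inferential quantity.  A fully degenerate spectrum
(all λ ≥ 1, e.g. a complete graph) yields NaN proportions rather than an
error so the embedding itself is still returned.

**Alignment** is joint orthogonal Procrustes over all K = 10 computed
components (analyses use the first two): columns are centered, the
orthogonal matrix minimizing the Frobenius distance to the reference comes
from an SVD, and no scaling or translation is applied to the output.
Column norms are preserved exactly only when the input columns are
orthonormal (a rotation mixes non-orthonormal columns); the tests assert
norm preservation in that regime.

## Parcellation

Each voxel's cortical targets are ranked by unsparsified Fisher-z FC
(ranking is invariant to any strictly monotone transform, so r vs z is
immaterial); the modal network among the top K = 100 targets wins, and the
confidence is the winner's fraction of the top K.  FC ties break by ROI
index, count ties by lower network id — both purely for determinism.  At
K = 1 the procedure reduces to classical winner-take-all.

## Twin-pair classification

A subject pair is one sample with feature vector `|x_Ai − x_Aj|` per voxel
from covariate-residualized FG1 maps.  Per repetition the larger class is
subsampled to balance, samples split 4:1, and C and γ of an RBF-kernel SVM
are tuned by stratified 5-fold CV over `{2^−5, 2^−4.8, …, 2^5}` (51 values
each); the tuned model is scored on the held-out fifth.  Reported numbers:
per-repetition accuracies, the area under the vertically averaged ROC
(right-continuous step interpolation on a fixed 101-point FPR grid, so
perfect separation gives AUC exactly 1), and the Haufe forward-model
pattern — the covariance of each feature with the training-set decision
score, which zeroes out suppressor features that carry weight but no
signal.  Mean patterns average absolute values across repetitions.

The permutation test shuffles pair labels and re-runs the full
train/tune/evaluate cycle per permutation (one repetition each, by
default), with `p = (#{null ≥ observed} + 1) / (n_perm + 1)` — the add-one
estimator cannot return an impossible p = 0.

Heavy validation runs use a documented coarser grid (exponent step 2, 6
values per parameter) and 5–10 repetitions; the planted-signal study uses
150 pairs per class and 500 voxels with a2 = 0.9 on a planted fifth of the
voxels, generated by the heritable-maps simulator so the features are
genuine twin distances, and subject maps are scaled to unit norm — the
scale eigenmap gradients actually have, and the scale the γ grid presumes.
The chance-level study uses 300 pairs per class for the accuracy
confidence interval: tuned cross-validated accuracy on null data has a
known small-sample pessimistic bias that shrinks with sample size, and at
150 pairs that bias is comparable to the CI width.  The permutation
calibration check runs at 150 pairs per class, where observed and null
accuracies share whatever bias remains.

## Spatial statistics

Spatial weights are inverse distances to the k = 26 nearest neighbours in
millimetre coordinates (the full 3-D lattice neighbourhood), symmetrized
by elementwise maximum.  Moran's I is the classical
`(N/S₀)(zᵀWz)/(zᵀz)`.  Surrogates use the singleton variant of Moran
spectrum randomization: the centered map is projected onto eigenvectors of
the doubly-centered weight matrix, coefficient signs are randomized, and
coefficients rotate within eigenvalue-degenerate subspaces (degeneracy
tolerance 1e-8 relative); any basis direction overlapping the constant
vector is orthogonalized away so the mean cannot shift.  This preserves
the mean, variance and Moran's I of the original map to machine precision.
Map-to-map tests randomize only the first map (conditioning on the
second); the default p is two-tailed with the add-one correction, and the
one-tailed proportion is available behind a flag.  Calibration holds for
maps with a broad spatial-frequency spectrum (rejection rate within
[0.03, 0.07] at α = 0.05 over 1000 trials of independent smoothed-noise
maps on a 10×10×5 lattice); maps dominated by one or two smooth components
make the null conservative — visible in the demo pipeline, where a strong
h²-to-planted-profile correlation on a 56-voxel lattice still yields a
non-significant spatial p.

## Synthetic data: what it emulates, and what it does not

Cohorts contain MZ, DZ and SIB pairs plus singletons; families never
exceed two non-singleton members, matching the pair-based likelihood.
Twins share age exactly within a pair (the within-pair covariate
correlation is not otherwise documented for real cohorts); age is uniform
on 22–37 years, sex Bernoulli(0.5), head motion log-normal
(μ = log 0.12 mm, σ = 0.4) — fixed, documented constants on the scale of
adult cohort summaries.  Heritable phenotypes draw a genetic factor shared
exactly within MZ pairs and as `√0.5·shared + √0.5·unique` within DZ/SIB
pairs (marginal variance exactly 1), a family factor, and independent
noise, mixed by the per-voxel √a2, √c2, √e2.

Time series place cortical ROIs on a latent [0, 1] coordinate and give
voxel v the kernel-weighted sum of i.i.d. ROI signals, with a Gaussian
kernel of width 0.15 in hierarchy-axis units (any smooth unimodal kernel
makes the 1-D ordering recoverable; the width trades gradient smoothness
against FC row diversity).  A per-subject heritable scalar shifts each
subject's kernel positions, making individual FG1 maps heritable.
Cortical network labels are contiguous slabs along the ROI coordinate —
mirroring how voxel networks are planted — so the top-K parcellation has a
recoverable ground truth.

Not emulated: hemodynamics, temporally autocorrelated noise, scanner/site
effects, spatial smoothing, motion artifacts, extended pedigrees, and
assortative mating.  Passing tests therefore demonstrate correctness of
the estimators and pipeline under the stated generative model, not
robustness to fMRI acquisition confounds.

## Problem sizes and defaults

| Quantity | Default | Where |
| --- | --- | --- |
| Retained FC fraction | 0.10 (0.25 in the 40-ROI demo, which would otherwise disconnect) | `threshold_top_fraction`, `RunConfig` |
| Components computed / analyzed | 10 / 2 | `LaplacianEigenmaps`, pipeline |
| Parcellation K | 100 (20 in the demo) | `TopKNetworkParcellation` |
| Pair floor | 20 MZ and 20 DZ/SIB pairs | `ACEModel` |
| Subsample replicates | 1000 (10–100 in demos) | `family_subsample_distribution` |
| SVM repetitions / grid | 100, exponent step 0.2 (2–10 and step 2 in validation studies) | `TwinPairSVM` |
| Permutations | 1000 (19–100 in validation studies) | `permutation_test` |
| Surrogates | 1000 (99–200 in validation studies) | `p_moran` |
| Spatial k-NN | 26 | `build_spatial_weights` |

Validation-study sizes (2000 + 2000 pairs for recovery, 2000 null
simulations for LRT calibration, 3000 + 3000 pairs for rG, 500 voxels for
gradient recovery, 1000 trials for spatial calibration, a 7×4×2 lattice
with 60 + 60 pairs for the pipeline demo) are chosen so each study's
sampling error is small against the property it checks while the whole
suite stays desk-scale on one CPU.

## Known limitations

- The ACE fit treats measurement error as part of E and models a single
  grand mean; covariate effects must be residualized beforehand.
- The mixture-LRT reference is asymptotic; at a few dozen pairs it can be
  conservative.
- The variance-explained convention is one of several in use; compare
  numbers across packages only qualitatively.
- MSR surrogates condition on the observed spectral power; for maps with
  very few effective spatial degrees of freedom the spatial null is
  conservative.
- The "top fraction" sparsification is row-wise by default (each voxel
  keeps its strongest cortical targets, standard gradient practice); the
  global-matrix reading is available via ``per_row=False``.
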