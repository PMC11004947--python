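# Methods

This note records the model, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Model and pipeline

The analysis treats a cohort of N template-space parametric volumes as a
linear mixture of a small number of spatial covariance patterns. Stages, in
order:

1. **DVR conversion (optional).** A BP_ND map becomes a DVR map via
   `(BP_ND + 1) / (BP_ND,ref + 1)`, where the denominator uses the
   arithmetic mean of the parametric BP_ND map over the reference
   (whole-cerebellum) mask. The reference value is a single scalar, so the
   reference-region mean of every DVR map is exactly 1. Voxels with
   BP_ND ≤ −1 are nonphysical; they are passed through arithmetically and
   counted in a warning rather than clipped, so data problems stay visible.
2. **Smoothing.** Isotropic-in-mm Gaussian, default FWHM 8 mm, with
   sigma_voxels = FWHM / (voxel_size · 2√(2 ln 2)). Boundaries are
   reflective (mirror), so constant fields are preserved exactly and the
   output range cannot escape the input range; on small grids this avoids
   the edge attenuation that zero-padding would cause. Smoothing happens
   before masking and vectorization.
3. **Masking.** Either a supplied whole-brain mask, or a relative-mean rule:
   include voxels whose cross-subject mean exceeds 0.3 × (mean over voxels
   with positive cross-subject mean). The rule is a simple, reproducible
   stand-in for a template-derived brain mask. Flattening order is C order
   (last axis fastest) and is fixed, so matrix columns map to voxels
   identically across runs.
4. **Matrix.** Rows are subjects in manifest order. Only row (subject)
   means are removed — voxel means are kept. This is substantive: removing
   voxel means would change the decomposition. Removed means are stored, so
   `data + row_means` reconstructs the input exactly.
5. **PCA.** SVD of the demeaned matrix; K ≤ N−1 because demeaning removes
   one degree of freedom. Because rows are mean-free, the right-singular
   vectors are exactly zero-mean over voxels, and scaling them by √V gives
   whitened images with identity covariance by construction (no separate
   whitening estimate).
6. **Infomax ICA.** Natural-gradient updates
   ΔW = lr · (I + (1 − 2g(U)) Uᵀ/B) · W with logistic g, over seeded
   random-permutation voxel mini-batches (batch size max(64, 8K)). Defaults:
   lr = 0.015/ln K, tolerance 1e-6 on the per-pass Frobenius weight change,
   at most 512 passes. The learning rate anneals by ×0.9 whenever a pass's
   weight change fails to shrink (oscillation/divergence guard) and the run
   restarts from identity at half the rate on overflow. The logistic
   nonlinearity targets super-Gaussian (spatially sparse) sources, the
   right model for focal PET covariance patterns; an extended variant
   (per-component kurtosis-signed tanh term) is available for sub-Gaussian
   sources and is off by default. K = 1 returns the PCA solution unchanged.
7. **Mixing recovery.** Least-squares projection of the demeaned data onto
   the sources (pseudo-inverse). The whitening-chain inverse is used when
   the raw matrix is unavailable; the two agree in exact arithmetic, and
   the least-squares route is preferred because it also yields the
   reconstruction RMSE directly.
8. **Orientation.** ICA leaves row permutation and sign undetermined. Each
   source is flipped (with its mixing column) so its extreme-|value| voxel
   is positive; the product A·S is unchanged.
9. **Z maps and clusters.** Each source is scaled to zero mean / unit
   population SD (divide by V, for bit-reproducibility) over the mask.
   Positive ({Z > 3}) and negative ({Z < −3}) excursion sets are labelled
   separately (cluster tables report signed peaks), default connectivity 26
   (vertex adjacency, the common reporting convention; 6 and 18 are
   available), clusters below 500 voxels dropped, rows ordered by
   descending |peak Z|. Anatomical labels are attached only when a label
   atlas on the same grid is supplied (label of the peak voxel).
10. **Statistics.** Per component: Kruskal–Wallis omnibus (tie-corrected
    mid-ranks, chi-square p with df = groups − 1) with Benjamini–Hochberg
    FDR over the K-component family; Dunn pairwise z tests on pooled ranks
    reported unadjusted as post hocs. Loading–score relations: Spearman rho
    with two-sided t-approximation p, pairwise deletion of missing scores
    with per-cell n, in the symptomatic-only (CN dropped before ranking)
    and full cohorts, BH within each cohort's full (component × score)
    family. All tests two-sided, significance at p < 0.05. Dunn's test was
    chosen as the standard companion post hoc to Kruskal–Wallis; its
    pairwise stars are deliberately not FDR-adjusted, matching the
    convention that the omnibus family carries the error control.

## Synthetic cohort

The generator emulates a three-group clinical synaptic-density PET study at
desk scale. Defaults (all configurable):

- 32³ grid at 2 mm; ellipsoidal brain mask (~8700 voxels) with a spherical
  cerebellum-like reference region, both symmetric about the first-axis
  midline.
- Baseline DVR 1.0 inside the brain mask, exactly 1 in the reference region.
- Four planted sources, one per geometry: unilateral mixed-sign, bilateral
  (mirrored across the midline), focal, and medial (blob pinned to the
  midline). Blobs are Gaussian profiles (FWHM 12 mm), zeroed inside the
  reference region, mean-centred over the rest of the mask and scaled to
  unit population SD; placement is rejected and re-drawn until all pairwise
  spatial correlations satisfy |r| ≤ 0.2.
- Loadings: group mean shift plus unit normal. Default shift (CN, MCI, AD)
  = (1.0, 0.5, 0.0) loading-SD on the first source only — an ordered
  AD < MCI < CN effect — and zero elsewhere.
- Volume = baseline + 0.05 × Σ loading·source + N(0, 0.03) voxel noise
  inside the brain. Amplitude 0.05 DVR per loading-SD with noise SD 0.03
  keeps effects in a plausible parametric-image regime while leaving
  recovery achievable.
- Scores: MMSE-like score linked to the first source (slope +1 loading-SD
  per score-SD, score noise SD 0.5) and a CDR-like score with slope −1;
  memory scores unlinked. Scores are mapped to natural ranges (MMSE
  integers clipped to [0, 30], CDR-sb non-negative halves, memory scores
  non-negative integers), so downstream rank statistics face realistic
  ties. The natural-scale offsets (MMSE 24 ± 2.5, CDR-sb 3 ± 1.5) put the
  symptomatic groups in clinically plausible ranges; they are presentation
  only and do not affect rank statistics beyond discretization.
- Group sizes default to 19 CN / 14 MCI / 24 AD. A single seed drives all
  randomness; identical seeds give bit-identical cohorts.

What the generator does **not** emulate: PET noise physics (Poisson
sinogram noise, resolution modelling), anatomical heterogeneity,
registration error, partial-volume effects, or longitudinal change.
Passing recovery tests therefore shows the decomposition and statistics
behave correctly under the linear-mixture model with additive Gaussian
noise — not that real SV2A cohorts satisfy that model.

## Validation design and measured behaviour

- Recovery experiments match estimated components to planted sources by
  greedy assignment on |spatial Pearson r|. At the default conditions
  (K = 6 against 4 planted sources) spatial recovery is ≈ 0.97–0.98 and
  loading recovery ≈ 0.99 per source.
- Detection experiments repeat the full pipeline over 50 seeds. The
  BH-corrected omnibus detection rate of the shifted component is ≈ 0.4–0.5.
  This is an inherent power ceiling of the planted effect size, not an
  estimation loss: a Monte Carlo oracle given the true loadings achieves
  ≈ 0.8 at uncorrected p < 0.05 and ≈ 0.53 after BH over 6 components at
  these group sizes. Zero-shift components are rejected in ≈ 2% of runs.
- Cognition-link experiments recover the linked cell at |rho| ≥ 0.7 with BH
  survival in ≈ 100% of seeds (median |rho| ≈ 0.88 at n = 38). Null-cell
  rates are assessed over components matched to link-free planted sources;
  the residual components (K exceeding the planted rank) are excluded from
  the null set because they absorb the part of the linked pattern the
  matched component missed and are therefore correlated with the linked
  score by construction.
- Exact oracles: cluster labelling is checked against a brute-force flood
  fill, BH against explicit step-up evaluation, PCA truncation against full
  SVD, and Kruskal–Wallis against a hand-ranked example; the KW chi-square
  approximation is calibrated to a 4–6% type-I rate at n = 10 + 10 over
  10,000 simulations.

Problem sizes used in tests (32³ or smaller grids, ≤ 57 subjects, 50-seed
repetitions) were chosen to keep the whole suite in the low minutes on one
CPU while leaving all qualitative behaviour intact; the 91×109×91 preset in
the generator exists for realistic-scale runs.

## Degenerate inputs and tie-breaks

- All-identical observations: Kruskal–Wallis reports H = 0, p = 1 with a
  warning (the tie correction is degenerate); Dunn reports p = 1.
- Zero-variance sources cannot be Z-scaled and raise; ICA raises if a
  source collapses to zero variance.
- Constant rows demean to zero and are preserved by the row-mean
  bookkeeping.
- Cluster peak ties resolve to the first voxel in C scan order.
- Missing cognitive scores are dropped pairwise per (component, score)
  cell with the surviving n reported; no imputation.
- Matrix caches (.npz) embed a mask hash and refuse to load on mismatch.

## Known limitations

- Infomax hyperparameters (batch scheme, annealing, tolerance) are
  conventional choices; the stochastic mini-batch order makes results
  seed-dependent, which is why the seed is a required, logged input.
- No ICASSO-style stability resampling across seeds; single-seed runs can
  land in different local optima for weakly expressed sources.
- The relative-mean mask rule is a pragmatic default, not a validated brain
  extraction; supply a real template mask for serious use.
- Anatomical cluster naming is a lookup hook only; no atlas ships with the
  package.
- SRTM2 fitting (producing BP_ND maps), registration, and amyloid status
  determination are upstream of this package and out of scope.
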