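# sbmpet — source-based morphometry for parametric PET

`sbmpet` decomposes a cohort of co-registered, template-space parametric PET
volumes — synaptic-density DVR maps from SV2A tracers such as [¹¹C]UCB-J, or
any comparable scalar maps — into maximally independent **spatial sources**
and per-subject **loading weights**, then runs the nonparametric statistics
that connect those loadings to diagnosis and cognition. It is aimed at
neuroimaging groups who want a reproducible, scriptable alternative to
GUI ICA toolboxes for multi-subject covariance-pattern analysis.

## The method

Each subject's DVR map (optionally derived from a BP_ND map as
`DVR(v) = (BP_ND(v) + 1) / (BP_ND,Cb + 1)` with the whole-cerebellum mean as
reference) is smoothed with an 8 mm FWHM Gaussian kernel, masked to the
brain, and flattened into one row of a subjects × voxels matrix `X`. After
removing each subject's mean value (rows become mean-free), the matrix is
reduced by PCA to `K` components and unmixed with Infomax ICA
(natural-gradient entropy maximization through a logistic nonlinearity):

```
X  ≈  A · S        A: N×K loading weights,  S: K×V spatial sources
```

A subject's loading weight says how strongly a pattern is expressed in that
subject relative to their global mean; lower loadings in patients read as
pattern-wise signal loss. Sources are visualized as unit-SD Z maps
thresholded at |Z| > 3, with connected suprathreshold clusters (> 500 voxels
by default) tabulated by peak |Z|. Loading weights are compared across
diagnostic groups (CN / MCI / AD) with Kruskal–Wallis omnibus tests
(Benjamini–Hochberg FDR over the K-component family, Dunn pairwise post
hocs unadjusted), and related to cognitive scores (CDR-sb, MMSE, LMII,
RAVLT-delay) with Spearman correlations in the symptomatic-only and full
cohorts.

A first-class synthetic-cohort generator plants smooth spatial sources with
known loadings, group shifts and score links on a DVR-scale brain phantom,
so every stage can be validated against ground truth.

## Worked example

Generate the default synthetic cohort (19 CN / 14 MCI / 24 AD subjects on a
32³ grid, four planted sources, a CN→AD loading shift on the first source
and an MMSE-like score linked to it), run the pipeline with K = 6, and
compare against the ground truth:

```python
from sbmpet import (CohortConfig, RunConfig, analyze_cohort, make_cohort,
                    match_sources)

volumes, metadata, truth = make_cohort(CohortConfig(), seed=1)
result = analyze_cohort(
    volumes, metadata,
    RunConfig(n_components=6, seed=1, min_cluster_voxels=50),
    mask=truth.brain_mask,
)
d = result.decomposition
print(f"converged: {d.converged} after {d.n_iterations} passes")
for m in match_sources(d, truth.sources_true, truth.loadings_true):
    print(f"planted source {m.true_index} -> component {m.est_index}: "
          f"spatial r = {m.spatial_r:+.3f}, loading r = {m.loading_r:+.3f}")
```

```
converged: True after 222 passes
planted source 0 -> component 3: spatial r = +0.979, loading r = +0.994
planted source 1 -> component 4: spatial r = +0.968, loading r = +0.999
planted source 2 -> component 1: spatial r = +0.980, loading r = +0.996
planted source 3 -> component 2: spatial r = +0.981, loading r = +0.998
```

All four planted patterns are recovered with spatial and loading
correlations near 1. The statistics tables single out the shifted,
score-linked source (matched to component 3 here):

```python
print(result.group_table.query("comparison == 'omnibus'")
      [["component", "statistic", "p_value", "p_adjusted"]].round(4))
```

```
 component  statistic  p_value  p_adjusted
         0     5.4509   0.0655      0.1310
         1     0.8587   0.6509      0.6509
         2     3.2290   0.1990      0.2985
         3    16.5114   0.0003      0.0016
         4     6.7395   0.0344      0.1032
         5     2.2112   0.3310      0.3972
```

Only component 3 — the one carrying the planted group shift — survives FDR
correction (H = 16.5, adjusted p = 0.0016). In the symptomatic-only
cognition analysis the same component shows the planted monotone links
(Spearman rho = +0.85 with the MMSE-like score and −0.86 with the CDR-like
score, both FDR-significant at n = 38), while unlinked cells stay null.

The same analysis runs from the shell on NIfTI files plus a CSV manifest:

```sh
sbm-pet simulate --seed 1 --out cohort/
sbm-pet run --manifest cohort/manifest.csv --mask cohort/brain_mask.nii.gz \
            --k 6 --seed 1 --out run/
```

which writes per-source Z maps, `mixing.tsv`, `clusters.tsv`, the statistics
tables and a `run_log.json` that reproduces the run exactly via
`sbm-pet run --config run/run_log.json`.

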