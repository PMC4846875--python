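# phenoks

Image-based compound profiling for high-content screens: per-cell
features over subcellular regions, **signed Kolmogorov–Smirnov Z-score**
phenotype profiles, and mechanism-of-action clustering.

## The problem

High-content screens image cells treated with a panel of compounds and
stained for signalling and trafficking markers (e.g. a GFP-tagged EGF
receptor, phospho-ERK, phospho-Akt, labelled transferrin). Each compound
perturbs the *distributions* of many per-cell image features —
intensities over the nucleus, cytoplasm, a perinuclear ring and a
plasma-membrane (PM) ring, endosome counts, colocalization — and
compounds with a shared mechanism shift those distributions in similar
ways. `phenoks` quantifies each perturbation, builds a per-compound
phenotypic profile and groups compounds by mechanism, for screeners who
want to flag compounds whose phenotype disagrees with their nominal
target.

## The statistic

For descriptor d, compound c, time t, treated cells are compared with
vehicle (DMSO) control cells by a signed two-sample KS statistic

    D+ = sup_x [F_ctrl(x) − F_trt(x)],   D− = sup_x [F_trt(x) − F_ctrl(x)]
    signed D = ±max(D+, D−)   (+ when the treated distribution sits higher)

standardized by the bootstrap SD of the null comparison (two independent
with-replacement resamples of the control, n_boot = 1000):

    Z_{d,c,t} = signed D_{d,c,t} / Std_{d,t}

Descriptors whose Z-scores do not reproduce across two independent
replicate experiments (Pearson r ≤ 0.4 across compounds) are discarded.
The retained compound × (descriptor, time) Z matrix is mean-centered,
reduced by PCA to the components explaining ≥ 95% of variance, and the
compounds (plus the control) are grouped by Ward hierarchical clustering
with a largest-merge-gap dendrogram cut. See `docs/methods.md` for the
full account.

Because screens of this kind rarely ship their raw images, the package
includes a synthetic-screen generator (`phenoks.synthetic`) with known
ground truth — cell geometry, spot counts, per-descriptor effect sizes
grouped into mechanism archetypes — so every stage, from segmentation to
clustering, is testable end to end.

## Worked example

```python
from phenoks.synthetic import SyntheticPanelConfig, generate_panel
from phenoks import CompoundProfiler

panel = generate_panel(SyntheticPanelConfig(rng_seed=1))   # 14 compounds + DMSO
results = CompoundProfiler.from_panel(panel, seed=1).fit()
print(results.summary())
print("ARI vs ground truth:", results.score_against(panel.ground_truth))
```

prints

```
Compound profiling results
==========================
Samples:               15 (14 compounds + DMSO)
Z-matrix columns:      63 (descriptor x time)
Reliability filter:    63/150 columns kept (replicate r > 0.4)
PCA:                   3 PCs retained, cumulative variance 99.3% (threshold 95%)
Ward clustering:       4 clusters (largest_gap cut)
  cluster 1: cmpd01, cmpd02, cmpd03, cmpd04, DMSO
  cluster 2: cmpd05, cmpd06, cmpd07, cmpd08
  cluster 3: cmpd12, cmpd13, cmpd14
  cluster 4: cmpd09, cmpd10, cmpd11
ARI vs ground truth: 1.0
```

Reading the output: of the 30 descriptors × 5 time points = 150 candidate
profile columns, 63 reproduce across the two simulated replicates and
survive the reliability filter; three principal components carry
essentially all the between-compound variance; and the largest-gap cut
of the Ward tree recovers the generator's four mechanism groups exactly
— the inactive compounds cluster with the DMSO control, and the
Akt-axis, receptor-blocking and trafficking-blocking compounds each form
their own cluster (adjusted Rand index 1.0 against the ground-truth
grouping). `results.z_matrix`, `results.pca` and
`results.plot_dendrogram()` expose the underlying estimates.

Image-based workflows use the same objects: `phenoks.segmentation`
(nucleus detection, seeded propagation of cell outlines, perinuclear/PM
rings, top-hat endosome detection) and `phenoks.features` turn
multi-channel images into the per-cell feature table consumed by
`CompoundProfiler`.

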