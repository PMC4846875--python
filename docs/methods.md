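# Methods

`phenoks` implements an image-based compound-profiling pipeline for
high-content screens of receptor signalling and trafficking: per-cell
feature extraction over subcellular regions, signed Kolmogorov–Smirnov
(KS) Z-scoring of compound effects against a vehicle control, replicate
reliability filtering, and multivariate grouping of compounds by
mechanism (PCA followed by Ward hierarchical clustering). This note
describes the statistical model, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical conventions.

## Region scheme and features

Segmentation proceeds from the DNA channel: nuclei are the connected
components of the Otsu-thresholded, Gaussian-smoothed (σ = 1 px) image,
filtered by area, with border-touching nuclei removed. Cell outlines grow
from the nuclei by seeded minimal-cost propagation over the receptor
(GFP-EGFR-like) channel: a pixel joins the seed reachable at minimal
accumulated cost, where one 8-connected step from p to q costs
`|I(p) − I(q)| + λ·dist(p, q)`. With λ (default 0.05) small the boundary
between adjacent cells follows intensity valleys in the guide channel;
in flat intensity it degenerates to the perpendicular bisector
(a Voronoi split under the octile path metric). Cost ties go to the
lower cell label — a measure-zero case for real images that matters only
on exactly symmetric synthetic inputs.

Derived regions per cell k, all with disk structuring elements:

* cytoplasm(k) = cell(k) \ nucleus(k) — an exact set identity;
* perinuclear(k) = (dilate(nucleus(k), `expand_px`) \ nucleus(k)) ∩ cell(k);
* PM(k) = cell(k) \ erode(cell(k), `shrink_px`), the plasma-membrane
  proxy ring; when the erosion empties the cell, PM(k) is the whole cell.

Defaults are `expand_px = 7`, `shrink_px = 5`; both are parameters
because the appropriate ring widths depend on magnification and cell
size, and because "diameter of N pixels" conventions vary between
instruments — here the values are structuring-element radii.

Endosome-like puncta are detected by white top-hat enhancement (image
minus its opening with a disk of radius `tophat_radius`, default 5 px),
thresholded at mean + 3 SD of the enhanced image (an absolute
`min_intensity` can override), labelled with 8-connectivity, filtered by
a minimum area (default 3 px², which removes single-pixel top-hat
residuals at discrete region edges), and assigned to the cell and ring
region containing the object centroid. Centroid assignment makes each
object count exactly once even when it straddles ring boundaries.

Descriptors are region × channel × statistic combinations: integrated
and mean intensities for every region/channel pair, endosome counts per
ring region, colocalization counts (an object in channel A colocalizes
when ≥ `min_overlap_frac` of its pixels, default 0.5, overlap the union
of channel-B objects), and the per-cell perinuclear/PM intensity ratio.
The per-batch regression coefficient — the ordinary least-squares slope
(with intercept) of perinuclear on PM intensity across cells — serves as
a population-level trafficking read-out. The default catalogue is a
documented working set assembled from these primitives; catalogues are
configurable lists of `DescriptorDef`, not a fixed schema.

## Signed-KS Z-score profiling

For descriptor d, compound c, time t, the treated per-cell distribution
is compared with the matched control cells by the two-sample KS
statistic, given a sign by the direction of the shift:

    D+ = sup_x [F_ctrl(x) − F_trt(x)]     (treated shifted to larger values)
    D− = sup_x [F_trt(x) − F_ctrl(x)]     (treated shifted to smaller values)
    signed D = +max(D+, D−) if D+ ≥ D−, else −max(D+, D−)

Both suprema are evaluated exactly over the pooled sample points, so
ties in the data are handled exactly. Ties between D+ and D− (within
1e−12, a float-noise guard) resolve to +; this makes the antisymmetry
`signedD(a,b) = −signedD(b,a)` hold everywhere except exactly tied
comparisons, where both directions report +.

The signed D is standardized into `Z = signedD / Std`, where Std is the
bootstrap SD of the null (control-vs-control) signed KS for that
(descriptor, time, replicate): in each of `n_boot = 1000` rounds two
independent with-replacement resamples of the control cells — one of the
treated sample's size, one of the control's — are compared. Resampling
is implemented as multinomial draws over the unique control values,
which is distributionally identical to index resampling and fully
vectorizable. Comparing two resamples rather than one resample against
the original control matters: the resample-vs-original statistic shares
half its sampling noise with its reference and its SD is smaller by
√2, which would inflate null Z-scores to SD ≈ 1.4. With the paired
comparator, Z is calibrated — control-vs-control Z has mean ≈ 0 and
SD ≈ 1 (the acceptance suite verifies SD ∈ [0.7, 1.3] over 200 trials at
600 cells). The single-resample variant remains available as
`mode="single"`. Descriptors whose control sample is constant have
Std = 0, are flagged degenerate and excluded rather than scored.

Each replicate experiment is processed against its own control wells
(null SD per descriptor × time × replicate), keeping the replicate Z
vectors independent. A (descriptor, time) column is retained when the
Pearson correlation of its Z-scores across compounds between the two
replicates exceeds 0.4; columns with undefined correlation (zero
variance) are dropped and logged. Retained replicate Z-scores are
combined by their mean (concatenation is available). The control enters
the final matrix as its own row, computed from a held-out random split
of the control cells into two halves, with the null SD rescaled by
√((1/n₁ + 1/n₂)/(2/n)) to match the half-sample sizes; by construction
this row sits near zero.

## Multivariate analysis

PCA is computed by SVD of the column-centered Z matrix. Columns are not
rescaled: Z-scores are already on a common standardized scale, and
rescaling would re-amplify the noise-only columns the reliability filter
left borderline (correlation-matrix PCA can be had by standardizing the
input first). With s samples at most s − 1 components are non-zero;
variance fractions are reported over the non-degenerate components and
the retained set is the smallest prefix reaching `var_threshold`
(default 95%).

Compounds (plus the control row) are clustered on the retained PC
scores, unweighted, by Ward's minimum-variance agglomeration on
Euclidean distances (scipy linkage; an independent naive greedy Ward
implementation recomputing within-cluster sums of squares from raw
points backs it in the tests). The dendrogram is flattened below the
largest gap between successive merge heights — a reproducible stand-in
for cutting a dendrogram by eye; `fixed_k` is available when the number
of groups is known. When every merge occurs at the same height (all
samples identical) there is no gap and a single cluster is returned.
Descriptor structure is summarized separately by hierarchically
clustering the descriptor × descriptor Pearson correlation matrix at
1 − r distance (average linkage), reported at two cut levels.

## The synthetic screen generator

The generator stands in for the microscope: its defaults describe a
screen of 14 compounds + DMSO, five time points (0/5/30/60/180 min after
ligand stimulation), 600 cells per condition (within the 500–1000 cells
per condition a 20× automated acquisition of ~36 fields yields) and two
independent replicates.

Per-cell intensity descriptors are log-normal — fluorescence intensities
are positive and right-skewed — parameterized so the control mean is
exactly the baseline m and the control SD exactly m·CV (CV = 0.3):
`value = m·f·exp(sε − s²/2)` with `s = scale·sqrt(ln(1 + CV²))`. A
location shift of δ control-SD units is applied as the multiplicative
factor `f = 1 + δ·CV` (floored at 0.05), which moves the mean by exactly
δ control SDs while keeping values positive; a scale factor multiplies
the log-scale spread. Count descriptors are Poisson with rate shifted by
δ·√rate (scale factors do not apply to counts). Stimulation kinetics are
piecewise-linear schedules over the five anchor times, not a mechanistic
ODE: the control perinuclear/PM receptor ratio rises to a maximum at
30 min and then decays as the receptor is degraded; nuclear pERK peaks
at 30 min and PM pAkt at 5 min. Archetype effects are modulated by a
shared expression schedule (0.2 at t = 0, rising to 1.0 at 30 min,
0.7 at 180 min).

Four default archetypes mirror the mechanism classes such a screen
separates: `null_like` (inactive), `akt_axis` (PM pAkt strongly down,
compensatory nuclear pERK up), `receptor_block` (both pathways down,
reduced perinuclear receptor accumulation and uptake) and
`trafficking_block` (receptor and recycling marker retained at the PM,
perinuclear accumulation reduced). Effect vectors are free parameters of
the generator — they are chosen to produce the qualitative cluster
structure, not measured values for any real compound. Compounds are
dealt across archetypes in near-equal blocks; a deterministic potency
multiplier (0.85–1.15 within each block) scales each compound's shifts
so same-mechanism compounds are similar but not identical. The DMSO
control is the exact null archetype. Batch randomness comes from
independent streams seeded by (run seed, batch index), so output is
bit-for-bit reproducible and order-independent.

Image mode renders cells as deformed ellipses with concentric elliptical
nuclei, Gaussian endosome spots (σ = 2 px) split between a perinuclear
shell and the periphery, flat background and optional Gaussian read
noise clipped at zero; ground-truth masks are disjoint by construction
(bounded placement retries) and spot coordinates/counts exactly match
the rendered content. Archetype effects appear in image mode only
coarsely (spot rates and the perinuclear fraction).

What the generator does **not** emulate: optical blur and illumination
gradients, cell crowding and touching cells, mitotic/apoptotic
morphologies, correlations between descriptors within a cell (each
descriptor is sampled independently given the condition), plate-position
effects, and any particular real compound's effect sizes. Passing the
end-to-end recovery test therefore shows the pipeline's statistics and
clustering are correct and calibrated under a realistic noise family —
it does not certify segmentation accuracy on real micrographs, nor that
any real screen will separate into four clusters.

## Numerical choices and problem sizes

* Bootstrap and panel problem sizes used by the test suite and the
  acceptance script — 600 cells/condition, 1000 bootstrap rounds, the
  ~30-descriptor default catalogue, 10–20 panel seeds — are the
  generator's study conditions; a full panel run fits in tens of seconds
  on one core.
* The KS tie guard (1e−12), the eigenvalue rank cut (1e−10 relative),
  and the dendrogram equal-height degenerate rule are documented above.
* Degenerate descriptors (constant control, zero replicate variance) are
  excluded with a log entry rather than raising, so one dead channel
  does not abort a screen-sized run.
* Seeds: every stochastic stage (generator batches, bootstrap
  substreams, control splits) derives its stream deterministically from
  one run-level seed via `numpy` `SeedSequence` spawning.

## Known limitations

* The reliability filter assumes exactly two replicates; with one
  replicate all non-degenerate columns are retained (reported as such).
* The propagation segmentation is a shortest-path labelling, adequate
  for well-separated synthetic cells; it has no shape priors and will
  not split confluent sheets the way trained cell-segmentation models
  do.
* The largest-gap cut is sensible when between-group merges tower over
  within-group merges; for weak group structure prefer `fixed_k` and
  inspect the dendrogram.
* Colocalization uses binary pixel overlap of detected objects, not
  intensity correlation coefficients.
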