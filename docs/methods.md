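# Methods

This note documents the models, defaults, and numerical choices behind
`adprog`, and what the synthetic-cohort experiments do and do not show
about real data.

## Synthetic cohort model

The generator emulates the statistical structure an AT(N) progression
analysis assumes, not the physics of acquisition.

**Trajectories.** Each subject's cognitive score follows
`score(t) = b + s·t + q·t² + ε`, `t` in years, `ε ~ N(0, σ)`, with
class-specific parameters (MMSE-like units):

| class | baseline (b) | slope (s, /yr) | quad (q, /yr²) | slope sd | noise sd |
|-------|-------------|----------------|----------------|----------|----------|
| MD    | 27.5 ± 1.2  | −1.25 ± 0.45   | 0              | 0.45     | 0.8      |
| FD    | 26.5 ± 1.4  | −4.75 ± 0.75   | −0.5           | 0.75     | 0.8      |

Defaults were calibrated so that two visibly separating trajectory
bundles emerge over 24 months and the clustering stage recovers the
generating classes with ARI ≥ 0.9 at n = 300 — the regime the analysis
method is designed for.  Visits default to months 0, 6, 12, 24 (four
time points including baseline; the schedule is configurable because the
convention of counting baseline is ambiguous in practice).

**Volumes.** Phantoms, not brains: a large cortex-like ellipsoidal
shell and a small hippocampus-like ellipsoid on a Gaussian noise
background (sd 0.10), 32³ voxels at 4 mm isotropic by default.  A
per-subject atrophy factor scales each region's intensity and its
volume (radii scale with the cube root).  Factors are drawn from
class-conditional clipped normals — hippocampal 0.92 ± 0.20 (MD) vs
0.72 ± 0.20 (FD); cortical 0.97 ± 0.12 vs 0.90 ± 0.12 — so imaging is
informative but imperfect, as in real cohorts where atrophy
distributions of fast and moderate decliners overlap substantially.
The rationale for scaling size as well as intensity: per-image
z-scoring (part of the model's preprocessing) removes global intensity
scale, so a pure-intensity class code would be partially erased by the
pipeline's own standardization.

**Scalar biomarkers.** Class-conditional normals clipped positive:
CSF Aβ 700/620 ± 150 pg/mL (MD/FD), p-tau 28/38 ± 8–10 pg/mL, FDG
composite 1.25/1.10 ± 0.10, SUVR 1.30/1.40 ± 0.12 (all amyloid-positive
continuum values), ICV 1.5×10⁶ ± 1.5×10⁵ mm³ (label-independent), plus
a pure-noise N(0,1) scalar for null-addition controls.

**Label refinement (the synergy cohort).** With a nonzero synergy
coefficient, class labels are resampled from a logistic model on
pathology-signed standardized biomarkers:

```
logit P(FD) = β₀ + 0.5·zA + 1.5·zT + 0.6·zN + c·zA·zT
```

with `zA = −z(Aβ)`, `zT = z(p-tau)`, `zN = −z(FDG)`, `c = 2.0` in
`default_synergy_config`, and `β₀` solved so the expected FD fraction
matches the configured proportions.  Trajectories and volumes are then
regenerated from the refined labels.  The weights are calibrated so a
desk-scale analogue of the biomarker-combination pattern emerges: an
oracle logistic on the generated features scores roughly N ≈ 0.74,
T(N) ≈ 0.78, AT(N) ≈ 0.80 linear / 0.84 with the interaction — tau
adds clearly over neurodegeneration alone, amyloid adds modestly on its
own, and the A×T product carries the largest joint gain.  A check that
the construction is self-consistent: a logistic refit of the generated
labels on (zA, zT, zA·zT, zN) recovers the synergy coefficient within
its 95% CI at n = 2000.

**What passing tests do not show.** The phantoms contain no anatomy,
scanner effects, registration error, or site variation; trajectories
have no floor effects, missed visits, or practice effects; biomarker
distributions are Gaussian by construction.  Results on this generator
validate the *pipeline* — its statistics, its training loop, its
leakage discipline — not clinical performance on any real cohort.

## Trajectory clustering

DTW uses absolute-difference local cost, the symmetric step pattern
{(1,0),(0,1),(1,1)}, no warping window, and no path-length
normalization; on 4-point series a locality constraint would be
vacuous, and absolute cost is more robust than squared cost to a single
aberrant visit.  Both choices are configurable.  `pairwise_dtw`
vectorizes the accumulated-cost recursion across all subject pairs.

Agglomeration is Lance–Williams with three linkages: `ward2` (Ward's
criterion on squared dissimilarities, heights reported as square
roots), `ward1` (the same recurrence on the dissimilarities
themselves), and `upgma`.  Equal-height ties merge the
lowest-creation-index pair first, which makes trees deterministic
across platforms.  Scores are clustered on the raw scale — the baseline
offset is part of the phenotype signal — and subjects with missing
visits are dropped rather than imputed, mirroring complete-series
inclusion criteria.

Cluster number is chosen by average silhouette width over k = 2, 3, 4,
computed directly from the dissimilarity matrix (singletons contribute
width 0).  For k = 2, the cluster with the more negative mean
least-squares slope is named FD; exact ties break toward the
higher-baseline cluster being MD.

## Statistics

**Permutation cluster test.** Post-clustering group comparison is a
selection problem: testing clusters found by the data with a standard
two-sample test is anti-conservative.  The package substitutes a
pipeline-honest permutation test: the statistic is the DTW distance
between cluster mean trajectories; the null is built by permuting
residuals (about the per-visit mean curve) independently within visits
and re-running the entire cluster-then-compute pipeline on each
permuted cohort; `p = (1 + #{null ≥ obs}) / (1 + n_perm)`.  Under a
null cohort with exchangeable within-visit residuals this is exact.  In
pipeline mode (labels derived internally) singleton clusters are
retained on both the observed and null sides — required for exact
exchangeability; user-supplied labels with a singleton group raise a
degenerate-cluster error instead.  This test is a methodological
stand-in for dedicated post-selection inference; it controls type I
error for the pipeline as a whole rather than implementing selective
inference for a fixed pair of clusters.

**Repeated-measures ANOVA.** Classical two-way mixed-design sums of
squares (between = phenotype, within = time, subject as the
within-error stratum), reporting F(t−1, (n−g)(t−1)) for time and
F((g−1)(t−1), (n−g)(t−1)) for the interaction.  No sphericity
correction is applied by default, matching the uncorrected reporting
convention for this analysis; the decomposition is cross-checked
against an independent mixed-ANOVA implementation in the tests.

**Group differences** use Welch's t or the Wilcoxon rank-sum normal
approximation (no tie correction, so identical groups give z = 0,
p = 1).  **Tau positivity** is strict: p-tau > 21.8 pg/mL.
**Chi-square** is Pearson's without continuity correction.  A note on
one published 3×2 table of subtype-by-phenotype counts (19/7, 26/21,
13/11): the standard Pearson statistic on those counts is ≈ 2.616
(p ≈ 0.27), not the χ² = 1.39 printed alongside them; the package
implements the standard formula and documents the discrepancy rather
than reconciling it.

## PENet and training

The volume encoder is 2 convolution blocks (3³ kernels, stride 2,
batch-norm, ELU) followed by 3 separable-convolution blocks (depthwise
3³ then pointwise 1³, batch-norm, ELU) with filter counts
8→16→32→64→128 — strictly increasing, as the parameter-efficient
design prescribes.  A separable block with c_in inputs and f filters
costs `c_in·27 + c_in·f` weights against `c_in·27·f` for a full block;
the factorization is what keeps the model trainable on hundreds of
subjects.  Scalar biomarkers pass through per-modality FC branches
(widths 8, 8) and are concatenated with the flattened volume features
into an FC fusion head (widths 32, 16, then 2-way softmax).

The engine is pure NumPy with analytic backprop (im2col + GEMM
convolutions, bincount scatter for input gradients); every layer is
checked against central finite differences at 1e-6 relative tolerance.
All randomness flows through seeded generators and the only kernels are
deterministic BLAS calls, so fixed seeds reproduce training bit-for-bit
on CPU.

Reference training configuration: SGD, batch 25, 50 epochs, initial
lr 8×10⁻⁴ halved every 10 epochs (the halving period is a package
choice), L2 5×10⁻⁴ on FC weights only, stratified 5-fold CV.
Augmentation — axial-plane rotation (angle ~ U(−90°, 90°)), translation
(fraction ~ U(0, 0.5) of each dimension, random direction, zero fill),
and left-right flips — is applied to training folds only, after the
fold split; per-image z-scoring and training-fold scalar statistics are
the only normalizations, and a fold-disjointness assertion on subject
ids runs before every fit.

**Desk-scale configuration.** The experiments the test suite and
acceptance script run use 32³ phantoms, n = 200, 8 epochs, initial
lr 0.02 halved every 4 epochs, one augmented copy per training subject
with mild settings (rotation ≤ 15°, shift ≤ 0.05), and 3 cohort seeds —
sizes chosen so the full property suite runs on a single CPU core in
minutes while the qualitative biomarker-combination pattern remains
resolvable above fold-to-fold noise (about ±3 accuracy points per
fold at 40-subject test folds).  The higher learning rate compensates
for the much shorter schedule; the reference configuration remains the
default in `TrainConfig`.

## Ablation statistics

AUC is the Mann–Whitney form (midranks, ties counted ½), which the test
suite verifies equals the ROC trapezoid integral to 1e-12.  DeLong's
test uses placement-value structural components, supporting both the
single-model comparison against chance (AUC = 0.5) and the paired
comparison of correlated AUCs; its variance estimate agrees with a
10,000-replicate bootstrap within 10% on fixed 40-subject data.  The
SVM baseline consumes a stated feature reduction of the imaging input —
an 8³ trilinear downsample of the standardized volume, flattened,
concatenated with the FDG scalar — because no convention exists for
feeding raw 3-D volumes to a kernel machine; this is an assumption, not
a reproduction.  No multiple-comparison correction is applied across
ablation cells by default (a Holm option exists in the group-difference
layer).

## Subtyping

HV:CTV thresholds are the within-sample 25th/75th percentiles with
linear interpolation between order statistics; assignments use strict
inequalities, so boundary-equal subjects fall to typical-AD, and a
degenerate all-equal ratio distribution yields all-tAD with a warning.
External reference thresholds can be supplied for cohort-external
calibration.  Voxelwise contrast mapping is out of scope; the phantom
pipeline emits regional mean-difference tables instead.

## Pipeline

Stages persist their artifacts (CSV/JSON/Newick/NIfTI) into the output
directory and are skipped when outputs exist; because cohort generation
is deterministic in the config seed, deleting any intermediate artifact
and resuming reproduces identical results.  Per-stage seeds derive from
the global seed by a keyed blake2 hash of the stage name, so stage
randomness is independent of execution order.  Reports record per-stage
runtimes and SHA-256 checksums of every artifact.

## Known limitations

* The permutation test's exactness argument requires exchangeable
  within-visit residuals; strong subject-level random effects without
  cluster structure make it conservative, not invalid.
* The NumPy engine is single-core and desk-scale by design; it is not a
  substitute for GPU-scale training, and the desk-scale accuracies are
  analogues of, not estimates of, any published cohort accuracy.
* Ward linkage on DTW dissimilarities is a heuristic (DTW is not
  Euclidean-embeddable); this mirrors the field's practice, and the
  robustness linkages quantify its stability.
* The generator's Gaussian biomarker model cannot represent the skewed
  or censored assay distributions of real CSF measurements.
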