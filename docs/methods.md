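# Methods

## The segmentation model

`tissueseg` treats cell segmentation in membrane-stained volumes as
boundary detection followed by signed-graph partitioning.  The underlying
assumptions are: cells tile the volume densely (every voxel belongs to
exactly one cell); the only reliable image evidence is on the cell–cell
interfaces; and boundary evidence is locally unreliable (blur, noise,
staining drop-outs), so the grouping decision must pool evidence over
whole interfaces rather than trust single voxels.  The second assumption
is why simple thresholding or connected components fail: one small hole
in a predicted boundary merges two cells.  Pooling happens at two levels:
supervoxels aggregate voxels, and the partitioners aggregate supervoxel
interfaces.

### Boundary targets (ground truth → training signal)

Ground-truth labels `S` are converted to a binary boundary image
`I = [Φ(S) ∗ G_σ > 0.5]` with σ = 1.0 by default.  `Φ` marks a
two-voxel-thick boundary: both voxels flanking every 6-connected face
where the label changes (implemented with scikit-image's
`find_boundaries(mode="thick")`).  The blur–threshold step regularises
the target; the result stays binary.

One measured consequence matters for synthetic studies: on Voronoi
geometry the 0.5 threshold *erases* obliquely oriented membranes — the
blurred staircase mask stays below 0.5 over long stretches (per-interface
retention down to 25 % on clean volumes).  A network trained on such
targets never sees those interfaces as positive, and no downstream
partitioner can recover evidence that does not exist.  The package
therefore also exposes the pre-threshold soft map
(`synthetic.soft_boundary_map`, values in [0, 1], peaked at membrane
centres), and uses *it* as the stand-in for CNN output in end-to-end
fixtures; the binary form remains the training target.

### Network

Standard encoder–decoder U-Net with same convolutions, 2× max-pooling,
nearest-neighbour upsampling and skip concatenation; each level is a
double block in the order normalisation → convolution → ReLU.  Group
normalisation is the default (appropriate for single-patch iterations);
batch normalisation is available for multi-patch training.  The residual
variant adds an identity/1×1-projected shortcut per block.  A final 1×1
convolution emits one logit map; the sigmoid is applied at prediction.
Inputs must be divisible by `2^(depth−1)`; `predict_tiled` mirror-pads to
that requirement, tiles with 50 % overlap and averages (unweighted) the
per-voxel probabilities, which suppresses seam artifacts.

The layers are implemented directly on numpy (im2col + matmul
convolutions, hand-derived backward passes, Adam).  This keeps the
package self-contained and CPU-friendly; correctness of every backward
pass is pinned by float64 finite-difference tests.  The intended scale is
desk-scale: two or three levels, 8–32 feature maps, 32³–64³ patches —
not the multi-GPU regime of production boundary detectors.

Loss: `α·BCE + β_loss·Dice` with α = β_loss = 1 (the Dice smoothing
constant is 10⁻⁶).  During training the loss is evaluated on logits
(`max(z,0) − z·t + log(1+e^(−|z|))`) for numerical stability.  Training
uses Adam with β₁ = 0.9, β₂ = 0.999, L2 penalty 10⁻⁵, initial learning
rate 2·10⁻⁴, halved when the validation score stagnates for `patience`
validations.  Validation follows the segmentation-oriented protocol:
threshold the predicted map at 0.4, label the sub-threshold connected
components (6-connectivity), and score adjusted Rand error against the
ground-truth cells; the checkpoint with the lowest validation error is
returned.  Augmentations: in-plane flips and 90° rotations (applied to
patch and target identically), optional grid-based elastic deformation
(linear resampling for the image, nearest for the target), additive
Gaussian and Poisson noise on the image only.

### Distance-transform watershed

Threshold the boundary map at δ = 0.4; compute the Euclidean distance of
every voxel to the thresholded boundary; smooth with σ = 2.0; place one
seed per local maximum (a connected plateau yields exactly one seed, its
first voxel in scan order); flood the negated smoothed distance with
6-connected watershed; absorb regions smaller than 50 voxels into the
neighbour with the largest shared contact surface (smallest regions
first, contact areas recomputed after each merge).  Output is a complete
partition with labels dense in 1..K.  Maxima of the distance-from-boundary
transform are cell centres, so seeding at maxima and seeding at minima of
the negated transform are the same convention.

The defaults (δ = 0.4, σ = 2.0, 50 voxels) were chosen once as the
pipeline-wide operating point and are exposed in `WatershedParams`.
On clean data this stage alone segments well; its characteristic failure
is over-segmentation (spurious seeds from noisy distance fields), which
is precisely what the graph stage repairs.

### Region adjacency graph and signed weights

Nodes are supervoxels; edges connect exactly the face-adjacent pairs.
Each edge stores its contact area (face count) and the arithmetic mean of
the boundary map over its interface voxel set — every voxel of either
region with a face neighbour in the other region, counted once.  The
probability-to-weight map is the log-odds with a log-odds bias:

    w(p, β) = log((1−p)/p) + log((1−β)/β),   p clamped to [1e−5, 1−1e−5].

This form was chosen because it is the unique simple map that (a) flips sign
at p = 1 − β (an edge is attractive exactly when its boundary evidence
is below 1 − β, so raising β shrinks the attractive range), (b) reduces to the plain log-odds
at β = 0.5, and (c) is strictly decreasing in both arguments, which makes
the advertised behaviour — higher β over-segments — a theorem rather
than a tendency (cluster counts are monotone in β for GASP, tested).

### Partitioners

*GASP (average linkage).*  Contract the highest-positive-weight edge;
merge parallel edges by contact-area-weighted averaging of signed
weights; stop when no edge is attractive.  Deterministic: ties broken by
the (min id, max id) edge pair.

*Mutex watershed.*  Process edges by decreasing |w|; attractive edges
union clusters unless a mutual-exclusion constraint separates them;
repulsive edges install such constraints unless already merged.
Invariant to positive rescaling of the weights.

*Multicut.*  Objective: sum of signed weights over cut edges.  Reported
in the normalised correlation-clustering "disagreement" form (the
constant Σ min(w,0) subtracted), which is 0 iff every attractive edge is
internal and every repulsive edge cut, and non-negative always; both
forms share their minimiser.  The production solver is greedy additive
edge contraction followed by deterministic local search: single-node
relocations, joint moves of adjacent pairs, whole-cluster merges, and
Kernighan–Lin passes over adjacent cluster pairs (tentative transfer
sequences, best improving prefix kept) including split-off attempts; the
refinement also runs from an all-singleton and a mutex-watershed start
and keeps the best local optimum.  Exact ILP solving is out of scope: an
exhaustive set-partition enumeration (`multicut_exact`, ≤ 12 nodes,
restricted-growth-string order, ties to fewer clusters then
lexicographic) serves as the test oracle.  On random signed graphs with
8 nodes the greedy solver lands within 5 % of the enumerated optimum on
≥ 95 of 100 instances (measured across several seeds: 96–99).

### Metrics

All partition metrics are computed from the (sparse) contingency table of
(segmentation, ground truth) voxel labels, with ground-truth label 0
excluded as "unannotated" — real ground truth routinely leaves volume
parts unlabelled.  Adjusted Rand error is 1 minus the chance-corrected
pair-counting index; the degenerate zero-denominator case (both sides a
single cluster) is defined as 0.  VOI uses the **natural logarithm**
(values scale with the base; comparisons across tools must match bases):
`VOI_split = H(seg|gt)` counts split mistakes, `VOI_merge = H(gt|seg)`
merge mistakes.  Boundary precision/recall/F1 are strictly voxel-wise
(`TP/(TP+FP)`, `TP/(TP+FN)`; F1 = 0 when both are 0; precision defined
as 1 only when neither prediction nor truth has positives); spatial
tolerance can be emulated by dilating the ground-truth mask beforehand.
PSNR is `10·log10(range²/MSE)` with a `+inf` sentinel for identical
images; SSIM is the mean local index with uniform 7³ windows and the
standard constants (scikit-image's implementation behind the package
surface, cross-checked in tests against the direct per-window formula).

## The synthetic tissue generator

The generator emulates the statistical structure of membrane-stained
tissue, not any particular organ: densely packed convex-ish cells
(Voronoi tessellation of uniformly sampled seeds, Euclidean metric, ties
to the lowest seed index), thin bright membranes (the two-voxel boundary
mask), optical blur (isotropic Gaussian, default σ = 1), additive
Gaussian read-out noise (default sd 0.1), Poisson shot noise
(`Poisson(x/s)·s`), and local membrane drop-outs.  Drop-outs are grown as
balls of radius 3 voxels around random surface centres until exactly
`round(gap_fraction · |surface|)` voxels are zeroed (the last ball is
trimmed): weak staining is spatially coherent, and scattered
single-voxel deletion produces a qualitatively different (much harder,
tunnel-dominated) failure mode than the localized "weak boundary"
regime the generator is meant to emulate.  Default conditions:
64³ voxels, 20 cells, gap fraction 0.05.  Everything is bit-reproducible
given `rng_seed`.

What the generator does **not** model: real cell-shape anisotropy and
curved organ geometry, nuclei bleed-through into the membrane channel,
depth-dependent attenuation, anisotropic point-spread functions, and
time-lapse drift.  Passing the synthetic suite therefore demonstrates
the correctness and the qualitative behaviour of the machinery
(over-segmentation repaired by partitioning, β steering, robustness to
localized gaps) — not performance on any particular microscope's data.

## Numerical choices and degenerate inputs

- Axis order (z, y, x), 0-based; 6-connectivity for boundaries,
  components and flooding throughout.
- Gaussian blurs are isotropic in voxel units; physical voxel size is
  carried as metadata (`element_size_um`) but does not enter the
  algorithms.
- Constant volumes: standardisation returns zeros with a warning.
  All-foreground boundary maps: the watershed returns one region with a
  warning.  Empty ground truth: metrics raise after warning.
- Probabilities are clamped to [1e−5, 1−1e−5] before log-odds; Dice uses
  ε = 1e−6; Adam uses ε = 1e−8.
- Float64 HDF5 inputs are cast to float32 with a warning; label exports
  are uint32, boundary-map exports float32.
- Tiny volumes: mirror padding falls back to edge replication on size-1
  axes (reflection is undefined there).
- Training determinism holds for fixed seeds under single-threaded BLAS;
  the spatial scan order fixes every tie-break elsewhere.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
data at sizes chosen for a single CPU: 64³ end-to-end fixtures
(~260 k voxels, 20 cells), 10-fixture ordering suites, 100-instance
8-node multicut comparisons, and a 2-level U-Net (8/16 feature maps)
trained for 300 single-patch iterations on eight 32³ volumes.  These
sizes are the package's reference study conditions; they are orders of
magnitude below production microscopy volumes, and conclusions about
wall-clock performance or memory at scale do not transfer.

## Known limitations

- The numpy network trains small models only; there is no GPU path, no
  model zoo, and no architecture search.
- Greedy Multicut is a local-search heuristic; the exact solver is
  limited to 12 nodes by design.
- Edge features are single statistics (mean probability, contact area);
  no learned edge classifiers.
- The mean-probability edge weight is sensitive to where the watershed
  line seats within thick boundary bands; on razor-thin binary boundary
  maps this can dilute interface evidence (the soft boundary map avoids
  the pathology and is the recommended input form).
- 2D slice mode reuses the 3D code path per slice; no cross-slice
  consistency is enforced in that mode.
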