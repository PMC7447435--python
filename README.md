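# tissueseg

Volumetric instance segmentation of densely packed cells in
membrane-stained microscopy, for quantitative morphogenesis studies
(cell counting, volume measurement, shape analysis) in plant and animal
tissues.

Intensity-based methods fail on this data because cells carry no interior
signal — only their shared walls are stained.  `tissueseg` therefore
segments in two steps:

1. **Boundary detection.**  A 3D (or 2D) U-Net / Residual U-Net predicts a
   per-voxel probability `p ∈ [0,1]` that the voxel lies on a cell–cell
   interface.  Training targets are built from ground-truth labels `S` as
   `I = [Φ(S) ∗ G_σ > 0.5]`, where `Φ` marks the two-voxel-thick
   inter-label boundary and `G_σ` is an isotropic Gaussian (σ = 1).  The
   loss is `α·L_BCE + β·L_Dice` (α = β = 1), optimised with Adam
   (lr 2·10⁻⁴, L2 penalty 10⁻⁵); inference mirror-pads the volume and
   averages overlapping tiles (50 % overlap).
2. **Graph partitioning.**  A distance-transform watershed (threshold
   δ = 0.4, seed smoothing σ = 2, regions < 50 voxels removed) turns the
   boundary map into supervoxels.  On the supervoxel region adjacency
   graph, each edge gets the mean boundary probability `p_e` over its
   interface and the signed weight

   `w_e = log((1 − p_e)/p_e) + log((1 − β)/β)`,  β = 0.6,

   positive weights attractive, negative repulsive.  The graph is
   partitioned by **GASP** (average-linkage agglomeration), the **Mutex
   watershed**, or **Multicut** (greedy contraction + Kernighan–Lin-style
   refinement, with an exact enumeration solver as small-instance oracle),
   and the partition is projected back to a label volume.

Evaluation metrics used throughout: adjusted Rand error
(`1 − AdjRand`), variation of information split/merge halves
(`VOI_split = H(seg|gt)`, `VOI_merge = H(gt|seg)`, natural log), boundary
precision/recall/F1 curves, PSNR and SSIM.

A synthetic tissue generator (Voronoi cells, thin bright membranes, blur,
Gaussian/Poisson noise, localized membrane drop-outs) makes every stage
testable without microscopy data.

## Worked example

Segment a synthetic 64³ volume of 20 cells whose boundary map has been
degraded with membrane drop-outs (5 % of the surface) and Gaussian noise
(sd 0.1):

```python
from tissueseg.synthetic import (TissueSimConfig, generate_voronoi_labels,
                                 soft_boundary_map, corrupt_boundary_map)
from tissueseg.watershed import dt_watershed, WatershedParams
from tissueseg.graph import PartitionParams, partition_volume
from tissueseg.metrics import arand_error, voi

cfg = TissueSimConfig(shape=(64, 64, 64), n_cells=20, membrane_sigma=0.0,
                      noise_gaussian_sd=0.1, gap_fraction=0.05, rng_seed=0)
labels = generate_voronoi_labels(cfg)
bmap = corrupt_boundary_map(soft_boundary_map(labels, sigma=1.0), cfg)

supervoxels = dt_watershed(bmap, WatershedParams())
for algo in ("gasp", "mutex", "multicut"):
    seg, rag = partition_volume(supervoxels, bmap, PartitionParams(algo, beta_bias=0.6))
    ar = arand_error(seg, labels); vs, vm = voi(seg, labels)
    print(f"{algo:9s} cells={seg.max():3d}  ARand={ar:.3f}  "
          f"VOI_split={vs:.3f}  VOI_merge={vm:.3f}")
```

Output:

```
gasp      cells= 21  ARand=0.076  VOI_split=0.196  VOI_merge=0.200
mutex     cells= 19  ARand=0.059  VOI_split=0.154  VOI_merge=0.200
multicut  cells= 19  ARand=0.059  VOI_split=0.154  VOI_merge=0.200
```

The watershed produced 34 supervoxels; all three partitioners recover the
20 cells to within one or two merge/split mistakes (ARand 0 would be a
perfect match; the residual VOI is dominated by voxels inside the thick
boundary band, whose assignment is geometrically ambiguous).

The same run from the shell:

```bash
tissueseg synth --shape 64 64 64 --n-cells 20 --seed 0 --out volume.h5
tissueseg segment --input volume.h5 --dataset boundary --algorithm gasp --out seg.h5
tissueseg evaluate --seg seg.h5 --gt volume.h5
```

`tissueseg run --config pipeline.yaml` chains preprocessing → CNN
prediction (or `checkpoint: skip` for precomputed boundary maps) →
watershed → partitioning → HDF5/TIFF export, and writes a JSON run log;
`tissueseg train` / `tissueseg predict` drive the network.

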