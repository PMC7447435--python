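"""Synthetic tissue phantoms for developing and testing the segmentation pipeline.

Densely packed plant tissue is emulated by a Voronoi tessellation of the
volume: cells are convex-ish, space-filling regions around randomly placed
seed points, separated by thin, bright membranes.  On top of the clean
geometry the simulators add the degradations that make real membrane-stained
microscopy hard to segment: optical blur, additive Gaussian read-out noise,
Poisson shot noise, and local membrane signal drop-outs ("weak boundaries",
the dominant failure mode of boundary-based segmentation).

Axis order is ``(z, y, x)`` throughout; volumes are plain numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import find_boundaries

__all__ = [
    "TissueSimConfig",
    "generate_voronoi_labels",
    "labels_to_boundary_target",
    "soft_boundary_map",
    "simulate_membrane_image",
    "corrupt_boundary_map",
]


@dataclass(frozen=True)
class TissueSimConfig:
    """Parameters of the synthetic tissue simulator.

    Parameters
    ----------
    shape:
        Volume shape ``(z, y, x)``, all entries positive.
    n_cells:
        Number of Voronoi cells; must not exceed the voxel count.
    membrane_sigma:
        Gaussian blur (in voxels) applied to the membrane signal,
        emulating the microscope point-spread function.
    noise_gaussian_sd:
        Standard deviation of additive Gaussian noise.
    noise_poisson_scale:
        Strength of signal-dependent Poisson (shot) noise; 0 disables it.
        The image is drawn as ``Poisson(x / s) * s`` with ``s`` the scale,
        so larger values give noisier images.
    gap_fraction:
        Fraction of membrane-surface voxels zeroed *before* blurring, to
        simulate locally missing/weak boundary signal.
    gap_radius:
        Radius (voxels) of the localized drop-out patches the gap budget is
        spent on; weak staining is spatially coherent, not salt-and-pepper.
    rng_seed:
        Seed for all randomness; runs are bit-reproducible given the seed.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_cells: int = 20
    membrane_sigma: float = 1.0
    noise_gaussian_sd: float = 0.1
    noise_poisson_scale: float = 0.0
    gap_fraction: float = 0.05
    gap_radius: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (2, 3) or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 2 or 3 positive integers, got {shape}")
        if not 1 <= self.n_cells <= int(np.prod(shape)):
            raise ValueError(
                f"n_cells must be in [1, prod(shape)={int(np.prod(shape))}], got {self.n_cells}"
            )
        if self.membrane_sigma < 0:
            raise ValueError("membrane_sigma must be >= 0")
        if self.noise_gaussian_sd < 0 or self.noise_poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap_fraction must be in [0, 1]")
        if self.gap_radius <= 0:
            raise ValueError("gap_radius must be positive")


def generate_voronoi_labels(config: TissueSimConfig) -> np.ndarray:
    """Ground-truth label volume: the Voronoi tessellation of random seeds.

    Each voxel is assigned to the nearest of ``n_cells`` seed points sampled
    uniformly (without replacement) from the voxel grid; Euclidean distance
    in voxel units, ties broken by lowest seed index.  Labels are 1..n_cells.
    """
    shape = config.shape
    rng = np.random.default_rng(config.rng_seed)
    n_vox = int(np.prod(shape))
    flat = rng.choice(n_vox, size=config.n_cells, replace=False)
    seeds = np.stack(np.unravel_index(flat, shape), axis=1).astype(np.float64)

    coords = np.indices(shape, dtype=np.float64).reshape(len(shape), -1).T
    # chunked distance computation keeps memory at ~n_chunk * n_cells floats
    labels = np.empty(n_vox, dtype=np.uint32)
    chunk = max(1, 2**22 // max(config.n_cells, 1))
    for start in range(0, n_vox, chunk):
        block = coords[start : start + chunk]
        d2 = ((block[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels[start : start + chunk] = np.argmin(d2, axis=1) + 1
    return labels.reshape(shape)


def _thick_boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Two-voxel-thick inter-label boundary: both voxels flanking each
    face where the label changes (6-connectivity in 3D)."""
    return find_boundaries(labels, connectivity=1, mode="thick", background=-1)


def labels_to_boundary_target(labels: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Binary boundary training target from a ground-truth label volume.

    Marks the two-voxel-thick boundary between labelled regions, convolves
    with an isotropic Gaussian of width ``sigma`` and re-binarises at 0.5.
    The blur thickens the boundary band, increasing foreground signal, while
    the threshold keeps the target binary.  ``sigma=0`` returns the raw mask.

    Returns a float32 array with values in {0, 1}.
    """
    labels = np.asarray(labels)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if labels.size == 0 or not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be a non-empty integer array")
    if labels.max() <= 0:
        raise ValueError("label volume contains no positive labels")
    mask = _thick_boundary_mask(labels).astype(np.float32)
    if sigma > 0:
        mask = (ndi.gaussian_filter(mask, sigma) > 0.5).astype(np.float32)
    return mask


def soft_boundary_map(labels: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Soft boundary-probability map: the pre-threshold form of the binary
    target (``Φ(S) ∗ G_σ`` without the 0.5 cut), clipped to [0, 1].

    This is the realistic stand-in for a trained network's output — graded
    probabilities, highest at membrane centres — and is what the
    end-to-end fixtures feed to the watershed/partitioning stages.  The
    hard threshold of the binary form erases obliquely oriented membranes
    (the blurred staircase mask stays below 0.5), which no downstream
    method could recover.
    """
    labels = np.asarray(labels)
    if labels.max() <= 0:
        raise ValueError("label volume contains no positive labels")
    mask = _thick_boundary_mask(labels).astype(np.float32)
    if sigma > 0:
        mask = ndi.gaussian_filter(mask, sigma)
    return np.clip(mask, 0.0, 1.0)


def _apply_gaps(
    signal: np.ndarray,
    surface: np.ndarray,
    gap_fraction: float,
    rng: np.random.Generator,
    gap_radius: float = 3.0,
) -> np.ndarray:
    """Zero ``round(gap_fraction * |surface|)`` surface voxels as localized
    drop-outs.

    Membrane signal loss is spatially coherent (a stretch of weak staining,
    not salt-and-pepper), so gaps are grown as balls of ``gap_radius``
    voxels around randomly drawn surface centres until the requested voxel
    quota is met exactly (the last ball is trimmed, nearest voxels first).
    """
    if gap_fraction <= 0:
        return signal
    coords = np.argwhere(surface)
    n_surface = coords.shape[0]
    quota = int(round(gap_fraction * n_surface))
    if quota == 0:
        return signal
    out = signal.copy()
    alive = np.ones(n_surface, dtype=bool)
    killed = 0
    while killed < quota and alive.any():
        centre = coords[rng.choice(np.flatnonzero(alive))]
        d2 = ((coords - centre) ** 2).sum(axis=1)
        ball = np.flatnonzero(alive & (d2 <= gap_radius**2))
        take = ball[np.argsort(d2[ball], kind="stable")][: quota - killed]
        alive[take] = False
        killed += take.size
        out[tuple(coords[take].T)] = 0.0
    return out


def _apply_noise(image: np.ndarray, config: TissueSimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_poisson_scale > 0:
        s = config.noise_poisson_scale
        image = rng.poisson(np.clip(image, 0, None) / s).astype(np.float32) * s
    if config.noise_gaussian_sd > 0:
        image = image + rng.normal(0.0, config.noise_gaussian_sd, image.shape).astype(np.float32)
    return image


def simulate_membrane_image(labels: np.ndarray, config: TissueSimConfig) -> np.ndarray:
    """Raw-like intensity volume: bright membranes, dark cell interiors.

    The inter-label boundary mask is taken as the membrane signal (value 1
    on membranes, 0 inside cells).  A ``gap_fraction`` of membrane voxels is
    zeroed before blurring (signal drop-outs), the signal is blurred with
    ``membrane_sigma``, then Poisson and Gaussian noise are added and the
    result is clipped to ``[0, max]``.  Deterministic given ``rng_seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(config.rng_seed)
    membrane = _thick_boundary_mask(labels).astype(np.float32)
    signal = _apply_gaps(membrane, membrane > 0, config.gap_fraction, rng, config.gap_radius)
    if config.membrane_sigma > 0:
        signal = ndi.gaussian_filter(signal, config.membrane_sigma)
    image = _apply_noise(signal, config, rng)
    return np.clip(image, 0.0, max(1.0, float(image.max()))).astype(np.float32)


def corrupt_boundary_map(bmap: np.ndarray, config: TissueSimConfig) -> np.ndarray:
    """Degrade a boundary-probability map the way an imperfect CNN would.

    Applies the same corruption chain as :func:`simulate_membrane_image` —
    gap deletion (on voxels with probability > 0.5), Gaussian blur and noise
    — directly to a probability map, then clips to [0, 1].  Useful for
    testing the partitioning stages against boundary discontinuities
    without training a network.
    """
    bmap = np.asarray(bmap, dtype=np.float32)
    if bmap.min() < 0 or bmap.max() > 1:
        raise ValueError("boundary map values must lie in [0, 1]")
    rng = np.random.default_rng(config.rng_seed)
    out = _apply_gaps(bmap, bmap > 0.5, config.gap_fraction, rng, config.gap_radius)
    if config.membrane_sigma > 0:
        out = ndi.gaussian_filter(out, config.membrane_sigma)
    out = _apply_noise(out, config, rng)
    return np.clip(out, 0.0, 1.0).astype(np.float32)
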