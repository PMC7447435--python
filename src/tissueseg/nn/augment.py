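"""Training-time data augmentation.

Geometric transforms (flips, 90° rotations in the XY-plane, elastic
deformations) are applied identically to the image patch and its boundary
target so voxel-wise correspondence is preserved; intensity noise
(additive Gaussian, additive Poisson) perturbs the image only.  All
randomness comes from the caller's generator, so augmented training runs
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["AugmentConfig", "apply_augmentations"]


@dataclass(frozen=True)
class AugmentConfig:
    """Switches and strengths for the augmentation chain.

    Flips act on the in-plane (y, x) axes; rotations are multiples of 90°
    in the XY-plane.  Elastic deformation displaces a coarse control grid
    by Gaussian offsets (``elastic_sigma`` voxels) spline-interpolated to
    the full grid; the image is resampled linearly, the target with
    nearest-neighbour so it stays binary.
    """

    flips: bool = True
    rotations: bool = True
    elastic: bool = False
    elastic_sigma: float = 2.0
    elastic_grid: int = 4
    noise_gaussian_sd: float = 0.0
    noise_poisson_scale: float = 0.0


def _elastic_fields(shape, cfg: AugmentConfig, rng: np.random.Generator):
    coarse = rng.normal(0.0, cfg.elastic_sigma, size=(len(shape), *([cfg.elastic_grid] * len(shape))))
    fields = []
    for d in range(len(shape)):
        zoom = [s / cfg.elastic_grid for s in shape]
        fields.append(ndi.zoom(coarse[d], zoom, order=3))
    return fields


def apply_augmentations(
    patch: np.ndarray,
    target: np.ndarray,
    cfg: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return an augmented ``(patch, target)`` pair.

    Works for 3D ``(z, y, x)`` and 2D ``(y, x)`` patches; the last two axes
    are the rotation/flip plane.
    """
    cfg = cfg or AugmentConfig()
    rng = rng or np.random.default_rng()
    if patch.shape != target.shape:
        raise ValueError("patch and target shapes differ")
    patch = np.asarray(patch, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    y_axis, x_axis = patch.ndim - 2, patch.ndim - 1

    if cfg.flips:
        for axis in (y_axis, x_axis):
            if rng.random() < 0.5:
                patch = np.flip(patch, axis=axis)
                target = np.flip(target, axis=axis)
    if cfg.rotations:
        k = int(rng.integers(0, 4))
        if k:
            patch = np.rot90(patch, k, axes=(y_axis, x_axis))
            target = np.rot90(target, k, axes=(y_axis, x_axis))
    if cfg.elastic:
        fields = _elastic_fields(patch.shape, cfg, rng)
        coords = np.indices(patch.shape, dtype=np.float64)
        warped = [c + f for c, f in zip(coords, fields)]
        patch = ndi.map_coordinates(patch, warped, order=1, mode="reflect").astype(np.float32)
        target = ndi.map_coordinates(target, warped, order=0, mode="reflect").astype(np.float32)
    if cfg.noise_poisson_scale > 0:
        s = cfg.noise_poisson_scale
        patch = (rng.poisson(np.clip(patch, 0, None) / s) * s).astype(np.float32)
    if cfg.noise_gaussian_sd > 0:
        patch = patch + rng.normal(0, cfg.noise_gaussian_sd, patch.shape).astype(np.float32)
    return np.ascontiguousarray(patch), np.ascontiguousarray(target)
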