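"""Tiled inference: boundary prediction for volumes of arbitrary size.

Volumes are mirror-padded (reflection without repeating the border voxel)
so predictions near the volume border see plausible context, parsed
patch-by-patch with 50% overlap between consecutive tiles, and the
per-voxel probabilities of all covering tiles are arithmetically
averaged.  Overlap-averaging suppresses checkerboard artifacts at tile
seams.  Output shape equals input shape, values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .unet import UNet

__all__ = ["InferenceConfig", "predict_tiled", "standardize"]


@dataclass(frozen=True)
class InferenceConfig:
    """Tiling parameters: patch shape, fractional tile overlap in [0, 1)
    (0.5 default), mirror padding."""

    patch_shape: tuple[int, ...] = (32, 64, 64)
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "patch_shape", tuple(int(p) for p in self.patch_shape))
        if any(p < 1 for p in self.patch_shape):
            raise ValueError("patch_shape entries must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")


def standardize(volume: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance standardisation over all voxels.

    A constant volume has no scale: it is shifted to zero with a warning
    (the division is guarded).
    """
    import warnings

    volume = np.asarray(volume, dtype=np.float32)
    mean = float(volume.mean())
    sd = float(volume.std())
    if sd < 1e-12:
        warnings.warn("constant volume: standardization returns zeros")
        return volume - mean
    return (volume - mean) / sd


def _mirror_pad(volume: np.ndarray, pad: list[tuple[int, int]]) -> np.ndarray:
    # reflect can't pad more than size-1 at once; iterate for tiny volumes
    out = volume
    pad = [list(p) for p in pad]
    while any(lo > 0 or hi > 0 for lo, hi in pad):
        step = []
        edge_step = []
        for ax, (lo, hi) in enumerate(pad):
            m = out.shape[ax] - 1
            if m == 0:  # size-1 axis: reflection undefined, repeat the slice
                step.append((0, 0))
                edge_step.append((lo, hi))
                pad[ax][0] = pad[ax][1] = 0
            else:
                lo_now, hi_now = min(lo, m), min(hi, m)
                step.append((lo_now, hi_now))
                edge_step.append((0, 0))
                pad[ax][0] -= lo_now
                pad[ax][1] -= hi_now
        if any(s != (0, 0) for s in edge_step):
            out = np.pad(out, edge_step, mode="edge")
        if any(s != (0, 0) for s in step):
            out = np.pad(out, step, mode="reflect")
    return out


def predict_tiled(
    model: UNet, volume: np.ndarray, cfg: InferenceConfig | None = None
) -> np.ndarray:
    """Boundary-probability map for ``volume`` via overlapping-tile inference.

    Every output voxel is the unweighted mean of all tile predictions
    covering it.  The patch shape is clipped to the (padded) volume and
    rounded up to the network's divisibility requirement, so volumes
    smaller than one patch reduce to a single mirrored-pad forward pass.
    """
    cfg = cfg or InferenceConfig()
    volume = np.asarray(volume, dtype=np.float32)
    nd = model.config.dims
    if volume.ndim != nd:
        raise ValueError(f"expected a {nd}D volume, got shape {volume.shape}")
    if len(cfg.patch_shape) != nd:
        raise ValueError("patch_shape dimensionality does not match the network")
    div = model.config.divisor

    def round_up(n: int) -> int:
        return ((n + div - 1) // div) * div

    patch = tuple(min(round_up(p), round_up(s)) for p, s in zip(cfg.patch_shape, volume.shape))
    # pad the volume so every axis fits an integer patch grid
    padded_shape = tuple(max(round_up(s), p) for s, p in zip(volume.shape, patch))
    pad = [(0, ps - s) for s, ps in zip(volume.shape, padded_shape)]
    padded = _mirror_pad(volume, pad)

    stride = tuple(max(1, int(round(p * (1 - cfg.overlap_fraction)))) for p in patch)
    starts_per_axis = []
    for s, p, st in zip(padded.shape, patch, stride):
        starts = list(range(0, s - p + 1, st))
        if starts[-1] != s - p:
            starts.append(s - p)
        starts_per_axis.append(starts)

    prob_sum = np.zeros(padded.shape, dtype=np.float64)
    count = np.zeros(padded.shape, dtype=np.float64)
    grids = np.meshgrid(*starts_per_axis, indexing="ij")
    for origin in zip(*(g.ravel() for g in grids)):
        sl = tuple(slice(o, o + p) for o, p in zip(origin, patch))
        tile = padded[sl][None, None]
        prob = model.predict(tile)[0, 0]
        prob_sum[sl] += prob
        count[sl] += 1.0
    out = prob_sum / count
    crop = tuple(slice(0, s) for s in volume.shape)
    return np.clip(out[crop], 0.0, 1.0).astype(np.float32)
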