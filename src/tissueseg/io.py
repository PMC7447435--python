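"""Reading, writing and resampling of volumetric images.

Volumes travel as HDF5 datasets (conventional keys: ``raw`` for intensity
input, ``predictions`` for boundary-probability maps, ``segmentation`` /
``label`` for label volumes) or multi-page TIFF stacks read as z-stacks.
Physical voxel spacing, when known, is stored on the HDF5 dataset as the
``element_size_um`` attribute (z, y, x order).  Exported segmentations are
dense-labelled uint32; exported boundary maps float32 in [0, 1].
"""

from __future__ import annotations

import warnings
from pathlib import Path

import h5py
import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = ["read_volume", "write_volume", "rescale_volume", "rescale_to_shape", "VOXEL_SIZE_ATTR"]

VOXEL_SIZE_ATTR = "element_size_um"

_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf", ".h5py"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _check_dtype(data: np.ndarray, path) -> np.ndarray:
    if data.dtype == np.float64:
        warnings.warn(f"{path}: float64 volume cast to float32")
        return data.astype(np.float32)
    if data.dtype in (np.float32, np.uint8, np.uint16, np.uint32, np.int8, np.int16,
                      np.int32, np.int64, np.uint64):
        return data
    if data.dtype == np.float16:
        return data.astype(np.float32)
    raise ValueError(f"{path}: unsupported dtype {data.dtype}")


def read_volume(path, dataset_name: str = "raw") -> tuple[np.ndarray, np.ndarray | None]:
    """Load ``(array, voxel_size)`` from HDF5 or TIFF.

    ``voxel_size`` is a per-axis spacing in µm when recorded, else None.
    2D images come back as 2D arrays; multi-page TIFFs as (z, y, x) stacks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as f:
            if dataset_name not in f:
                raise KeyError(
                    f"dataset {dataset_name!r} not found in {path}; "
                    f"available: {sorted(f.keys())}"
                )
            ds = f[dataset_name]
            data = ds[()]
            voxel_size = np.asarray(ds.attrs[VOXEL_SIZE_ATTR]) if VOXEL_SIZE_ATTR in ds.attrs else None
        return _check_dtype(data, path), voxel_size
    if suffix in _TIFF_SUFFIXES:
        data = tifffile.imread(path)
        return _check_dtype(np.asarray(data), path), None
    raise ValueError(f"unsupported file format {suffix!r} (use HDF5 or TIFF)")


def write_volume(
    data: np.ndarray,
    path,
    dataset_name: str = "raw",
    voxel_size=None,
) -> None:
    """Write a volume to HDF5 (named dataset) or TIFF (multi-page).

    Integer label volumes are stored as uint32, floating-point maps as
    float32.
    """
    path = Path(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    elif np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.uint32)
    suffix = path.suffix.lower()
    if suffix in _HDF5_SUFFIXES:
        with h5py.File(path, "a") as f:
            if dataset_name in f:
                del f[dataset_name]
            ds = f.create_dataset(dataset_name, data=data, compression="gzip")
            if voxel_size is not None:
                ds.attrs[VOXEL_SIZE_ATTR] = np.asarray(voxel_size, dtype=np.float64)
    elif suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, data)
    else:
        raise ValueError(f"unsupported file format {suffix!r} (use HDF5 or TIFF)")


def rescale_volume(
    volume: np.ndarray, factors, order: int = 1, is_labels: bool = False
) -> np.ndarray:
    """Resample a volume by per-axis zoom ``factors`` (spline of the given
    order; label volumes always use order 0 so no fractional labels are
    interpolated into existence).  Output shape is ``round(shape × factor)``.
    """
    factors = tuple(float(f) for f in np.atleast_1d(factors))
    if len(factors) == 1:
        factors = factors * volume.ndim
    if len(factors) != volume.ndim:
        raise ValueError("one rescale factor per axis required")
    if any(f <= 0 for f in factors):
        raise ValueError("rescale factors must be positive")
    target = tuple(int(round(s * f)) for s, f in zip(volume.shape, factors))
    if any(t == 0 for t in target):
        raise ValueError(f"rescale factors {factors} collapse shape {volume.shape} to {target}")
    if target == volume.shape:
        return volume.copy()
    if is_labels:
        order = 0
    exact = tuple(t / s for t, s in zip(target, volume.shape))
    out = ndi.zoom(volume, exact, order=order, grid_mode=True, mode="nearest")
    assert out.shape == target
    return out


def rescale_to_shape(volume: np.ndarray, shape, order: int = 0) -> np.ndarray:
    """Resample to an exact target shape (used to undo preprocessing)."""
    factors = tuple(t / s for t, s in zip(shape, volume.shape))
    out = ndi.zoom(volume, factors, order=order, grid_mode=True, mode="nearest")
    assert out.shape == tuple(shape)
    return out
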