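"""Geometric and intensity harmonization of CT volumes.

All downstream stages (superpixel clustering and texture extraction) consume
volumes that have been brought onto a common 1 mm isotropic grid.  Two
intensity paths then diverge:

* clustering path: clip to the lung window (-1250..250 HU) and z-normalize
  within the lesion mask;
* texture path: discretize the masked intensities into a fixed number of
  equal-width gray-level bins (default 25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class CTVolume:
    """A 3D CT volume in Hounsfield units.

    Parameters
    ----------
    data : (nx, ny, nz) float array of HU values.
    spacing : voxel spacing in mm per axis.
    origin : world coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("CTVolume.data must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CTVolume.data contains non-finite values")


@dataclass
class PreprocSpec:
    """Preprocessing parameters.

    ``window`` is the lung display window (level -500 HU, width 1500 HU);
    ``n_bins`` is the fixed gray-level bin count used for texture matrices.
    """

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    window: tuple[float, float] = (-1250.0, 250.0)
    n_bins: int = 25

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window low must be < high")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def resample_isotropic(
    vol: CTVolume,
    spec: PreprocSpec | None = None,
    *,
    is_mask: bool = False,
) -> CTVolume:
    """Resample a volume to the target spacing.

    Intensity volumes use trilinear interpolation; label/mask volumes use
    nearest-neighbour so values stay in the original label set.
    """
    spec = spec or PreprocSpec()
    target = np.asarray(spec.target_spacing, dtype=float)
    if np.any(target <= 0):
        raise ValueError(f"non-positive target spacing {tuple(target)}")
    src = np.asarray(vol.spacing, dtype=float)
    zoom = src / target
    if np.allclose(zoom, 1.0):
        return CTVolume(vol.data.copy(), tuple(target), vol.origin)
    order = 0 if is_mask else 1
    out = ndimage.zoom(vol.data, zoom, order=order, mode="nearest", grid_mode=True)
    return CTVolume(out, tuple(target), vol.origin)


def clip_window(vol: CTVolume, spec: PreprocSpec | None = None) -> CTVolume:
    """Clip intensities to the lung window range."""
    spec = spec or PreprocSpec()
    lo, hi = spec.window
    return CTVolume(np.clip(vol.data, lo, hi), vol.spacing, vol.origin)


def znormalize(vol: CTVolume, mask: np.ndarray) -> CTVolume:
    """Standardize masked intensities to mean 0, variance 1 (population ÷n).

    The transform is applied to the whole array (so out-of-mask voxels move
    consistently) but its statistics come from the lesion mask only.

    Raises
    ------
    ValueError
        If the masked region has fewer than 2 voxels or zero variance
        (a degenerate, constant lesion).
    """
    mask = np.asarray(mask, dtype=bool)
    vals = vol.data[mask]
    if vals.size < 2:
        raise ValueError("mask must contain at least 2 voxels")
    mu = vals.mean()
    sd = vals.std()  # population convention (ddof=0)
    if sd == 0:
        raise ValueError("degenerate lesion: zero intensity variance inside mask")
    return CTVolume((vol.data - mu) / sd, vol.spacing, vol.origin)


def discretize_fixed_bins(
    vol: CTVolume | np.ndarray, mask: np.ndarray, n_bins: int = 25
) -> np.ndarray:
    """Discretize masked intensities into ``n_bins`` equal-width gray levels.

    Bins are half-open over [min, max) of the masked values, with the top
    edge closed so the maximum lands in bin ``n_bins``.  Returns an integer
    volume with levels 1..n_bins inside the mask and 0 outside.  A constant
    lesion occupies the single level 1.
    """
    data = vol.data if isinstance(vol, CTVolume) else np.asarray(vol, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = data[mask]
    lo, hi = vals.min(), vals.max()
    out = np.zeros(data.shape, dtype=np.int64)
    if hi == lo:
        out[mask] = 1
        return out
    width = (hi - lo) / n_bins
    levels = np.floor((vals - lo) / width).astype(np.int64) + 1
    np.clip(levels, 1, n_bins, out=levels)
    out[mask] = levels
    return out
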