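"""Reliable-voxel selection from ghost-free background noise.

Four square background ROIs (default width 5 voxels) are placed in the
in-plane corners of the difference-image timeseries, replicated on every
slice, and pooled across slices and timepoints. A voxel is kept when its
difference signal exceeds mean + 1 SD of that background on at least one
image in the series. Ghosting is an in-plane EPI phenomenon, hence the
corner placement; excluded voxels are labelled "unclassified" downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, GridMismatchError

__all__ = ["BackgroundNoise", "corner_roi_mask", "estimate_background",
           "reliable_voxel_mask"]


@dataclass(frozen=True)
class BackgroundNoise:
    """Pooled noise statistics of the four corner background ROIs."""

    roi_width: int
    n_rois: int
    mean: float
    sd: float
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("sd must be non-negative")


def corner_roi_mask(shape: tuple[int, int, int], roi_width: int = 5) -> np.ndarray:
    """Boolean volume marking the four in-plane corner squares on every slice."""
    nx, ny = shape[0], shape[1]
    if nx < 2 * roi_width or ny < 2 * roi_width:
        raise ConfigurationError(
            f"in-plane dimensions {nx}x{ny} cannot hold four non-overlapping "
            f"{roi_width}-voxel corner ROIs")
    mask = np.zeros(shape, dtype=bool)
    w = roi_width
    for sx in (slice(0, w), slice(nx - w, nx)):
        for sy in (slice(0, w), slice(ny - w, ny)):
            mask[sx, sy, :] = True
    return mask


def estimate_background(diff_series: np.ndarray, roi_width: int = 5) -> BackgroundNoise:
    """Mean/SD of the corner background, pooled over ROIs, slices and timepoints.

    ``diff_series`` is a 4D array (x, y, z, t); a 3D volume is treated as a
    single-timepoint series. SD is the sample standard deviation (ddof=1).
    """
    series = np.asarray(diff_series, dtype=float)
    if series.ndim == 3:
        series = series[..., np.newaxis]
    if series.ndim != 4 or series.shape[3] < 1:
        raise ConfigurationError("diff_series must be 3D or 4D with >= 1 volume")
    mask = corner_roi_mask(series.shape[:3], roi_width)
    samples = series[mask, :].ravel()
    sd = float(np.std(samples, ddof=1)) if samples.size > 1 else 0.0
    return BackgroundNoise(roi_width=roi_width, n_rois=4,
                           mean=float(np.mean(samples)), sd=sd,
                           grid_shape=series.shape[:3])


def reliable_voxel_mask(diff_series: np.ndarray, noise: BackgroundNoise) -> np.ndarray:
    """uint8 volume: 1 where max-over-time difference signal > mean + 1·SD."""
    series = np.asarray(diff_series, dtype=float)
    if series.ndim == 3:
        series = series[..., np.newaxis]
    if series.shape[:3] != tuple(noise.grid_shape):
        raise GridMismatchError(
            f"series grid {series.shape[:3]} != noise grid {tuple(noise.grid_shape)}")
    threshold = noise.mean + noise.sd
    return (series.max(axis=3) > threshold).astype(np.uint8)
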