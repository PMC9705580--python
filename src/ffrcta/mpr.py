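"""Straightened MPR reconstruction along artery centerlines.

Each cross-section is a 127 x 127 grid with 0.1 mm in-plane pixel size,
perpendicular to the local centerline tangent, sampled from the CT volume
by trilinear interpolation; slices are 0.5 mm apart along the centerline.
Intensities are then z-normalized with statistics pooled over the training
set (the same statistics are reapplied, unchanged, at test time).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import map_coordinates

from .centerline import ArteryCenterline, rotation_minimizing_frames
from .types import ImageVolume, IntensityStats, MPRVolume

log = logging.getLogger(__name__)

MPR_SIZE = 127
MPR_IN_PLANE_SPACING = 0.1
FILL_HU = -1024.0
MAX_FILL_FRACTION = 0.05


def mpr_sample_points(centerline: ArteryCenterline, size: int = MPR_SIZE,
                      in_plane_spacing: float = MPR_IN_PLANE_SPACING
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Physical sample coordinates of the MPR grid: (S, size, size, 3) mm,
    plus the (S, 3, 3) rotation-minimizing frames used to build them.
    Pixel (size//2, size//2) is the centerline point."""
    frames = rotation_minimizing_frames(centerline.points)
    half = (size - 1) / 2.0
    offsets = (np.arange(size) - half) * in_plane_spacing
    e1 = frames[:, 1, :]
    e2 = frames[:, 2, :]
    grid = (centerline.points[:, None, None, :]
            + offsets[None, :, None, None] * e1[:, None, None, :]
            + offsets[None, None, :, None] * e2[:, None, None, :])
    return grid, frames


def reconstruct_mpr(volume: ImageVolume, centerline: ArteryCenterline,
                    size: int = MPR_SIZE,
                    in_plane_spacing: float = MPR_IN_PLANE_SPACING,
                    max_fill_fraction: float | None = MAX_FILL_FRACTION) -> MPRVolume:
    """Reconstruct the straightened MPR for one artery.

    Samples outside the volume are filled with air (-1024 HU) and counted;
    an artery with more than ``max_fill_fraction`` filled samples is rejected
    (it violates the requirement that the artery lie in the field of view).
    Pass ``max_fill_fraction=None`` to disable the check.
    """
    grid, frames = mpr_sample_points(centerline, size, in_plane_spacing)
    idx = volume.mm_to_index(grid.reshape(-1, 3))
    shape = np.array(volume.data.shape)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    n_filled = int((~inside).sum())
    frac = n_filled / idx.shape[0]
    if n_filled:
        log.warning("MPR sampling: %d/%d samples (%.2f%%) outside the volume, filled with %g HU",
                    n_filled, idx.shape[0], 100 * frac, FILL_HU)
    if max_fill_fraction is not None and frac > max_fill_fraction:
        raise ValueError(f"artery rejected: {100 * frac:.1f}% of MPR samples fall outside "
                         f"the volume (limit {100 * max_fill_fraction:.0f}%)")
    values = map_coordinates(volume.data, idx.T, order=1, mode="constant", cval=FILL_HU)
    data = values.reshape(len(centerline), size, size)
    return MPRVolume(data=data, in_plane_spacing=in_plane_spacing,
                     slice_spacing=centerline.spacing, frames=frames, n_filled=n_filled)


def fit_intensity_stats(mprs: list[MPRVolume]) -> IntensityStats:
    """Pooled mean/sd over all voxels of all training MPRs."""
    if not mprs:
        raise ValueError("at least one training MPR is required")
    n = sum(m.data.size for m in mprs)
    mean = sum(float(m.data.sum()) for m in mprs) / n
    sq = sum(float(((m.data - mean) ** 2).sum()) for m in mprs)
    var = sq / n
    if var <= 0:
        raise ValueError("zero intensity variance in the training MPRs")
    return IntensityStats(mean=mean, sd=float(np.sqrt(var)))


def apply_intensity_norm(mpr: MPRVolume, stats: IntensityStats) -> MPRVolume:
    """(x - mean) / sd with frozen training statistics."""
    return MPRVolume(data=(mpr.data - stats.mean) / stats.sd,
                     in_plane_spacing=mpr.in_plane_spacing,
                     slice_spacing=mpr.slice_spacing,
                     frames=mpr.frames, n_filled=mpr.n_filled)
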