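"""Centerline resampling, rotation-minimizing frames and MPR geometry."""

import numpy as np
import pytest

from ffrcta.centerline import (CenterlineTree, TreeNode, centerline_tangents,
                               resample_centerline, rotation_minimizing_frames)
from ffrcta.mpr import (apply_intensity_norm, fit_intensity_stats, mpr_sample_points,
                        reconstruct_mpr)
from ffrcta.types import ImageVolume, IntensityStats, MPRVolume


def trilinear_oracle(data: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Independent 8-neighbor trilinear interpolation at fractional indices."""
    out = np.empty(idx.shape[0])
    for n, (x, y, z) in enumerate(idx):
        x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
        fx, fy, fz = x - x0, y - y0, z - z0
        acc = 0.0
        for dx, wx in ((0, 1 - fx), (1, fx)):
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dz, wz in ((0, 1 - fz), (1, fz)):
                    acc += wx * wy * wz * data[x0 + dx, y0 + dy, z0 + dz]
        out[n] = acc
    return out


# --- resampling --------------------------------------------------------------


def test_straight_10mm_polyline_gives_21_points():
    raw = np.array([[0, 0, 0], [0, 0, 10.0]])
    cl = resample_centerline(raw)
    assert len(cl) == 21
    np.testing.assert_allclose(np.diff(cl.points[:, 2]), 0.5, atol=1e-12)


def test_resampling_is_idempotent():
    raw = np.column_stack([np.zeros(41), np.zeros(41), np.arange(41) * 0.5])
    cl = resample_centerline(raw)
    np.testing.assert_allclose(cl.points, raw, atol=1e-9)


def test_circular_arc_chord_spacing():
    """Resampled chord spacing along a circular arc is 0.5 mm +- 1e-6.

    Arc-length parameterization of a finely sampled circle of radius 20 mm:
    consecutive resampled points must be 0.5 mm apart along the curve, so
    chords are 2 R sin(l / 2R) ~ 0.4999967 mm analytically."""
    R = 20.0
    theta = np.linspace(0, np.pi / 2, 20001)  # fine enough that chords ~ arcs
    raw = np.column_stack([R * np.cos(theta), R * np.sin(theta), np.zeros_like(theta)])
    cl = resample_centerline(raw)
    chords = np.linalg.norm(np.diff(cl.points, axis=0), axis=1)
    expected = 2 * R * np.sin(0.5 / (2 * R))
    np.testing.assert_allclose(chords, expected, atol=1e-6)


def test_too_short_centerline_rejected():
    with pytest.raises(ValueError, match="1.0 mm"):
        resample_centerline(np.array([[0, 0, 0], [0, 0, 0.8]]))


def test_labels_carried_from_nearest_raw_point():
    raw = np.array([[0, 0, 0], [0, 0, 5.0], [0, 0, 10.0]])
    cl = resample_centerline(raw, labels=["LAD", "LAD", "side-branch"],
                             successor_counts=[1, 2, 0])
    assert cl.labels[0] == "LAD"
    assert cl.labels[-1] == "side-branch"
    assert cl.successor_counts[10] == 2  # midpoint maps to the middle raw point


# --- frames ------------------------------------------------------------------


def _random_smooth_curve(seed=0, n=80):
    rng = np.random.default_rng(seed)
    s = np.arange(n) * 0.5
    x = 2.0 * np.sin(s / 12.0) + rng.normal(0, 0.01)
    y = 1.5 * np.cos(s / 15.0)
    return np.column_stack([x, y, s])


def test_frames_orthonormal():
    frames = rotation_minimizing_frames(_random_smooth_curve())
    for f in frames:
        np.testing.assert_allclose(f @ f.T, np.eye(3), atol=1e-9)


def test_frames_have_no_flips():
    frames = rotation_minimizing_frames(_random_smooth_curve())
    e1 = frames[:, 1, :]
    cosang = np.sum(e1[1:] * e1[:-1], axis=1)
    assert np.all(cosang > np.cos(np.radians(10.0)))


def test_degenerate_tangent_rejected():
    pts = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1.0]])
    with pytest.raises(ValueError, match="degenerate"):
        centerline_tangents(pts)


# --- MPR reconstruction -------------------------------------------------------


@pytest.fixture(scope="module")
def random_volume():
    rng = np.random.default_rng(11)
    data = rng.standard_normal((40, 44, 60)) * 200.0 + 100.0
    return ImageVolume(data, spacing=(0.7, 0.5, 0.9))


def _diagonal_centerline():
    s = np.linspace(0, 1, 30)
    raw = np.column_stack([8 + 6 * s + np.sin(3 * s), 7 + 5 * s, 12 + 25 * s])
    return resample_centerline(raw)


def test_mpr_matches_brute_force_trilinear(random_volume):
    """1 000 random MPR samples agree with the 8-neighbor trilinear formula
    to 1e-9 (the interpolation is exactly trilinear, not approximate)."""
    cl = _diagonal_centerline()
    mpr = reconstruct_mpr(random_volume, cl, max_fill_fraction=None)
    grid, _ = mpr_sample_points(cl)
    rng = np.random.default_rng(4)
    S = mpr.n_slices
    si = rng.integers(0, S, 1000)
    ui = rng.integers(20, 107, 1000)   # stay inside the volume
    vi = rng.integers(20, 107, 1000)
    pts_mm = grid[si, ui, vi]
    idx = random_volume.mm_to_index(pts_mm)
    inside = np.all((idx >= 0) & (idx <= np.array(random_volume.data.shape) - 1), axis=1)
    expected = trilinear_oracle(random_volume.data, idx[inside])
    np.testing.assert_allclose(mpr.data[si[inside], ui[inside], vi[inside]],
                               expected, atol=1e-9)


def test_straight_tube_centered_at_pixel_63():
    data = np.zeros((41, 41, 40))
    data[20, 20, :] = 1000.0
    vol = ImageVolume(data, spacing=(0.5, 0.5, 0.5))
    raw = np.array([[10.0, 10.0, 2.0], [10.0, 10.0, 18.0]])
    mpr = reconstruct_mpr(vol, resample_centerline(raw), max_fill_fraction=None)
    center = mpr.data[:, 63, 63]
    assert np.all(center == center.max())
    assert np.all(mpr.data.max(axis=(1, 2)) == center)


def test_constant_volume_gives_constant_mpr():
    vol = ImageVolume(np.full((30, 30, 40), 123.0), spacing=(0.6, 0.6, 0.6))
    raw = np.array([[9.0, 9.0, 4.0], [9.0, 9.0, 20.0]])
    mpr = reconstruct_mpr(vol, resample_centerline(raw), max_fill_fraction=None)
    inside = mpr.data != -1024.0
    np.testing.assert_allclose(mpr.data[inside], 123.0, atol=1e-9)


def test_rigid_translation_invariance(random_volume):
    s = np.linspace(0, 1, 30)
    raw = np.column_stack([8 + 6 * s + np.sin(3 * s), 7 + 5 * s, 12 + 25 * s])
    mpr_a = reconstruct_mpr(random_volume, resample_centerline(raw),
                            max_fill_fraction=None)
    shift = np.array([1.7, -2.1, 3.3])
    vol_b = ImageVolume(random_volume.data, random_volume.spacing,
                        origin=tuple(shift))
    mpr_b = reconstruct_mpr(vol_b, resample_centerline(raw + shift),
                            max_fill_fraction=None)
    np.testing.assert_allclose(mpr_a.data, mpr_b.data, atol=1e-6)


def test_artery_outside_field_of_view_rejected():
    vol = ImageVolume(np.zeros((20, 20, 30)), spacing=(0.5, 0.5, 0.5))
    raw = np.array([[1.0, 1.0, 2.0], [1.0, 1.0, 12.0]])  # plane mostly outside
    with pytest.raises(ValueError, match="rejected"):
        reconstruct_mpr(vol, resample_centerline(raw))


# --- intensity normalization --------------------------------------------------


def test_self_normalization_gives_zero_mean_unit_sd():
    rng = np.random.default_rng(5)
    mprs = [MPRVolume(rng.standard_normal((7, 127, 127)) * 300 + 80) for _ in range(3)]
    stats = fit_intensity_stats(mprs)
    normed = [apply_intensity_norm(m, stats) for m in mprs]
    allv = np.concatenate([m.data.ravel() for m in normed])
    assert abs(allv.mean()) < 1e-6
    assert abs(allv.std() - 1.0) < 1e-6


def test_zero_variance_corpus_rejected():
    with pytest.raises(ValueError, match="variance"):
        fit_intensity_stats([MPRVolume(np.full((3, 127, 127), 7.0))])


def test_stats_are_frozen_at_test_time():
    rng = np.random.default_rng(6)
    a = [MPRVolume(rng.standard_normal((5, 127, 127)))]
    b = [MPRVolume(rng.standard_normal((5, 127, 127)) + 50.0)]
    stats_a = fit_intensity_stats(a)
    normed_b = apply_intensity_norm(b[0], stats_a)
    assert abs(normed_b.data.mean()) > 1.0  # no re-fitting on corpus B
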