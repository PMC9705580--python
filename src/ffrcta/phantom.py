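"""Synthetic CCTA vessel phantoms.

Generates contrast-filled curved tubular arteries (lumen ~400 HU) embedded
in soft-tissue background (~50 HU), with focal cosine-shaped stenoses,
calcified plaque (~800 HU) abutting the lumen, an optional side branch, and
Gaussian HU noise — together with voxel-exact lumen/calcium masks, a labeled
centerline tree, and analytically computed ground-truth characteristics and
a toy-model FFR label. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .centerline import CenterlineTree, TreeNode, rotation_minimizing_frames
from .hemodynamics import simulate_ffr
from .types import ATTENUATION_SENTINEL, CharacteristicProfile, ImageVolume, MPRVolume

CALCIUM_THICKNESS_MM = 0.8
GT_SLICE_SPACING = 0.5


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of one phantom scan."""

    volume_shape: tuple[int, int, int] = (72, 72, 160)
    voxel_spacing: tuple[float, float, float] = (0.3, 0.3, 0.3)
    lumen_hu: float = 400.0
    background_hu: float = 50.0
    calcium_hu: float = 800.0
    noise_sd: float = 20.0
    n_arteries: int = 1
    artery_length_mm: float = 40.0
    baseline_radius_mm: float = 1.0
    #: (center_mm, length_mm, fractional_area_reduction) per stenosis
    stenosis_spec: list[tuple[float, float, float]] = field(default_factory=list)
    #: (center_mm, length_mm, arc_fraction) per calcified plaque
    calcium_spec: list[tuple[float, float, float]] = field(default_factory=list)
    #: sd (mm) of the random smooth in-plane centerline perturbation
    curvature_sd_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_radius_mm <= 0:
            raise ValueError("baseline radius must be > 0")
        if not 1 <= self.n_arteries <= 3:
            raise ValueError("n_arteries must be 1..3")
        for center, length, sev in self.stenosis_spec:
            if not 0.0 <= sev <= 0.95:
                raise ValueError("fractional area reduction must be in [0, 0.95]")
            if center - length / 2 < 0 or center + length / 2 > self.artery_length_mm:
                raise ValueError(
                    f"stenosis at {center} mm (length {length} mm) overlaps the artery end")
        for center, length, arc in self.calcium_spec:
            if not 0.0 < arc <= 1.0:
                raise ValueError("calcium arc fraction must be in (0, 1]")
            if not 0.0 <= center <= self.artery_length_mm:
                raise ValueError("calcium center outside the artery")


@dataclass
class PhantomGroundTruth:
    """Analytic per-slice reference values of the main artery (0.5 mm spacing)."""

    lumen_area: np.ndarray      # mm^2
    attenuation: np.ndarray     # HU
    calcium_area: np.ndarray    # mm^2
    lesion_location: int | None
    true_ffr: float

    def __post_init__(self):
        if np.any(self.lumen_area < 0) or np.any(self.calcium_area < 0):
            raise ValueError("areas must be non-negative")
        if not 0.0 < self.true_ffr <= 1.0:
            raise ValueError("true FFR must be in (0, 1]")
        if self.lesion_location is not None and not (
                0 <= self.lesion_location < len(self.lumen_area)):
            raise ValueError("lesion location outside the profile")


@dataclass
class Phantom:
    """Everything the downstream pipeline needs about one phantom scan."""

    volume: ImageVolume
    tree: CenterlineTree
    lumen_mask: ImageVolume
    calcium_mask: ImageVolume
    ground_truth: PhantomGroundTruth
    main_centerline_raw: np.ndarray          # (N, 3) mm, 0.5 mm spacing
    main_label: str = "LAD"


def _smooth_centerline(rng: np.random.Generator, length_mm: float,
                       center_xy: np.ndarray, z0: float,
                       curvature_sd: float, step: float) -> np.ndarray:
    """Smooth random 3-D curve: straight z-path with a cubic-spline in-plane
    perturbation, bounded so the tube never self-intersects."""
    from scipy.interpolate import CubicSpline

    n_ctrl = max(4, int(length_mm / 8) + 1)
    s_ctrl = np.linspace(0.0, length_mm, n_ctrl)
    amp = np.clip(rng.normal(0.0, curvature_sd, size=(n_ctrl, 2)), -2.5, 2.5)
    amp[0] = 0.0
    spline = CubicSpline(s_ctrl, amp, bc_type="natural")
    s = np.arange(0.0, length_mm + 1e-9, step)
    xy = center_xy[None, :] + spline(s)
    z = z0 + s
    return np.column_stack([xy, z])


def _radius_profile(config: PhantomConfig, s: np.ndarray) -> np.ndarray:
    """r(s) = baseline_radius * sqrt(1 - reduction(s)) with cosine-squared bumps."""
    reduction = np.zeros_like(s)
    for center, ln, sev in config.stenosis_spec:
        inside = np.abs(s - center) <= ln / 2.0
        reduction[inside] += sev * np.cos(np.pi * (s[inside] - center) / ln) ** 2
    reduction = np.clip(reduction, 0.0, 0.95)
    return config.baseline_radius_mm * np.sqrt(1.0 - reduction)


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Rasterize one phantom CCTA volume with masks, tree and ground truth."""
    rng = np.random.default_rng(config.seed)
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    shape = tuple(config.volume_shape)
    extent = spacing * np.asarray(shape)
    # generic sub-voxel offset: real arteries are never aligned with the
    # voxel lattice, and exact alignment is the worst case for mask areas
    center_xy = extent[:2] / 2.0 + spacing[:2] * np.array([0.29, 0.41])
    z0 = (extent[2] - config.artery_length_mm) / 2.0
    if z0 < 1.0:
        raise ValueError("volume too short for the requested artery length")

    fine_step = 0.1
    main_fine = _smooth_centerline(rng, config.artery_length_mm, center_xy, z0,
                                   config.curvature_sd_mm, fine_step)
    s_fine = np.arange(main_fine.shape[0]) * fine_step
    r_fine = _radius_profile(config, s_fine)

    branches: list[np.ndarray] = []
    branch_radii: list[np.ndarray] = []
    branch_attach_fine: list[int] = []
    branch_dirs = [np.array([1.0, 0.6, 0.9]), np.array([-0.8, 1.0, 0.9])]
    for b in range(config.n_arteries - 1):
        attach_s = config.artery_length_mm * (0.4 + 0.25 * b)
        i0 = int(round(attach_s / fine_step))
        direction = branch_dirs[b] / np.linalg.norm(branch_dirs[b])
        blen = 12.0
        sb = np.arange(0.0, blen + 1e-9, fine_step)
        curve = main_fine[i0] + sb[:, None] * direction
        # gentle random curvature on the branch as well
        bend = rng.normal(0.0, 0.3, size=2)
        curve[:, 0] += bend[0] * (sb / blen) ** 2
        curve[:, 1] += bend[1] * (sb / blen) ** 2
        branches.append(curve)
        branch_radii.append(np.full(sb.shape, 0.6 * config.baseline_radius_mm))
        branch_attach_fine.append(i0)

    all_pts = np.vstack([main_fine] + branches)
    all_r = np.concatenate([r_fine] + branch_radii)

    # --- rasterization restricted to a bounding box around the tube ----------
    vol = np.full(shape, config.background_hu, dtype=np.float32)
    lumen = np.zeros(shape, dtype=np.uint8)
    calcium = np.zeros(shape, dtype=np.uint8)

    margin = all_r.max() + CALCIUM_THICKNESS_MM + 2.0 * spacing.max()
    lo = np.maximum(np.floor((all_pts.min(axis=0) - margin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((all_pts.max(axis=0) + margin) / spacing).astype(int) + 1,
                    np.asarray(shape))
    ix = [np.arange(lo[a], hi[a]) for a in range(3)]
    gx, gy, gz = np.meshgrid(*ix, indexing="ij")
    vox_mm = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) * spacing

    tree_all = cKDTree(all_pts)
    dist, nearest = tree_all.query(vox_mm)
    r_near = all_r[nearest]
    edge = spacing.min()
    frac = np.clip((r_near - dist) / edge + 0.5, 0.0, 1.0)
    hu = config.background_hu + (config.lumen_hu - config.background_hu) * frac
    inside = dist <= r_near

    sub_shape = tuple(hi - lo)
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = hu.reshape(sub_shape).astype(np.float32)
    lumen[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside.reshape(sub_shape)

    # --- calcified plaque abutting the main-artery lumen ---------------------
    if config.calcium_spec:
        frames = rotation_minimizing_frames(main_fine)
        tree_main = cKDTree(main_fine)
        dist_m, near_m = tree_main.query(vox_mm)
        s_m = s_fine[near_m]
        r_m = r_fine[near_m]
        dvec = vox_mm - main_fine[near_m]
        u = np.einsum("ij,ij->i", dvec, frames[near_m, 1, :])
        v = np.einsum("ij,ij->i", dvec, frames[near_m, 2, :])
        angle = np.mod(np.arctan2(v, u), 2 * np.pi)
        ca = np.zeros(vox_mm.shape[0], dtype=bool)
        for center, ln, arc in config.calcium_spec:
            theta0 = rng.uniform(0.0, 2 * np.pi)
            dtheta = np.mod(angle - theta0, 2 * np.pi)
            sel = ((np.abs(s_m - center) <= ln / 2.0)
                   & (dist_m > r_m) & (dist_m <= r_m + CALCIUM_THICKNESS_MM)
                   & (dtheta <= 2 * np.pi * arc))
            ca |= sel
        ca3 = ca.reshape(sub_shape)
        view = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        view[ca3] = config.calcium_hu
        calcium[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = ca3

    vol += rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)

    # --- arc-length resampled main centerline (0.5 mm between MPR slices) -----
    # Ground truth is indexed by MPR slice, i.e. by arc length along the curve;
    # the radius profile is a function of the curve parameter, so map arc
    # positions back to parameters before evaluating it.
    chord = np.linalg.norm(np.diff(main_fine, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(chord)])
    arc_samples = np.arange(0.0, arc[-1] + 1e-9, GT_SLICE_SPACING)
    s_gt = np.interp(arc_samples, arc, s_fine)           # curve parameter per slice
    main_raw = np.column_stack([np.interp(arc_samples, arc, main_fine[:, a])
                                for a in range(3)])

    # --- centerline tree (one node per MPR slice, labeled) --------------------
    step_ratio = int(round(GT_SLICE_SPACING / fine_step))
    nodes: dict[int, TreeNode] = {}
    for i, p in enumerate(main_raw):
        nodes[i] = TreeNode(i, p.copy(), None if i == 0 else i - 1, "LAD")
    nid = len(nodes)
    for b, curve in enumerate(branches):
        attach = int(np.argmin(np.linalg.norm(
            main_raw - main_fine[branch_attach_fine[b]], axis=1)))
        parent = attach
        for p in curve[::step_ratio][1:]:
            nodes[nid] = TreeNode(nid, p.copy(), parent, "side-branch")
            parent = nid
            nid += 1
    tree = CenterlineTree(nodes)

    # --- analytic ground truth -------------------------------------------------
    r_gt = _radius_profile(config, s_gt)
    lumen_area = np.pi * r_gt ** 2
    attenuation = np.full_like(lumen_area, config.lumen_hu)
    calcium_area = np.zeros_like(lumen_area)
    for center, ln, arc_frac in config.calcium_spec:
        inside = np.abs(s_gt - center) <= ln / 2.0
        ring = np.pi * ((r_gt[inside] + CALCIUM_THICKNESS_MM) ** 2 - r_gt[inside] ** 2)
        calcium_area[inside] += arc_frac * ring
    lesion = int(np.argmin(lumen_area)) if config.stenosis_spec else None
    gt = PhantomGroundTruth(lumen_area=lumen_area, attenuation=attenuation,
                            calcium_area=calcium_area, lesion_location=lesion,
                            true_ffr=simulate_ffr(lumen_area, GT_SLICE_SPACING))

    mk = lambda arr: ImageVolume(arr, tuple(spacing))
    return Phantom(volume=ImageVolume(vol, tuple(spacing)), tree=tree,
                   lumen_mask=mk(lumen), calcium_mask=mk(calcium),
                   ground_truth=gt, main_centerline_raw=main_raw)


def reference_characteristics(mpr_lumen_mask: MPRVolume, mpr_calcium_mask: MPRVolume,
                              mpr_image: MPRVolume,
                              mask_threshold: float = 0.5) -> CharacteristicProfile:
    """Reference lumen area, calcium area and mean lumen attenuation from
    MPR-resampled segmentation masks.

    Areas are pixel counts times the in-plane pixel area (0.1 mm -> 0.01 mm^2
    per pixel); attenuation is the mean image HU over the lumen-mask pixels of
    each slice, with a NaN sentinel where a slice has no lumen pixels (mapped
    to 0 after z-normalization downstream). Tree-derived flags are returned
    as zeros; they come from the centerline tree, not from masks.
    """
    for m in (mpr_lumen_mask, mpr_calcium_mask):
        if m.data.shape != mpr_image.data.shape or m.in_plane_spacing != mpr_image.in_plane_spacing:
            raise ValueError("masks and image must share the MPR geometry")
    px_area = mpr_image.in_plane_spacing ** 2
    lum = mpr_lumen_mask.data >= mask_threshold
    cal = mpr_calcium_mask.data >= mask_threshold
    lumen_area = lum.sum(axis=(1, 2)) * px_area
    calcium_area = cal.sum(axis=(1, 2)) * px_area
    s = mpr_image.n_slices
    attenuation = np.full(s, ATTENUATION_SENTINEL)
    for i in range(s):
        if lum[i].any():
            attenuation[i] = float(mpr_image.data[i][lum[i]].mean())
    zeros = np.zeros(s)
    return CharacteristicProfile(lumen_area=lumen_area, attenuation=attenuation,
                                 calcium_area=calcium_area, bifurcation=zeros,
                                 main_branch=zeros.copy())
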