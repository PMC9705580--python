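"""Core domain containers shared across the pipeline.

Units: positions and spacings in mm, areas in mm^2, intensities in HU,
FFR dimensionless in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: attenuation value reported for a cross-section with no lumen pixels;
#: mapped to 0 after z-normalization downstream.
ATTENUATION_SENTINEL = np.nan

#: FFR at or below this value defines a functionally significant stenosis.
FFR_THRESHOLD = 0.8


@dataclass
class ImageVolume:
    """3-D image grid in HU with physical geometry (axes ordered x, y, z)."""

    data: np.ndarray          # (nx, ny, nz)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive on every axis")

    def mm_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Physical mm coordinates -> fractional voxel indices (0-based)."""
        return (np.asarray(points_mm) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class MPRVolume:
    """Straightened multiplanar reformation: a stack of cross-sections
    perpendicular to the centerline (0.1 mm in-plane, 0.5 mm between slices).

    ``frames`` holds the per-slice orthonormal (tangent, e1, e2) triple used
    to sample the plane; pixel (63, 63) of each 127x127 slice is the
    centerline point.
    """

    data: np.ndarray                  # (S, 127, 127)
    in_plane_spacing: float = 0.1
    slice_spacing: float = 0.5
    frames: np.ndarray | None = None  # (S, 3, 3): rows tangent, e1, e2
    n_filled: int = 0                 # out-of-volume samples filled with -1024

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class CharacteristicProfile:
    """Per-cross-section artery characteristics along the centerline."""

    lumen_area: np.ndarray        # mm^2
    attenuation: np.ndarray       # HU (NaN sentinel where lumen is empty)
    calcium_area: np.ndarray      # mm^2
    bifurcation: np.ndarray       # {0, 1}
    main_branch: np.ndarray       # {0, 1}

    def __post_init__(self):
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.lumen_area, self.attenuation, self.calcium_area,
                   self.bifurcation, self.main_branch)]
        lengths = {a.shape for a in arrays}
        if len(lengths) != 1 or arrays[0].ndim != 1:
            raise ValueError("all five characteristic series must be 1-D of equal length")
        (self.lumen_area, self.attenuation, self.calcium_area,
         self.bifurcation, self.main_branch) = arrays
        for flags in (self.bifurcation, self.main_branch):
            if not np.isin(flags, (0.0, 1.0)).all():
                raise ValueError("bifurcation/main-branch flags must be binary")

    def __len__(self) -> int:
        return self.lumen_area.shape[0]

    def stacked(self) -> np.ndarray:
        """(5, S) array ordered lumen, attenuation, calcium, bifurcation, main."""
        return np.stack([self.lumen_area, self.attenuation, self.calcium_area,
                         self.bifurcation, self.main_branch])


CHARACTERISTIC_NAMES = ("lumen_area", "attenuation", "calcium_area",
                        "bifurcation", "main_branch")


@dataclass
class FFRReference:
    """Invasive-FFR-style reference label for one artery."""

    ffr: float
    lesion_location: int | None       # slice index of the most severe stenosis
    measurement_index: int            # slice index of the pressure measurement

    def __post_init__(self):
        if not 0.0 < self.ffr <= 1.0:
            raise ValueError("FFR must lie in (0, 1]")
        if self.measurement_index < 0:
            raise ValueError("measurement index must be non-negative")

    @property
    def label(self) -> bool:
        """True when the stenosis is functionally significant (FFR <= 0.8)."""
        return self.ffr <= FFR_THRESHOLD


@dataclass
class Prediction:
    """Outputs of the stenosis-assessment stage for one artery."""

    ffr_regressed: float
    prob_class: float
    prob_pseudo: float = np.nan
    prob_merged: float = np.nan
    uncertainty_prob: float = 0.0
    uncertainty_ffr: float = 0.0


@dataclass
class IntensityStats:
    """Pooled intensity mean/sd of the training MPRs (z-normalization)."""

    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("intensity sd must be > 0")

    def to_dict(self) -> dict:
        return {"mean": float(self.mean), "sd": float(self.sd)}

    @classmethod
    def from_dict(cls, d: dict) -> "IntensityStats":
        return cls(mean=d["mean"], sd=d["sd"])


@dataclass
class CharacteristicStats:
    """Per-characteristic mean/sd pooled over all slices of the training set."""

    mean: np.ndarray   # (5,)
    sd: np.ndarray     # (5,)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (5,) or self.sd.shape != (5,):
            raise ValueError("characteristic stats must cover exactly 5 characteristics")
        if not (self.sd > 0).all():
            raise ValueError("characteristic sds must be > 0")

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist(),
                "characteristics": list(CHARACTERISTIC_NAMES)}

    @classmethod
    def from_dict(cls, d: dict) -> "CharacteristicStats":
        return cls(mean=np.array(d["mean"]), sd=np.array(d["sd"]))
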