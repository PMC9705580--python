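"""Toy hemodynamic model assigning ground-truth FFR to phantom arteries.

The pressure drop over an artery is modeled as serial viscous (Poiseuille-
type) resistances plus a quadratic flow-separation term for the dominant
stenosis:

    dP = Q * sum_i c * l / A_i**2  +  k * Q**2 * max(0, 1/A_min - 1/A_ref)**2
    FFR = (P_a - dP) / P_a, clipped to (0, 1]

with per-slice lumen areas ``A_i`` (mm^2), slice thickness ``l`` (mm),
nominal hyperemic flow ``Q``, aortic pressure ``P_a`` (mmHg) and a fixed
healthy reference area ``A_ref``. The constants are fixed once by a
calibration anchor (root-finding), not fitted to literature: a 70%-area
stenosis of 10 mm length in an otherwise healthy 3 mm^2, 40 mm artery must
yield FFR = 0.70, and the unobstructed artery FFR >= 0.97.

The separation term uses the single most severe narrowing relative to a
*fixed* reference area, which makes FFR provably non-increasing under any
pointwise reduction of the lumen-area profile (serial lesions still
accumulate through the viscous sum).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq


@dataclass(frozen=True)
class HemodynamicModel:
    """Calibrated constants of the toy pressure-drop model."""

    c: float          # viscous resistance coefficient, mmHg * mm^3 / flow unit
    k: float          # separation-loss coefficient
    q: float = 1.0    # nominal hyperemic flow (arbitrary units)
    p_a: float = 100.0  # aortic pressure, mmHg
    a_ref: float = 3.5  # healthy reference lumen area, mm^2


# calibration anchor geometry
_ANCHOR_BASELINE_AREA = 3.0    # mm^2
_ANCHOR_LENGTH = 40.0          # mm
_ANCHOR_STENOSIS_LEN = 10.0    # mm
_ANCHOR_SEVERITY = 0.7         # fractional area reduction
_ANCHOR_FFR = 0.70
_SLICE = 0.5                   # mm


def stenosis_profile(baseline_area: float, length_mm: float,
                     stenoses: list[tuple[float, float, float]],
                     slice_spacing: float = _SLICE) -> np.ndarray:
    """Lumen-area profile of a tube with smooth cosine-squared stenoses.

    ``stenoses`` are (center_mm, length_mm, fractional_area_reduction).
    """
    s = np.arange(0.0, length_mm + 1e-9, slice_spacing)
    reduction = np.zeros_like(s)
    for center, ln, sev in stenoses:
        inside = np.abs(s - center) <= ln / 2.0
        reduction[inside] += sev * np.cos(np.pi * (s[inside] - center) / ln) ** 2
    reduction = np.clip(reduction, 0.0, 0.95)
    return baseline_area * (1.0 - reduction)


def pressure_drop(areas: np.ndarray, slice_spacing: float, model: HemodynamicModel) -> float:
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("lumen areas must be strictly positive")
    viscous = model.q * model.c * slice_spacing * float(np.sum(1.0 / areas ** 2))
    a_min = float(areas.min())
    sep = max(0.0, 1.0 / a_min - 1.0 / model.a_ref)
    return viscous + model.k * model.q ** 2 * sep ** 2


def simulate_ffr(areas: np.ndarray, slice_spacing: float = _SLICE,
                 model: "HemodynamicModel | None" = None) -> float:
    """Ground-truth FFR of a lumen-area profile under the calibrated toy model."""
    if model is None:
        model = calibrated_model()
    dp = pressure_drop(areas, slice_spacing, model)
    ffr = (model.p_a - dp) / model.p_a
    return float(np.clip(ffr, 1e-6, 1.0))


@lru_cache(maxsize=None)
def calibrated_model(c: float = 0.5) -> HemodynamicModel:
    """Fix the separation coefficient ``k`` by root-finding on the anchor:
    the calibration stenosis (70% area, 10 mm, 3 mm^2 baseline) must give
    FFR exactly 0.70."""
    anchor = stenosis_profile(_ANCHOR_BASELINE_AREA, _ANCHOR_LENGTH,
                              [(_ANCHOR_LENGTH / 2, _ANCHOR_STENOSIS_LEN, _ANCHOR_SEVERITY)])

    def residual(k: float) -> float:
        m = HemodynamicModel(c=c, k=k)
        return simulate_ffr(anchor, _SLICE, m) - _ANCHOR_FFR

    k = brentq(residual, 0.0, 1e4, xtol=1e-10)
    model = HemodynamicModel(c=c, k=k)
    healthy = np.full(int(_ANCHOR_LENGTH / _SLICE) + 1, _ANCHOR_BASELINE_AREA)
    if simulate_ffr(healthy, _SLICE, model) < 0.97:
        raise RuntimeError("calibration failed: unobstructed anchor artery below FFR 0.97")
    return model
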