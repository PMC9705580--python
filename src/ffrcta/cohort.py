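"""Synthetic patient cohorts for training and evaluating the stenosis stage.

Each patient carries 1-3 arteries. An artery is a phantom tube whose
analytic characteristic profile (lumen area, attenuation, calcium area,
tree indicators) is perturbed by measurement noise emulating the
characterization network's regression error; its ground-truth FFR comes
from the calibrated toy hemodynamic model, and stenosis severities are
drawn so that a requested fraction of arteries is functionally significant
(FFR <= 0.8). Profiles are generated analytically (no voxel rasterization),
which is what makes cohorts of hundreds of arteries cheap; ``render=True``
additionally builds the full phantom volume per artery via
:func:`ffrcta.phantom.generate_phantom`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .hemodynamics import simulate_ffr
from .phantom import CALCIUM_THICKNESS_MM, Phantom, PhantomConfig, generate_phantom
from .stenosis import MEASUREMENT_OFFSET_MM, MIN_RELEVANT_LUMEN_MM2
from .types import CharacteristicProfile, FFRReference

log = logging.getLogger(__name__)

SLICE = 0.5
MAIN_LABELS = ("LAD", "LCX", "RCA")


@dataclass
class CohortConfig:
    """Study conditions of a synthetic cohort."""

    class_balance: float = 0.42        # fraction of arteries with FFR <= 0.8
    min_arteries: int = 1
    max_arteries: int = 3
    artery_length_mm: tuple[float, float] = (35.0, 50.0)
    baseline_radius_mm: tuple[float, float] = (0.85, 1.25)
    stenosis_length_mm: tuple[float, float] = (6.0, 14.0)
    p_second_stenosis: float = 0.25
    p_calcium: float = 0.4
    p_side_branch: float = 0.6
    lumen_noise_rel: float = 0.05      # relative sd of lumen-area measurement noise
    attenuation_noise_hu: float = 10.0
    calcium_noise_mm2: float = 0.05
    lumen_hu: float = 400.0
    max_draw_tries: int = 40


@dataclass
class ArteryRecord:
    patient_id: int
    artery_id: str
    label: str                          # anatomical segment of the artery
    profile: CharacteristicProfile      # noisy "measured" characteristics
    true_profile: CharacteristicProfile  # noise-free analytic characteristics
    reference: FFRReference
    phantom: Phantom | None = None      # populated only when render=True


def _measurement_index(lesion: int | None, lumen_area: np.ndarray, s: int) -> int:
    if lesion is not None:
        return min(lesion + int(round(MEASUREMENT_OFFSET_MM / SLICE)), s - 1)
    distal = np.flatnonzero(lumen_area > MIN_RELEVANT_LUMEN_MM2)
    return int(distal[-1]) if distal.size else s - 1


def _draw_artery(rng: np.random.Generator, config: CohortConfig,
                 want_positive: bool) -> tuple[dict, float, int | None]:
    """Rejection-sample stenosis geometry until the FFR label matches."""
    for attempt in range(config.max_draw_tries):
        length = rng.uniform(*config.artery_length_mm)
        radius = rng.uniform(*config.baseline_radius_mm)
        stenoses = []
        if want_positive:
            sev = rng.uniform(0.58, 0.85)
        else:
            sev = rng.uniform(0.0, 0.5)
        sten_len = rng.uniform(*config.stenosis_length_mm)
        if sev > 0.02:
            center = rng.uniform(sten_len / 2 + 1.0, length - sten_len / 2 - 1.0)
            stenoses.append((center, sten_len, sev))
            if sev > 0.1 and rng.random() < config.p_second_stenosis:
                sev2 = rng.uniform(0.1, min(sev, 0.6))
                len2 = rng.uniform(*config.stenosis_length_mm)
                center2 = rng.uniform(len2 / 2 + 1.0, length - len2 / 2 - 1.0)
                stenoses.append((center2, len2, sev2))
        geom = {"length": length, "radius": radius, "stenoses": stenoses}
        s_gt = np.arange(0.0, length + 1e-9, SLICE)
        reduction = np.zeros_like(s_gt)
        for c, ln, sv in stenoses:
            inside = np.abs(s_gt - c) <= ln / 2
            reduction[inside] += sv * np.cos(np.pi * (s_gt[inside] - c) / ln) ** 2
        reduction = np.clip(reduction, 0.0, 0.95)
        area = np.pi * radius ** 2 * (1.0 - reduction)
        ffr = simulate_ffr(area, SLICE)
        positive = ffr <= 0.8
        # keep positives above a floor so the cohort FFR distribution sits
        # around the threshold (an intermediate-stenosis population) rather
        # than at the fully-occluded extreme
        ok = positive == want_positive and (not want_positive or ffr >= 0.25)
        if ok or attempt == config.max_draw_tries - 1:
            geom["area"] = area
            lesion = int(np.argmin(area)) if stenoses else None
            return geom, ffr, lesion
    raise AssertionError("unreachable")


def generate_cohort(n_patients: int, class_balance: float = 0.42, seed: int = 0,
                    config: CohortConfig | None = None,
                    render: bool = False) -> list[ArteryRecord]:
    """Generate a reproducible cohort of phantom arteries grouped by patient.

    Stenosis severities are drawn so that the fraction of FFR <= 0.8 arteries
    matches ``class_balance`` within sampling error; a warning is emitted if
    the realized fraction deviates by more than 5 percentage points.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    config = config or CohortConfig()
    config = CohortConfig(**{**vars(config), "class_balance": class_balance})
    rng = np.random.default_rng(seed)
    records: list[ArteryRecord] = []
    for pid in range(n_patients):
        n_art = int(rng.integers(config.min_arteries, config.max_arteries + 1))
        labels = list(rng.choice(MAIN_LABELS, size=min(n_art, 3), replace=False))
        for a in range(n_art):
            want_positive = bool(rng.random() < config.class_balance)
            geom, ffr, lesion = _draw_artery(rng, config, want_positive)
            area = geom["area"]
            s = area.size
            has_branch = rng.random() < config.p_side_branch
            bifurcation = np.zeros(s)
            if has_branch:
                bifurcation[int(rng.integers(s // 4, 3 * s // 4))] = 1.0
            main_branch = np.ones(s)
            attenuation = np.full(s, config.lumen_hu)
            calcium = np.zeros(s)
            if rng.random() < config.p_calcium:
                c = rng.uniform(5.0, geom["length"] - 5.0)
                ln = rng.uniform(3.0, 8.0)
                arc = rng.uniform(0.15, 0.5)
                inside = np.abs(np.arange(s) * SLICE - c) <= ln / 2
                r = np.sqrt(area / np.pi)
                calcium[inside] = arc * np.pi * (
                    (r[inside] + CALCIUM_THICKNESS_MM) ** 2 - r[inside] ** 2)
            true_profile = CharacteristicProfile(
                lumen_area=area, attenuation=attenuation, calcium_area=calcium,
                bifurcation=bifurcation, main_branch=main_branch)
            noisy = CharacteristicProfile(
                lumen_area=np.maximum(area * (1 + rng.normal(0, config.lumen_noise_rel, s)),
                                      0.05),
                attenuation=attenuation + rng.normal(0, config.attenuation_noise_hu, s),
                calcium_area=np.maximum(calcium + rng.normal(0, config.calcium_noise_mm2, s),
                                        0.0),
                bifurcation=bifurcation, main_branch=main_branch)
            reference = FFRReference(ffr=ffr, lesion_location=lesion,
                                     measurement_index=_measurement_index(lesion, area, s))
            phantom = None
            if render:
                spacing = 0.3
                nz = int(np.ceil((geom["length"] + 8.0) / spacing))
                phantom = generate_phantom(PhantomConfig(
                    volume_shape=(72, 72, nz),
                    voxel_spacing=(spacing, spacing, spacing),
                    artery_length_mm=geom["length"],
                    baseline_radius_mm=geom["radius"],
                    stenosis_spec=geom["stenoses"],
                    n_arteries=2 if has_branch else 1,
                    seed=int(rng.integers(2 ** 31))))
            records.append(ArteryRecord(
                patient_id=pid, artery_id=f"p{pid:04d}_a{a}", label=labels[a % len(labels)],
                profile=noisy, true_profile=true_profile, reference=reference,
                phantom=phantom))
    realized = np.mean([r.reference.label for r in records])
    # tiny cohorts cannot resolve the prevalence to 5 points; stay silent there
    if len(records) >= 30 and abs(realized - config.class_balance) > 0.05:
        warnings.warn(f"realized positive fraction {realized:.2f} deviates from the "
                      f"requested {config.class_balance:.2f} by more than 0.05")
    return records
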