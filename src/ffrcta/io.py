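"""Reading and writing the pipeline's on-disk formats.

Volumes and MPRs are NIfTI (spacing in the header), centerline trees are
JSON, characteristic profiles and predictions are CSV, statistics and
metrics are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import CharacteristicProfile, ImageVolume, MPRVolume


def save_volume(volume: ImageVolume, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))


def load_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return ImageVolume(np.asarray(img.dataobj), spacing, origin)


def save_mpr(mpr: MPRVolume, path) -> None:
    affine = np.diag([mpr.in_plane_spacing, mpr.in_plane_spacing, mpr.slice_spacing, 1.0])
    # store as (x, y, slice) so the header spacing matches the axes
    nib.save(nib.Nifti1Image(np.ascontiguousarray(mpr.data.transpose(1, 2, 0)), affine),
             str(path))


def load_mpr(path) -> MPRVolume:
    img = nib.load(str(path))
    spac = np.abs(np.diag(img.affine)[:3])
    return MPRVolume(data=np.ascontiguousarray(np.asarray(img.dataobj).transpose(2, 0, 1)),
                     in_plane_spacing=float(spac[0]), slice_spacing=float(spac[2]))


def profile_to_csv(profile: CharacteristicProfile, path) -> None:
    pd.DataFrame({
        "slice": np.arange(len(profile)),
        "lumen_area_mm2": profile.lumen_area,
        "attenuation_hu": profile.attenuation,
        "calcium_area_mm2": profile.calcium_area,
        "bifurcation": profile.bifurcation.astype(int),
        "main_branch": profile.main_branch.astype(int),
    }).to_csv(path, index=False)


def profile_from_csv(path) -> CharacteristicProfile:
    df = pd.read_csv(path)
    return CharacteristicProfile(
        lumen_area=df["lumen_area_mm2"].to_numpy(float),
        attenuation=df["attenuation_hu"].to_numpy(float),
        calcium_area=df["calcium_area_mm2"].to_numpy(float),
        bifurcation=df["bifurcation"].to_numpy(float),
        main_branch=df["main_branch"].to_numpy(float))


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
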