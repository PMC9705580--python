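"""Tree-derived artery characteristics and characteristic normalization.

Two binary per-slice indicators come from the labeled centerline tree:
whether a bifurcation is present at the mapped tree node (>= 2 children)
and whether the node lies on a main branch (LM/LAD/LCX/RCA) rather than a
side branch. All five characteristics are z-normalized with statistics
pooled over all slices of all training arteries; the same statistics are
reapplied unchanged at test time.
"""

from __future__ import annotations

import logging

import numpy as np

from .centerline import MAIN_BRANCH_LABELS, ArteryCenterline, CenterlineTree
from .types import CharacteristicProfile, CharacteristicStats

log = logging.getLogger(__name__)

MAPPING_TOLERANCE_MM = 1.0


def extract_tree_characteristics(tree: CenterlineTree, artery: ArteryCenterline
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice (bifurcation, main_branch) indicator series for one artery.

    Every artery point is mapped to its nearest tree node (within 1.0 mm);
    bifurcation[i] = 1 iff that node has >= 2 children, main_branch[i] = 1
    iff its label is one of LM/LAD/LCX/RCA.
    """
    s = len(artery)
    bifurcation = np.zeros(s)
    main_branch = np.zeros(s)
    for i, point in enumerate(artery.points):
        try:
            nid = tree.nearest_node(point, max_dist=MAPPING_TOLERANCE_MM)
        except ValueError as exc:
            raise ValueError(f"artery point {i} could not be mapped to the tree: {exc}") from exc
        bifurcation[i] = 1.0 if tree.successor_count(nid) >= 2 else 0.0
        main_branch[i] = 1.0 if tree.nodes[nid].label in MAIN_BRANCH_LABELS else 0.0
    return bifurcation, main_branch


def fit_characteristic_stats(profiles: list[CharacteristicProfile]) -> CharacteristicStats:
    """Per-characteristic mean/sd pooled over all slices of the training arteries.

    A zero-variance characteristic (e.g. all-zero calcium in a small corpus)
    gets sd = 1 with a warning, leaving that series unchanged by normalization.
    NaN attenuation sentinels are excluded from the pooled statistics.
    """
    if len(profiles) < 2:
        raise ValueError("at least 2 training profiles are required")
    stacked = np.concatenate([p.stacked() for p in profiles], axis=1)  # (5, total)
    mean = np.nanmean(stacked, axis=1)
    sd = np.nanstd(stacked, axis=1)
    for idx in np.flatnonzero(sd <= 0):
        log.warning("characteristic %d has zero variance in the training set; sd set to 1", idx)
        sd[idx] = 1.0
        mean[idx] = 0.0
    return CharacteristicStats(mean=mean, sd=sd)


def apply_characteristic_norm(profile: CharacteristicProfile,
                              stats: CharacteristicStats) -> np.ndarray:
    """Z-normalize all five characteristic series with frozen training stats.

    Returns a (5, S) array in the order lumen_area, attenuation, calcium_area,
    bifurcation, main_branch. NaN attenuation sentinels become 0 after
    normalization.
    """
    z = (profile.stacked() - stats.mean[:, None]) / stats.sd[:, None]
    z[1] = np.nan_to_num(z[1], nan=0.0)
    return z
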