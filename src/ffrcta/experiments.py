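"""End-to-end study harnesses on synthetic cohorts.

Two experiments exercise the full pipeline at desk scale:

* :func:`characterizer_recovery` — parameter recovery: train the
  characterization CNN on rendered phantom MPRs and measure the held-out
  relative error of the regressed lumen area against the analytic ground
  truth.
* :func:`end_to_end_discrimination` — train a patient-disjoint k-fold
  ensemble of stenosis-assessment networks on a synthetic cohort
  (toy-model FFR labels) and measure the held-out AUC of the merged
  probability, optionally with input-characteristic ablations.

Problem sizes default to a desk-scale protocol (tens of patients, a few
hundred updates) chosen so both experiments run on a single CPU core in
minutes; all randomness is seed-controlled.
"""

from __future__ import annotations

import copy
import logging

import numpy as np

from .centerline import resample_centerline
from .characterizer import (CharacterizerConfig, CharacterizerNet, _target_matrix,
                            characterize_artery, make_triplets,
                            train_characterizer_arrays)
from .cohort import ArteryRecord, generate_cohort
from .ensemble import crossval_train, ensemble_predict
from .evaluation import compute_metrics
from .mpr import apply_intensity_norm, reconstruct_mpr
from .stenosis import StenosisNetConfig
from .treechar import fit_characteristic_stats
from .types import CharacteristicProfile, IntensityStats, MPRVolume

log = logging.getLogger(__name__)


def rendered_artery(rec: ArteryRecord) -> tuple[MPRVolume, CharacteristicProfile]:
    """MPR and slice-aligned analytic ground-truth profile of a rendered phantom."""
    ph = rec.phantom
    if ph is None:
        raise ValueError("record was generated without render=True")
    cl = resample_centerline(ph.main_centerline_raw)
    mpr = reconstruct_mpr(ph.volume, cl, max_fill_fraction=None)
    gt = ph.ground_truth
    n = min(mpr.n_slices, len(gt.lumen_area))
    mpr = copy.copy(mpr)
    mpr.data = mpr.data[:n]
    zeros = np.zeros(n)
    profile = CharacteristicProfile(gt.lumen_area[:n], gt.attenuation[:n],
                                    gt.calcium_area[:n], zeros, zeros.copy())
    return mpr, profile


def characterizer_recovery(n_patients: int = 60, n_val_patients: int = 10,
                           slices_per_artery: int = 14, steps: int = 500,
                           lr: float = 3e-4, batch_size: int = 8,
                           seed: int = 0) -> dict:
    """Parameter-recovery experiment for the characterization network.

    Phantom scans are rendered patient by patient (so memory stays flat);
    the network trains on a random subset of slices of the training
    arteries and is evaluated on every slice of the held-out patients'
    arteries. Returns the held-out relative MAE of the lumen area plus the
    absolute MAEs of attenuation and calcium area.
    """
    rng = np.random.default_rng(seed)
    xs_list: list[np.ndarray] = []
    ys_list: list[np.ndarray] = []
    n_train_arteries = 0
    val_pairs: list[tuple[MPRVolume, CharacteristicProfile]] = []
    total, total_sum, total_sq = 0, 0.0, 0.0
    for p in range(n_patients):
        recs = generate_cohort(1, seed=seed * 100003 + p, render=True)
        for rec in recs:
            mpr, profile = rendered_artery(rec)
            rec.phantom = None  # free the voxel volumes
            if p < n_patients - n_val_patients:
                total += mpr.data.size
                total_sum += float(mpr.data.sum())
                total_sq += float((mpr.data.astype(np.float64) ** 2).sum())
                idx = np.sort(rng.choice(mpr.n_slices,
                                         size=min(slices_per_artery, mpr.n_slices),
                                         replace=False))
                # triplets built from the full artery so stack neighbors are
                # true adjacent cross-sections, then subsampled
                xs_list.append(make_triplets(mpr.data)[idx])
                ys_list.append(_target_matrix(profile)[idx])
                n_train_arteries += 1
            else:
                val_pairs.append((mpr, profile))
    mean = total_sum / total
    sd = float(np.sqrt(total_sq / total - mean ** 2))
    stats = IntensityStats(mean=mean, sd=sd)
    xs = (np.concatenate(xs_list, axis=0) - mean) / sd
    ys = np.concatenate(ys_list, axis=0)
    del xs_list, ys_list
    val_pairs = [(apply_intensity_norm(m, stats), pr) for m, pr in val_pairs]

    config = CharacterizerConfig(lr=lr, batch_size=batch_size, seed=seed)
    model = CharacterizerNet(config)
    history = train_characterizer_arrays(model, xs, ys, config, steps=steps, log_every=0)

    rel_lumen, abs_att, abs_cal = [], [], []
    for mpr, profile in val_pairs:
        pred = characterize_artery(model, mpr)
        rel_lumen.append(np.abs(pred.lumen_area - profile.lumen_area) / profile.lumen_area)
        abs_att.append(np.abs(pred.attenuation - profile.attenuation))
        abs_cal.append(np.abs(pred.calcium_area - profile.calcium_area))
    return {
        "rel_mae_lumen": float(np.concatenate(rel_lumen).mean()),
        "mae_attenuation_hu": float(np.concatenate(abs_att).mean()),
        "mae_calcium_mm2": float(np.concatenate(abs_cal).mean()),
        "n_train_arteries": n_train_arteries,
        "n_val_arteries": len(val_pairs),
        "final_loss": float(np.mean(history[-20:])),
        "model": model,
        "intensity_stats": stats,
    }


def end_to_end_discrimination(n_patients: int = 60, n_test_patients: int = 12,
                              folds: int = 10, epochs: int = 45,
                              lr_high: float = 2e-3, lr_period: float = 20.0,
                              class_balance: float = 0.42,
                              seed: int = 0,
                              ablate: frozenset[str] | set[str] = frozenset()) -> dict:
    """Cross-validated ensemble discrimination on a synthetic cohort.

    Patients are split into a development and a held-out test set; a
    ``folds``-fold patient-disjoint ensemble is trained on the development
    arteries and applied, as an ensemble, to the test arteries. Returns the
    held-out metrics of the merged probability plus per-artery predictions.
    """
    recs = generate_cohort(n_patients, class_balance=class_balance, seed=seed)
    dev = [r for r in recs if r.patient_id < n_patients - n_test_patients]
    test = [r for r in recs if r.patient_id >= n_patients - n_test_patients]
    stats = fit_characteristic_stats([r.profile for r in dev])
    cohort = [(r.profile, r.reference) for r in dev]
    pids = np.array([r.patient_id for r in dev])
    config = StenosisNetConfig(seed=seed, lr_high=lr_high, lr_period=lr_period)
    models, fold_map = crossval_train(cohort, pids, stats, config,
                                      k=folds, seed=seed, epochs=epochs, ablate=ablate)
    predictions = [ensemble_predict(models, r.profile, stats, r.reference, ablate)[0]
                   for r in test]
    labels = np.array([r.reference.label for r in test])
    scores = np.array([p.prob_merged for p in predictions])
    report = compute_metrics(scores, labels)
    return {
        "auc": report.auc,
        "report": report,
        "predictions": predictions,
        "test_records": test,
        "models": models,
        "stats": stats,
        "fold_map": fold_map,
    }


#: leave-one-out and single-characteristic input subsets; values name the
#: characteristics whose channels are zeroed at train and test time
ABLATION_SUBSETS: dict[str, frozenset[str]] = {
    "all": frozenset(),
    "no_lumen": frozenset({"lumen"}),
    "no_attenuation": frozenset({"attenuation"}),
    "no_calcium": frozenset({"calcium"}),
    "no_tree": frozenset({"tree"}),
    "lumen_only": frozenset({"attenuation", "calcium"}),
    "attenuation_only": frozenset({"lumen", "calcium"}),
    "calcium_only": frozenset({"lumen", "attenuation"}),
}


def ablation_harness(subsets: dict[str, frozenset[str]] | None = None,
                     **experiment_kwargs) -> dict[str, dict]:
    """Train and evaluate one stenosis-assessment ensemble per input subset.

    ``subsets`` maps a name to the set of characteristics to zero out
    (tree indicators always remain available unless 'tree' is excluded);
    an empty exclusion set is the full model. Zeroing every characteristic
    is rejected. Returns {name: metrics report dict} on the shared held-out
    test split.
    """
    subsets = dict(subsets) if subsets is not None else dict(ABLATION_SUBSETS)
    results = {}
    for name, excluded in subsets.items():
        if set(excluded) >= {"lumen", "attenuation", "calcium", "tree"}:
            raise ValueError(f"subset {name!r} excludes every characteristic")
        out = end_to_end_discrimination(ablate=excluded, **experiment_kwargs)
        results[name] = {"report": out["report"], "auc": out["auc"],
                         "excluded": sorted(excluded)}
        log.info("ablation %s (without %s): AUC %.3f", name, sorted(excluded), out["auc"])
    return results
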