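"""Pseudo-probability merging, 10-fold cross-validation ensembling and
prediction uncertainty.

The regressed FFR is mapped to a pseudo-probability by linearly scaling a
symmetric window around the 0.8 significance threshold:

    p = 0.5 - (FFR - 0.8) / 0.4   for FFR in [0.6, 1.0]
    p = 1.0                        for FFR in [0.0, 0.6)

so FFR = 0.8 maps to 0.5 and the transformation saturates at 1 below 0.6.
The pseudo-probability is averaged with the classification-head probability;
an ensemble of k networks (trained on k-fold, patient-disjoint subsets)
averages the member probabilities and FFR values, and reports the standard
deviation across members as the prediction uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .stenosis import StenosisNet, StenosisNetConfig, predict_artery, train_stenosis_net
from .types import CharacteristicProfile, CharacteristicStats, FFRReference, Prediction

log = logging.getLogger(__name__)


def pseudo_probability(ffr_regressed: float | np.ndarray) -> float | np.ndarray:
    """Piecewise-linear map from regressed FFR to a pseudo-probability."""
    x = np.asarray(ffr_regressed, dtype=float)
    if np.any(x > 1.0):
        log.warning("regressed FFR > 1 clipped to 1")
    if np.any(x < 0.0):
        log.warning("regressed FFR < 0 clipped to 0")
    x = np.clip(x, 0.0, 1.0)
    p = np.where(x < 0.6, 1.0, 0.5 - (x - 0.8) / 0.4)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(ffr_regressed) or p.ndim == 0 else p


def merge_outputs(prob_class, prob_pseudo):
    """Arithmetic mean of the two heads' probabilities."""
    return (np.asarray(prob_class, dtype=float) + np.asarray(prob_pseudo, dtype=float)) / 2.0


def finalize_prediction(pred: Prediction) -> Prediction:
    """Fill in pseudo- and merged probabilities from the raw head outputs."""
    pp = pseudo_probability(pred.ffr_regressed)
    return replace(pred, prob_pseudo=float(pp),
                   prob_merged=float(merge_outputs(pred.prob_class, pp)))


def patient_folds(patient_ids: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random patient-disjoint fold assignment: all arteries of a patient
    share a fold. Returns the fold index per artery."""
    patient_ids = np.asarray(patient_ids)
    uniq = np.unique(patient_ids)
    if k > uniq.size:
        raise ValueError(f"cannot split {uniq.size} patients into {k} folds")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(uniq)
    fold_of = {pid: i % k for i, pid in enumerate(shuffled)}
    return np.array([fold_of[p] for p in patient_ids])


def crossval_train(cohort: list[tuple[CharacteristicProfile, FFRReference]],
                   patient_ids: np.ndarray,
                   stats: CharacteristicStats,
                   config: StenosisNetConfig,
                   k: int = 10, seed: int = 0,
                   epochs: int | None = None,
                   ablate: frozenset[str] | set[str] = frozenset()
                   ) -> tuple[list[StenosisNet], np.ndarray]:
    """Train k networks on the k leave-one-fold-out subsets of the cohort.

    Folds are patient-disjoint; returns (models, per-artery fold index).
    Model ``i`` never saw fold ``i`` during training.
    """
    if len(cohort) < k:
        raise ValueError("cohort smaller than the number of folds")
    folds = patient_folds(patient_ids, k=k, seed=seed)
    models = []
    for i in range(k):
        model = StenosisNet(replace(config, seed=seed * 1000 + i))
        train_subset = [rec for rec, f in zip(cohort, folds) if f != i]
        train_stenosis_net(model, train_subset, stats, epochs=epochs, ablate=ablate)
        models.append(model)
        log.info("fold %d/%d trained on %d arteries", i + 1, k, len(train_subset))
    return models, folds


def ensemble_predict(models: list[StenosisNet], profile: CharacteristicProfile,
                     stats: CharacteristicStats,
                     reference: FFRReference | None = None,
                     ablate: frozenset[str] | set[str] = frozenset()
                     ) -> tuple[Prediction, list[Prediction]]:
    """Average member predictions; uncertainty is the population standard
    deviation of the merged probability and the regressed FFR across members.

    Returns (ensemble prediction, member predictions)."""
    if len(models) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    members = [finalize_prediction(predict_artery(m, profile, stats, reference, ablate))
               for m in models]
    ffrs = np.array([m.ffr_regressed for m in members])
    probs_cls = np.array([m.prob_class for m in members])
    probs_pseudo = np.array([m.prob_pseudo for m in members])
    probs_merged = np.array([m.prob_merged for m in members])
    ens = Prediction(ffr_regressed=float(ffrs.mean()),
                     prob_class=float(probs_cls.mean()),
                     prob_pseudo=float(probs_pseudo.mean()),
                     prob_merged=float(probs_merged.mean()),
                     uncertainty_prob=float(probs_merged.std()),
                     uncertainty_ffr=float(ffrs.std()))
    return ens, members
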