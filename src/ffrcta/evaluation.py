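"""Evaluation: AUC/accuracy/sensitivity/specificity, patient-level
aggregation, paired AUC permutation testing, and the uncertainty-based
referral simulation."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .types import FFR_THRESHOLD

log = logging.getLogger(__name__)

OPERATING_THRESHOLD = 0.5


@dataclass
class MetricsReport:
    auc: float            # NaN when the reference has a single class
    accuracy: float
    sensitivity: float
    specificity: float
    n_arteries: int
    n_positive: int
    threshold: float

    def to_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in vars(self).items()}


def dichotomize(values: np.ndarray, threshold: float | None = None,
                mode: str = "ffr") -> np.ndarray:
    """Binary positive labels: FFR mode is positive iff value <= 0.8;
    probability mode is positive iff value >= the operating threshold."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if mode == "ffr":
        thr = FFR_THRESHOLD if threshold is None else threshold
        return values <= thr
    if mode == "probability":
        thr = OPERATING_THRESHOLD if threshold is None else threshold
        return values >= thr
    raise ValueError(f"unknown mode {mode!r}")


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = OPERATING_THRESHOLD) -> MetricsReport:
    """Artery-level metrics for probability-like scores (higher = positive).

    AUC follows the Mann-Whitney construction (ties count 1/2); it is NaN when
    the reference contains a single class, while the thresholded metrics are
    still reported.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    n = scores.size
    auc = float("nan")
    if labels.any() and not labels.all():
        auc = float(roc_auc_score(labels, scores))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return MetricsReport(auc=auc, accuracy=(tp + tn) / n, sensitivity=sens,
                         specificity=spec, n_arteries=n, n_positive=int(labels.sum()),
                         threshold=threshold)


def patient_level(scores: np.ndarray, ffr_reference: np.ndarray,
                  patient_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate artery scores/labels to patients.

    Patient score = highest artery score; patient is positive iff any of the
    measured arteries has FFR <= 0.8. Returns (scores, labels, patient ids).
    """
    scores = np.asarray(scores, dtype=float)
    ffr_reference = np.asarray(ffr_reference, dtype=float)
    patient_ids = np.asarray(patient_ids)
    if not (scores.shape == ffr_reference.shape == patient_ids.shape):
        raise ValueError("scores, references and patient ids must align")
    uniq = np.unique(patient_ids)
    p_scores, p_labels, keep = [], [], []
    for pid in uniq:
        sel = patient_ids == pid
        if not sel.any():  # pragma: no cover - unique guarantees non-empty
            log.warning("patient %r has no arteries; excluded", pid)
            continue
        p_scores.append(scores[sel].max())
        p_labels.append(bool((ffr_reference[sel] <= FFR_THRESHOLD).any()))
        keep.append(pid)
    return np.array(p_scores), np.array(p_labels), np.array(keep)


def referral_simulation(scores: np.ndarray, uncertainties: np.ndarray,
                        labels: np.ndarray, fraction: float,
                        mode: str = "correct",
                        threshold: float = OPERATING_THRESHOLD) -> MetricsReport:
    """Refer the most uncertain cases for invasive measurement.

    The ceil(fraction * n) highest-uncertainty cases are either removed
    (``exclude``) or have their score replaced by the reference outcome
    (``correct``: 1 for reference-positive, 0 for reference-negative), after
    which the metrics are recomputed. Ties in uncertainty are broken by case
    index for determinism.
    """
    scores = np.asarray(scores, dtype=float).copy()
    unc = np.asarray(uncertainties, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (scores.shape == unc.shape == labels.shape):
        raise ValueError("scores, uncertainties and labels must align")
    if mode not in ("exclude", "correct"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exclude" and fraction >= 1.0:
        raise ValueError("cannot exclude all cases")
    n = scores.size
    n_ref = int(np.ceil(fraction * n))
    # sort by (uncertainty desc, index asc)
    order = np.lexsort((np.arange(n), -unc))
    referred = order[:n_ref]
    if mode == "exclude":
        keep = np.ones(n, dtype=bool)
        keep[referred] = False
        return compute_metrics(scores[keep], labels[keep], threshold)
    scores[referred] = np.where(labels[referred], 1.0, 0.0)
    return compute_metrics(scores, labels, threshold)


def _auc(labels: np.ndarray, scores: np.ndarray) -> float:
    return float(roc_auc_score(labels, scores))


def auc_permutation_test(scores_a: np.ndarray, scores_b: np.ndarray,
                         labels: np.ndarray, n_iter: int = 1000,
                         seed: int | None = 0) -> float:
    """Paired permutation test for the AUC difference of two models.

    The null is generated by independently swapping the two models' scores
    per case with probability 1/2; p uses add-one smoothing:
    p = (#{permuted |dAUC| >= observed} + 1) / (n_iter + 1).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == labels.shape):
        raise ValueError("permutation test requires paired scores on identical cases")
    observed = abs(_auc(labels, a) - _auc(labels, b))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_iter):
        swap = rng.random(a.size) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        if abs(_auc(labels, pa) - _auc(labels, pb)) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_iter + 1)
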