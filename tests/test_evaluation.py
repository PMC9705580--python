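"""Metrics, patient-level aggregation, referral simulation and the paired
AUC permutation test (with brute-force and exhaustive oracles)."""

import itertools

import numpy as np
import pytest

from ffrcta.evaluation import (auc_permutation_test, compute_metrics, dichotomize,
                               patient_level, referral_simulation)


def pairwise_auc_oracle(labels, scores):
    """AUC as the exhaustive positive-negative pair count (ties = 1/2)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_dichotomize_ffr_threshold_inclusive():
    out = dichotomize(np.array([0.80, 0.81, 0.5]), mode="ffr")
    assert out.tolist() == [True, False, True]


def test_dichotomize_probability_tie_rule():
    out = dichotomize(np.array([0.5, 0.49]), mode="probability")
    assert out.tolist() == [True, False]


def test_perfectly_separated_scores_auc_one():
    labels = np.array([True, True, False, False])
    rep = compute_metrics(np.array([0.9, 0.8, 0.2, 0.1]), labels)
    assert rep.auc == 1.0
    assert rep.accuracy == 1.0


def test_all_tied_scores_auc_half():
    labels = np.array([True, False, True, False])
    rep = compute_metrics(np.full(4, 0.5), labels)
    assert rep.auc == 0.5


def test_auc_matches_pairwise_oracle_random_instances():
    rng = np.random.default_rng(0)
    for n in range(2, 51):
        labels = np.zeros(n, dtype=bool)
        labels[: rng.integers(1, n)] = True
        rng.shuffle(labels)
        if labels.all() or not labels.any():
            continue
        scores = np.round(rng.random(n), 2)   # rounding produces ties
        rep = compute_metrics(scores, labels)
        assert rep.auc == pytest.approx(pairwise_auc_oracle(labels, scores), abs=1e-12)


def test_single_class_reference_gives_nan_auc():
    labels = np.array([True, True, True])
    rep = compute_metrics(np.array([0.9, 0.2, 0.6]), labels)
    assert np.isnan(rep.auc)
    assert rep.accuracy == pytest.approx(2 / 3)
    assert rep.sensitivity == pytest.approx(2 / 3)
    assert np.isnan(rep.specificity)


def test_patient_level_max_rule():
    scores, labels, pids = patient_level(np.array([0.2, 0.9, 0.3]),
                                         np.array([0.9, 0.7, 0.85]),
                                         np.array([1, 1, 2]))
    assert scores.tolist() == [0.9, 0.3]
    assert labels.tolist() == [True, False]     # any artery FFR <= 0.8 -> positive
    assert pids.tolist() == [1, 2]


def test_patient_negative_only_if_no_artery_positive():
    _, labels, _ = patient_level(np.array([0.1, 0.2]), np.array([0.81, 0.92]),
                                 np.array([7, 7]))
    assert labels.tolist() == [False]


def test_single_artery_patient_score_passthrough():
    scores, _, _ = patient_level(np.array([0.42]), np.array([0.7]), np.array([3]))
    assert scores.tolist() == [0.42]


# --- referral simulation -----------------------------------------------------


def _referral_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < 0.4
    scores = np.clip(labels * 0.4 + rng.random(n) * 0.6, 0, 1)
    unc = rng.random(n)
    return scores, unc, labels


def test_zero_fraction_is_identity():
    scores, unc, labels = _referral_data()
    a = referral_simulation(scores, unc, labels, fraction=0.0, mode="correct")
    b = compute_metrics(scores, labels)
    assert a.__dict__ == b.__dict__


def test_full_correction_is_perfect():
    scores, unc, labels = _referral_data()
    rep = referral_simulation(scores, unc, labels, fraction=1.0, mode="correct")
    assert rep.accuracy == 1.0
    assert rep.sensitivity == 1.0
    assert rep.specificity == 1.0


def test_exclude_removes_exactly_ceil_fraction():
    scores, unc, labels = _referral_data(37)
    rep = referral_simulation(scores, unc, labels, fraction=0.2, mode="exclude")
    assert rep.n_arteries == 37 - int(np.ceil(0.2 * 37))


def test_exclude_everything_rejected():
    scores, unc, labels = _referral_data()
    with pytest.raises(ValueError):
        referral_simulation(scores, unc, labels, fraction=1.0, mode="exclude")


def test_uncertainty_ties_broken_by_case_index():
    scores = np.array([0.9, 0.1, 0.9, 0.1])
    labels = np.array([False, True, False, True])
    unc = np.full(4, 0.7)
    # deterministic: the first ceil(0.5*4)=2 cases by index are corrected
    rep = referral_simulation(scores, unc, labels, fraction=0.5, mode="correct")
    rep2 = referral_simulation(scores, unc, labels, fraction=0.5, mode="correct")
    assert rep.__dict__ == rep2.__dict__
    assert rep.accuracy == pytest.approx(0.5)


# --- permutation test ---------------------------------------------------------


def test_identical_models_give_p_one():
    scores = np.array([0.1, 0.9, 0.4, 0.8, 0.3, 0.7])
    labels = np.array([False, True, False, True, False, True])
    assert auc_permutation_test(scores, scores, labels, n_iter=100, seed=0) == 1.0


def test_p_value_in_unit_interval_and_seeded():
    rng = np.random.default_rng(1)
    labels = rng.random(20) < 0.5
    a, b = rng.random(20), rng.random(20)
    p1 = auc_permutation_test(a, b, labels, n_iter=200, seed=7)
    p2 = auc_permutation_test(a, b, labels, n_iter=200, seed=7)
    assert p1 == p2
    assert 0.0 < p1 <= 1.0


def test_permutation_p_matches_exhaustive_enumeration():
    """On 8 paired cases the Monte-Carlo p must sit within sampling error of
    the exact p over all 2^8 swap patterns."""
    rng = np.random.default_rng(3)
    labels = np.array([True, True, True, False, False, False, True, False])
    a = rng.random(8)
    b = np.clip(a + rng.normal(0, 0.25, 8), 0, 1)

    def auc(scores):
        from sklearn.metrics import roc_auc_score
        return roc_auc_score(labels, scores)

    observed = abs(auc(a) - auc(b))
    count = 0
    total = 0
    for pattern in itertools.product([0, 1], repeat=8):
        swap = np.array(pattern, dtype=bool)
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        total += 1
        if abs(auc(pa) - auc(pb)) >= observed - 1e-12:
            count += 1
    exact = count / total
    n_iter = 2000
    p_mc = auc_permutation_test(a, b, labels, n_iter=n_iter, seed=11)
    mc_sd = np.sqrt(exact * (1 - exact) / n_iter)
    assert abs(p_mc - exact) < 4 * mc_sd + 2 / n_iter


def test_p_super_uniform_under_exchangeability():
    """When the two models are exchangeable, small p-values are not
    over-produced (super-uniformity, checked at reduced iteration count)."""
    rng = np.random.default_rng(5)
    hits = 0
    reps = 40
    for _ in range(reps):
        labels = np.array([True] * 6 + [False] * 6)
        base = rng.random(12)
        a = np.clip(base + rng.normal(0, 0.2, 12), 0, 1)
        b = np.clip(base + rng.normal(0, 0.2, 12), 0, 1)
        if auc_permutation_test(a, b, labels, n_iter=99, seed=int(rng.integers(1e6))) <= 0.25:
            hits += 1
    assert hits / reps <= 0.45   # expected ~0.25 under exchangeability


def test_unpaired_inputs_rejected():
    with pytest.raises(ValueError):
        auc_permutation_test(np.zeros(3), np.zeros(4), np.array([True, False, True]))
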