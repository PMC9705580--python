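"""Stenosis-assessment network: input transforms, measurement masking,
architectural guarantees of the pressure-drop head, training mechanics."""

import numpy as np
import pytest

from ffrcta import nn
from ffrcta.stenosis import (StenosisNet, StenosisNetConfig, bce_with_logit,
                             load_stenosis_net, measurement_mask, pct_difference,
                             predict_artery, prepare_inputs, save_stenosis_net,
                             train_stenosis_net)
from ffrcta.types import CharacteristicProfile, CharacteristicStats, FFRReference


def _stats():
    return CharacteristicStats(mean=np.array([2.5, 380.0, 0.3, 0.05, 0.9]),
                               sd=np.array([0.8, 40.0, 0.4, 0.2, 0.3]))


def _profile(s=84, seed=0):
    rng = np.random.default_rng(seed)
    return CharacteristicProfile(
        lumen_area=rng.uniform(1.0, 4.0, s),
        attenuation=rng.uniform(320, 420, s),
        calcium_area=rng.uniform(0.0, 1.5, s),
        bifurcation=(rng.random(s) < 0.1).astype(float),
        main_branch=np.ones(s))


# --- percentage difference ----------------------------------------------------


def test_pct_difference_of_constant_is_zero():
    np.testing.assert_array_equal(pct_difference(np.full(10, 3.3)), 0.0)


def test_pct_difference_arithmetic():
    d = pct_difference(np.array([2.0, 1.0]))
    assert d[0] == 0.0
    assert d[1] == pytest.approx(-0.5, abs=1e-5)


def test_pct_difference_inverse_transform():
    rng = np.random.default_rng(1)
    x = rng.uniform(0.5, 5.0, 60)
    d = pct_difference(x)
    recon = x[0] * np.cumprod(np.concatenate([[1.0], 1.0 + d[1:]]))
    np.testing.assert_allclose(recon, x, rtol=1e-5)


# --- measurement mask ---------------------------------------------------------


def test_mask_covers_10mm_distal_to_lesion():
    slice_mask, _ = measurement_mask(100, lesion_location=10)
    assert slice_mask[:31].all() and not slice_mask[31:].any()


def test_mask_without_lesion_ends_at_last_relevant_slice():
    lumen = np.linspace(4.0, 0.5, 80)      # crosses 2 mm^2 on the way down
    slice_mask, _ = measurement_mask(80, lumen_area=lumen)
    last = np.flatnonzero(lumen > 2.0)[-1]
    assert slice_mask[last] and not slice_mask[last + 1:].any()


def test_mask_clipped_at_artery_end():
    slice_mask, _ = measurement_mask(25, lesion_location=20)
    assert slice_mask.all()


def test_mask_full_artery_when_no_slice_qualifies(caplog):
    with caplog.at_level("WARNING"):
        slice_mask, _ = measurement_mask(30, lumen_area=np.full(30, 1.0))
    assert slice_mask.all()
    assert "full artery" in caplog.text


def test_pooled_mask_any_rule():
    slice_mask, pooled = measurement_mask(16, lesion_location=0)
    # lesion at 0 -> slices 0..20 clipped to 15 -> all 4 pooled positions
    assert pooled.tolist() == [True, True, True, True]
    # no lesion, lumen drops below 2 mm^2 after slice 5 -> pooled [T, T, F, F]
    lumen = np.concatenate([np.full(6, 3.0), np.full(10, 1.0)])
    _, pooled2 = measurement_mask(16, lumen_area=lumen)
    assert pooled2.tolist() == [True, True, False, False]


# --- architecture guarantees --------------------------------------------------


@pytest.fixture()
def net():
    return StenosisNet(StenosisNetConfig(seed=0))


def test_regressed_ffr_never_exceeds_one(net):
    stats = _stats()
    for seed in range(5):
        x = prepare_inputs(_profile(60, seed), stats)
        _, pooled = measurement_mask(60, lesion_location=20)
        ffr, _, drops = net.forward(*x, pooled)
        assert ffr <= 1.0
        assert (drops >= 0.0).all()


def test_zero_mask_gives_ffr_exactly_one(net):
    x = prepare_inputs(_profile(40), _stats())
    ffr, _, _ = net.forward(*x, np.zeros(10))
    assert ffr == 1.0


def test_ffr_plus_masked_drops_is_one(net):
    x = prepare_inputs(_profile(80, 3), _stats())
    _, pooled = measurement_mask(80, lesion_location=30)
    ffr, _, drops = net.forward(*x, pooled)
    assert abs(ffr + float((drops * pooled).sum()) - 1.0) < 1e-6


@pytest.mark.parametrize("s", [4, 37, 400])
def test_forward_succeeds_for_odd_lengths(net, s):
    x = prepare_inputs(_profile(s, 5), _stats())
    _, pooled = measurement_mask(s, lesion_location=min(2, s - 1))
    ffr, logit, drops = net.forward(*x, pooled)
    assert np.isfinite([ffr, logit]).all()
    assert drops.shape == (s // 4,)


def test_artery_shorter_than_one_pooled_position_rejected(net):
    x = prepare_inputs(_profile(3, 6), _stats())
    with pytest.raises(ValueError, match="pooled"):
        net.forward(*x, np.zeros(0))


def test_inference_is_deterministic_with_dropout_off(net):
    profile = _profile(50, 7)
    ref = FFRReference(ffr=0.7, lesion_location=20, measurement_index=40)
    a = predict_artery(net, profile, _stats(), ref)
    b = predict_artery(net, profile, _stats(), ref)
    assert a.ffr_regressed == b.ffr_regressed
    assert a.prob_class == b.prob_class


class _IdentityModule(nn.Module):
    def forward(self, x, train=False):
        return x

    def backward(self, g):
        return g


def test_distal_modification_beyond_mask_cannot_change_ffr():
    """Locality: with the (globally-connected) transformer replaced by an
    identity and the sequence-global instance norms removed, editing the
    inputs far distal to the measurement mask leaves FFR unchanged (the
    convolutional receptive field is finite and masked drops contribute 0)."""
    net = StenosisNet(StenosisNetConfig(seed=2))
    net.transformer = _IdentityModule()
    for seq in (net.encoder, net.reg_head):
        seq.layers = [l for l in seq.layers if not isinstance(l, nn.InstanceNorm1d)]
    s = 400
    stats = _stats()
    profile = _profile(s, 8)
    _, pooled = measurement_mask(s, lesion_location=20, pool_kernel=4)
    assert pooled.sum() == 11  # slices 0..40 -> pooled 0..10
    x_ref = prepare_inputs(profile, stats)
    ffr_ref, _, _ = net.forward(*x_ref, pooled)
    modified = _profile(s, 8)
    modified.lumen_area[380:] *= 0.2        # far beyond the masked region
    x_mod = prepare_inputs(modified, stats)
    ffr_mod, _, _ = net.forward(*x_mod, pooled)
    assert ffr_mod == pytest.approx(ffr_ref, abs=1e-6)


def test_full_network_gradients_match_numerics():
    """Composite backward pass of both heads checked against central
    differences (double precision, dropout off)."""
    config = StenosisNetConfig(seed=3)
    net = StenosisNet(config, dtype=np.float64)
    s = 24
    x = prepare_inputs(_profile(s, 9), _stats())
    _, pooled = measurement_mask(s, lesion_location=2)

    def loss():
        ffr, logit, _ = net.forward(*x, pooled)
        return ffr + 0.7 * logit

    base = loss()
    net.zero_grad()
    net.backward(dffr=1.0, dlogit=0.7)
    eps = 1e-6
    rng = np.random.default_rng(0)
    for p in net.parameters():
        flat = p.value.reshape(-1)
        gflat = p.grad.reshape(-1)
        for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss()
            flat[idx] = orig - eps
            lm = loss()
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert gflat[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


# --- training -----------------------------------------------------------------


def test_bce_with_logit_matches_manual():
    for logit, target in [(0.3, 1.0), (-2.0, 0.0), (5.0, 1.0)]:
        loss, prob, grad = bce_with_logit(logit, target)
        p = 1 / (1 + np.exp(-logit))
        manual = -(target * np.log(p) + (1 - target) * np.log(1 - p))
        assert loss == pytest.approx(manual, rel=1e-9)
        assert grad == pytest.approx(p - target, rel=1e-9)


def test_eight_artery_overfit():
    """Capacity sanity: a small cohort is memorized; both loss terms are
    small in deterministic (dropout-off) evaluation."""
    rng = np.random.default_rng(4)
    stats = _stats()
    cohort = []
    for i in range(8):
        profile = _profile(40, 20 + i)
        ffr = float(rng.uniform(0.4, 1.0))
        cohort.append((profile, FFRReference(ffr=ffr, lesion_location=15,
                                             measurement_index=35)))
    config = StenosisNetConfig(seed=1, lr_high=2e-3, lr_period=40)
    net = StenosisNet(config)
    train_stenosis_net(net, cohort, stats, config, epochs=500)
    mse, bce = [], []
    for profile, ref in cohort:
        pred = predict_artery(net, profile, stats, ref)
        mse.append((pred.ffr_regressed - ref.ffr) ** 2)
        bce.append(bce_with_logit(np.log(pred.prob_class / (1 - pred.prob_class + 1e-12)),
                                  float(ref.label))[0])
    assert np.mean(mse) < 0.01
    assert np.mean(bce) < 0.1


def test_training_is_seed_reproducible():
    stats = _stats()
    cohort = [(_profile(30, i), FFRReference(ffr=0.75, lesion_location=10,
                                             measurement_index=30 - 1))
              for i in range(4)]

    def run():
        net = StenosisNet(StenosisNetConfig(seed=5))
        train_stenosis_net(net, cohort, stats, epochs=3)
        return predict_artery(net, cohort[0][0], stats, cohort[0][1])

    a, b = run(), run()
    assert a.ffr_regressed == b.ffr_regressed
    assert a.prob_class == b.prob_class


def test_checkpoint_roundtrip(tmp_path, net):
    stats = _stats()
    path = tmp_path / "stenosis.npz"
    save_stenosis_net(net, stats, path)
    restored, restored_stats = load_stenosis_net(path)
    profile = _profile(44, 12)
    ref = FFRReference(ffr=0.8, lesion_location=10, measurement_index=30)
    a = predict_artery(net, profile, stats, ref)
    b = predict_artery(restored, profile, restored_stats, ref)
    assert a.ffr_regressed == b.ffr_regressed
    np.testing.assert_allclose(stats.mean, restored_stats.mean)
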