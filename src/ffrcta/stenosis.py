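"""Stenosis-assessment network over the five per-slice artery characteristics.

A 1-D CNN + single transformer layer with two heads:

* a regression head that predicts non-negative per-position pressure drops
  (ReLU), sums them over the measurement mask and outputs FFR = 1 - sum,
  mirroring the additivity of sequential flow resistances;
* a classification head (adaptive sum pooling to 5 bins + dense layers +
  sigmoid) for the presence of a functionally significant stenosis
  (FFR <= 0.8).

Lumen area and attenuation enter as slice-to-slice fractional differences
through separate two-layer convolutional pre-encoders; calcium and the two
tree indicators enter z-normalized. After average pooling (kernel 4) and
two dilated convolutions, the encoding is concatenated with pooled copies
of the normalized lumen area and attenuation and passed through the
transformer (2 heads, no positional encoding). Convolutions use kernel 3
with zero padding; dropout is 0.5 throughout the encoder and the heads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .treechar import apply_characteristic_norm
from .types import CharacteristicProfile, CharacteristicStats, FFRReference, Prediction

log = logging.getLogger(__name__)

PCT_EPS = 1e-6
MEASUREMENT_OFFSET_MM = 10.0          # measurement assumed 10 mm distal to the lesion
MIN_RELEVANT_LUMEN_MM2 = 2.0          # most distal clinically relevant location
ABLATABLE = ("lumen", "attenuation", "calcium", "tree")


@dataclass
class StenosisNetConfig:
    filters: int = 16
    kernel: int = 3
    dropout: float = 0.5
    pool_kernel: int = 4
    dilations: tuple[int, int] = (1, 2)
    heads: int = 2
    class_bins: int = 5
    epochs: int = 150
    lr_high: float = 5e-4
    lr_low: float = 1e-5
    lr_period: float = 40.0
    accum_steps: int = 8
    loss_weights: tuple[float, float] = (1.0, 1.0)   # (regression, classification)
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.filters < 1:
            raise ValueError("filters must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.class_bins < 1:
            raise ValueError("class_bins must be >= 1")


def pct_difference(series: np.ndarray, eps: float = PCT_EPS) -> np.ndarray:
    """Fractional change vs the previous location: d[0] = 0,
    d[i] = (x[i] - x[i-1]) / (|x[i-1]| + eps)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("series must be 1-D and non-empty")
    d = np.zeros_like(x)
    if x.size > 1:
        d[1:] = np.diff(x) / (np.abs(x[:-1]) + eps)
    return d


def measurement_mask(s: int, lesion_location: int | None = None,
                     lumen_area: np.ndarray | None = None,
                     slice_spacing: float = 0.5,
                     pool_kernel: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Binary masks selecting pressure-drop positions up to the measurement
    location.

    With an annotated lesion the mask covers slices up to 10 mm distal to it;
    without one it covers slices up to the most distal location with lumen
    area > 2 mm^2 (whole artery, with a warning, if no slice qualifies).
    Returns (slice mask (s,), pooled mask (s // pool_kernel,)); a pooled
    position is unmasked iff any of its source slices is unmasked.
    """
    if s < 1:
        raise ValueError("artery must have at least one slice")
    offset = int(round(MEASUREMENT_OFFSET_MM / slice_spacing))
    if lesion_location is not None:
        end = min(lesion_location + offset, s - 1)
    elif lumen_area is not None:
        distal = np.flatnonzero(np.asarray(lumen_area) > MIN_RELEVANT_LUMEN_MM2)
        if distal.size == 0:
            log.warning("no slice with lumen area > %g mm^2; masking the full artery",
                        MIN_RELEVANT_LUMEN_MM2)
            end = s - 1
        else:
            end = int(distal[-1])
    else:
        raise ValueError("either a lesion location or a lumen-area profile is required")
    slice_mask = np.zeros(s, dtype=bool)
    slice_mask[:end + 1] = True
    p = s // pool_kernel
    pooled = slice_mask[:p * pool_kernel].reshape(p, pool_kernel).any(axis=1)
    return slice_mask, pooled


def prepare_inputs(profile: CharacteristicProfile, stats: CharacteristicStats,
                   ablate: frozenset[str] | set[str] = frozenset()
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Network inputs for one artery.

    Returns (lumen pct-difference (1, S), attenuation pct-difference (1, S),
    normalized calcium/bifurcation/main series (3, S), normalized
    lumen/attenuation bypass (2, S)). ``ablate`` names characteristics whose
    channels are zeroed at train and test time.
    """
    unknown = set(ablate) - set(ABLATABLE)
    if unknown:
        raise ValueError(f"unknown characteristics to ablate: {sorted(unknown)}")
    att_raw = np.where(np.isfinite(profile.attenuation), profile.attenuation, stats.mean[1])
    x_lumen = pct_difference(profile.lumen_area)[None, :]
    x_att = pct_difference(att_raw)[None, :]
    z = apply_characteristic_norm(profile, stats)
    rest = z[2:5].copy()
    bypass = z[0:2].copy()
    if "lumen" in ablate:
        x_lumen = np.zeros_like(x_lumen)
        bypass[0] = 0.0
    if "attenuation" in ablate:
        x_att = np.zeros_like(x_att)
        bypass[1] = 0.0
    if "calcium" in ablate:
        rest[0] = 0.0
    if "tree" in ablate:
        rest[1:] = 0.0
    return x_lumen, x_att, rest, bypass


class StenosisNet(nn.Module):
    """One artery per forward pass (variable length S >= 4)."""

    def __init__(self, config: StenosisNetConfig, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.dropout_rng = np.random.default_rng(config.seed + 1)
        f, k, p = config.filters, config.kernel, config.dropout
        d1, d2 = config.dilations

        def drop():
            return nn.Dropout(p, self.dropout_rng)

        self.pre_lumen = nn.Sequential(nn.Conv1d(1, f, k, rng=rng, dtype=dtype),
                                       nn.LeakyReLU(),
                                       nn.Conv1d(f, f, k, rng=rng, dtype=dtype))
        self.pre_att = nn.Sequential(nn.Conv1d(1, f, k, rng=rng, dtype=dtype),
                                     nn.LeakyReLU(),
                                     nn.Conv1d(f, f, k, rng=rng, dtype=dtype))
        cat_ch = 2 * f + 3
        self.pool_in = nn.AvgPool1d(config.pool_kernel)
        self.encoder = nn.Sequential(
            nn.Conv1d(cat_ch, f, k, dilation=d1, rng=rng, dtype=dtype),
            nn.LeakyReLU(), nn.InstanceNorm1d(f, dtype=dtype), drop(),
            nn.Conv1d(f, f, k, dilation=d2, rng=rng, dtype=dtype),
            nn.LeakyReLU(), nn.InstanceNorm1d(f, dtype=dtype), drop(),
        )
        self.pool_bypass = nn.AvgPool1d(config.pool_kernel)
        self.d_model = f + 2
        self.transformer = nn.TransformerEncoderLayer(self.d_model, config.heads,
                                                      rng=rng, dtype=dtype)
        self.reg_head = nn.Sequential(
            nn.Conv1d(self.d_model, f, k, rng=rng, dtype=dtype),
            nn.LeakyReLU(), nn.InstanceNorm1d(f, dtype=dtype), drop(),
            nn.Conv1d(f, f, k, rng=rng, dtype=dtype),
            nn.LeakyReLU(), nn.InstanceNorm1d(f, dtype=dtype), drop(),
            nn.Conv1d(f, 1, k, rng=rng, dtype=dtype),
            nn.ReLU(),
        )
        # start from the healthy prior: near-zero pressure drops (FFR ~ 1),
        # so the early MSE gradient is not dominated by a huge random drop sum
        self.reg_head.layers[-2].weight.value *= 0.05
        self.cls_pool = nn.AdaptiveSumPool1d(config.class_bins)
        self.cls_head = nn.Sequential(
            nn.Linear(self.d_model * config.class_bins, f, rng=rng, dtype=dtype),
            nn.LeakyReLU(), drop(),
            nn.Linear(f, f, rng=rng, dtype=dtype),
            nn.LeakyReLU(), drop(),
            nn.Linear(f, 1, rng=rng, dtype=dtype),
        )

    def forward(self, x_lumen, x_att, rest, bypass, pooled_mask, train=False):
        """Returns (ffr_regressed, classification logit, per-position drops)."""
        s = x_lumen.shape[1]
        if s < self.config.pool_kernel:
            raise ValueError(f"artery with {s} slices is shorter than one pooled position")
        dtype = self.pre_lumen.layers[0].weight.dtype
        el = self.pre_lumen.forward(x_lumen.astype(dtype), train)
        ea = self.pre_att.forward(x_att.astype(dtype), train)
        cat = np.concatenate([el, ea, rest.astype(dtype)], axis=0)      # (35, S)
        pooled = self.pool_in.forward(cat, train)                        # (35, P)
        enc = self.encoder.forward(pooled, train)                        # (16, P)
        byp = self.pool_bypass.forward(bypass.astype(dtype), train)      # (2, P)
        feat = np.concatenate([enc, byp], axis=0)                        # (18, P)
        trans = self.transformer.forward(feat.T, train).T                # (18, P)
        drops = self.reg_head.forward(trans, train)[0]                   # (P,)
        mask = np.asarray(pooled_mask, dtype=dtype)
        ffr = 1.0 - float((drops * mask).sum())
        binned = self.cls_pool.forward(trans, train)                     # (18, bins)
        logit = float(self.cls_head.forward(binned.reshape(1, -1), train)[0, 0])
        self._cache = (mask, cat.shape, enc.shape[0])
        return ffr, logit, drops

    def backward(self, dffr: float, dlogit: float) -> None:
        mask, cat_shape, enc_ch = self._cache
        self._cache = None
        dtype = mask.dtype
        # classification path
        gbin = self.cls_head.backward(np.array([[dlogit]], dtype=dtype))
        gtrans_cls = self.cls_pool.backward(gbin.reshape(self.d_model, -1))
        # regression path: d loss / d drops = -dffr * mask
        gdrops = (-dffr) * mask
        gtrans_reg = self.reg_head.backward(gdrops[None, :].astype(dtype))
        gtrans = gtrans_cls + gtrans_reg
        gfeat = self.transformer.backward(gtrans.T.astype(dtype)).T
        genc, gbyp = gfeat[:enc_ch], gfeat[enc_ch:]
        self.pool_bypass.backward(gbyp)
        gpooled = self.encoder.backward(np.ascontiguousarray(genc))
        gcat = self.pool_in.backward(gpooled)
        f = self.config.filters
        self.pre_lumen.backward(np.ascontiguousarray(gcat[:f]))
        self.pre_att.backward(np.ascontiguousarray(gcat[f:2 * f]))


def bce_with_logit(logit: float, target: float) -> tuple[float, float, float]:
    """Numerically stable binary cross entropy on a logit.

    Returns (loss, probability, d loss / d logit)."""
    prob = 1.0 / (1.0 + np.exp(-logit))
    loss = max(logit, 0.0) - logit * target + np.log1p(np.exp(-abs(logit)))
    return float(loss), float(prob), float(prob - target)


def predict_artery(model: StenosisNet, profile: CharacteristicProfile,
                   stats: CharacteristicStats, reference: FFRReference | None = None,
                   ablate: frozenset[str] | set[str] = frozenset()) -> Prediction:
    """Deterministic inference (dropout off) for one artery."""
    x_lumen, x_att, rest, bypass = prepare_inputs(profile, stats, ablate)
    _, pooled_mask = measurement_mask(
        len(profile),
        lesion_location=None if reference is None else reference.lesion_location,
        lumen_area=profile.lumen_area,
        slice_spacing=0.5, pool_kernel=model.config.pool_kernel)
    ffr, logit, _ = model.forward(x_lumen, x_att, rest, bypass, pooled_mask, train=False)
    prob = 1.0 / (1.0 + np.exp(-logit))
    return Prediction(ffr_regressed=ffr, prob_class=float(prob))


def train_stenosis_net(model: StenosisNet,
                       cohort: list[tuple[CharacteristicProfile, FFRReference]],
                       stats: CharacteristicStats,
                       config: StenosisNetConfig | None = None,
                       epochs: int | None = None,
                       ablate: frozenset[str] | set[str] = frozenset()) -> list[float]:
    """Train on (profile, reference) pairs, one artery per forward pass.

    Loss = MSE(regressed FFR, reference FFR) + BCE(class probability, label),
    weighted per config, accumulated over ``accum_steps`` arteries before each
    AdamW update, with the triangular cyclic learning-rate schedule. Returns
    the per-epoch mean loss history.
    """
    config = config or model.config
    epochs = config.epochs if epochs is None else epochs
    w_reg, w_cls = config.loss_weights
    prepared = []
    for profile, ref in cohort:
        x = prepare_inputs(profile, stats, ablate)
        _, pooled_mask = measurement_mask(len(profile),
                                          lesion_location=ref.lesion_location,
                                          lumen_area=profile.lumen_area,
                                          pool_kernel=config.pool_kernel)
        prepared.append((x, pooled_mask, ref.ffr, float(ref.label)))
    opt = nn.AdamW(model.parameters(), lr=config.lr_high, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 2)
    history = []
    accum = 0
    for epoch in range(epochs):
        opt.lr = nn.cyclic_lr(epoch, config.lr_high, config.lr_low, config.lr_period)
        order = rng.permutation(len(prepared))
        losses = []
        for i in order:
            (x_lumen, x_att, rest, bypass), mask, ffr_ref, label = prepared[i]
            ffr, logit, _ = model.forward(x_lumen, x_att, rest, bypass, mask, train=True)
            bce, _, dlogit = bce_with_logit(logit, label)
            loss = w_reg * (ffr - ffr_ref) ** 2 + w_cls * bce
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss in epoch {epoch} on artery {i}: ffr={ffr}, logit={logit}")
            scale = 1.0 / config.accum_steps
            model.backward(dffr=w_reg * 2.0 * (ffr - ffr_ref) * scale,
                           dlogit=w_cls * dlogit * scale)
            losses.append(loss)
            accum += 1
            if accum == config.accum_steps:
                opt.step()
                model.zero_grad()
                accum = 0
        history.append(float(np.mean(losses)))
    if accum:
        opt.step()
        model.zero_grad()
    return history


def save_stenosis_net(model: StenosisNet, stats: CharacteristicStats, path) -> None:
    meta = {"config": asdict(model.config), "stats": stats.to_dict()}
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_stenosis_net(path) -> tuple[StenosisNet, CharacteristicStats]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg = meta["config"]
    cfg["dilations"] = tuple(cfg["dilations"])
    cfg["loss_weights"] = tuple(cfg["loss_weights"])
    model = StenosisNet(StenosisNetConfig(**cfg))
    model.load_state_dict([data[f"p{i}"] for i in range(len(model.parameters()))])
    return model, CharacteristicStats.from_dict(meta["stats"])
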