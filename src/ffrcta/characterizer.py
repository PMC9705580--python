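"""2-D CNN that regresses per-cross-section artery characteristics.

For each centerline point, a stack of three neighboring 127 x 127 MPR
cross-sections (edge-replicated at the artery ends) is mapped to three
scalars for the central slice: lumen area (mm^2), mean lumen attenuation
(HU) and calcium area (mm^2). The trunk is four blocks of two 3x3
convolutions (16 filters, batch norm, ReLU) each followed by 2x2 max
pooling (127 -> 63 -> 31 -> 15 -> 7); each output head is a global average
pool followed by a single linear unit.

Targets are trained in z-normalized space (statistics over the training
slices, stored with the model) and de-normalized at output, which puts the
0.1-weighted attenuation loss term on the same scale as the area terms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .types import CharacteristicProfile, MPRVolume

log = logging.getLogger(__name__)


@dataclass
class CharacterizerConfig:
    in_slices: int = 3
    blocks: int = 4
    filters: int = 16
    kernel: int = 3
    lr: float = 1e-5
    batch_size: int = 512
    epochs: int = 800
    attenuation_weight: float = 0.1
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.in_slices % 2 != 1:
            raise ValueError("in_slices must be odd")
        if self.filters < 1:
            raise ValueError("filters must be >= 1")


class CharacterizerNet(nn.Module):
    """Trunk + three scalar regression heads (lumen, attenuation, calcium)."""

    def __init__(self, config: CharacterizerConfig, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, k = config.filters, config.kernel
        layers: list[nn.Module] = []
        cin = config.in_slices
        for _ in range(config.blocks):
            layers += [nn.Conv2d(cin, f, k, rng=rng, dtype=dtype), nn.BatchNorm2d(f, dtype=dtype),
                       nn.ReLU(),
                       nn.Conv2d(f, f, k, rng=rng, dtype=dtype), nn.BatchNorm2d(f, dtype=dtype),
                       nn.ReLU(),
                       nn.MaxPool2d()]
            cin = f
        self.trunk = nn.Sequential(*layers)
        self.pools = [nn.GlobalAvgPool2d() for _ in range(3)]
        self.heads = [nn.Linear(f, 1, rng=rng, dtype=dtype) for _ in range(3)]
        # z-normalization of the three targets, fitted during training
        self.target_mean = np.zeros(3, dtype=dtype)
        self.target_sd = np.ones(3, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, in_slices, 127, 127) -> (N, 3) normalized-space predictions."""
        feat = self.trunk.forward(x, train)
        outs = [head.forward(pool.forward(feat, train), train)
                for pool, head in zip(self.pools, self.heads)]
        return np.concatenate(outs, axis=1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gfeat = None
        for i, (pool, head) in enumerate(zip(self.pools, self.heads)):
            g = pool.backward(head.backward(gout[:, i:i + 1]))
            gfeat = g if gfeat is None else gfeat + g
        return self.trunk.backward(gfeat)


def make_triplets(mpr_data: np.ndarray) -> np.ndarray:
    """(S, 127, 127) -> (S, 3, 127, 127) stacks with edge replication."""
    s = mpr_data.shape[0]
    lo = np.clip(np.arange(s) - 1, 0, s - 1)
    hi = np.clip(np.arange(s) + 1, 0, s - 1)
    return np.stack([mpr_data[lo], mpr_data, mpr_data[hi]], axis=1)


def _target_matrix(profile: CharacteristicProfile) -> np.ndarray:
    """(S, 3) training targets; NaN attenuation sentinels replaced by the
    slice-wise finite mean (phantom arteries always have lumen, so this is
    a no-op there)."""
    att = profile.attenuation.copy()
    bad = ~np.isfinite(att)
    if bad.any():
        att[bad] = np.nanmean(att) if np.isfinite(att).any() else 0.0
    return np.column_stack([profile.lumen_area, att, profile.calcium_area])


def characterizer_loss(pred: np.ndarray, target: np.ndarray,
                       attenuation_weight: float) -> tuple[float, np.ndarray]:
    """Weighted MAE: L = MAE(lumen) + w * MAE(attenuation) + MAE(calcium).

    Returns (loss, gradient wrt pred)."""
    n = pred.shape[0]
    diff = pred - target
    weights = np.array([1.0, attenuation_weight, 1.0], dtype=pred.dtype)
    loss = float((np.abs(diff).mean(axis=0) * weights).sum())
    grad = np.sign(diff) * weights / n
    return loss, grad.astype(pred.dtype)


def train_characterizer(model: CharacterizerNet,
                        arteries: list[tuple[MPRVolume, CharacteristicProfile]],
                        config: CharacterizerConfig | None = None,
                        steps: int | None = None,
                        log_every: int = 50) -> list[float]:
    """Train on (normalized MPR, reference profile) pairs; returns loss history.

    ``arteries`` are whole arteries (the train/validation split is artery-wise
    and happens outside this function). Slices from all arteries are pooled
    and sampled in shuffled minibatches. ``steps`` overrides the epoch count
    with an explicit number of updates (desk-scale runs).
    """
    xs = np.concatenate([make_triplets(m.data) for m, _ in arteries], axis=0)
    ys = np.concatenate([_target_matrix(p) for _, p in arteries], axis=0)
    return train_characterizer_arrays(model, xs, ys, config, steps, log_every)


def train_characterizer_arrays(model: CharacterizerNet, xs: np.ndarray, ys: np.ndarray,
                               config: CharacterizerConfig | None = None,
                               steps: int | None = None,
                               log_every: int = 50) -> list[float]:
    """Train on prebuilt (N, 3, 127, 127) stacks and (N, 3) targets."""
    config = config or model.config
    dtype = model.heads[0].weight.dtype
    xs = np.ascontiguousarray(xs, dtype=dtype)
    model.target_mean = ys.mean(axis=0).astype(dtype)
    sd = ys.std(axis=0)
    sd[sd <= 0] = 1.0
    model.target_sd = sd.astype(dtype)
    yn = ((ys - model.target_mean) / model.target_sd).astype(dtype)

    n = xs.shape[0]
    bs = min(config.batch_size, n)
    if steps is None:
        steps = config.epochs * max(1, n // bs)
    opt = nn.AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    order = rng.permutation(n)
    cursor = 0
    for step in range(steps):
        if cursor + bs > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor:cursor + bs]
        cursor += bs
        pred = model.forward(xs[idx], train=True)
        loss, grad = characterizer_loss(pred, yn[idx], config.attenuation_weight)
        if not np.isfinite(loss):
            raise RuntimeError(f"NaN/inf loss at step {step}; aborting training")
        model.zero_grad()
        model.backward(grad)
        opt.step()
        history.append(loss)
        if log_every and step % log_every == 0:
            log.info("characterizer step %d/%d loss %.4f", step, steps, loss)
    return history


def characterize_artery(model: CharacterizerNet, mpr: MPRVolume,
                        chunk: int = 32) -> CharacteristicProfile:
    """Apply the trained network to every cross-section of a normalized MPR.

    Returns a profile with regressed areas and attenuation (de-normalized,
    not clipped); tree flags are zeros and are filled in from the tree."""
    s = mpr.n_slices
    if s < 1:
        raise ValueError("MPR must have at least one slice")
    dtype = model.heads[0].weight.dtype
    triplets = make_triplets(mpr.data).astype(dtype)
    preds = []
    for start in range(0, s, chunk):
        preds.append(model.forward(triplets[start:start + chunk], train=False))
    out = np.concatenate(preds, axis=0) * model.target_sd + model.target_mean
    zeros = np.zeros(s)
    return CharacteristicProfile(lumen_area=out[:, 0], attenuation=out[:, 1],
                                 calcium_area=out[:, 2], bifurcation=zeros,
                                 main_branch=zeros.copy())


def save_characterizer(model: CharacterizerNet, path) -> None:
    meta = {"config": asdict(model.config),
            "target_mean": model.target_mean.tolist(),
            "target_sd": model.target_sd.tolist()}
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    bn_state = {}
    for i, layer in enumerate(model.trunk.layers):
        if isinstance(layer, nn.BatchNorm2d):
            bn_state[f"bn{i}_mean"] = layer.running_mean
            bn_state[f"bn{i}_var"] = layer.running_var
    np.savez(path, meta=json.dumps(meta), **arrays, **bn_state)


def load_characterizer(path) -> CharacterizerNet:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    model = CharacterizerNet(CharacterizerConfig(**meta["config"]))
    model.load_state_dict([data[f"p{i}"] for i in range(len(model.parameters()))])
    model.target_mean = np.array(meta["target_mean"], dtype=np.float32)
    model.target_sd = np.array(meta["target_sd"], dtype=np.float32)
    for i, layer in enumerate(model.trunk.layers):
        if isinstance(layer, nn.BatchNorm2d):
            layer.running_mean = data[f"bn{i}_mean"]
            layer.running_var = data[f"bn{i}_var"]
    return model
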