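"""Composite objective and training loop.

The total objective combines four signals:

    L_total = w_seg * L_seg + w_adv * L_adv
              + w_selfsup * (L_ctr + L_cst) + w_pseudo * L_lmd

* ``L_seg``  — pixel loss: binary cross-entropy plus (1 - Dice).
* ``L_adv``  — adversarial loss from a small discriminator that judges
  predicted vessel maps against ground-truth masks; the generator term is
  the non-saturating form -E[log D(Y_pre)].
* ``L_cst`` — affine equivariance of the self-supervised landmarks.
* ``L_ctr`` — NT-Xent contrastive loss over landmark descriptors of the
  original and a photometrically jittered ("style") view.
* ``L_lmd`` — squared distance between image landmarks and pseudo-label
  landmarks extracted from the ground-truth mask through the shared
  encoder (treated as a fixed target).

Defaults: weights (0.2, 0.3, 0.4, 0.1), Adam with lr 0.001 and weight
decay 0.0005, one image per iteration.  Landmark-specific terms are only
active for the ``transunet_sld`` variant; weights that are exactly zero
skip their branch entirely, so a run with only the segmentation weight
performs plain Dice+BCE training.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .data import SamplePair, resize_pair
from .landmarks import (consistency_loss, contrastive_loss,
                        render_gaussian_map_t, sample_descriptors,
                        soft_argmax_t, spatial_softmax_t)
from .model import NetConfig, SegModel, TransformerConfig, image_to_tensor
from .synthetic import apply_affine_image, sample_affine, style_transform

__all__ = [
    "LossWeights", "TrainConfig", "LossBundle", "TrainResult",
    "Discriminator", "seg_loss", "adversarial_losses", "landmark_loss",
    "total_loss", "train", "save_checkpoint", "load_checkpoint",
]

_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Balance coefficients of the four loss groups."""

    seg: float = 0.2
    adv: float = 0.3
    selfsup: float = 0.4     # shared by the contrastive and consistency terms
    pseudo: float = 0.1

    def __post_init__(self):
        if min(self.seg, self.adv, self.selfsup, self.pseudo) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    weight_decay: float = 0.0005
    batch_size: int = 1
    image_size: tuple[int, int] = (512, 512)
    epochs: int = 1
    seed: int = 0
    variant: str = "transunet_sld"
    weights: LossWeights = field(default_factory=LossWeights)
    net: NetConfig | None = None
    temperature: float = 0.2
    max_rotation: float = 10.0
    max_scale_dev: float = 0.05
    max_shear: float = 0.05
    max_translate: float = 4.0
    style_amplitude: float = 1.0
    landmark_matching: str = "indexed"   # indexed | sinkhorn
    d_lr: float | None = None     # None -> lr / 10
    d_interval: int = 2           # discriminator update every N generator steps

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.net is not None and self.net.variant != self.variant:
            raise ValueError("cfg.net.variant disagrees with cfg.variant")

    def net_config(self) -> NetConfig:
        if self.net is not None:
            return self.net
        return NetConfig(variant=self.variant, seed=self.seed)


@dataclass(frozen=True)
class LossBundle:
    """Named scalar losses plus their weighted total."""

    seg: float
    adv: float
    ctr: float
    cst: float
    lmd: float
    total: float
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        w = self.weights
        expect = (w.seg * self.seg + w.adv * self.adv
                  + w.selfsup * (self.ctr + self.cst) + w.pseudo * self.lmd)
        if not math.isclose(self.total, expect, rel_tol=0, abs_tol=1e-6):
            raise ValueError(
                f"total {self.total} violates the weighted recomposition "
                f"{expect}")


@dataclass
class TrainResult:
    model: SegModel
    history: pd.DataFrame
    checkpoint_path: str | None = None


# -- losses ---------------------------------------------------------------

def _as_map(x) -> nn.Tensor:
    if isinstance(x, nn.Tensor):
        return x
    arr = np.asarray(x, dtype=np.float32)
    while arr.ndim < 4:
        arr = arr[None]
    return nn.Tensor(arr)


def seg_loss(y_pre, y) -> nn.Tensor:
    """Mean BCE plus (1 - Dice) with eps = 1e-6."""
    p = _as_map(y_pre)
    t = _as_map(y)
    if p.shape != t.shape:
        raise ValueError(f"prediction {p.shape} vs target {t.shape}")
    p = p.clip(_EPS, 1 - _EPS)
    bce = -(t * p.log() + (1 - t) * (1 - p).log()).mean()
    eps = 1e-6
    inter = (p * t).sum()
    dice = (inter * 2.0 + eps) / (p.sum() + t.sum() + eps)
    return bce + (1 - dice)


def adversarial_losses(d, y, y_pre) -> tuple[nn.Tensor, nn.Tensor]:
    """(discriminator loss, generator loss).

    The discriminator minimises -[log D(Y) + log(1 - D(Y_pre))] on a
    detached prediction; the generator term is the non-saturating
    -log D(Y_pre), which decreases as the prediction fools D.
    """
    y_t = _as_map(y)
    p_t = _as_map(y_pre)
    real = d(y_t).clip(_EPS, 1 - _EPS)
    fake_detached = d(nn.Tensor(p_t.data)).clip(_EPS, 1 - _EPS)
    l_d = -(real.log().mean() + (1 - fake_detached).log().mean())
    fake = d(p_t).clip(_EPS, 1 - _EPS)
    l_g = -fake.log().mean()
    return l_d, l_g


def landmark_loss(r, ry, matching: str = "indexed",
                  sinkhorn_eps: float = 0.5,
                  sinkhorn_iters: int = 50) -> nn.Tensor:
    """Distance between predicted and pseudo-label landmark sets.

    ``matching="indexed"`` (default) compares landmarks index-wise: the
    mean squared Euclidean distance over the ordered sets.
    ``matching="sinkhorn"`` instead computes an entropy-regularised
    optimal-transport cost: a doubly stochastic plan from Sinkhorn
    iterations on the (detached) pairwise cost matrix reweights the
    squared distances, so landmarks are compared to their best soft
    assignment rather than their index twin.
    """
    from .landmarks import _coords_tensor
    rt, ryt = _coords_tensor(r), _coords_tensor(ry)
    if rt.shape != ryt.shape:
        raise ValueError(
            f"landmark count mismatch: {rt.shape[0]} vs {ryt.shape[0]}")
    if matching == "indexed":
        d = rt - ryt
        return (d * d).sum(axis=1).mean()
    if matching != "sinkhorn":
        raise ValueError(f"unknown matching {matching!r}")
    k = rt.shape[0]
    diff_r = rt[:, 0:1] - ryt[:, 0:1].transpose(1, 0)
    diff_c = rt[:, 1:2] - ryt[:, 1:2].transpose(1, 0)
    cost = diff_r * diff_r + diff_c * diff_c           # (K, K)
    # transport plan from detached costs (uniform marginals, mass 1)
    kern = np.exp(-cost.data / max(sinkhorn_eps, 1e-6))
    u = np.full(k, 1.0 / k)
    v = np.full(k, 1.0 / k)
    for _ in range(sinkhorn_iters):
        u = (1.0 / k) / np.maximum(kern @ v, 1e-30)
        v = (1.0 / k) / np.maximum(kern.T @ u, 1e-30)
    plan = u[:, None] * kern * v[None, :]
    return (nn.Tensor(plan.astype(np.float32)) * cost).sum() * float(k)


def total_loss(seg, adv=0.0, ctr=0.0, cst=0.0, lmd=0.0,
               weights: LossWeights = LossWeights()) -> LossBundle:
    """Combine named components into a :class:`LossBundle`."""
    vals = {}
    for name, v in [("seg", seg), ("adv", adv), ("ctr", ctr),
                    ("cst", cst), ("lmd", lmd)]:
        v = v.item() if isinstance(v, nn.Tensor) else float(v)
        if not math.isfinite(v):
            raise ValueError(f"loss component {name!r} is not finite: {v}")
        vals[name] = v
    total = (weights.seg * vals["seg"] + weights.adv * vals["adv"]
             + weights.selfsup * (vals["ctr"] + vals["cst"])
             + weights.pseudo * vals["lmd"])
    return LossBundle(total=total, weights=weights, **vals)


class Discriminator(nn.Module):
    """Patch-free mask critic: 4 stride-2 convs, LeakyReLU, global average
    pool, sigmoid scalar.  Judges the segmentation map alone."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [1, 16, 32, 64, 128]
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], 4, rng, stride=2,
                                padding=1) for i in range(4)]
        self.fc = nn.Linear(128, 1, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for conv in self.convs:
            x = nn.leaky_relu(conv(x))
        pooled = x.mean(axis=(2, 3))          # (N, 128)
        return nn.sigmoid(self.fc(pooled))


# -- training loop --------------------------------------------------------

def _forward(model: SegModel, x_t: nn.Tensor, use_landmarks: bool,
             sigma: float):
    """One generator forward pass; returns (y_pre, landmark tensors)."""
    feats = model.encoder(x_t)
    r_t = prob = None
    mgm = None
    if use_landmarks:
        heads = model.landmark_head(feats.m3)
        k, h, w = heads.shape[1:]
        prob = spatial_softmax_t(heads.reshape(k, h, w))
        r_t = soft_argmax_t(prob)
        mgm = render_gaussian_map_t(r_t, (h, w), sigma).reshape(1, k, h, w)
    mt = model.bottleneck(feats.m3)
    y_pre = model.decoder(feats, mt, mgm)
    return y_pre, r_t, feats


def _landmarks_of(model: SegModel, arr: np.ndarray):
    """Landmark coordinates (Tensor (K, 2)) plus the deep encoder feature
    map (C3, h, w) of a raster; descriptors are sampled from the latter."""
    if arr.ndim == 2:
        arr = np.stack([arr.astype(np.float32)] * 3, axis=-1)
    feats = model.encoder(image_to_tensor(arr))
    heads = model.landmark_head(feats.m3)
    k, h, w = heads.shape[1:]
    coords = soft_argmax_t(spatial_softmax_t(heads.reshape(k, h, w)))
    c3 = feats.m3.shape[1]
    return coords, feats.m3.reshape(c3, h, w)


def train(pairs: list[SamplePair], cfg: TrainConfig,
          out_dir: str | None = None) -> TrainResult:
    """Train a segmentation model on image/mask pairs.

    Per iteration (one image): resize to the training resolution, run the
    generator forward pass, assemble the active loss components, update the
    discriminator (if the adversarial weight is positive) and then the
    generator.  Weights that are exactly zero skip their branch and consume
    no randomness, so runs with reduced objectives remain bit-comparable.
    Writes ``losses.csv`` and a checkpoint when `out_dir` is given.
    """
    if not pairs:
        raise ValueError("training set is empty")
    w = cfg.weights
    net_cfg = cfg.net_config()
    model = SegModel(net_cfg)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    disc = opt_d = None
    if w.adv > 0:
        disc = Discriminator(seed=cfg.seed + 1)
        d_lr = cfg.d_lr if cfg.d_lr is not None else cfg.lr / 10
        opt_d = nn.Adam(disc.parameters(), lr=d_lr,
                        weight_decay=cfg.weight_decay)
    rng_order = np.random.default_rng(cfg.seed + 2)
    rng_views = np.random.default_rng(cfg.seed + 3)
    use_lmk = cfg.variant == "transunet_sld"
    sigma = net_cfg.gaussian_sigma
    resized = [resize_pair(p, cfg.image_size) for p in pairs]
    rows = []
    it = 0
    for epoch in range(cfg.epochs):
        order = rng_order.permutation(len(resized))
        for idx in order:
            pair = resized[int(idx)]
            x_t = image_to_tensor(pair.image)
            y_t = nn.Tensor(pair.mask.astype(np.float32)[None, None])
            y_pre, r_t, feats = _forward(model, x_t, use_lmk, sigma)

            comps: dict[str, nn.Tensor] = {"seg": seg_loss(y_pre, y_t)}
            zero = nn.Tensor(np.float32(0.0))
            comps["adv"] = comps["ctr"] = comps["cst"] = comps["lmd"] = zero
            if w.adv > 0:
                l_d, l_g = adversarial_losses(disc, y_t, y_pre)
                if it % cfg.d_interval == 0:
                    opt_d.zero_grad()
                    l_d.backward()
                    opt_d.step()
                comps["adv"] = l_g
            if use_lmk and w.pseudo > 0:
                ry_t, _ = _landmarks_of(model, pair.mask)
                comps["lmd"] = landmark_loss(r_t, ry_t.detach(),
                                             matching=cfg.landmark_matching)
            if use_lmk and w.selfsup > 0:
                h2, w2 = pair.shape
                aff = sample_affine(
                    int(rng_views.integers(0, 2**31 - 1)),
                    cfg.max_rotation, cfg.max_scale_dev, cfg.max_shear,
                    cfg.max_translate, centre=(h2 / 2, w2 / 2))
                warped = apply_affine_image(aff, pair.image, order=1)
                r_a, _ = _landmarks_of(model, warped)
                comps["cst"] = consistency_loss(r_t, r_a, aff.in_units(4.0))
                styled = style_transform(
                    pair.image, int(rng_views.integers(0, 2**31 - 1)),
                    amplitude=cfg.style_amplitude)
                r_s, feat_s = _landmarks_of(model, styled)
                c3 = feats.m3.shape[1]
                h4, w4 = feats.m3.shape[2:]
                feat_o = feats.m3.reshape(c3, h4, w4)
                desc_o = sample_descriptors(feat_o, r_t.data)
                desc_s = sample_descriptors(feat_s, r_s.data)
                comps["ctr"] = contrastive_loss(desc_o, desc_s,
                                                cfg.temperature)

            total_t = (comps["seg"] * w.seg + comps["adv"] * w.adv
                       + (comps["ctr"] + comps["cst"]) * w.selfsup
                       + comps["lmd"] * w.pseudo)
            bundle = total_loss(**{k: v.item() for k, v in comps.items()},
                                weights=w)
            if not math.isfinite(bundle.total):
                if out_dir:
                    save_checkpoint(model, net_cfg,
                                    os.path.join(out_dir, "diverged.ckpt"))
                raise RuntimeError(
                    f"loss diverged at epoch {epoch} iteration {it}: {bundle}")
            opt.zero_grad()
            total_t.backward()
            opt.step()
            rows.append(dict(iteration=it, epoch=epoch, id=pair.id,
                             seg=bundle.seg, adv=bundle.adv, ctr=bundle.ctr,
                             cst=bundle.cst, lmd=bundle.lmd,
                             total=bundle.total))
            it += 1
    history = pd.DataFrame(rows)
    ckpt_path = None
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        history.to_csv(os.path.join(out_dir, "losses.csv"), index=False)
        ckpt_path = os.path.join(out_dir, "model.ckpt")
        save_checkpoint(model, net_cfg, ckpt_path)
    return TrainResult(model=model, history=history, checkpoint_path=ckpt_path)


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(model: SegModel, cfg: NetConfig, path: str) -> None:
    state = model.state_dict()
    meta = json.dumps(asdict(cfg))
    np.savez(path if path.endswith(".npz") else path + ".npz",
             __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)
    if not path.endswith(".npz") and os.path.exists(path + ".npz"):
        os.replace(path + ".npz", path)


def load_checkpoint(path: str) -> tuple[SegModel, NetConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    meta["transformer"] = TransformerConfig(**meta["transformer"])
    meta["channels"] = tuple(meta["channels"])
    cfg = NetConfig(**meta)
    model = SegModel(cfg)
    model.load_state_dict(state)
    return model, cfg
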