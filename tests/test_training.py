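"""Composite objective: closed forms, recomposition, training loop."""

import math

import numpy as np
import pytest

from lavs import nn
from lavs.data import resize_pair
from lavs.model import SegModel, image_to_tensor
from lavs.training import (Discriminator, LossBundle, LossWeights,
                           TrainConfig, adversarial_losses, landmark_loss,
                           load_checkpoint, seg_loss, total_loss, train,
                           _forward)

from conftest import synth_pair, tiny_net


class QueueD:
    """Stub discriminator returning scripted outputs in call order."""

    def __init__(self, outputs):
        self.outputs = list(outputs)

    def __call__(self, _):
        return nn.Tensor(np.array([[self.outputs.pop(0)]], dtype=np.float32))


def test_seg_loss_perfect_half_and_disjoint(rng):
    y = (rng.uniform(0, 1, (16, 16)) > 0.7).astype(np.float32)
    eps = 1e-7
    perfect = seg_loss(np.clip(y, eps, 1 - eps), y).item()
    assert perfect < 1e-4
    # flat 0.5 prediction: BCE term is exactly ln 2
    half = seg_loss(np.full_like(y, 0.5), y).item()
    inter = 0.5 * y.sum()
    dice = (2 * inter + 1e-6) / (0.5 * y.size + y.sum() + 1e-6)
    assert half == pytest.approx(math.log(2) + (1 - dice), abs=1e-5)
    # fully disjoint prediction drives the Dice term to 1
    disjoint = seg_loss(np.clip(1 - y, eps, 1 - eps), y).item()
    bce_big = disjoint - 1.0
    assert bce_big > 10                      # confident and wrong
    assert seg_loss(np.full_like(y, 0.5), y)  # shapes fine
    with pytest.raises(ValueError):
        seg_loss(np.zeros((4, 4)), np.zeros((5, 5)))


def test_adversarial_closed_forms():
    y = np.ones((8, 8), dtype=np.float32)
    y_pre = np.zeros((8, 8), dtype=np.float32)
    l_d, _ = adversarial_losses(QueueD([1.0, 0.0, 0.0]), y, y_pre)
    assert l_d.item() < 1e-4                 # perfect discrimination
    l_d, l_g = adversarial_losses(QueueD([0.5, 0.5, 0.5]), y, y_pre)
    assert l_d.item() == pytest.approx(2 * math.log(2), abs=1e-6)
    assert l_g.item() == pytest.approx(math.log(2), abs=1e-6)


def test_generator_loss_monotone_in_fooling():
    y = np.ones((4, 4), dtype=np.float32)
    values = [adversarial_losses(QueueD([0.5, 0.5, d]), y, y)[1].item()
              for d in [0.1, 0.3, 0.5, 0.7, 0.9]]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_real_discriminator_outputs_probability(rng):
    d = Discriminator(seed=0)
    out = d(nn.Tensor(rng.uniform(0, 1, (1, 1, 32, 32)).astype(np.float32)))
    assert out.shape == (1, 1)
    assert 0 < out.item() < 1


def test_landmark_loss_values_and_symmetry():
    r = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert landmark_loss(r, r).item() == 0
    offset = landmark_loss(r, r + [3.0, 4.0]).item()
    assert offset == pytest.approx(25.0)
    assert landmark_loss(r, r + 1).item() == \
        pytest.approx(landmark_loss(r + 1, r).item())
    with pytest.raises(ValueError):
        landmark_loss(r, r[:1])


def test_landmark_loss_sinkhorn_matching():
    """The transport variant ignores a permutation of the pseudo-labels;
    the indexed variant does not."""
    r = np.array([[1.0, 1.0], [10.0, 2.0], [5.0, 12.0]])
    assert landmark_loss(r, r, matching="sinkhorn").item() < 1e-3
    permuted = r[[2, 0, 1]]
    indexed = landmark_loss(r, permuted).item()
    transported = landmark_loss(r, permuted, matching="sinkhorn").item()
    assert transported < 0.1 * indexed
    with pytest.raises(ValueError):
        landmark_loss(r, r, matching="hungarian")


def test_total_loss_recomposition_and_linearity():
    bundle = total_loss(1, 1, 1, 1, 1)
    assert bundle.total == pytest.approx(0.2 + 0.3 + 0.4 * 2 + 0.1)
    zero = total_loss(1, 1, 1, 1, 1, weights=LossWeights(0, 0, 0, 0))
    assert zero.total == 0
    base = total_loss(1.0, 2.0, 0.5, 0.25, 3.0).total
    bumped = total_loss(1.0, 2.0 + 1.0, 0.5, 0.25, 3.0).total
    assert bumped - base == pytest.approx(0.3)
    with pytest.raises(ValueError, match="adv"):
        total_loss(1.0, float("nan"))
    with pytest.raises(ValueError):
        LossBundle(seg=1, adv=1, ctr=1, cst=1, lmd=1, total=99.0)


def test_train_bookkeeping_and_checkpoint(tmp_path):
    pairs = [synth_pair(s, size=32) for s in range(4)]
    cfg = TrainConfig(image_size=(32, 32), epochs=1, seed=3,
                      variant="transunet_sld", net=tiny_net(seed=3))
    result = train(pairs, cfg, out_dir=str(tmp_path))
    assert len(result.history) == 4
    assert (tmp_path / "losses.csv").exists()
    model, cfg_loaded = load_checkpoint(result.checkpoint_path)
    assert cfg_loaded.variant == "transunet_sld"
    x = pairs[0].image
    from lavs.model import forward_segment
    assert np.array_equal(forward_segment(x, model),
                          forward_segment(x, result.model))
    with pytest.raises(ValueError):
        train([], cfg)


def test_unet_variant_logs_zero_landmark_losses():
    pairs = [synth_pair(s, size=32) for s in range(2)]
    cfg = TrainConfig(image_size=(32, 32), epochs=1, seed=1, variant="unet",
                      net=tiny_net(variant="unet", seed=1))
    result = train(pairs, cfg)
    assert (result.history[["ctr", "cst", "lmd"]].to_numpy() == 0).all()
    assert (result.history["adv"] > 0).all()


def test_loss_bundle_recomposition_every_iteration():
    pairs = [synth_pair(s, size=32) for s in range(2)]
    cfg = TrainConfig(image_size=(32, 32), epochs=2, seed=2,
                      variant="transunet_sld", net=tiny_net(seed=2))
    h = train(pairs, cfg).history
    w = cfg.weights
    recomposed = (w.seg * h.seg + w.adv * h.adv
                  + w.selfsup * (h.ctr + h.cst) + w.pseudo * h.lmd)
    assert np.abs(recomposed - h.total).max() < 1e-6


def test_seg_only_training_equals_composite_with_zero_weights():
    """With the adversarial, self-supervised and pseudo-label weights at
    zero, the full loop's parameter updates must be bit-identical to plain
    Dice+BCE training under the same seed."""
    pairs = [synth_pair(s, size=32) for s in range(2)]
    net = tiny_net(seed=5)
    weights = LossWeights(seg=0.2, adv=0.0, selfsup=0.0, pseudo=0.0)
    cfg = TrainConfig(image_size=(32, 32), epochs=2, seed=5,
                      variant="transunet_sld", net=net, weights=weights)
    result = train(pairs, cfg)

    # independent reference: plain seg-loss loop, same seed and init
    model = SegModel(net)
    opt = nn.Adam(model.parameters(), lr=cfg.lr,
                  weight_decay=cfg.weight_decay)
    rng_order = np.random.default_rng(cfg.seed + 2)
    resized = [resize_pair(p, (32, 32)) for p in pairs]
    for _ in range(cfg.epochs):
        for idx in rng_order.permutation(len(resized)):
            pair = resized[int(idx)]
            y_pre, _, _ = _forward(model, image_to_tensor(pair.image), True,
                                   net.gaussian_sigma)
            y_t = nn.Tensor(pair.mask.astype(np.float32)[None, None])
            loss = seg_loss(y_pre, y_t) * weights.seg
            opt.zero_grad()
            loss.backward()
            opt.step()
    ours = dict(result.model.named_parameters())
    for name, p in model.named_parameters():
        assert np.array_equal(p.data, ours[name].data), name
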