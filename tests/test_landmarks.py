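"""Landmark pipeline: spatial softmax, soft-argmax, consistency,
contrastive descriptors and Gaussian heatmaps."""

import numpy as np
import pytest

from lavs import nn
from lavs.landmarks import (LandmarkSet, ProbabilityMaps, consistency_loss,
                            contrastive_loss, extract_landmarks,
                            project_heads, render_gaussian_map,
                            sample_descriptors, scalar_gaussian_map,
                            soft_argmax, soft_argmax_t, spatial_softmax,
                            spatial_softmax_t)
from lavs.model import SegModel, image_to_tensor
from lavs.synthetic import AffineTransform, sample_affine

from conftest import tiny_net


def test_spatial_softmax_uniform_peaked_and_shift_invariant(rng):
    uniform = spatial_softmax(np.zeros((1, 2, 2)))
    assert np.allclose(uniform.maps, 0.25)
    peaked = np.zeros((1, 4, 4))
    peaked[0, 1, 2] = 20.0
    out = spatial_softmax(peaked)
    assert out.maps[0, 1, 2] > 0.999
    x = rng.normal(size=(3, 8, 8))
    assert np.allclose(spatial_softmax(x).maps,
                       spatial_softmax(x + 7.5).maps, atol=1e-7)


def test_spatial_softmax_matches_exhaustive_exp_sum(rng):
    x = rng.normal(size=(4, 8, 8))
    got = spatial_softmax(x).maps
    for c in range(4):
        expect = np.exp(x[c]) / np.exp(x[c]).sum()   # direct oracle
        assert np.abs(got[c] - expect).max() < 1e-6
    assert np.abs(got.sum(axis=(1, 2)) - 1).max() < 1e-5


def test_probability_maps_validation():
    with pytest.raises(ValueError):
        ProbabilityMaps(maps=np.full((1, 2, 2), 0.3))
    with pytest.raises(ValueError):
        ProbabilityMaps(maps=np.array([[[1.5, -0.5], [0.0, 0.0]]]))


def test_soft_argmax_delta_uniform_and_brute_force(rng):
    onehot = np.zeros((1, 8, 8))
    onehot[0, 3, 5] = 1.0
    assert np.allclose(soft_argmax(onehot).coords, [[3.0, 5.0]])
    uniform = np.full((1, 6, 10), 1 / 60)
    assert np.allclose(soft_argmax(uniform).coords, [[2.5, 4.5]])
    raw = rng.uniform(0.1, 1, (3, 7, 5))
    maps = raw / raw.sum(axis=(1, 2), keepdims=True)
    got = soft_argmax(maps).coords
    rows, cols = np.mgrid[:7, :5]
    for c in range(3):   # exhaustive-sum oracle
        expect = [(maps[c] * rows).sum(), (maps[c] * cols).sum()]
        assert np.abs(got[c] - expect).max() < 1e-6


def test_soft_argmax_equivariant_to_integer_translation(rng):
    raw = np.zeros((1, 16, 16))
    rr, cc = np.mgrid[:16, :16]
    raw[0] = np.exp(-((rr - 8) ** 2 + (cc - 7) ** 2) / 2.0)
    maps = raw / raw.sum()
    base = soft_argmax(maps).coords[0]
    moved = np.roll(maps, (3, -2), axis=(1, 2))
    got = soft_argmax(moved).coords[0]
    assert np.abs(got - (base + [3, -2])).max() < 0.05


def test_consistency_loss_zero_offset_and_mismatch():
    pts = np.array([[2.0, 3.0], [5.0, 1.0], [4.0, 4.0]])
    for seed in range(10):
        a = sample_affine(seed, 15, 0.1, 0.1, 3)
        warped = a.apply_points(pts)
        assert consistency_loss(pts, warped, a).item() < 1e-9
    ident = AffineTransform.identity()
    offset = consistency_loss(pts, pts + [1.0, 0.0], ident)
    assert offset.item() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        consistency_loss(pts, pts[:2], ident)


def test_contrastive_loss_alignment_shuffle_and_brute_force(rng):
    desc = np.eye(3, 4) * 5          # well-separated rows
    aligned = contrastive_loss(desc, desc, temperature=0.05).item()
    assert aligned < 1e-3
    shuffled = contrastive_loss(desc, desc[[1, 2, 0]], temperature=0.05).item()
    assert shuffled > aligned
    # exhaustive enumeration oracle at K=3, d=2
    a = rng.normal(size=(3, 2))
    b = rng.normal(size=(3, 2))
    tau = 0.3
    za = a / np.linalg.norm(a, axis=1, keepdims=True)
    zb = b / np.linalg.norm(b, axis=1, keepdims=True)
    z = np.vstack([za, zb])
    sim = z @ z.T / tau
    losses = []
    for i in range(6):
        pos = (i + 3) % 6
        negs = [j for j in range(6) if j != i]
        mx = max(sim[i, j] for j in negs)
        lse = np.log(sum(np.exp(sim[i, j] - mx) for j in negs)) + mx
        losses.append(lse - sim[i, pos])
    expect = np.mean(losses)
    got = contrastive_loss(a, b, temperature=tau).item()
    assert got == pytest.approx(expect, abs=1e-5)
    assert got == pytest.approx(contrastive_loss(b, a, temperature=tau).item(),
                                abs=1e-6)
    with pytest.raises(ValueError):
        contrastive_loss(a[:1], b[:1], temperature=tau)


def test_sample_descriptors_bilinear(rng):
    feats = nn.Tensor(rng.normal(size=(4, 8, 8)).astype(np.float32))
    got = sample_descriptors(feats, np.array([[2.0, 3.0], [2.5, 3.0]]))
    assert np.allclose(got.data[0], feats.data[:, 2, 3], atol=1e-6)
    mid = 0.5 * (feats.data[:, 2, 3] + feats.data[:, 3, 3])
    assert np.allclose(got.data[1], mid, atol=1e-6)


def test_project_heads_shape_and_gradient_flow(pair64):
    model = SegModel(tiny_net())
    feats = model.encoder(image_to_tensor(pair64.image))
    heads = project_heads(feats.m3.data[0].transpose(1, 2, 0), model)
    assert heads.shape == (8, 16, 16)
    heads_t = model.landmark_head(feats.m3)
    coords = soft_argmax_t(spatial_softmax_t(
        heads_t.reshape(8, 16, 16)))
    coords.sum().backward()
    assert model.encoder.e1.c1.w.grad is not None
    assert np.all(np.isfinite(model.encoder.e1.c1.w.grad))
    model.zero_grad()


def test_extract_landmarks_deterministic_and_in_bounds(pair64):
    model = SegModel(tiny_net())
    lm1 = extract_landmarks(pair64.image, model)
    lm2 = extract_landmarks(pair64.image, model)
    assert np.array_equal(lm1.coords, lm2.coords)
    assert len(lm1) == 8
    assert (lm1.coords >= 0).all()
    assert (lm1.coords[:, 0] <= 15).all() and (lm1.coords[:, 1] <= 15).all()
    masked = extract_landmarks(pair64.mask.astype(float), model,
                               source="ground_truth")
    assert masked.source == "ground_truth"


def test_peaked_heads_recover_blob_centroid():
    """Near-one-hot probability maps land within a pixel of the blob."""
    rr, cc = np.mgrid[:16, :16]
    heads = np.stack([40 * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / 2.0)
                      for r0, c0 in [(4, 11), (10, 3)]])
    coords = soft_argmax(spatial_softmax(heads)).coords
    assert np.abs(coords - [[4, 11], [10, 3]]).max() < 1.0


def test_gaussian_map_values_and_argmax():
    lm = LandmarkSet(coords=np.array([[4.0, 4.0], [2.3, 7.8]]))
    maps = render_gaussian_map(lm, (16, 16), sigma=0.7)
    assert maps[0, 4, 4] == pytest.approx(1.0)
    assert maps.min() > 0 and maps.max() <= 1.0
    # closed form at distance sigma (landmark placed a grid-aligned sigma away)
    lm_s = LandmarkSet(coords=np.array([[4.0 - 0.7, 4.0]]))
    at_site = render_gaussian_map(lm_s, (16, 16), sigma=0.7)[0, 4, 4]
    assert at_site == pytest.approx(np.exp(-0.5), abs=1e-6)
    # argmax-scan oracle: channel max sits at the nearest grid site
    idx = np.unravel_index(np.argmax(maps[1]), (16, 16))
    assert idx == (2, 8)
    with pytest.raises(ValueError):
        render_gaussian_map(lm, (16, 16), sigma=0.0)


def test_gaussian_map_decreases_with_distance():
    maps = render_gaussian_map(LandmarkSet(coords=np.array([[8.0, 8.0]])),
                               (17, 17), sigma=0.7)[0]
    row = maps[8, 8:]
    assert np.all(np.diff(row) < 0)


def test_scalar_gaussian_reading():
    r = np.array([[1.0, 1.0], [2.0, 2.0]])
    ry = np.array([[1.0, 1.0], [2.0, 2.7]])
    vals = scalar_gaussian_map(r, ry, sigma=0.7)
    assert vals[0] == pytest.approx(1.0)
    assert vals[1] == pytest.approx(np.exp(-0.5))
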