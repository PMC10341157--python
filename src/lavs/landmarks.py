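"""Self-supervised landmark detection on encoder features.

A 1x1 projection maps the deepest encoder features (H/4 x W/4 x C3) to K
response channels.  Each channel is turned into a spatial probability
distribution by a softmax over all sites (spatial softmax) and read out as
a continuous (row, col) coordinate by soft-argmax — the probability-
weighted mean of site coordinates, which keeps the whole pipeline
differentiable.  Landmarks are made meaningful without any annotation by
three signals: an equivariance (consistency) penalty under random affine
warps, a contrastive objective across photometric "style" views, and a
pseudo-label regression toward landmarks extracted from the ground-truth
mask through the shared encoder.  For the decoder, landmarks are rendered
as K Gaussian heatmaps on the feature grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .synthetic import AffineTransform

__all__ = [
    "ProbabilityMaps", "LandmarkSet", "project_heads", "spatial_softmax",
    "soft_argmax", "consistency_loss", "contrastive_loss",
    "extract_landmarks", "render_gaussian_map", "scalar_gaussian_map",
    "spatial_softmax_t", "soft_argmax_t", "render_gaussian_map_t",
    "sample_descriptors",
]


@dataclass(frozen=True)
class ProbabilityMaps:
    """K per-channel spatial distributions over an h x w grid."""

    maps: np.ndarray     # (K, h, w), rows sum to 1 per channel

    def __post_init__(self):
        m = np.asarray(self.maps, dtype=np.float64)
        if m.ndim != 3:
            raise ValueError(f"expected (K, h, w) maps, got {m.shape}")
        if m.min() < 0:
            raise ValueError("probability maps must be non-negative")
        sums = m.sum(axis=(1, 2))
        if np.abs(sums - 1).max() > 1e-5:
            raise ValueError("each channel must sum to 1 within 1e-5")
        object.__setattr__(self, "maps", m)


@dataclass(frozen=True)
class LandmarkSet:
    """K ordered continuous (row, col) coordinates in feature-grid units."""

    coords: np.ndarray   # (K, 2)
    source: str = "image"    # image | ground_truth

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=np.float64)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError(f"expected (K, 2) coordinates, got {c.shape}")
        object.__setattr__(self, "coords", c)

    def __len__(self):
        return self.coords.shape[0]


def _as_khw(x) -> nn.Tensor:
    if isinstance(x, nn.Tensor):
        return x
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError(f"expected (K, h, w), got {arr.shape}")
    return nn.Tensor(arr)


# -- tensor-level core (differentiable) ----------------------------------

def spatial_softmax_t(heads: nn.Tensor) -> nn.Tensor:
    """Per-channel softmax over all h*w sites; (K, h, w) -> (K, h, w)."""
    k, h, w = heads.shape
    flat = heads.reshape(k, h * w)
    return nn.softmax(flat, axis=-1).reshape(k, h, w)


def soft_argmax_t(p: nn.Tensor) -> nn.Tensor:
    """Expected (row, col) per channel; (K, h, w) -> (K, 2)."""
    k, h, w = p.shape
    rows = nn.Tensor(np.arange(h, dtype=np.float32)[None, :, None])
    cols = nn.Tensor(np.arange(w, dtype=np.float32)[None, None, :])
    r = (p * rows).sum(axis=(1, 2))
    c = (p * cols).sum(axis=(1, 2))
    return nn.stack([r, c], axis=1)


def render_gaussian_map_t(coords: nn.Tensor, grid: tuple[int, int],
                          sigma: float = 0.7) -> nn.Tensor:
    """K isotropic Gaussian heatmaps centred at `coords`; peak value <= 1."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    h, w = grid
    rows = nn.Tensor(np.arange(h, dtype=np.float32)[None, :, None])
    cols = nn.Tensor(np.arange(w, dtype=np.float32)[None, None, :])
    k = coords.shape[0]
    cr = coords[:, 0:1].reshape(k, 1, 1)
    cc = coords[:, 1:2].reshape(k, 1, 1)
    d2 = (rows - cr) ** 2.0 + (cols - cc) ** 2.0
    return (d2 * (-1.0 / (2.0 * sigma * sigma))).exp()


def consistency_loss(r_orig, r_warped, a: AffineTransform):
    """Mean squared distance between R and A^-1(R'), the equivariance
    penalty: landmarks of the warped view, mapped back through the inverse
    affine, should land on the original landmarks."""
    r_orig = _coords_tensor(r_orig)
    r_warped = _coords_tensor(r_warped)
    if r_orig.shape != r_warped.shape:
        raise ValueError(
            f"landmark count mismatch: {r_orig.shape[0]} vs {r_warped.shape[0]}")
    inv = a.invert()
    binv = nn.Tensor(inv.linear.T.astype(np.float32))
    tinv = nn.Tensor(inv.translation.astype(np.float32))
    back = r_warped @ binv + tinv
    d = r_orig - back
    return (d * d).sum(axis=1).mean()


def contrastive_loss(desc_a, desc_b, temperature: float = 0.5):
    """NT-Xent over per-landmark descriptors of two views.

    Descriptors are L2-normalised; the positive for landmark i in one view
    is landmark i in the other view, every other landmark in either view is
    a negative.  Symmetric in (a, b).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    da = desc_a if isinstance(desc_a, nn.Tensor) else nn.astensor(desc_a)
    db = desc_b if isinstance(desc_b, nn.Tensor) else nn.astensor(desc_b)
    if da.shape != db.shape:
        raise ValueError("descriptor shapes must match")
    k = da.shape[0]
    if k < 2:
        raise ValueError("need at least 2 landmarks for negatives")
    z = nn.concat([da, db], axis=0)                      # (2K, d)
    norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12) ** -0.5
    z = z * norm
    sim = (z @ z.transpose(1, 0)) * (1.0 / temperature)  # (2K, 2K)
    diag = nn.Tensor(np.eye(2 * k, dtype=np.float32) * -1e9)
    logits = sim + diag
    # stable log-sum-exp per row (max detached; constant shift)
    shift = nn.Tensor(logits.data.max(axis=-1, keepdims=True))
    lse = (logits - shift).exp().sum(axis=-1, keepdims=True).log() + shift
    anchors = np.arange(2 * k)
    positives = np.concatenate([np.arange(k, 2 * k), np.arange(k)])
    return (lse.reshape(2 * k) - logits[anchors, positives]).mean()


def sample_descriptors(features: nn.Tensor, coords: np.ndarray) -> nn.Tensor:
    """Bilinearly sample (C, h, w) features at (K, 2) coordinates -> (K, C).

    Coordinates are treated as constants: the gradient flows through the
    feature values only.
    """
    c, h, w = features.shape
    pts = np.asarray(coords, dtype=np.float64)
    r = np.clip(pts[:, 0], 0, h - 1)
    cc = np.clip(pts[:, 1], 0, w - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(cc).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (r - r0).astype(np.float32)
    fc = (cc - c0).astype(np.float32)
    w00 = nn.Tensor(((1 - fr) * (1 - fc))[None, :])
    w01 = nn.Tensor(((1 - fr) * fc)[None, :])
    w10 = nn.Tensor((fr * (1 - fc))[None, :])
    w11 = nn.Tensor((fr * fc)[None, :])
    v = (nn.gather_hw(features, r0, c0) * w00 +
         nn.gather_hw(features, r0, c1) * w01 +
         nn.gather_hw(features, r1, c0) * w10 +
         nn.gather_hw(features, r1, c1) * w11)           # (C, K)
    return v.transpose(1, 0)


def _coords_tensor(r) -> nn.Tensor:
    if isinstance(r, nn.Tensor):
        return r
    if isinstance(r, LandmarkSet):
        return nn.Tensor(r.coords.astype(np.float32))
    return nn.astensor(np.asarray(r, dtype=np.float32))


# -- numpy-level front-ends -----------------------------------------------

def project_heads(m3, model, k: int | None = None) -> np.ndarray:
    """1x1 projection of an (h, w, C3) feature raster to (K, h, w) heads."""
    t = nn.Tensor(np.asarray(m3, dtype=np.float32).transpose(2, 0, 1)[None])
    out = model.landmark_head(t)
    return out.data[0]


def spatial_softmax(heads) -> ProbabilityMaps:
    t = _as_khw(heads)
    return ProbabilityMaps(maps=spatial_softmax_t(t).data.astype(np.float64))


def soft_argmax(p) -> LandmarkSet:
    maps = p.maps if isinstance(p, ProbabilityMaps) else np.asarray(p)
    t = nn.Tensor(maps.astype(np.float32))
    return LandmarkSet(coords=soft_argmax_t(t).data.astype(np.float64))


def extract_landmarks(x: np.ndarray, model, source: str = "image",
                      return_tensors: bool = False):
    """Image (or mask) raster -> K landmarks on the H/4 grid.

    A 2-D binary mask (the ground-truth path producing pseudo-label
    landmarks) is replicated to three channels before encoding; the encoder
    weights are shared with the segmentation branch.
    """
    from .model import image_to_tensor
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    feats = model.encoder(image_to_tensor(arr))
    heads = model.landmark_head(feats.m3)
    k = heads.shape[1]
    h, w = heads.shape[2:]
    prob = spatial_softmax_t(heads.reshape(k, h, w))
    coords = soft_argmax_t(prob)
    if return_tensors:
        return coords, prob, feats
    return LandmarkSet(coords=coords.data.astype(np.float64), source=source)


def render_gaussian_map(r, grid: tuple[int, int],
                        sigma: float = 0.7) -> np.ndarray:
    """(K, h, w) Gaussian heatmaps for a LandmarkSet or (K, 2) array.

    Computed in float64 so far-field values stay strictly positive on the
    grid sizes in use (float32 underflows beyond ~17 grid units at the
    default sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    c = r.coords if isinstance(r, LandmarkSet) else np.asarray(r, np.float64)
    h, w = grid
    rows = np.arange(h, dtype=np.float64)[None, :, None]
    cols = np.arange(w, dtype=np.float64)[None, None, :]
    d2 = (rows - c[:, 0:1, None]) ** 2 + (cols - c[:, 1:2, None]) ** 2
    return np.exp(-d2 / (2.0 * sigma * sigma))


def scalar_gaussian_map(r, ry, sigma: float = 0.7) -> np.ndarray:
    """Alternative scalar reading: per-landmark exp(-||R - RY||^2 / 2s^2),
    a K-vector measuring predicted/pseudo-label landmark agreement."""
    rc = r.coords if isinstance(r, LandmarkSet) else np.asarray(r, float)
    ryc = ry.coords if isinstance(ry, LandmarkSet) else np.asarray(ry, float)
    if rc.shape != ryc.shape:
        raise ValueError("landmark count mismatch")
    d2 = ((rc - ryc) ** 2).sum(axis=1)
    return np.exp(-d2 / (2 * sigma ** 2))
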