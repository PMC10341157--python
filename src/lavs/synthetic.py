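"""Synthetic fundus images with known vessel ground truth.

Fundus photographs show a branching vascular tree, darker than the retinal
background, inside a circular field of view (FOV) on a near-black surround.
This module emulates exactly those properties — a recursive branching tree
with controllable thin-vessel content, low and tunable vessel/background
contrast, and sensor noise — so that the segmentation framework can be
trained and evaluated end to end without any external dataset.  It also
provides the photometric ("style") and geometric (affine) perturbations the
self-supervised landmark branch trains against.

It makes no attempt at photorealism: there is no optic disc, no macula, no
pathology, and the background is a smooth vignette rather than retinal
texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as _disk
from skimage.draw import line as _line

__all__ = [
    "VesselTreeParams", "AffineTransform", "generate_vessel_mask",
    "render_fundus", "style_transform", "sample_affine",
    "apply_affine_points", "apply_affine_image",
    "FOV_RADIUS_FRACTION", "VESSEL_DEPTH", "CHANNEL_GAIN", "CHANNEL_OFFSET",
]

# Fundus geometry: FOV disc radius as a fraction of min(H, W), centred.
FOV_RADIUS_FRACTION = 0.48
# Gray-level gap between background and vessel pixels at contrast=1.
VESSEL_DEPTH = 0.40
# Per-channel affine map from the gray template to RGB (red-dominant tint).
CHANNEL_GAIN = (1.0, 0.9, 0.7)
CHANNEL_OFFSET = (0.10, 0.02, 0.0)


@dataclass(frozen=True)
class VesselTreeParams:
    """Parameters of the recursive branching vessel tree."""

    seed: int = 0
    canvas_size: tuple[int, int] = (128, 128)
    n_roots: int = 2
    max_depth: int = 5
    root_width: float = 3.0
    width_decay: float = 0.75
    tortuosity: float = 0.12
    thin_fraction: float = 0.35

    def __post_init__(self):
        h, w = self.canvas_size
        if h < 32 or w < 32:
            raise ValueError(f"canvas_size must be at least 32x32, got {h}x{w}")
        if self.n_roots < 1:
            raise ValueError("n_roots must be >= 1")
        if not 0 < self.width_decay < 1:
            raise ValueError("width_decay must be in (0, 1)")
        if not 0 <= self.thin_fraction <= 1:
            raise ValueError("thin_fraction must be in [0, 1]")
        if self.root_width < 1:
            raise ValueError("root_width must be >= 1 px")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


@dataclass(frozen=True)
class AffineTransform:
    """2x3 matrix acting homogeneously on (row, col) coordinates."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) <= 1e-8:
            raise ValueError("affine linear block is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.linear))

    def invert(self) -> "AffineTransform":
        binv = np.linalg.inv(self.linear)
        return AffineTransform(np.hstack([binv, (-binv @ self.translation)[:, None]]))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self o other)(p) = self(other(p))."""
        b = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        return AffineTransform(np.hstack([b, t[:, None]]))

    def in_units(self, scale: float) -> "AffineTransform":
        """The same map expressed in coordinates divided by `scale`
        (e.g. scale=4 converts a pixel-space map to the H/4 feature grid)."""
        return AffineTransform(
            np.hstack([self.linear, (self.translation / scale)[:, None]]))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return pts @ self.linear.T + self.translation


def apply_affine_points(a: AffineTransform, pts) -> np.ndarray:
    """Map (K, 2) (row, col) points through `a`."""
    if hasattr(pts, "coords"):
        pts = pts.coords
    return a.apply_points(pts)


def apply_affine_image(a: AffineTransform, img: np.ndarray,
                       order: int | None = None) -> np.ndarray:
    """Warp an image so that content at p moves to a(p).

    Bilinear resampling for intensity images, nearest for binary masks
    (auto-detected when `order` is None); out-of-bounds filled with 0.
    """
    img = np.asarray(img)
    if order is None:
        binary = img.dtype == bool or (
            img.dtype.kind in "ui" or set(np.unique(img)) <= {0.0, 1.0})
        order = 0 if binary else 1
    inv = a.invert()
    kwargs = dict(matrix=inv.linear, offset=inv.linear @ -a.translation,
                  order=order, mode="constant", cval=0.0)
    if img.ndim == 2:
        return ndi.affine_transform(img.astype(np.float64), **kwargs).astype(img.dtype) \
            if order == 0 else ndi.affine_transform(img, **kwargs)
    out = np.stack([ndi.affine_transform(img[..., c].astype(np.float64), **kwargs)
                    for c in range(img.shape[-1])], axis=-1)
    return out.astype(img.dtype) if order == 0 else out


# -- vessel tree ----------------------------------------------------------

def _midpoint_polyline(p0, p1, rng, amp, depth=3):
    """Midpoint-displaced polyline from p0 to p1 (fractal jitter)."""
    pts = [np.asarray(p0, float), np.asarray(p1, float)]
    for _ in range(depth):
        nxt = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            mid = (a + b) / 2
            seg = b - a
            normal = np.array([-seg[1], seg[0]])
            nrm = np.linalg.norm(normal)
            if nrm > 1e-9:
                mid = mid + normal / nrm * rng.normal(0, amp * nrm / 2)
            nxt.extend([mid, b])
        pts = nxt
    return np.array(pts)


def _stamp_polyline(canvas, pts, width):
    """Rasterise a polyline with the given stroke width onto `canvas`."""
    h, w = canvas.shape
    if width <= 1.2:
        for a, b in zip(pts[:-1], pts[1:]):
            rr, cc = _line(int(round(a[0])), int(round(a[1])),
                           int(round(b[0])), int(round(b[1])))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            canvas[rr[keep], cc[keep]] = 1
        return
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(b - a) * 2)))
        for t in np.linspace(0, 1, n):
            p = a + t * (b - a)
            if -width <= p[0] <= h + width and -width <= p[1] <= w + width:
                rr, cc = _disk((p[0], p[1]), max(width / 2, 0.8), shape=(h, w))
                canvas[rr, cc] = 1


def _grow_branch(canvas, rng, start, angle, length, width, depth, params):
    h, w = canvas.shape
    end = start + length * np.array([np.sin(angle), np.cos(angle)])
    # keep growth inside the FOV disc
    centre = np.array([h / 2, w / 2])
    radius = FOV_RADIUS_FRACTION * min(h, w)
    if np.linalg.norm(end - centre) > radius - 2:
        d = end - centre
        end = centre + d / np.linalg.norm(d) * (radius - 2)
    pts = _midpoint_polyline(start, end, rng, params.tortuosity)
    terminal = depth >= params.max_depth
    stroke = width
    if terminal and rng.uniform() < params.thin_fraction:
        stroke = 1.0
    _stamp_polyline(canvas, pts, stroke)
    if terminal:
        return
    spread = rng.uniform(0.3, 0.7)
    for sign in (-1.0, 1.0):
        child_angle = angle + sign * spread + rng.normal(0, 0.15)
        child_len = length * rng.uniform(0.6, 0.85)
        if child_len < 3:
            continue
        _grow_branch(canvas, rng, end, child_angle, child_len,
                     width * params.width_decay, depth + 1, params)


def generate_vessel_mask(params: VesselTreeParams) -> np.ndarray:
    """Binary (H, W) uint8 mask of a branching vessel tree.

    Each of the `n_roots` primary vessels enters from the FOV rim and
    branches recursively toward the interior; every tree is 8-connected by
    construction (children start exactly where the parent ends).
    Deterministic for a fixed parameter set.
    """
    h, w = params.canvas_size
    rng = np.random.default_rng(params.seed)
    canvas = np.zeros((h, w), dtype=np.uint8)
    centre = np.array([h / 2, w / 2])
    radius = FOV_RADIUS_FRACTION * min(h, w)
    for i in range(params.n_roots):
        theta = 2 * np.pi * (i / params.n_roots) + rng.uniform(-0.4, 0.4)
        start = centre + (radius - 3) * np.array([np.sin(theta), np.cos(theta)])
        inward = np.arctan2(centre[0] - start[0], centre[1] - start[1])
        length = radius * rng.uniform(0.55, 0.8)
        _grow_branch(canvas, rng, start, inward + rng.normal(0, 0.2),
                     length, params.root_width, 0, params)
    return canvas


def fov_mask(shape: tuple[int, int]) -> np.ndarray:
    """Binary circular field-of-view disc for the given (H, W)."""
    h, w = shape
    rr, cc = np.mgrid[:h, :w]
    radius = FOV_RADIUS_FRACTION * min(h, w)
    return (((rr - h / 2) ** 2 + (cc - w / 2) ** 2) <= radius ** 2).astype(np.uint8)


# -- photometric rendering ------------------------------------------------

def render_fundus(mask: np.ndarray, seed: int, contrast: float = 0.6,
                  noise_sd: float = 0.02) -> np.ndarray:
    """Render an RGB fundus-like image in [0, 1] from a binary vessel mask.

    Vessels are darker than the background by `VESSEL_DEPTH * contrast`
    gray levels (a constant offset, so the mean vessel/background gap inside
    the FOV is exactly monotone in `contrast`); a smooth vignette and seeded
    Gaussian pixel noise complete the picture.  Outside the FOV the image is
    near black.
    """
    mask = np.asarray(mask)
    if not set(np.unique(mask)) <= {0, 1}:
        raise ValueError("mask must be binary {0, 1}")
    if not 0 < contrast <= 1:
        raise ValueError("contrast must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    h, w = mask.shape
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[:h, :w]
    radius = FOV_RADIUS_FRACTION * min(h, w)
    r2 = ((rr - h / 2) ** 2 + (cc - w / 2) ** 2) / radius ** 2
    gray = 0.50 + 0.12 * np.clip(1 - r2, 0, 1)          # gentle vignette
    gray = gray + ndi.gaussian_filter(rng.normal(0, 1, (h, w)), h / 16) * 0.02
    gray = np.clip(gray, 0.45, 0.70)
    gray = gray - VESSEL_DEPTH * contrast * mask        # vessels darker
    img = np.stack([g * gray + o for g, o in zip(CHANNEL_GAIN, CHANNEL_OFFSET)],
                   axis=-1)
    fov = fov_mask((h, w)).astype(bool)
    img = np.where(fov[..., None], img, 0.02)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def expected_vessel_gap(contrast: float) -> float:
    """Mean (over RGB) background-minus-vessel intensity gap inside the FOV."""
    return VESSEL_DEPTH * contrast * float(np.mean(CHANNEL_GAIN))


# -- style (photometric) transform ---------------------------------------

def style_transform(image: np.ndarray, seed: int,
                    amplitude: float = 1.0) -> np.ndarray:
    """Seeded per-pixel photometric jitter standing in for a style change.

    Per-channel gamma in [0.7, 1.4], contrast scale in [0.8, 1.25] about
    mid-gray, brightness offset within +/-0.15, and channel mixing with
    off-diagonal terms within +/-0.1 — all interpolated toward identity by
    `amplitude` (amplitude=0 is the exact identity).  Purely per-pixel, so
    it commutes with cropping and displaces no geometry.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.7, 1.4, size=3)
    scale = rng.uniform(0.8, 1.25, size=3)
    offset = rng.uniform(-0.15, 0.15, size=3)
    mix = np.eye(3) + rng.uniform(-0.1, 0.1, size=(3, 3)) * (1 - np.eye(3))
    a = float(amplitude)
    gamma = 1 + a * (gamma - 1)
    scale = 1 + a * (scale - 1)
    offset = a * offset
    mix = np.eye(3) + a * (mix - np.eye(3))
    out = image ** gamma
    out = (out - 0.5) * scale + 0.5 + offset
    out = out @ mix.T
    return np.clip(out, 0.0, 1.0)


# -- affine sampling ------------------------------------------------------

def sample_affine(seed: int, max_rotation: float = 15.0,
                  max_scale_dev: float = 0.1, max_shear: float = 0.1,
                  max_translate: float = 5.0,
                  centre: tuple[float, float] | None = None) -> AffineTransform:
    """Random invertible affine within the stated bounds (degrees, ratios, px).

    With all bounds zero the exact identity is returned.  When `centre` is
    given the rotation/scale/shear act about that point instead of the
    origin.
    """
    for name, v in [("max_rotation", max_rotation), ("max_scale_dev", max_scale_dev),
                    ("max_shear", max_shear), ("max_translate", max_translate)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(rng.uniform(-max_rotation, max_rotation))
    sr, sc = rng.uniform(1 - max_scale_dev, 1 + max_scale_dev, size=2)
    shear = rng.uniform(-max_shear, max_shear)
    tr, tc = rng.uniform(-max_translate, max_translate, size=2)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    b = rot @ np.array([[sr, shear * sr], [0.0, sc]])
    t = np.array([tr, tc])
    if centre is not None:
        c = np.asarray(centre, dtype=np.float64)
        t = t + c - b @ c
    return AffineTransform(np.hstack([b, t[:, None]]))
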