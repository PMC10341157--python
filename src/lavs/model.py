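"""Segmentation backbone: convolutional encoder, transformer bottleneck,
and a decoder with modified skip connections.

The network is a three-resolution U-Net hybrid.  Two 3x3 conv + ReLU blocks
per level encode the image at H, H/2 and H/4; the H/4 features pass through
a stack of pre-norm transformer layers (patch embedding -> MHSA/MLP with
residuals -> patch merging) so that global vessel context is modelled where
it is cheapest; the decoder then upsamples bilinearly and, beyond the two
standard skips, re-injects a pooled copy of the full-resolution encoder
features at the middle stage — texture detail that offsets what global
attention smooths away.  When landmark guidance is enabled, K Gaussian
landmark heatmaps are concatenated with the bottleneck output before
decoding.

Three variants support the ablation: ``unet`` (conv bottleneck, no
landmarks), ``transunet`` (transformer bottleneck), and ``transunet_sld``
(transformer + self-supervised landmark guidance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "TransformerConfig", "NetConfig", "EncoderFeatures", "SegModel",
    "encode", "transformer_forward", "decode", "forward_segment",
    "image_to_tensor", "summary",
]

VARIANTS = ("unet", "transunet", "transunet_sld")


@dataclass(frozen=True)
class TransformerConfig:
    n_layers: int = 4
    n_heads: int = 8
    patch_size: int = 8
    embed_dim: int | None = None     # None -> C3
    mlp_ratio: float = 4.0
    ln_affine: bool = True
    pos_grid: int = 8                # base grid for learned position embeddings

    def __post_init__(self):
        if self.embed_dim is not None and self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_layers < 0 or self.patch_size < 1:
            raise ValueError("invalid transformer config")


@dataclass(frozen=True)
class NetConfig:
    variant: str = "transunet_sld"
    channels: tuple[int, int, int] = (64, 128, 256)
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    landmark_channels: int = 32
    gaussian_sigma: float = 0.7      # grid units on the H/4 landmark grid
    landmark_head_gain: float = 20.0  # init gain of the 1x1 landmark projection
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        c1, c2, c3 = self.channels
        if not c1 < c2 < c3:
            raise ValueError("channel counts must increase per level")
        embed = self.transformer.embed_dim or c3
        if embed % self.transformer.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.landmark_channels < 1:
            raise ValueError("landmark_channels must be >= 1")


@dataclass
class EncoderFeatures:
    """Multi-resolution encoder feature maps (N, C, H, W) tensors."""

    m1: nn.Tensor     # (1, C1, H, W)
    m2: nn.Tensor     # (1, C2, H/2, W/2)
    m3: nn.Tensor     # (1, C3, H/4, W/4)


class ConvBlock(nn.Module):
    """Two 3x3 conv + instance norm + ReLU layers at constant resolution.

    Instance normalisation (batch size is 1 throughout) keeps feature
    scales stable while the auxiliary landmark objectives pull on the
    shared encoder.
    """

    def __init__(self, c_in, c_out, rng):
        self.c1 = nn.Conv2d(c_in, c_out, 3, rng, padding=1)
        self.n1 = nn.InstanceNorm(c_out)
        self.c2 = nn.Conv2d(c_out, c_out, 3, rng, padding=1)
        self.n2 = nn.InstanceNorm(c_out)

    def __call__(self, x):
        return nn.relu(self.n2(self.c2(nn.relu(self.n1(self.c1(x))))))


class Encoder(nn.Module):
    def __init__(self, channels, rng):
        c1, c2, c3 = channels
        self.e1 = ConvBlock(3, c1, rng)
        self.e2 = ConvBlock(c1, c2, rng)
        self.e3 = ConvBlock(c2, c3, rng)

    def __call__(self, x: nn.Tensor) -> EncoderFeatures:
        _, _, h, w = x.shape
        if h % 4 or w % 4:
            raise ValueError(f"input spatial size {h}x{w} must be divisible by 4")
        m1 = self.e1(x)
        m2 = self.e2(nn.max_pool2(m1))
        m3 = self.e3(nn.max_pool2(m2))
        return EncoderFeatures(m1=m1, m2=m2, m3=m3)


class MHSA(nn.Module):
    def __init__(self, dim, n_heads, rng):
        self.n_heads = n_heads
        self.dim = dim
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        t, d = x.shape
        h = self.n_heads
        dh = d // h
        qkv = self.qkv(x).reshape(t, 3, h, dh).transpose(1, 2, 0, 3)
        q, k, v = qkv[0], qkv[1], qkv[2]          # each (h, t, dh)
        att = nn.softmax((q @ k.transpose(0, 2, 1)) * (dh ** -0.5), axis=-1)
        out = (att @ v).transpose(1, 0, 2).reshape(t, d)
        return self.proj(out)


class TransformerLayer(nn.Module):
    """Pre-norm layer: x' = MHSA(LN(x)) + x; x'' = MLP(LN(x')) + x'."""

    def __init__(self, dim, n_heads, mlp_ratio, ln_affine, rng):
        self.ln1 = nn.LayerNorm(dim, affine=ln_affine)
        self.attn = MHSA(dim, n_heads, rng)
        self.ln2 = nn.LayerNorm(dim, affine=ln_affine)
        hidden = int(dim * mlp_ratio)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def __call__(self, x):
        x = self.attn(self.ln1(x)) + x
        x = self.fc2(nn.relu(self.fc1(self.ln2(x)))) + x
        return x


class TransformerBottleneck(nn.Module):
    """Patch embed -> position embed -> Nt layers -> patch merge.

    Position embeddings are learned on a fixed base grid and bilinearly
    resized to the actual token grid, so one parameter set serves any input
    size whose H/4, W/4 are divisible by the patch size.
    """

    def __init__(self, c3: int, cfg: TransformerConfig, rng):
        self.cfg = cfg
        dim = cfg.embed_dim or c3
        p = cfg.patch_size
        self.embed = nn.Conv2d(c3, dim, p, rng, stride=p)
        self.pos = nn.Parameter(rng.normal(0, 0.02, (1, dim, cfg.pos_grid, cfg.pos_grid)))
        self.layers = [TransformerLayer(dim, cfg.n_heads, cfg.mlp_ratio,
                                        cfg.ln_affine, rng)
                       for _ in range(cfg.n_layers)]
        # Zero-init patch merging: the bottleneck output fades in as training
        # progresses, so the decoder is not fed unstructured token mixtures
        # at the start (the conv bottleneck of the plain U-Net variant is
        # locality-preserving from init; attention is not).
        self.merge = nn.Linear(dim, c3 * p * p, rng, zero_init=True)
        self.c3 = c3

    def embed_tokens(self, m3: nn.Tensor) -> tuple[nn.Tensor, int, int]:
        _, c, h, w = m3.shape
        p = self.cfg.patch_size
        if h % p or w % p:
            raise ValueError(
                f"feature grid {h}x{w} not divisible by patch size {p}")
        gh, gw = h // p, w // p
        z = self.embed(m3)                                   # (1, dim, gh, gw)
        pos = nn.bilinear_resize(self.pos, (gh, gw))
        z = z + pos
        dim = z.shape[1]
        return z.reshape(dim, gh * gw).transpose(1, 0), gh, gw

    def run_blocks(self, tokens: nn.Tensor) -> nn.Tensor:
        for layer in self.layers:
            tokens = layer(tokens)
        return tokens

    def merge_tokens(self, tokens: nn.Tensor, gh: int, gw: int) -> nn.Tensor:
        p = self.cfg.patch_size
        z = self.merge(tokens)                               # (T, C3*p*p)
        z = z.reshape(gh, gw, self.c3, p, p)
        z = z.transpose(2, 0, 3, 1, 4).reshape(1, self.c3, gh * p, gw * p)
        return z

    def __call__(self, m3: nn.Tensor) -> nn.Tensor:
        tokens, gh, gw = self.embed_tokens(m3)
        tokens = self.run_blocks(tokens)
        return self.merge_tokens(tokens, gh, gw)


class Decoder(nn.Module):
    """Three-stage decoder with the extra pooled-m1 skip at stage two."""

    def __init__(self, channels, k_landmarks, rng):
        c1, c2, c3 = channels
        self.d1 = ConvBlock(c3 + k_landmarks, c3, rng)
        self.d2 = ConvBlock(c3 + c2 + c1, c2, rng)
        self.d3 = ConvBlock(c2 + c1, c1, rng)
        self.out = nn.Conv2d(c1, 1, 1, rng)
        self.k = k_landmarks
        self.channels = channels

    def __call__(self, feats: EncoderFeatures, mt: nn.Tensor,
                 mgm: nn.Tensor | None = None) -> nn.Tensor:
        _, c3, h4, w4 = mt.shape
        if mgm is None:
            mgm = nn.Tensor(np.zeros((1, self.k, h4, w4), dtype=np.float32))
        if mgm.shape[2:] != (h4, w4):
            raise ValueError(
                f"decoder stage 1: Gaussian map grid {mgm.shape[2:]} does not "
                f"match bottleneck grid {(h4, w4)}")
        if mgm.shape[1] != self.k:
            raise ValueError(
                f"decoder stage 1: Gaussian map has {mgm.shape[1]} channels, "
                f"expected {self.k}")
        if feats.m3.shape[2:] != (h4, w4):
            raise ValueError(
                f"decoder stage 1: bottleneck grid {(h4, w4)} does not match "
                f"encoder m3 grid {feats.m3.shape[2:]}")
        d1 = self.d1(nn.concat([mt, mgm], axis=1))
        up1 = nn.bilinear_resize(d1, feats.m2.shape[2:])
        m1_pooled = nn.max_pool2(feats.m1)
        if up1.shape[2:] != feats.m2.shape[2:]:
            raise ValueError("decoder stage 2: upsample/skip grid mismatch")
        d2 = self.d2(nn.concat([up1, feats.m2, m1_pooled], axis=1))
        up2 = nn.bilinear_resize(d2, feats.m1.shape[2:])
        d3 = self.d3(nn.concat([up2, feats.m1], axis=1))
        return nn.sigmoid(self.out(d3))


class ConvBottleneck(nn.Module):
    """Plain convolutional bottleneck used by the ``unet`` variant."""

    def __init__(self, c3, rng):
        self.block = ConvBlock(c3, c3, rng)

    def __call__(self, m3):
        return self.block(m3)


class SegModel(nn.Module):
    """Full segmentation network for a given :class:`NetConfig`."""

    def __init__(self, cfg: NetConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        c1, c2, c3 = cfg.channels
        self.encoder = Encoder(cfg.channels, rng)
        if cfg.variant == "unet":
            self.bottleneck = ConvBottleneck(c3, rng)
        else:
            self.bottleneck = TransformerBottleneck(c3, cfg.transformer, rng)
        self.decoder = Decoder(cfg.channels, cfg.landmark_channels, rng)
        # 1x1 projection from m3 to K landmark response channels.  The large
        # init gain makes the initial spatial softmax peaked; with a standard
        # small init every channel is near-uniform and soft-argmax collapses
        # all landmarks onto the grid centre, a degenerate equilibrium the
        # self-supervised losses cannot escape.
        self.landmark_head = nn.Conv2d(c3, cfg.landmark_channels, 1, rng)
        self.landmark_head.w.data *= cfg.landmark_head_gain

    def __call__(self, x: nn.Tensor, mgm: nn.Tensor | None = None) -> nn.Tensor:
        feats = self.encoder(x)
        mt = self.bottleneck(feats.m3)
        return self.decoder(feats, mt, mgm)


# -- functional front-ends on numpy rasters -------------------------------

def image_to_tensor(img: np.ndarray) -> nn.Tensor:
    """(H, W, 3) raster in [0, 1] -> (1, 3, H, W) float32 tensor."""
    img = np.asarray(img, dtype=np.float32)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {img.shape}")
    return nn.Tensor(img.transpose(2, 0, 1)[None])


def encode(x: np.ndarray, model: SegModel) -> EncoderFeatures:
    return model.encoder(image_to_tensor(x))


def transformer_forward(m3, model_or_cfg) -> np.ndarray:
    """Run the transformer bottleneck on an (h, w, C3) feature raster."""
    if isinstance(model_or_cfg, SegModel):
        bott = model_or_cfg.bottleneck
    else:
        bott = model_or_cfg
    if not isinstance(bott, TransformerBottleneck):
        raise TypeError("model variant has no transformer bottleneck")
    t = nn.Tensor(np.asarray(m3, dtype=np.float32).transpose(2, 0, 1)[None])
    out = bott(t)
    return out.data[0].transpose(1, 2, 0)


def decode(feats: EncoderFeatures, mt: nn.Tensor, model: SegModel,
           mgm: nn.Tensor | None = None) -> np.ndarray:
    return model.decoder(feats, mt, mgm).data[0, 0]


def forward_segment(x: np.ndarray, model: SegModel,
                    mgm: np.ndarray | nn.Tensor | None = None) -> np.ndarray:
    """Image raster -> (H, W) vessel probability map."""
    if mgm is not None and not isinstance(mgm, nn.Tensor):
        mgm = nn.Tensor(np.asarray(mgm, dtype=np.float32)[None])
    return model(image_to_tensor(x), mgm).data[0, 0]


def summary(cfg: NetConfig, input_size: tuple[int, int] = (64, 64)) -> str:
    """Layer/shape/parameter-count report for a config."""
    model = SegModel(cfg)
    h, w = input_size
    x = nn.Tensor(np.zeros((1, 3, h, w), dtype=np.float32))
    feats = model.encoder(x)
    mt = model.bottleneck(feats.m3)
    y = model.decoder(feats, mt, None)
    lines = [
        f"variant            {cfg.variant}",
        f"input              {h}x{w}x3",
        f"m1                 {tuple(feats.m1.shape[1:])}",
        f"m2                 {tuple(feats.m2.shape[1:])}",
        f"m3                 {tuple(feats.m3.shape[1:])}",
        f"bottleneck out     {tuple(mt.shape[1:])}",
        f"output             {tuple(y.shape[1:])}",
        f"parameters         {model.n_parameters():,}",
    ]
    return "\n".join(lines)
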