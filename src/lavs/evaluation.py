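"""Pixel-classification metrics and evaluation orchestration.

Vessel segmentation is scored as per-pixel binary classification: TP are
vessel pixels predicted as vessel, TN background predicted background, FP
background predicted vessel (over-segmentation), FN vessel predicted
background (missed vessel).  Derived metrics are accuracy, sensitivity
(recall on vessels), specificity and F1; F1 is the headline number.  When a
field-of-view mask is available, counting is restricted to it.

Error overlays follow the conventional colour coding: white TP, blue FN
(missed vessels), red FP (over-segmentation), dimmed background elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .data import SamplePair, resize_pair
from .model import SegModel, forward_segment
from .training import TrainConfig, train

__all__ = [
    "ConfusionCounts", "MetricReport", "confusion", "metrics", "predict",
    "evaluate_split", "leave_one_out", "render_error_overlay",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    """Acc/Se/Sp/F1; a metric with a zero denominator is NaN, not 0."""

    acc: float
    se: float
    sp: float
    f1: float

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(name for name in ("acc", "se", "sp", "f1")
                     if math.isnan(getattr(self, name)))


def confusion(y_pre: np.ndarray, y: np.ndarray, threshold: float = 0.5,
              fov: np.ndarray | None = None) -> ConfusionCounts:
    """Binarise the prediction at `threshold` and tally pixels (within the
    FOV when given, else over the whole frame)."""
    y_pre = np.asarray(y_pre)
    y = np.asarray(y)
    if y_pre.shape != y.shape:
        raise ValueError(f"prediction {y_pre.shape} vs truth {y.shape}")
    pred = y_pre >= threshold
    truth = y > 0.5
    if fov is not None:
        if fov.shape != y.shape:
            raise ValueError("fov shape mismatch")
        sel = fov > 0.5
        pred, truth = pred[sel], truth[sel]
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)), tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)), fn=int(np.sum(~pred & truth)))


def metrics(c: ConfusionCounts) -> MetricReport:
    def ratio(num, den):
        return num / den if den > 0 else math.nan

    return MetricReport(
        acc=ratio(c.tp + c.tn, c.total),
        se=ratio(c.tp, c.tp + c.fn),
        sp=ratio(c.tn, c.tn + c.fp),
        f1=ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn))


def predict(model: SegModel, pair: SamplePair,
            image_size: tuple[int, int]) -> np.ndarray:
    """Probability map at the pair's native resolution.

    The image is resized to the training resolution for the forward pass
    and the probability map is resized back (nearest) before counting.
    """
    work = resize_pair(pair, image_size)
    prob = forward_segment(work.image, model)
    if prob.shape != pair.shape:
        prob = _sk_resize(prob, pair.shape, order=0, preserve_range=True,
                          anti_aliasing=False)
    return prob


def evaluate_split(model: SegModel, pairs: list[SamplePair],
                   image_size: tuple[int, int] = (512, 512),
                   threshold: float = 0.5, use_fov: bool = True):
    """Per-image and pooled metrics over a test split.

    Returns ``(reports, table)`` where reports maps the pooling mode
    (``pixel_pooled`` — one tally over all pixels, the default headline
    convention — and ``per_image_mean``) to a :class:`MetricReport`, and
    table is a per-image DataFrame plus a summary row.
    """
    if not pairs:
        raise ValueError("no pairs to evaluate")
    rows, counts, per_image = [], ConfusionCounts(0, 0, 0, 0), []
    for pair in pairs:
        prob = predict(model, pair, image_size)
        c = confusion(prob, pair.mask, threshold,
                      fov=pair.fov if use_fov else None)
        m = metrics(c)
        counts = counts + c
        per_image.append(m)
        rows.append(dict(id=pair.id, acc=m.acc, se=m.se, sp=m.sp, f1=m.f1,
                         tp=c.tp, tn=c.tn, fp=c.fp, fn=c.fn))
    pooled = metrics(counts)
    mean = MetricReport(
        acc=float(np.nanmean([m.acc for m in per_image])),
        se=float(np.nanmean([m.se for m in per_image])),
        sp=float(np.nanmean([m.sp for m in per_image])),
        f1=float(np.nanmean([m.f1 for m in per_image])))
    rows.append(dict(id="POOLED", acc=pooled.acc, se=pooled.se, sp=pooled.sp,
                     f1=pooled.f1, tp=counts.tp, tn=counts.tn, fp=counts.fp,
                     fn=counts.fn))
    return ({"pixel_pooled": pooled, "per_image_mean": mean},
            pd.DataFrame(rows))


def leave_one_out(pairs: list[SamplePair], cfg: TrainConfig,
                  use_fov: bool = True):
    """N rounds of train-on-(N-1)/test-on-1; per-fold seed = seed + fold.

    Returns ``(aggregate, fold_reports)`` where the aggregate is the
    arithmetic mean of per-fold metrics.
    """
    if len(pairs) < 2:
        raise ValueError("leave-one-out needs at least 2 pairs")
    fold_reports = []
    for fold, held_out in enumerate(pairs):
        train_pairs = [p for i, p in enumerate(pairs) if i != fold]
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + fold})
        result = train(train_pairs, fold_cfg)
        reports, _ = evaluate_split(result.model, [held_out],
                                    image_size=cfg.image_size,
                                    use_fov=use_fov)
        fold_reports.append(reports["pixel_pooled"])
    aggregate = MetricReport(
        acc=float(np.mean([r.acc for r in fold_reports])),
        se=float(np.mean([r.se for r in fold_reports])),
        sp=float(np.mean([r.sp for r in fold_reports])),
        f1=float(np.mean([r.f1 for r in fold_reports])))
    return aggregate, fold_reports


def render_error_overlay(y_pre: np.ndarray, y: np.ndarray,
                         image: np.ndarray, threshold: float = 0.5,
                         dim: float = 0.35) -> np.ndarray:
    """Colour-coded error map: TP white, FN blue, FP red, TN dimmed image."""
    y_pre = np.asarray(y_pre)
    y = np.asarray(y)
    if y_pre.shape != y.shape or image.shape[:2] != y.shape:
        raise ValueError("shape mismatch between prediction, truth and image")
    pred = y_pre >= threshold
    truth = y > 0.5
    out = np.asarray(image, dtype=np.float64) * dim
    out[pred & truth] = (1.0, 1.0, 1.0)      # TP
    out[~pred & truth] = (0.0, 0.0, 1.0)     # FN: missed vessel
    out[pred & ~truth] = (1.0, 0.0, 0.0)     # FP: over-segmentation
    return np.clip(out, 0, 1)
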