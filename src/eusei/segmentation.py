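"""Segmentation metrics and a toy trainable lesion segmenter.

The clinical system segments lesions with a deep network trained on study
images that are not part of this package; here masks are inputs.  This
module provides the evaluation metrics (Dice, IoU, detection precision /
recall at an IoU threshold) and a small trainable demonstrator that
segments phantom B-mode panels: a multi-scale Gaussian filter-bank feeding
a logistic pixel classifier with morphological post-processing.  The
demonstrator shares the metric contracts (determinism under a seed,
held-out Dice) but is not a reproduction of any clinical model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .errors import InvalidArgumentError
from .panelio import LesionMask, luma

MIN_TRAIN_FRAMES = 50
FEATURE_SIGMAS = (1.0, 2.0, 4.0, 8.0)


def _bits(mask) -> np.ndarray:
    return mask.bits if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks agree perfectly (1.0)."""
    a, b = _bits(a), _bits(b)
    if a.shape != b.shape:
        raise InvalidArgumentError("mask dimensions differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(a, b) -> float:
    """Intersection over union; two empty masks score 1.0."""
    a, b = _bits(a), _bits(b)
    if a.shape != b.shape:
        raise InvalidArgumentError("mask dimensions differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def detection_pr(
    predictions: Sequence[Sequence],
    truths: Sequence[Sequence],
    iou_threshold: float = 0.5,
) -> tuple[float, float]:
    """Frame-wise detection precision and recall at an IoU threshold.

    ``predictions`` and ``truths`` are parallel per-frame lists of masks.
    Within each frame, predictions are matched one-to-one to truths greedily
    in decreasing IoU order; a match counts as a true positive iff its IoU
    reaches the threshold.  Empty sets give precision/recall 1.0 by
    convention.
    """
    if len(predictions) != len(truths):
        raise InvalidArgumentError("prediction and truth lists differ in length")
    if not 0 < iou_threshold <= 1:
        raise InvalidArgumentError("iou_threshold must lie in (0, 1]")
    tp = n_pred = n_truth = 0
    for preds, gts in zip(predictions, truths):
        n_pred += len(preds)
        n_truth += len(gts)
        pairs = [
            (iou(p, g), i, j)
            for i, p in enumerate(preds)
            for j, g in enumerate(gts)
        ]
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_p, used_g = set(), set()
        for score, i, j in pairs:
            if score < iou_threshold:
                break
            if i in used_p or j in used_g:
                continue
            used_p.add(i)
            used_g.add(j)
            tp += 1
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_truth if n_truth else 1.0
    return float(precision), float(recall)


def _pixel_features(bmode: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack: raw luma, Gaussian scales, gradient magnitude."""
    g = luma(bmode) / 255.0
    feats = [g]
    for s in FEATURE_SIGMAS:
        feats.append(ndimage.gaussian_filter(g, s))
    feats.append(ndimage.gaussian_gradient_magnitude(g, 2.0))
    return np.stack(feats, axis=-1)


@dataclass
class ToySegmenter:
    """Trained phantom segmenter (filter-bank + logistic pixel classifier)."""

    scaler: StandardScaler
    clf: LogisticRegression
    threshold: float = 0.5

    def predict(self, bmode: np.ndarray) -> LesionMask:
        """Predict a left-panel lesion mask for one B-mode panel."""
        feats = _pixel_features(bmode)
        h, w = feats.shape[:2]
        prob = self.clf.predict_proba(
            self.scaler.transform(feats.reshape(-1, feats.shape[-1]))
        )[:, 1].reshape(h, w)
        bits = prob >= self.threshold
        bits = ndimage.binary_closing(bits, iterations=2)
        bits = ndimage.binary_fill_holes(bits)
        labels, n = ndimage.label(bits)
        if n > 1:  # keep the largest connected component
            sizes = ndimage.sum_labels(bits, labels, index=np.arange(1, n + 1))
            bits = labels == (1 + int(np.argmax(sizes)))
        return LesionMask(bits=bits, panel_side="left")


def train_toy_segmenter(
    bmode_panels: Sequence[np.ndarray],
    truth_masks: Sequence,
    epochs: int = 20,
    seed: int = 0,
    pixels_per_frame: int = 1500,
) -> ToySegmenter:
    """Train the demonstrator segmenter on phantom B-mode panels.

    Subsamples ``pixels_per_frame`` pixels per frame (reproducibly from
    ``seed``) and fits a logistic classifier; ``epochs`` scales the
    optimizer iteration budget.  Requires at least 50 training frames.
    """
    if len(bmode_panels) != len(truth_masks):
        raise InvalidArgumentError("panels and masks differ in length")
    if len(bmode_panels) < MIN_TRAIN_FRAMES:
        raise InvalidArgumentError(
            f"need >= {MIN_TRAIN_FRAMES} training frames, got {len(bmode_panels)}"
        )
    if epochs < 1:
        raise InvalidArgumentError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for panel, mask in zip(bmode_panels, truth_masks):
        feats = _pixel_features(panel)
        flat = feats.reshape(-1, feats.shape[-1])
        lab = _bits(mask).reshape(-1)
        take = min(pixels_per_frame, flat.shape[0])
        idx = rng.choice(flat.shape[0], size=take, replace=False)
        xs.append(flat[idx])
        ys.append(lab[idx])
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    if y.min() == y.max():
        raise InvalidArgumentError("training data contain a single class")
    scaler = StandardScaler().fit(X)
    clf = LogisticRegression(max_iter=50 * epochs, random_state=seed)
    clf.fit(scaler.transform(X), y)
    return ToySegmenter(scaler=scaler, clf=clf)


def evaluate_segmenter(
    model: ToySegmenter,
    bmode_panels: Sequence[np.ndarray],
    truth_masks: Sequence,
    iou_threshold: float = 0.5,
) -> dict:
    """Held-out evaluation report: Dice mean/SD and detection PR."""
    dices = []
    preds = []
    for panel, truth in zip(bmode_panels, truth_masks):
        pred = model.predict(panel)
        dices.append(dice(pred, truth))
        preds.append([pred])
    precision, recall = detection_pr(
        preds, [[m] for m in truth_masks], iou_threshold
    )
    return {
        "dice_mean": float(np.mean(dices)),
        "dice_sd": float(np.std(dices, ddof=1)) if len(dices) > 1 else 0.0,
        "precision": precision,
        "recall": recall,
        "iou_threshold": iou_threshold,
        "n_frames": len(dices),
    }
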