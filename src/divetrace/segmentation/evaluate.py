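"""Corpus handling and segmentation evaluation.

Covers the train/validation split, mask-preserving augmentation of the
training corpus, and per-class evaluation (precision, recall, F1, binary
accuracy) including precision-recall threshold sweeps with F1-maximizing
threshold selection on probability maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ..classes import CLASS_NAMES, N_CLASSES


def split_corpus(images: list, train_fraction: float, seed: int = 0):
    """Random disjoint, exhaustive split; training size is
    floor(train_fraction * n). Deterministic under seed."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(images)
    if n == 0:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    train = [images[i] for i in order[:n_train]]
    val = [images[i] for i in order[n_train:]]
    return train, val


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _random_transform(
    rng: np.random.Generator,
    img: np.ndarray,
    mask: np.ndarray,
    transforms=("crop", "flip", "rotate", "elastic"),
    crop_scale=(0.6, 1.0),
    max_rotate_deg: float = 15.0,
    elastic_alpha: float = 8.0,
    elastic_sigma: float = 4.0,
):
    """One randomly transformed (image, mask) copy. Every geometric
    operation is applied identically to image and mask (mask with
    nearest-neighbour interpolation so labels stay categorical)."""
    img = img.copy()
    mask = mask.copy()
    H, W = img.shape
    if "crop" in transforms:
        s = rng.uniform(*crop_scale)
        h, w = max(int(round(s * H)), 8), max(int(round(s * W)), 8)
        r0 = int(rng.integers(0, H - h + 1))
        c0 = int(rng.integers(0, W - w + 1))
        sub_i = img[r0:r0 + h, c0:c0 + w]
        sub_m = mask[r0:r0 + h, c0:c0 + w]
        img = ndimage.zoom(sub_i, (H / h, W / w), order=1)[:H, :W]
        mask = ndimage.zoom(sub_m, (H / h, W / w), order=0)[:H, :W]
        # zoom can come up one pixel short; pad by edge replication
        if img.shape != (H, W):
            img = np.pad(img, ((0, H - img.shape[0]), (0, W - img.shape[1])), mode="edge")
            mask = np.pad(mask, ((0, H - mask.shape[0]), (0, W - mask.shape[1])), mode="edge")
    if "flip" in transforms:
        if rng.random() < 0.5:
            img, mask = img[:, ::-1], mask[:, ::-1]
        if rng.random() < 0.5:
            img, mask = img[::-1, :], mask[::-1, :]
    if "rotate" in transforms:
        angle = rng.uniform(-max_rotate_deg, max_rotate_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="reflect")
        mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="reflect")
    if "elastic" in transforms:
        dr = ndimage.gaussian_filter(
            rng.normal(0, 1, (H, W)), elastic_sigma
        ) * elastic_alpha
        dc = ndimage.gaussian_filter(
            rng.normal(0, 1, (H, W)), elastic_sigma
        ) * elastic_alpha
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        coords = (rr + dr, cc + dc)
        img = ndimage.map_coordinates(img, coords, order=1, mode="reflect")
        mask = ndimage.map_coordinates(mask, coords, order=0, mode="reflect")
    return np.ascontiguousarray(img), np.ascontiguousarray(mask)


def augment_training_set(
    train: list,
    multiplier: int,
    seed: int = 0,
    transforms=("crop", "flip", "rotate", "elastic"),
    **kwargs,
) -> list:
    """Expand (image, mask) pairs by random crops, flips, rotations and
    elastic deformations; output size is multiplier x input size. With an
    empty transform tuple every copy is the identity. Deterministic under
    seed."""
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(multiplier):
        for img, mask in train:
            if not transforms:
                out.append((np.array(img, copy=True), np.array(mask, copy=True)))
            else:
                out.append(_random_transform(rng, np.asarray(img), np.asarray(mask),
                                             transforms, **kwargs))
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-class segmentation quality. ``per_class`` has one row per class
    (precision, recall, f1, accuracy); ``pr_curves`` holds the threshold
    sweep (class, threshold, precision, recall, f1) when probabilities were
    supplied, with ``optimal_thresholds`` the F1-maximizer per class."""

    per_class: pd.DataFrame
    confusion: np.ndarray
    pr_curves: pd.DataFrame | None = None
    optimal_thresholds: dict = field(default_factory=dict)

    @property
    def f1(self) -> pd.Series:
        return self.per_class.set_index("class")["f1"]


def _binary_prf(pred: np.ndarray, true: np.ndarray):
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / max(tp + tn + fp + fn, 1)
    return precision, recall, f1, accuracy


def evaluate_segmentation(
    pred,
    truth: np.ndarray,
    thresholds_grid: np.ndarray | None = None,
    class_names=CLASS_NAMES,
) -> EvaluationReport:
    """Compare a predicted mask — or a probability map — against a truth
    mask, per class (one-vs-rest at pixel level).

    When ``pred`` has a trailing class axis it is treated as probabilities:
    each class is swept over a threshold grid to produce precision-recall
    curves, the F1-maximizing threshold is selected per class, and the
    headline metrics are computed at those optima (labels via argmax among
    passing classes is the production path; the sweep here is one-vs-rest,
    which is how the curves are defined).
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    n_classes = len(class_names)
    is_probs = pred.ndim == truth.ndim + 1
    if (pred.shape[: truth.ndim] if is_probs else pred.shape) != truth.shape:
        raise ValueError(
            f"prediction shape {pred.shape} does not align with truth {truth.shape}"
        )

    t = truth.ravel()
    pr_rows = []
    optimal: dict = {}
    if is_probs:
        probs = pred.reshape(-1, n_classes)
        if thresholds_grid is None:
            thresholds_grid = np.round(np.arange(0.05, 1.0, 0.05), 2)
        for c, name in enumerate(class_names):
            true_c = t == c
            best = (0.0, 0.5)
            for thr in thresholds_grid:
                p, r, f1, _ = _binary_prf(probs[:, c] >= thr, true_c)
                pr_rows.append(
                    {"class": name, "threshold": float(thr),
                     "precision": p, "recall": r, "f1": f1}
                )
                if f1 > best[0]:
                    best = (f1, float(thr))
            optimal[name] = best[1]
        thr_vec = np.array([optimal[n] for n in class_names])
        from .estimators import threshold_labels  # local import, avoids cycle

        labels = threshold_labels(pred.reshape(truth.shape + (n_classes,)), thr_vec)
        p = labels.ravel()
    else:
        p = pred.ravel()

    rows = []
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (t, p), 1)
    for c, name in enumerate(class_names):
        precision, recall, f1, accuracy = _binary_prf(p == c, t == c)
        rows.append(
            {"class": name, "precision": precision, "recall": recall,
             "f1": f1, "accuracy": accuracy}
        )
    return EvaluationReport(
        per_class=pd.DataFrame(rows),
        confusion=confusion,
        pr_curves=pd.DataFrame(pr_rows) if pr_rows else None,
        optimal_thresholds=optimal,
    )
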