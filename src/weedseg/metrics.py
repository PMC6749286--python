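"""Segmentation evaluation: Dice-based error and weed-centric rates.

All quantities are percentages in [0, 100] computed from hard class masks
(soil=0, crop=1, weed=2, ignore=255).  Ignore pixels are excluded from every
count.

* ``dice_error`` — 100% minus the Dice coefficient 2|E∩P| / (|E|+|P|) averaged
  over images and the three classes.  A class absent from both the label E and
  the prediction P of an image contributes Dice 1 by default (no error where
  nothing exists); ``absent_class="skip"`` drops it from the average instead.
* ``weed_recall`` — |E_weed ∩ P_weed| / |E_weed|: fraction of true weed area
  detected (drives weeding effectiveness).
* ``weed_precision`` — |E_weed ∩ P_weed| / |P_weed|: fraction of predicted
  weed area that is truly weed (drives herbicide waste).
* ``crop_as_weed`` — |E_crop ∩ P_weed| / |E_crop|: fraction of crop area
  misclassified as weed (drives yield loss).

The three ratios are pooled over all pixels of the evaluation set by default
(their printed form is a single quotient); ``per_image=True`` averages
per-image ratios instead.  An empty denominator yields ``nan`` — an undefined
metric, deliberately distinct from 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Sequence

import numpy as np

__all__ = [
    "SOIL",
    "CROP",
    "WEED",
    "IGNORE",
    "MetricsReport",
    "argmax_classes",
    "dice_error",
    "weed_recall",
    "weed_precision",
    "crop_as_weed",
    "evaluate_masks",
]

SOIL, CROP, WEED, IGNORE = 0, 1, 2, 255
CLASSES = (SOIL, CROP, WEED)


@dataclass(frozen=True)
class MetricsReport:
    """The four headline numbers for a prediction set (all percent)."""

    e_dice: float
    r_weed: float
    p_weed: float
    m_crop_as_weed: float
    n_images: int

    def as_dict(self) -> dict:
        return {
            "e_dice": self.e_dice,
            "r_weed": self.r_weed,
            "p_weed": self.p_weed,
            "m_crop_as_weed": self.m_crop_as_weed,
            "n_images": self.n_images,
        }


def argmax_classes(probs: np.ndarray) -> np.ndarray:
    """Per-pixel most-probable class; ties break toward the lowest index
    (soil < crop < weed), which is numpy argmax's convention."""
    probs = np.asarray(probs)
    if probs.ndim < 1 or probs.shape[-1] != len(CLASSES):
        raise ValueError(f"expected a trailing axis of {len(CLASSES)} classes")
    return probs.argmax(axis=-1).astype(np.uint8)


def _check_pairs(preds: Sequence[np.ndarray], labels: Sequence[np.ndarray]) -> None:
    if len(preds) == 0 or len(preds) != len(labels):
        raise ValueError("need equal-length, non-empty prediction/label lists")
    for i, (p, e) in enumerate(zip(preds, labels)):
        if np.shape(p) != np.shape(e):
            raise ValueError(f"pair {i}: shape mismatch {np.shape(p)} vs {np.shape(e)}")


def dice_error(
    preds: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
    absent_class: Literal["one", "skip"] = "one",
) -> float:
    """100% minus the mean (over images, then classes) Dice coefficient."""
    _check_pairs(preds, labels)
    dices: List[float] = []
    for p, e in zip(preds, labels):
        p = np.asarray(p)
        e = np.asarray(e)
        valid = e != IGNORE
        for c in CLASSES:
            E = (e == c) & valid
            P = (p == c) & valid
            denom = int(E.sum()) + int(P.sum())
            if denom == 0:
                if absent_class == "one":
                    dices.append(1.0)
                continue
            dices.append(2.0 * int((E & P).sum()) / denom)
    if not dices:
        raise ValueError("no class terms to average (all absent and skipped)")
    return 100.0 * (1.0 - float(np.mean(dices)))


def _pooled_ratio(
    preds: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
    num_classes: tuple,  # (label class, prediction class)
    den_from: Literal["label", "pred"],
    den_class: int,
    per_image: bool,
) -> float:
    _check_pairs(preds, labels)
    lab_c, pred_c = num_classes
    nums, dens = [], []
    for p, e in zip(preds, labels):
        p = np.asarray(p)
        e = np.asarray(e)
        valid = e != IGNORE
        num = int(((e == lab_c) & (p == pred_c) & valid).sum())
        if den_from == "label":
            den = int(((e == den_class) & valid).sum())
        else:
            den = int(((p == den_class) & valid).sum())
        nums.append(num)
        dens.append(den)
    if per_image:
        vals = [100.0 * n / d for n, d in zip(nums, dens) if d > 0]
        return float(np.mean(vals)) if vals else float("nan")
    total_den = sum(dens)
    if total_den == 0:
        return float("nan")
    return 100.0 * sum(nums) / total_den


def weed_recall(preds, labels, per_image: bool = False) -> float:
    """Detected fraction of true weed area (percent); nan if no weed labelled."""
    return _pooled_ratio(preds, labels, (WEED, WEED), "label", WEED, per_image)


def weed_precision(preds, labels, per_image: bool = False) -> float:
    """Truly-weed fraction of predicted weed area (percent); nan if nothing
    predicted weed."""
    return _pooled_ratio(preds, labels, (WEED, WEED), "pred", WEED, per_image)


def crop_as_weed(preds, labels, per_image: bool = False) -> float:
    """Crop area misclassified as weed (percent of true crop area)."""
    return _pooled_ratio(preds, labels, (CROP, WEED), "label", CROP, per_image)


def evaluate_masks(preds, labels, absent_class: Literal["one", "skip"] = "one") -> MetricsReport:
    """All four metrics for a prediction set."""
    return MetricsReport(
        e_dice=dice_error(preds, labels, absent_class=absent_class),
        r_weed=weed_recall(preds, labels),
        p_weed=weed_precision(preds, labels),
        m_crop_as_weed=crop_as_weed(preds, labels),
        n_images=len(preds),
    )
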