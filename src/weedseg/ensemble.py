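"""Ensemble teachers: combining independently trained model instances.

Single trained segmentation models are generally correct but noisy; averaging
the per-pixel class-probability maps of many independently initialised and
trained instances suppresses that noise.  The combined output is the teacher
signal for knowledge distillation.  Mean combination stays on the probability
simplex by convexity; the per-class marginal median does not, so it is
renormalised per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Sequence, Tuple

import numpy as np

from .metrics import argmax_classes, dice_error
from .models import SegModel

__all__ = ["EnsembleTeacher", "combine_probmaps", "teacher_predict", "ensemble_stability"]


def combine_probmaps(
    maps: Sequence[np.ndarray], method: Literal["mean", "median"] = "mean"
) -> np.ndarray:
    """Per-pixel, per-class mean or (renormalised) median across members."""
    if len(maps) == 0:
        raise ValueError("need at least one probability map")
    stack = np.stack([np.asarray(m, np.float32) for m in maps])
    if any(m.shape != stack[0].shape for m in stack):
        raise ValueError("probability maps must share a shape")
    if method == "mean":
        return stack.mean(axis=0)
    if method == "median":
        med = np.median(stack, axis=0)
        total = med.sum(axis=-1, keepdims=True)
        total = np.where(total <= 0, 1.0, total)
        return (med / total).astype(np.float32)
    raise ValueError(f"unknown combine method {method!r}")


@dataclass
class EnsembleTeacher:
    """A non-empty list of trained members plus a combination rule."""

    members: List[SegModel]
    combine: Literal["mean", "median"] = "mean"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.combine not in ("mean", "median"):
            raise ValueError(f"unknown combine method {self.combine!r}")

    def predict(self, image: np.ndarray) -> np.ndarray:
        return teacher_predict(self, image)


def teacher_predict(teacher: EnsembleTeacher, image: np.ndarray) -> np.ndarray:
    """Run every member on ``image`` and combine; deterministic given member
    weights.  Raises if members disagree about the output shape."""
    preds = [m.predict(image) for m in teacher.members]
    shapes = {p.shape for p in preds}
    if len(shapes) != 1:
        raise ValueError(f"ensemble members disagree on output shape: {shapes}")
    return combine_probmaps(preds, teacher.combine)


def ensemble_stability(
    teacher: EnsembleTeacher, images: Sequence[np.ndarray]
) -> float:
    """Dice error (percent) between the first-half and second-half
    sub-ensembles' hard predictions, averaged over ``images``.

    Near-zero values mean the ensemble is large enough that adding members no
    longer changes the output.  Symmetric in the two halves.
    """
    n = len(teacher.members)
    if n < 2:
        raise ValueError("stability needs at least 2 members")
    half_a = EnsembleTeacher(teacher.members[: n // 2], teacher.combine)
    half_b = EnsembleTeacher(teacher.members[n // 2 : 2 * (n // 2)], teacher.combine)
    preds_a = [argmax_classes(teacher_predict(half_a, im)) for im in images]
    preds_b = [argmax_classes(teacher_predict(half_b, im)) for im in images]
    return dice_error(preds_a, preds_b)
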