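"""Model training: hard labels with border exclusion, and soft-label
knowledge distillation.

Hard-label training minimises mean per-pixel cross-entropy over non-ignore
pixels.  Ground-truth masks rasterised at full image resolution are brought to
the model's 4x-coarser output grid by per-cell majority vote (ties become
ignore), and pixels near class borders — where manual labels are inherently
ambiguous — are excluded by :func:`exclude_borders`.

Distillation trains a student on the *full probability distribution* a teacher
assigns to every pixel (soft-target cross-entropy at temperature 1, equivalent
to KL divergence up to the constant teacher entropy).  Every pixel
participates; there is no ignore value in soft labels.

The optimiser is Adam (lr 1e-3 default); runs are bitwise reproducible for a
fixed config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import maximum_filter

from . import engine
from .metrics import CLASSES, IGNORE
from .models import OUTPUT_FACTOR, SegModel

__all__ = [
    "TrainConfig",
    "exclude_borders",
    "downsample_mask",
    "augment_pair",
    "soft_cross_entropy",
    "train_hard",
    "train_distill",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 1e-3
    seed: int = 0
    augment: bool = True
    border_radius: int = 1  # output-grid pixels excluded around class borders

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not (self.learning_rate > 0):
            raise ValueError("learning_rate must be > 0")
        if self.border_radius < 0:
            raise ValueError("border_radius must be >= 0")


# ---------------------------------------------------------------------------
# Label preparation
# ---------------------------------------------------------------------------

def exclude_borders(mask: np.ndarray, radius: int) -> np.ndarray:
    """Mark pixels within Chebyshev distance ``radius`` of a different
    (non-ignore) class as ignore.  Radius 0 is the identity; the operation is
    idempotent at fixed radius and its ignore set grows with the radius."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mask = np.asarray(mask)
    if radius == 0:
        return mask.copy()
    out = mask.copy()
    size = 2 * radius + 1
    for c in np.unique(mask):
        if c == IGNORE:
            continue
        other = (mask != c) & (mask != IGNORE)
        near_other = maximum_filter(other.astype(np.uint8), size=size) > 0
        out[(mask == c) & near_other] = IGNORE
    return out


def downsample_mask(mask: np.ndarray, factor: int = OUTPUT_FACTOR) -> np.ndarray:
    """Majority vote per ``factor``x``factor`` cell; ties and all-ignore cells
    become ignore."""
    h, w = mask.shape
    if h % factor or w % factor:
        raise ValueError(f"mask dims {h}x{w} not divisible by {factor}")
    cells = mask.reshape(h // factor, factor, w // factor, factor)
    cells = cells.transpose(0, 2, 1, 3).reshape(h // factor, w // factor, -1)
    counts = np.stack([(cells == c).sum(axis=-1) for c in CLASSES], axis=-1)
    best = counts.argmax(axis=-1).astype(np.uint8)
    sorted_counts = np.sort(counts, axis=-1)
    tie = sorted_counts[..., -1] == sorted_counts[..., -2]
    empty = sorted_counts[..., -1] == 0
    best[tie | empty] = IGNORE
    return best


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    brightness: Tuple[float, float] = (0.7, 1.3),
    saturation: Tuple[float, float] = (0.7, 1.3),
) -> Tuple[np.ndarray, np.ndarray]:
    """Random brightness/saturation jitter (image only) and joint horizontal /
    vertical flips (probability 0.5 each); image values clipped to [0, 1].

    The image and mask may live on different grids (full vs output
    resolution); flips act per-axis so the spatial correspondence survives.
    """
    image = np.asarray(image, np.float32)
    mask = np.asarray(mask)
    b = rng.uniform(*brightness)
    s = rng.uniform(*saturation)
    gray = image.mean(axis=-1, keepdims=True)
    image = gray + s * (image - gray)
    image = np.clip(image * b, 0.0, 1.0)
    if rng.random() < 0.5:  # horizontal flip
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if rng.random() < 0.5:  # vertical flip
        image = image[::-1]
        mask = mask[::-1]
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

_LOG_EPS = 1e-12


def soft_cross_entropy(target: np.ndarray, probs: np.ndarray) -> float:
    """Mean per-pixel cross-entropy H(target, probs).

    Always >= the target's own entropy, with equality iff the distributions
    match pixelwise.
    """
    return float(-(target * np.log(probs + _LOG_EPS)).sum(axis=-1).mean())


def _logits_node(model: SegModel) -> str:
    term = model.graph.terminal()
    if term.kind != "softmax":
        raise ValueError("model must end in a softmax node")
    return term.inputs[0]


def _run_epochs(
    model: SegModel,
    images: np.ndarray,
    targets: np.ndarray,
    tweight: np.ndarray,
    config: TrainConfig,
) -> SegModel:
    """Shared minibatch loop.  ``targets`` are per-pixel distributions and
    ``tweight`` per-pixel weights (0 excludes a pixel)."""
    rng = np.random.default_rng(config.seed)
    opt = engine.Adam(lr=config.learning_rate)
    logits_id = _logits_node(model)
    out_id = model.graph.output_nodes[-1]
    n = len(images)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_pix = 0.0, 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = images[idx]
            tb = targets[idx]
            wb = tweight[idx]
            if config.augment:
                xb = xb.copy()
                tb = tb.copy()
                wb = wb.copy()
                for k in range(len(idx)):
                    pair = np.concatenate([tb[k], wb[k][..., None]], axis=-1)
                    xb[k], pair = augment_pair(xb[k], pair, rng)
                    tb[k], wb[k] = pair[..., :-1], pair[..., -1]
            nw = wb.sum()
            if nw == 0:
                continue  # ignore-only batch contributes zero gradient
            acts, saved = engine.forward(model.graph, model.weights,
                                         model.buffers, xb, training=True)
            p = acts[out_id]
            epoch_loss += float(-(wb[..., None] * tb * np.log(p + _LOG_EPS)).sum())
            epoch_pix += float(nw)
            grad = (p - tb) * wb[..., None] / nw
            grads = engine.backward(model.graph, model.weights, acts, saved,
                                    {logits_id: grad})
            opt.step(model.weights, grads)
        model.history.append(epoch_loss / max(epoch_pix, 1.0))
    return model


def _prepare_hard(
    dataset: Sequence[Tuple[np.ndarray, np.ndarray]], border_radius: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    images, targets, weights = [], [], []
    for image, mask in dataset:
        image = np.asarray(image, np.float32)
        mask = np.asarray(mask)
        if mask.shape[0] * OUTPUT_FACTOR == image.shape[0]:
            pass  # already at output resolution
        elif mask.shape == image.shape[:2]:
            mask = downsample_mask(mask)
        else:
            raise ValueError("mask must be at image or output resolution")
        mask = exclude_borders(mask, border_radius)
        onehot = np.zeros(mask.shape + (len(CLASSES),), np.float32)
        for c in CLASSES:
            onehot[..., c] = mask == c
        images.append(image)
        targets.append(onehot)
        weights.append((mask != IGNORE).astype(np.float32))
    return np.stack(images), np.stack(targets), np.stack(weights)


def train_hard(
    model: SegModel,
    dataset: Sequence[Tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> SegModel:
    """Train on (image, class-mask) pairs; masks may be at full or output
    resolution.  Raises if, after border exclusion, no labelled pixel remains
    anywhere in the dataset."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    images, targets, weights = _prepare_hard(dataset, config.border_radius)
    if weights.sum() == 0:
        raise ValueError("dataset has zero non-ignore pixels")
    return _run_epochs(model, images, targets, weights, config)


def train_distill(
    student: SegModel,
    dataset: Sequence[Tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> SegModel:
    """Train on (image, teacher probability map) pairs.

    The student mimics the teacher's entire output distribution; soft labels
    whose rows do not sum to 1 are rejected.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    images, targets = [], []
    for image, soft in dataset:
        soft = np.asarray(soft, np.float32)
        if soft.ndim != 3 or soft.shape[-1] != len(CLASSES):
            raise ValueError("soft labels must be (h, w, n_classes)")
        if np.abs(soft.sum(axis=-1) - 1.0).max() > 1e-4 or (soft < 0).any():
            raise ValueError("soft labels must be per-pixel distributions")
        images.append(np.asarray(image, np.float32))
        targets.append(soft)
    images = np.stack(images)
    targets = np.stack(targets)
    weights = np.ones(targets.shape[:-1], np.float32)
    return _run_epochs(student, images, targets, weights, config)
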