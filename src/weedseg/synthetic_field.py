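"""Seeded synthetic field imagery with exact ground truth.

Emulates a camera looking straight down at a single crop row: brown soil with
low-frequency texture, a few large crop plants (rosettes of overlapping
elliptical leaves) centred on a vertical row line, smaller irregular weed
blobs scattered uniformly, and an optional harsh diagonal lighting band with a
hard shadow.  Crops and weeds differ in size, shape regularity and a small hue
offset (default 15 degrees toward yellow-green), mirroring the fact that
colour alone does not separate the classes when plants are equally sized or
adjacent — set ``hue_offset_deg=0`` for that hard regime.

Every plant pixel is green-dominant (G >= R and G >= B): plant hues stay
inside [90, 150] degrees and all later lighting/noise operations act on the
channels jointly, so a trivial colour-threshold baseline is always available
as a sanity comparison.

Masks use 0=soil, 1=crop, 2=weed at full image resolution; the generator never
emits ignore pixels (border exclusion and downsampling happen at training
time).
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from skimage.draw import ellipse as _ellipse
from skimage.transform import resize as _resize

from .metrics import CROP, SOIL, WEED

__all__ = ["FieldConfig", "generate_field", "generate_dataset"]

_SOIL_RGB = np.array([0.42, 0.31, 0.21], np.float32)
_CROP_HUE_DEG = 120.0


@dataclass(frozen=True)
class FieldConfig:
    """Study conditions for one synthetic field image.

    Defaults emulate the nominal 320x240 capture: a few large crop plants in a
    row (radius 20-40 px), around six smaller weeds per image (Poisson, radius
    4-12 px), and a 30% chance of a harsh lighting band.
    """

    height: int = 240
    width: int = 320
    n_crops: int = 3
    crop_radius_range: Tuple[float, float] = (20.0, 40.0)
    weed_density: float = 6.0
    weed_radius_range: Tuple[float, float] = (4.0, 12.0)
    row_jitter: float = 6.0
    shadow_prob: float = 0.3
    hue_offset_deg: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("field must be at least 8x8 pixels")
        for name in ("crop_radius_range", "weed_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval")
        if self.n_crops < 0 or self.weed_density < 0:
            raise ValueError("plant counts must be non-negative")
        if not (0 <= self.shadow_prob <= 1):
            raise ValueError("shadow_prob must be in [0, 1]")


def _plant_rgb(rng: np.random.Generator, hue_deg: float) -> np.ndarray:
    # keep hue within [90, 150] so green stays the dominant channel
    h = float(np.clip(hue_deg + rng.normal(0.0, 3.0), 90.0, 150.0)) / 360.0
    s = 0.55 + 0.15 * rng.random()
    v = 0.40 + 0.25 * rng.random()
    return np.array(colorsys.hsv_to_rgb(h, s, v), np.float32)


def _paint_blob(
    class_map: np.ndarray,
    color_map: np.ndarray,
    rng: np.random.Generator,
    cy: float,
    cx: float,
    radius: float,
    n_lobes: int,
    spread: float,
    aspect: Tuple[float, float],
    cls: int,
    rgb: np.ndarray,
) -> None:
    h, w = class_map.shape
    base_angle = rng.uniform(0, 2 * np.pi)
    for k in range(n_lobes):
        theta = base_angle + 2 * np.pi * k / n_lobes + rng.normal(0.0, 0.25)
        ly = cy + spread * radius * np.sin(theta)
        lx = cx + spread * radius * np.cos(theta)
        a = max(1.0, aspect[0] * radius * (0.8 + 0.4 * rng.random()))
        b = max(1.0, aspect[1] * radius * (0.8 + 0.4 * rng.random()))
        rr, cc = _ellipse(ly, lx, a, b, shape=(h, w), rotation=theta)
        class_map[rr, cc] = cls
        color_map[rr, cc] = rgb * (0.9 + 0.2 * rng.random())


def generate_field(
    config: FieldConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """One image/mask pair; identical output for an identically seeded rng.

    Returns ``(image, mask)``: float32 RGB in [0, 1] of shape (H, W, 3) and a
    uint8 class map of shape (H, W).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width

    # soil: brown base modulated by low-frequency value noise + fine grain
    coarse = rng.random((H // 16 + 2, W // 16 + 2))
    texture = _resize(coarse, (H, W), order=1, anti_aliasing=False)
    img = _SOIL_RGB * (0.80 + 0.35 * texture)[..., None]
    img = img + rng.normal(0.0, 0.015, (H, W, 1))

    class_map = np.full((H, W), SOIL, np.uint8)
    color_map = np.zeros((H, W, 3), np.float32)

    # crops: rosettes of 5-9 leaves on the central row line
    for i in range(config.n_crops):
        cy = (i + 0.5) * H / max(config.n_crops, 1) + rng.normal(0, config.row_jitter)
        cx = W / 2 + rng.normal(0, config.row_jitter)
        radius = rng.uniform(*config.crop_radius_range)
        _paint_blob(
            class_map, color_map, rng, cy, cx, radius,
            n_lobes=int(rng.integers(5, 10)), spread=0.45, aspect=(0.55, 0.28),
            cls=CROP, rgb=_plant_rgb(rng, _CROP_HUE_DEG),
        )

    # weeds: smaller irregular blobs anywhere, hue shifted toward yellow-green
    weed_hue = _CROP_HUE_DEG - config.hue_offset_deg
    for _ in range(int(rng.poisson(config.weed_density))):
        cy = rng.uniform(0, H)
        cx = rng.uniform(0, W)
        radius = rng.uniform(*config.weed_radius_range)
        _paint_blob(
            class_map, color_map, rng, cy, cx, radius,
            n_lobes=int(rng.integers(2, 5)), spread=0.35, aspect=(0.9, 0.5),
            cls=WEED, rgb=_plant_rgb(rng, weed_hue),
        )

    plant = class_map != SOIL
    grain = np.clip(1.0 + rng.normal(0.0, 0.05, (H, W)), 0.8, 1.2)
    img = np.where(plant[..., None], color_map * grain[..., None], img)

    # harsh diagonal lighting: bright band on one side of a line, hard shadow
    # on the other; channels scale jointly so green dominance is preserved
    if rng.random() < config.shadow_prob:
        phi = rng.uniform(0, np.pi)
        py, px = rng.uniform(0, H), rng.uniform(0, W)
        yy, xx = np.mgrid[0:H, 0:W]
        side = (yy - py) * np.cos(phi) - (xx - px) * np.sin(phi) > 0
        img = np.where(side[..., None], img * 1.6, img * 0.5)

    return np.clip(img, 0.0, 1.0).astype(np.float32), class_map


def generate_dataset(
    config: FieldConfig,
    n_images: int,
    out_dir,
    overlap_stride: Optional[int] = None,
) -> Path:
    """Write ``images/NNNN.png`` + ``masks/NNNN.png`` + ``manifest.json``.

    Image i is generated from the seed sequence ``(config.seed, i)``, so the
    manifest alone reproduces the dataset bit-for-bit.  With
    ``overlap_stride`` (< height) a single tall field strip is generated and
    windowed at that vertical stride, emulating strongly overlapping video
    frames.
    """
    from .cli_io import write_image, write_mask  # deferred: cli_io imports us

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    if overlap_stride is not None:
        if not (0 < overlap_stride < config.height):
            raise ValueError("overlap_stride must be in (0, height)")
        strip_h = overlap_stride * (n_images - 1) + config.height
        ratio = strip_h / config.height
        strip_cfg = replace(
            config,
            height=strip_h,
            n_crops=max(1, round(config.n_crops * ratio)),
            weed_density=config.weed_density * ratio,
        )
        image, mask = generate_field(strip_cfg, np.random.default_rng([config.seed, 0]))
        frames = [
            (image[i * overlap_stride : i * overlap_stride + config.height],
             mask[i * overlap_stride : i * overlap_stride + config.height])
            for i in range(n_images)
        ]
    else:
        frames = [
            generate_field(config, np.random.default_rng([config.seed, i]))
            for i in range(n_images)
        ]

    for i, (image, mask) in enumerate(frames):
        write_image(image, out / "images" / f"{i:04d}.png")
        write_mask(mask, out / "masks" / f"{i:04d}.png")

    manifest = {
        "generator": "weedseg.synthetic_field",
        "config": asdict(config),
        "n_images": int(n_images),
        "overlap_stride": overlap_stride,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
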