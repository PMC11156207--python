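"""Training-time data augmentation.

Augmentations are applied in random order per sample: horizontal flip
(p = 0.5), independent brightness/contrast jitter (factors ~ U(0.5, 1.5),
p = 0.95), rotation ~ U(-25, 25) degrees combined with shear
~ U(-15, 15) degrees (p = 1/3), and isotropic scaling ~ U(0.8, 1.2)
(p = 1/3). Geometric transforms are applied identically to the image and
all target channels (nearest-neighbour for the binary region/vessel
channels, linear for the image and the fovea heat map) and the fovea
column annotation is carried through every transform. Peripapillary
scans (1536 x 768) are trained on 768 x 768 crops taken at a random
multiple-of-192 column offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform

from ..io_prep import adjust_contrast

__all__ = ["AugmentationConfig", "augment_sample", "peripapillary_crop"]


@dataclass(frozen=True)
class AugmentationConfig:
    hflip_p: float = 0.5
    brightness_range: tuple[float, float] = (0.5, 1.5)
    contrast_range: tuple[float, float] = (0.5, 1.5)
    photometric_p: float = 0.95
    rotation_range: tuple[float, float] = (-25.0, 25.0)
    shear_range: tuple[float, float] = (-15.0, 15.0)
    affine_p: float = 1.0 / 3.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    scale_p: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for p in (self.hflip_p, self.photometric_p, self.affine_p, self.scale_p):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


def _apply_affine(
    image: np.ndarray,
    targets: np.ndarray,
    point: np.ndarray,
    fwd: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Warp image/targets by the 2x2 matrix ``fwd`` about the image centre.

    ``point`` is a (row, col) coordinate mapped through the same forward
    transform. scipy's affine_transform pulls output pixels from
    ``inv @ (out - centre) + centre``.
    """
    h, w = image.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    inv = np.linalg.inv(fwd)
    offset = centre - inv @ centre

    def warp(channel: np.ndarray, order: int) -> np.ndarray:
        return affine_transform(
            channel, inv, offset=offset, order=order, mode="constant", cval=0.0
        )

    image = warp(image, 1)
    out_t = np.stack(
        [
            warp(targets[0], 0),  # region: binary
            warp(targets[1], 0),  # vessel: binary
            warp(targets[2], 1),  # fovea heat map: linear
        ]
    )
    new_point = fwd @ (point - centre) + centre
    return image, out_t, new_point


def augment_sample(
    image: np.ndarray,
    targets: np.ndarray,
    fovea_col: int,
    config: AugmentationConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Photometric + geometric augmentation of one (image, targets) pair.

    ``targets`` is a (3, H, W) stack in (region, vessel, fovea) order.
    Returns the transformed pair and the updated fovea column. Fully
    deterministic given ``seed``.
    """
    cfg = config or AugmentationConfig()
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float64)
    tgt = np.asarray(targets, dtype=np.float64)
    h, w = img.shape
    point = np.array([(h - 1) / 2.0, float(fovea_col)])

    ops = ["flip", "photometric", "rotate_shear", "scale"]
    rng.shuffle(ops)
    for op in ops:
        if op == "flip":
            if rng.random() < cfg.hflip_p:
                img = img[:, ::-1].copy()
                tgt = tgt[:, :, ::-1].copy()
                point[1] = w - 1 - point[1]
        elif op == "photometric":
            if rng.random() < cfg.photometric_p:
                brightness = rng.uniform(*cfg.brightness_range)
                contrast = rng.uniform(*cfg.contrast_range)
                img = np.clip(img * brightness, 0.0, 1.0)
                img = adjust_contrast(img, contrast)
        elif op == "rotate_shear":
            if rng.random() < cfg.affine_p:
                theta = math.radians(rng.uniform(*cfg.rotation_range))
                shear = math.radians(rng.uniform(*cfg.shear_range))
                rot = np.array(
                    [[math.cos(theta), -math.sin(theta)],
                     [math.sin(theta), math.cos(theta)]]
                )
                shr = np.array([[1.0, 0.0], [math.tan(shear), 1.0]])
                img, tgt, point = _apply_affine(img, tgt, point, rot @ shr)
        elif op == "scale":
            if rng.random() < cfg.scale_p:
                factor = rng.uniform(*cfg.scale_range)
                img, tgt, point = _apply_affine(
                    img, tgt, point, np.diag([factor, factor])
                )
    new_col = int(np.clip(round(point[1]), 0, w - 1))
    return img, tgt, new_col


def peripapillary_crop(
    image: np.ndarray,
    targets: np.ndarray,
    seed: int = 0,
    crop: int = 768,
    multiple: int = 192,
) -> tuple[np.ndarray, np.ndarray]:
    """Random 768-wide crop at a multiple-of-192 column offset."""
    rng = np.random.default_rng(seed)
    w = image.shape[1]
    if w < crop:
        raise ValueError("image narrower than the crop")
    n_offsets = (w - crop) // multiple + 1
    off = int(rng.integers(0, n_offsets)) * multiple
    return image[:, off : off + crop], targets[:, :, off : off + crop]
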