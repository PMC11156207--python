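"""Niblack local-thresholding vessel segmentation.

Niblack thresholding labels a pixel as vessel when its intensity falls
below ``local_mean + k * local_std`` computed over a fixed sliding
window. With a negative ``k`` this picks out locally dark structures —
the choroidal vessel lumina — and is the conventional automated
comparator for choroidal vessel segmentation (window 51, k = -0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["NiblackConfig", "local_stats", "segment_vessels_niblack"]


@dataclass(frozen=True)
class NiblackConfig:
    window: int = 51
    k: float = -0.05

    def __post_init__(self) -> None:
        if self.window % 2 != 1 or self.window < 3:
            raise ValueError("window must be odd and >= 3")


def local_stats(image: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and population std over a centred ``window`` square.

    Borders are handled by reflection padding (scipy's ``reflect`` mode,
    which mirrors without repeating the edge sample).
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    img = np.asarray(image, dtype=np.float64)
    if window > min(img.shape):
        raise ValueError("window larger than the image")
    mean = uniform_filter(img, size=window, mode="mirror")
    sq_mean = uniform_filter(img * img, size=window, mode="mirror")
    var = np.maximum(sq_mean - mean * mean, 0.0)
    return mean, np.sqrt(var)


def segment_vessels_niblack(
    image: np.ndarray,
    region_mask: np.ndarray,
    config: NiblackConfig | None = None,
) -> np.ndarray:
    """Binary vessel mask: ``image < mean + k*std`` restricted to the region.

    The inequality is strict, so a perfectly constant image yields an
    empty mask.
    """
    cfg = config or NiblackConfig()
    mean, std = local_stats(image, cfg.window)
    threshold = mean + cfg.k * std
    return (np.asarray(image, dtype=np.float64) < threshold) & (
        np.asarray(region_mask, dtype=bool)
    )
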