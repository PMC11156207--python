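"""Fovea heat-map target construction and fovea-column extraction.

A single fovea pixel is too sparse a target for a dense segmentation
network: an all-zero prediction would achieve almost the same loss as a
perfect one. The fovea channel is therefore trained against a small
smoothed plateau centred on the annotated fovea location: the exact pixel
is 1.0, its column 0.95, neighbouring columns decay linearly with column
distance, and every other pixel is held at a small positive floor
(one-sided label smoothing) to stabilise training.

At inference time the fovea column is recovered by summing the predicted
map column-wise, smoothing the sums with a triangular filter, and taking
the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FoveaTargetConfig",
    "build_fovea_target",
    "triangular_kernel",
    "extract_fovea_column",
    "extract_fovea_row",
    "NoFoveaError",
]


class NoFoveaError(ValueError):
    """Raised when a probability map carries no fovea signal at all."""


@dataclass(frozen=True)
class FoveaTargetConfig:
    """Parameters of the fovea training target and of column extraction.

    ``target_height`` x ``target_width`` is the window centred on the
    annotated fovea; the column at distance ``d`` from the fovea column is
    set to ``column_base - d * column_decay`` (floored at ``background``),
    the fovea column itself to ``column_base`` and the exact fovea pixel to
    ``peak``. ``filter_width`` is the width of the triangular filter used
    when reading the column back out of a predicted map.
    """

    target_height: int = 51
    target_width: int = 19
    peak: float = 1.0
    column_base: float = 0.95
    column_decay: float = 0.1
    background: float = 0.01
    filter_width: int = 21

    def __post_init__(self) -> None:
        if self.target_width % 2 != 1 or self.target_height % 2 != 1:
            raise ValueError("target window dimensions must be odd")
        if self.filter_width % 2 != 1:
            raise ValueError("filter_width must be odd")


def build_fovea_target(
    shape: tuple[int, int],
    fovea_col: int,
    fovea_row: int,
    config: FoveaTargetConfig | None = None,
) -> np.ndarray:
    """Render the smoothed fovea target for an ``shape`` = (H, W) image.

    The window is clipped at the image borders; pixels outside it hold the
    background floor.
    """
    cfg = config or FoveaTargetConfig()
    h, w = shape
    if not (0 <= fovea_col < w and 0 <= fovea_row < h):
        raise ValueError(
            f"fovea ({fovea_row}, {fovea_col}) outside image of shape {shape}"
        )
    target = np.full((h, w), cfg.background, dtype=np.float64)

    half_h = (cfg.target_height - 1) // 2
    half_w = (cfg.target_width - 1) // 2
    r0, r1 = max(0, fovea_row - half_h), min(h, fovea_row + half_h + 1)
    c0, c1 = max(0, fovea_col - half_w), min(w, fovea_col + half_w + 1)

    cols = np.arange(c0, c1)
    col_vals = np.maximum(
        cfg.column_base - np.abs(cols - fovea_col) * cfg.column_decay,
        cfg.background,
    )
    target[r0:r1, c0:c1] = col_vals[None, :]
    target[fovea_row, fovea_col] = cfg.peak
    return target


def triangular_kernel(width: int) -> np.ndarray:
    """Symmetric triangular filter of odd ``width``, normalised to sum 1.

    For width 21 the unnormalised taps are 1, 2, ..., 11, ..., 2, 1.
    """
    if width % 2 != 1 or width < 1:
        raise ValueError("kernel width must be odd and positive")
    half = (width + 1) // 2
    ramp = np.arange(1, half + 1, dtype=np.float64)
    taps = np.concatenate([ramp, ramp[-2::-1]])
    return taps / taps.sum()


def _filtered_sums(prob: np.ndarray, axis: int, width: int) -> np.ndarray:
    sums = np.asarray(prob, dtype=np.float64).sum(axis=axis)
    return np.convolve(sums, triangular_kernel(width), mode="same")


def extract_fovea_column(
    fovea_prob: np.ndarray, config: FoveaTargetConfig | None = None
) -> int:
    """Fovea column = argmax of triangular-filtered column sums.

    Ties are broken toward the lowest column index; the convolution uses
    zero padding, so a uniform map would (deterministically) resolve to an
    interior column rather than an edge.
    """
    cfg = config or FoveaTargetConfig()
    prob = np.asarray(fovea_prob, dtype=np.float64)
    if prob.size == 0:
        raise ValueError("empty probability map")
    if not np.any(prob > 0):
        raise NoFoveaError("probability map carries no fovea signal")
    return int(np.argmax(_filtered_sums(prob, axis=0, width=cfg.filter_width)))


def extract_fovea_row(
    fovea_prob: np.ndarray, config: FoveaTargetConfig | None = None
) -> int:
    """Fovea row via the same triangular filtering applied to row sums.

    The row is needed only to centre the target window vertically; the
    fovea-centred region of interest itself depends on the column alone.
    """
    cfg = config or FoveaTargetConfig()
    prob = np.asarray(fovea_prob, dtype=np.float64)
    if prob.size == 0:
        raise ValueError("empty probability map")
    if not np.any(prob > 0):
        raise NoFoveaError("probability map carries no fovea signal")
    return int(np.argmax(_filtered_sums(prob, axis=1, width=cfg.filter_width)))
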