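"""Loading, normalisation and device-specific preprocessing of B-scans.

Also provides the photometric primitives (gamma brightness fixing,
linear contrast adjustment) shared by the vessel ground-truth ensemble
and the training augmentations.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import zoom

from .core import BScan, DegenerateInputError, Device, ScanType

__all__ = [
    "load_bscan",
    "normalize_image",
    "gamma_to_target_mean",
    "adjust_contrast",
    "preprocess_topcon",
    "HEIDELBERG_SCALE_X",
]

# 30 degree (9 mm) lateral field over 768 columns
HEIDELBERG_SCALE_X = 9000.0 / 768.0


def normalize_image(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Luminance conversion + per-image min-max scaling to [0, 1].

    Returns the image and a flag set when the input had zero dynamic range
    (such an image is returned as all zeros).
    """
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim == 3:  # RGB(A) -> ITU-R 601 luminance
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {raw.shape}")
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo <= 0:
        warnings.warn("image has zero dynamic range; loading as all zeros")
        return np.zeros_like(arr), True
    return (arr - lo) / (hi - lo), False


def load_bscan(
    path: str | Path,
    scale_x: float,
    scale_y: float,
    device: Device | str = Device.UNKNOWN,
    scan_type: ScanType | str = ScanType.HLINE,
) -> BScan:
    """Read a PNG/TIFF raster (8- or 16-bit, gray or RGB) as a BScan."""
    image, flat = normalize_image(iio.imread(Path(path)))
    return BScan(
        image=image,
        scale_x=scale_x,
        scale_y=scale_y,
        device=Device(device),
        scan_type=ScanType(scan_type),
        zero_dynamic_range=flat,
    )


def gamma_to_target_mean(
    image: np.ndarray, target_mean: float, tol: float = 1e-4
) -> np.ndarray:
    """Gamma-correct ``image`` so its mean brightness equals ``target_mean``.

    Solves mean(image ** g) = target_mean for g > 0 by bisection; the map
    g -> mean(image**g) is strictly decreasing for non-degenerate images
    with values in [0, 1], so the root is unique. Raises
    DegenerateInputError for constant images, for which no gamma exists
    unless the value already equals the target.
    """
    if not (0.0 < target_mean < 1.0):
        raise ValueError("target_mean must lie strictly inside (0, 1)")
    img = np.asarray(image, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    if img.max() - img.min() <= 0:
        raise DegenerateInputError("constant image: gamma cannot move the mean")

    def mean_at(g: float) -> float:
        return float(np.mean(img**g))

    # mean(img**g) is strictly decreasing in g; bisect in log space since
    # the root can span several decades
    lo, hi = 1e-3, 1e3
    if target_mean >= mean_at(lo):
        return img**lo
    if target_mean <= mean_at(hi):
        return img**hi
    g = 1.0
    for _ in range(100):
        g = float(np.sqrt(lo * hi))
        m = mean_at(g)
        if abs(m - target_mean) <= tol:
            break
        if m > target_mean:
            lo = g
        else:
            hi = g
    return img**g


def adjust_contrast(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale deviations from the image mean by ``factor``, clipped to [0, 1]."""
    if factor <= 0:
        raise ValueError("contrast factor must be positive")
    img = np.asarray(image, dtype=np.float64)
    mean = float(img.mean())
    return np.clip(mean + factor * (img - mean), 0.0, 1.0)


def preprocess_topcon(
    image: np.ndarray,
    scale_x: float | None = None,
    scale_y: float | None = None,
    crop_side: str = "both",
) -> BScan:
    """Map a raw 992 x 1024 Triton B-scan onto the 768 x 768 working grid.

    Removes 32 columns (16 per side by default; ``crop_side`` may be
    ``left``/``right``/``both``), bilinearly resizes to 768 x 768 and
    rescales the pixel sizes so the physical extent is preserved.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape != (992, 1024):
        raise ValueError(f"expected a 992 x 1024 Triton scan, got {img.shape}")
    if crop_side == "both":
        cropped = img[:, 16:-16]
    elif crop_side == "left":
        cropped = img[:, 32:]
    elif crop_side == "right":
        cropped = img[:, :-32]
    else:
        raise ValueError("crop_side must be left, right or both")

    h0, w0 = cropped.shape
    out = zoom(cropped, (768 / h0, 768 / w0), order=1, grid_mode=True, mode="nearest")
    out = np.clip(out, min(0.0, img.min()), max(1.0, img.max()))
    if img.min() >= 0 and img.max() <= 1:
        out = np.clip(out, 0.0, 1.0)
    sx = (scale_x * w0 / 768.0) if scale_x is not None else HEIDELBERG_SCALE_X
    sy = (scale_y * h0 / 768.0) if scale_y is not None else HEIDELBERG_SCALE_X
    return BScan(
        image=out if out.max() <= 1 else out / out.max(),
        scale_x=sx,
        scale_y=sy,
        device=Device.TOPCON_TRITON,
        scan_type=ScanType.RADIAL,
    )


def transform_topcon_column(col: float, crop_side: str = "both") -> float:
    """Column-coordinate counterpart of :func:`preprocess_topcon`."""
    offset = {"both": 16.0, "left": 32.0, "right": 0.0}[crop_side]
    return (col - offset) * 768.0 / 992.0
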