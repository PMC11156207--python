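"""Fovea-centred choroidal metrics: thickness, area and vascular index.

All metrics are computed inside a region of interest (ROI) centred at the
foveal pit and extending 3 mm temporally and nasally — the 6000 micron
ETDRS macular width. Thickness is measured at the three columns spanning
the ROI as point-source micron distances between the upper (RPE-C) and
lower (C-S) choroid boundaries, locally perpendicular to the upper
boundary; area is pixel counting scaled to mm^2; the choroid vascular
index (CVI) is the vessel fraction of the choroid, with a "soft" variant
computed directly from predicted probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.measure import label as cc_label

from .core import BScan, ScanType, SegmentationOutput, UndefinedMetricError
from .fovea import FoveaTargetConfig, NoFoveaError, extract_fovea_column

__all__ = [
    "Boundaries",
    "ROIWindow",
    "ChoroidMetrics",
    "extract_boundaries",
    "define_roi",
    "compute_thickness",
    "compute_area",
    "compute_vascular_index",
    "analyze_scan",
]

ETDRS_HALF_WIDTH_UM = 3000.0
TANGENT_HALF_WINDOW = 15  # columns on each side of a measurement location


@dataclass
class Boundaries:
    """Per-column subpixel traces of the choroid boundaries.

    ``upper``/``lower`` use a half-pixel edge convention: a column whose
    region pixels occupy rows r0..r1 has upper = r0 - 0.5 and
    lower = r1 + 0.5, so (lower - upper) equals the pixel count. Columns
    without region pixels hold NaN. ``upper_smooth``/``lower_smooth`` are
    15-column moving-average copies kept for display; tangents are
    estimated by local linear fits on the raw traces.
    """

    upper: np.ndarray
    lower: np.ndarray
    valid_columns: np.ndarray
    upper_smooth: np.ndarray = field(default=None)  # type: ignore[assignment]
    lower_smooth: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class ROIWindow:
    """Inclusive column bounds of the fovea-centred ETDRS window."""

    center_col: int
    half_width_um: float
    col_lo: int
    col_hi: int


@dataclass
class ChoroidMetrics:
    """Derived metrics for one scan; NaN where a quantity is unavailable."""

    thickness_um: tuple[float, float, float]
    thickness_mean_um: float
    area_mm2: float
    cvi: float
    soft_cvi: float
    roi: Optional[ROIWindow]
    fovea_col: Optional[int] = None
    region_mask: Optional[np.ndarray] = None
    vessel_mask: Optional[np.ndarray] = None
    flags: list[str] = field(default_factory=list)


def _smooth_trace(trace: np.ndarray, window: int = 15) -> np.ndarray:
    out = np.full_like(trace, np.nan)
    valid = ~np.isnan(trace)
    if valid.any():
        out[valid] = uniform_filter1d(trace[valid], size=window, mode="nearest")
    return out


def extract_boundaries(region_mask: np.ndarray) -> Boundaries:
    """Trace the RPE-C (upper) and C-S (lower) junctions from a region mask.

    Only the largest connected component is traced, so isolated specks
    from imperfect binarization are ignored.
    """
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    labels = cc_label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest

    h, w = mask.shape
    has = mask.any(axis=0)
    rows = np.arange(h)[:, None]
    upper = np.full(w, np.nan)
    lower = np.full(w, np.nan)
    top = np.where(mask, rows, h).min(axis=0)
    bot = np.where(mask, rows, -1).max(axis=0)
    upper[has] = top[has] - 0.5
    lower[has] = bot[has] + 0.5
    return Boundaries(
        upper=upper,
        lower=lower,
        valid_columns=np.flatnonzero(has),
        upper_smooth=_smooth_trace(upper),
        lower_smooth=_smooth_trace(lower),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def define_roi(
    fovea_col: Optional[int],
    scale_x: float,
    width: int,
    scan_type: ScanType | str = ScanType.HLINE,
    half_width_um: float = ETDRS_HALF_WIDTH_UM,
) -> ROIWindow:
    """Fovea-centred ETDRS window, clipped to the image columns.

    Volume scans carry no fovea; their ROI is centred at the middle
    column index.
    """
    if scale_x <= 0:
        raise ValueError("scale_x must be positive")
    if ScanType(scan_type) == ScanType.VOLUME or fovea_col is None:
        center = width // 2
    else:
        center = int(fovea_col)
    half_px = _round_half_away(half_width_um / scale_x)
    return ROIWindow(
        center_col=center,
        half_width_um=half_width_um,
        col_lo=max(0, center - half_px),
        col_hi=min(width - 1, center + half_px),
    )


def _local_line(
    bounds_trace: np.ndarray, col: int, scale_x: float, scale_y: float
) -> tuple[float, float]:
    """OLS fit of the boundary over +/-15 columns in micron space.

    Returns (value at ``col`` in µm, slope dy/dx). Unbiased at trace ends
    for straight boundaries since the fit needs no symmetric window.
    """
    lo = max(col - TANGENT_HALF_WINDOW, 0)
    hi = min(col + TANGENT_HALF_WINDOW + 1, bounds_trace.size)
    cols = np.arange(lo, hi)
    vals = bounds_trace[lo:hi]
    ok = ~np.isnan(vals)
    cols, vals = cols[ok], vals[ok]
    if cols.size < 2:
        return float(vals[0] * scale_y) if vals.size else np.nan, 0.0
    x = cols * scale_x
    y = vals * scale_y
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope * col * scale_x + intercept), float(slope)


def _perpendicular_distance(
    bounds: Boundaries, col: int, scale_x: float, scale_y: float
) -> float:
    """Micron distance from the upper boundary at ``col`` along its inward
    normal to the (piecewise-linear) lower boundary."""
    if np.isnan(bounds.upper[col]):
        return np.nan
    py, slope = _local_line(bounds.upper, col, scale_x, scale_y)
    px = col * scale_x
    s = math.hypot(1.0, slope)
    ux, uy = -slope / s, 1.0 / s  # unit normal pointing toward the sclera

    valid = bounds.valid_columns
    lx = valid * scale_x
    ly = bounds.lower[valid] * scale_y

    def gap(t: float) -> float:
        x = px + t * ux
        if x < lx[0] - scale_x or x > lx[-1] + scale_x:
            return np.nan
        return (py + t * uy) - float(np.interp(x, lx, ly))

    height_um = (np.nanmax(bounds.lower) - np.nanmin(bounds.upper)) * scale_y
    t_max = 2.0 * height_um + 2.0 * max(scale_x, scale_y) + 1.0
    g0 = gap(0.0)
    if np.isnan(g0):
        return np.nan
    if g0 >= -1e-9:  # zero-height column (tolerate fit round-off)
        return 0.0
    # march until the ray crosses the lower boundary, then bisect
    step = max(min(scale_x, scale_y) / 4.0, 1e-3)
    t_prev, g_prev = 0.0, g0
    t = step
    while t <= t_max:
        g = gap(t)
        if np.isnan(g):
            return np.nan
        if g >= 0:
            for _ in range(60):
                mid = 0.5 * (t_prev + t)
                if gap(mid) < 0:
                    t_prev = mid
                else:
                    t = mid
            return 0.5 * (t_prev + t)
        t_prev, g_prev = t, g
        t += step
    return np.nan


def compute_thickness(
    bounds: Boundaries, roi: ROIWindow, scale_x: float, scale_y: float
) -> tuple[float, float, float]:
    """Choroid thickness (µm) at the three columns spanning the ROI.

    Measured perpendicular to the locally fitted RPE-C tangent; a
    location whose normal ray fails to meet the lower boundary inside the
    image yields NaN with a warning.
    """
    locations = [roi.col_lo, _round_half_away((roi.col_lo + roi.col_hi) / 2.0),
                 roi.col_hi]
    out = []
    for col in locations:
        d = _perpendicular_distance(bounds, col, scale_x, scale_y)
        if np.isnan(d):
            warnings.warn(f"thickness undefined at column {col}")
        out.append(float(d))
    return tuple(out)  # type: ignore[return-value]


def compute_area(
    region_mask: np.ndarray, roi: ROIWindow, scale_x: float, scale_y: float
) -> float:
    """Region pixel count within the ROI columns, scaled to mm^2."""
    mask = np.asarray(region_mask, dtype=bool)
    count = int(mask[:, roi.col_lo : roi.col_hi + 1].sum())
    return count * scale_x * scale_y * 1e-6


def compute_vascular_index(
    region: np.ndarray,
    vessel: np.ndarray,
    roi: ROIWindow,
    mode: str = "hard",
    region_threshold: float = 0.5,
    vessel_threshold: float = 0.5,
    literal_ratio: bool = False,
) -> float:
    """Choroid vascular index within the ROI columns.

    hard: binarize both maps and return vessel / total choroid pixel
    counts (the conventional CVI, bounded by 1). soft: use the
    probabilities directly, sum(p_vessel * p_region) / sum(p_region) —
    which reduces exactly to the hard index on binary maps.
    ``literal_ratio`` switches the denominator to non-vessel pixels.
    """
    r = np.asarray(region, dtype=np.float64)[:, roi.col_lo : roi.col_hi + 1]
    v = np.asarray(vessel, dtype=np.float64)[:, roi.col_lo : roi.col_hi + 1]
    if r.shape != v.shape:
        raise ValueError("region and vessel grids must be aligned")
    if mode == "hard":
        rb = r > region_threshold
        vb = (v > vessel_threshold) & rb
        total = float(rb.sum())
        vess = float(vb.sum())
    elif mode == "soft":
        total = float(r.sum())
        vess = float((v * r).sum())
    else:
        raise ValueError("mode must be 'hard' or 'soft'")
    if total <= 0:
        raise UndefinedMetricError("no choroid in the region of interest")
    if literal_ratio:
        if total - vess <= 0:
            raise UndefinedMetricError("no non-vessel choroid pixels in ROI")
        return vess / (total - vess)
    return vess / total


def analyze_scan(
    bscan: BScan,
    seg: SegmentationOutput,
    region_threshold: float = 0.5,
    vessel_threshold: float = 0.5,
    peripapillary_vessel_threshold: float = 0.25,
    fovea_config: FoveaTargetConfig | None = None,
) -> ChoroidMetrics:
    """Full metric derivation for one scan from soft segmentation maps.

    Peripapillary scans have no fovea-centred ROI: only the binarized
    masks are returned (vessels thresholded at 0.25). A fovea-expected
    scan whose fovea channel is empty falls back to the centre column
    with a warning flag.
    """
    flags: list[str] = []
    h, w = bscan.shape

    if bscan.scan_type == ScanType.PERIPAPILLARY:
        region = np.asarray(seg.region_prob) > region_threshold
        vessel = (np.asarray(seg.vessel_prob) > peripapillary_vessel_threshold) & region
        nan3 = (np.nan, np.nan, np.nan)
        return ChoroidMetrics(
            thickness_um=nan3, thickness_mean_um=np.nan, area_mm2=np.nan,
            cvi=np.nan, soft_cvi=np.nan, roi=None, fovea_col=None,
            region_mask=region, vessel_mask=vessel,
            flags=["peripapillary: segmentation-only output"],
        )

    if bscan.scan_type == ScanType.VOLUME:
        fovea_col: Optional[int] = None
    else:
        try:
            fovea_col = extract_fovea_column(seg.fovea_prob, fovea_config)
        except NoFoveaError:
            fovea_col = w // 2
            warnings.warn("no fovea signal; falling back to the centre column")
            flags.append("fovea-fallback-center")

    roi = define_roi(fovea_col, bscan.scale_x, w, bscan.scan_type)
    region = np.asarray(seg.region_prob) > region_threshold
    vessel = (np.asarray(seg.vessel_prob) > vessel_threshold) & region
    if not region[:, roi.col_lo : roi.col_hi + 1].any():
        raise UndefinedMetricError("no choroid region inside the ROI")

    bounds = extract_boundaries(region)
    thickness = compute_thickness(bounds, roi, bscan.scale_x, bscan.scale_y)
    area = compute_area(region, roi, bscan.scale_x, bscan.scale_y)
    cvi = compute_vascular_index(region, vessel, roi, "hard",
                                 region_threshold, vessel_threshold)
    soft = compute_vascular_index(seg.region_prob, seg.vessel_prob, roi, "soft")
    return ChoroidMetrics(
        thickness_um=thickness,
        thickness_mean_um=float(np.nanmean(thickness)),
        area_mm2=area,
        cvi=cvi,
        soft_cvi=soft,
        roi=roi,
        fovea_col=fovea_col,
        region_mask=region,
        vessel_mask=vessel,
        flags=flags,
    )
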