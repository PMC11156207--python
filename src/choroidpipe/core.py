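"""Shared container types for the choroidal analysis pipeline.

Coordinate convention used throughout: row 0 is the top of the B-scan
(vitreous side) and rows increase toward the sclera; all indices are
0-based. ``scale_x`` / ``scale_y`` are the lateral / axial pixel sizes in
microns per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Device",
    "ScanType",
    "Eye",
    "BScan",
    "SegmentationOutput",
    "ConfigurationError",
    "DegenerateInputError",
    "UndefinedMetricError",
]


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


class DegenerateInputError(ValueError):
    """Raised for inputs on which an operation is mathematically undefined."""


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


class Device(str, Enum):
    HEIDELBERG_STANDARD = "heidelberg_standard"
    HEIDELBERG_FLEX = "heidelberg_flex"
    TOPCON_TRITON = "topcon_triton"
    UNKNOWN = "unknown"


class ScanType(str, Enum):
    HLINE = "hline"
    VLINE = "vline"
    RADIAL = "radial"
    VOLUME = "volume"
    PERIPAPILLARY = "peripapillary"


class Eye(str, Enum):
    OD = "OD"
    OS = "OS"


@dataclass
class BScan:
    """A single OCT B-scan with physical pixel scaling and acquisition metadata.

    Attributes
    ----------
    image:
        H x W float array with intensities in [0, 1].
    scale_x, scale_y:
        Lateral and axial pixel size in microns per pixel.
    device, scan_type, eye:
        Acquisition metadata. Peripapillary scans are expected to be wider
        than tall (e.g. 1536 x 768).
    zero_dynamic_range:
        Set when the source image was constant and was loaded as all zeros.
    """

    image: np.ndarray
    scale_x: float
    scale_y: float
    device: Device = Device.UNKNOWN
    scan_type: ScanType = ScanType.HLINE
    eye: Optional[Eye] = None
    zero_dynamic_range: bool = False

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ConfigurationError("BScan image must be 2-D")
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ConfigurationError("pixel scales must be positive")
        lo, hi = float(self.image.min()), float(self.image.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ConfigurationError("BScan intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]


@dataclass
class SegmentationOutput:
    """Three aligned probability maps: choroid region, vessels, fovea."""

    region_prob: np.ndarray
    vessel_prob: np.ndarray
    fovea_prob: np.ndarray

    def __post_init__(self) -> None:
        maps = (self.region_prob, self.vessel_prob, self.fovea_prob)
        shapes = {np.asarray(m).shape for m in maps}
        if len(shapes) != 1:
            raise ConfigurationError("segmentation channels must be aligned")
        for m in maps:
            a = np.asarray(m)
            if a.min() < -1e-9 or a.max() > 1 + 1e-9:
                raise ConfigurationError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.region_prob).shape  # type: ignore[return-value]

    def stack(self) -> np.ndarray:
        """Return a 3 x H x W array in (region, vessel, fovea) order."""
        return np.stack([self.region_prob, self.vessel_prob, self.fovea_prob])
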