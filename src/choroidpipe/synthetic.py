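"""Seeded synthetic OCT B-scan generator with exact ground truth.

Real choroidal OCT data cannot be redistributed, so every test in this
package runs against synthetic B-scans whose geometry is known exactly.
A sample emulates the qualitative anatomy of a macular B-scan: a dark
vitreous at the top, a layered retinal complex with a foveal pit, a bright
choroidal stroma band containing dark elliptical vessel cross-sections
(larger lumina sampled toward the scleral side, mimicking Haller/Sattler
stratification), and a dimmer sclera below. Multiplicative log-normal
speckle is applied last; the returned masks describe the exact rendered
geometry *before* noise.

The generator is not a physical OCT simulator: there is no A-scan model,
no attenuation with depth, and speckle is spatially white. See
docs/methods.md for what this does and does not validate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ConfigurationError, SegmentationOutput
from .fovea import FoveaTargetConfig, build_fovea_target

__all__ = ["GeneratorConfig", "SyntheticSample", "generate_bscan",
           "generate_dataset", "degrade_to_probability_maps"]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of a synthetic B-scan.

    Units: geometry in microns, converted internally through the pixel
    scales; intensities in [0, 1]. ``height`` and ``width`` must be
    multiples of 64 so generated scans feed the segmentation network
    without padding. ``seed`` fully determines the output.
    """

    height: int = 768
    width: int = 768
    scale_x: float = 11.72      # µm/px lateral (30° / 9 mm over 768 px)
    scale_y: float = 3.87       # µm/px axial
    choroid_mean_thickness: float = 350.0   # µm, perpendicular to the band
    choroid_thickness_variation: float = 0.15
    vessel_count: int = 140
    vessel_radius_range: tuple[float, float] = (20.0, 120.0)  # µm
    vessel_intensity: float = 0.2
    stroma_intensity: float = 0.8
    fovea_pit_depth: float = 120.0          # µm
    speckle_sigma: float = 0.05
    tilt_degrees: float = 0.0
    seed: int = 0
    # surrounding tissue rendering (cosmetic, exposed for fixtures)
    vitreous_intensity: float = 0.05
    sclera_intensity: float = 0.35
    retina_thickness: float = 300.0         # µm
    band_top_fraction: float = 0.45         # RPE-C depth as fraction of height
    max_vessel_overlap: float = 0.25

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.height % 64 or self.width % 64:
            raise ConfigurationError("height and width must be multiples of 64")
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ConfigurationError("pixel scales must be positive")
        for name in ("vessel_intensity", "stroma_intensity", "speckle_sigma",
                     "vitreous_intensity", "sclera_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.vessel_radius_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("vessel radii must be positive and ordered")
        if self.vessel_count < 0:
            raise ConfigurationError("vessel_count must be >= 0")
        if self.choroid_mean_thickness <= 0:
            raise ConfigurationError("choroid thickness must be positive")
        if abs(self.tilt_degrees) >= 45:
            raise ConfigurationError("tilt limited to |tilt| < 45 degrees")


@dataclass
class SyntheticSample:
    """A synthetic B-scan plus its exact ground truth.

    ``thickness_px`` and ``band_top_px`` are the generator's internal
    per-column rasterised band profile (the number of region rows in each
    column and the first region row). ``vessel_area_tally`` is the
    accumulated per-ellipse rasterised area (clipped to the band) divided
    by the band area; because vessels are placed with bounded mutual
    overlap this analytic tally tracks the realised vessel fraction.
    """

    image: np.ndarray
    region_mask: np.ndarray
    vessel_mask: np.ndarray
    fovea_col: int
    fovea_row: int
    scale_x: float
    scale_y: float
    thickness_px: np.ndarray = field(default=None)  # type: ignore[assignment]
    band_top_px: np.ndarray = field(default=None)   # type: ignore[assignment]
    vessel_area_tally: float = 0.0
    config: Optional[GeneratorConfig] = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]

    @property
    def vessel_fraction(self) -> float:
        return float(self.vessel_mask.sum() / max(self.region_mask.sum(), 1))


def _smooth_profile(rng: np.random.Generator, width: int) -> np.ndarray:
    """Smooth zero-mean profile in [-1, 1] from two low-frequency cosines."""
    x = np.arange(width) / max(width, 1)
    out = np.zeros(width)
    for cycles in (0.5, 1.5):
        amp = rng.uniform(0.4, 1.0)
        phase = rng.uniform(0, 2 * math.pi)
        out += amp * np.cos(2 * math.pi * cycles * x + phase)
    m = np.abs(out).max()
    return out / m if m > 0 else out


def generate_bscan(config: GeneratorConfig) -> SyntheticSample:
    """Render one synthetic B-scan; fully determined by ``config.seed``."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    rows = np.arange(h)[:, None]

    # --- band geometry -----------------------------------------------------
    tilt = math.radians(cfg.tilt_degrees)
    slope_px = math.tan(tilt) * cfg.scale_x / cfg.scale_y  # px of depth per px of width
    x = np.arange(w, dtype=np.float64)
    fovea_col = w // 2

    thickness_um = cfg.choroid_mean_thickness * (
        1.0 + cfg.choroid_thickness_variation * _smooth_profile(rng, w)
    )
    # vertical extent chosen so the locally perpendicular thickness equals
    # the configured micron thickness under the global tilt
    vertical_px = thickness_um / (cfg.scale_y * math.cos(tilt))

    top_f = cfg.band_top_fraction * h + slope_px * (x - w / 2)
    band_top = np.round(top_f).astype(np.int64)
    thickness_px = np.maximum(np.round(vertical_px).astype(np.int64), 1)
    band_bot = band_top + thickness_px - 1  # inclusive
    if band_top.min() < 1 or band_bot.max() >= h - 1:
        raise ConfigurationError(
            "band leaves the image; reduce tilt, thickness or band_top_fraction"
        )

    region_mask = (rows >= band_top[None, :]) & (rows <= band_bot[None, :])

    # --- retina with foveal pit -------------------------------------------
    retina_px = cfg.retina_thickness / cfg.scale_y
    pit_px = cfg.fovea_pit_depth / cfg.scale_y
    pit_sigma_px = 350.0 / cfg.scale_x
    pit = pit_px * np.exp(-0.5 * ((x - fovea_col) / pit_sigma_px) ** 2)
    inner_surface = top_f - (retina_px - pit)  # inner limiting membrane
    fovea_row = int(round(inner_surface[fovea_col]))
    fovea_row = min(max(fovea_row, 0), h - 1)

    image = np.full((h, w), cfg.vitreous_intensity, dtype=np.float64)
    # retinal strata: fractional depth bands between ILM and RPE-C
    strata = [(0.00, 0.30, 0.45), (0.30, 0.55, 0.25),
              (0.55, 0.85, 0.55), (0.85, 1.00, 0.75)]
    depth_frac = (rows - inner_surface[None, :]) / np.maximum(
        top_f[None, :] - inner_surface[None, :], 1e-9
    )
    in_retina = (depth_frac >= 0) & (rows < band_top[None, :])
    for lo, hi, val in strata:
        sel = in_retina & (depth_frac >= lo) & (depth_frac < hi + 1e-12)
        image[sel] = val
    image[rows > band_bot[None, :]] = cfg.sclera_intensity
    image[region_mask] = cfg.stroma_intensity

    # --- vessels ------------------------------------------------------------
    vessel_mask = np.zeros((h, w), dtype=bool)
    band_area = int(region_mask.sum())
    tally_px = 0
    r_lo, r_hi = cfg.vessel_radius_range
    placed = 0
    attempts = 0
    max_attempts = max(cfg.vessel_count * 40, 1)
    while placed < cfg.vessel_count and attempts < max_attempts:
        attempts += 1
        radius = rng.uniform(r_lo, r_hi)
        cx = rng.uniform(0, w)
        # larger lumina toward the scleral (deep) side
        rel = (radius - r_lo) / max(r_hi - r_lo, 1e-9)
        depth = np.clip(rng.normal(0.3 + 0.5 * rel, 0.15), 0.05, 0.95)
        col = int(np.clip(round(cx), 0, w - 1))
        cy = band_top[col] + depth * (thickness_px[col] - 1)
        ecc = math.exp(rng.uniform(-0.35, 0.35))
        a_um, b_um = radius * ecc, radius / ecc
        phi = rng.uniform(0, math.pi)

        half_w_px = (max(a_um, b_um)) / cfg.scale_x + 1
        half_h_px = (max(a_um, b_um)) / cfg.scale_y + 1
        c0 = max(int(cx - half_w_px), 0)
        c1 = min(int(cx + half_w_px) + 1, w)
        r0 = max(int(cy - half_h_px), 0)
        r1 = min(int(cy + half_h_px) + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dx_um = (xx - cx) * cfg.scale_x
        dy_um = (yy - cy) * cfg.scale_y
        u = dx_um * math.cos(phi) + dy_um * math.sin(phi)
        v = -dx_um * math.sin(phi) + dy_um * math.cos(phi)
        ellipse = (u / a_um) ** 2 + (v / b_um) ** 2 <= 1.0
        in_band = ellipse & region_mask[r0:r1, c0:c1]
        n_in_band = int(in_band.sum())
        if n_in_band == 0:
            continue
        n_new = int((in_band & ~vessel_mask[r0:r1, c0:c1]).sum())
        if n_new < (1.0 - cfg.max_vessel_overlap) * n_in_band:
            continue  # too much overlap with existing lumina
        vessel_mask[r0:r1, c0:c1] |= in_band
        tally_px += n_in_band
        placed += 1

    image[vessel_mask] = cfg.vessel_intensity

    # --- speckle ------------------------------------------------------------
    if cfg.speckle_sigma > 0:
        s = cfg.speckle_sigma
        factor = np.exp(rng.normal(0.0, s, size=(h, w)) - 0.5 * s * s)
        image = image * factor
    image = np.clip(image, 0.0, 1.0)

    return SyntheticSample(
        image=image,
        region_mask=region_mask,
        vessel_mask=vessel_mask,
        fovea_col=fovea_col,
        fovea_row=fovea_row,
        scale_x=cfg.scale_x,
        scale_y=cfg.scale_y,
        thickness_px=thickness_px,
        band_top_px=band_top,
        vessel_area_tally=tally_px / max(band_area, 1),
        config=cfg,
    )


def generate_dataset(
    config: GeneratorConfig, n: int, seed: int
) -> list[SyntheticSample]:
    """Generate ``n`` samples with deterministically derived per-sample seeds.

    Per-sample parameters are jittered around ``config``: fovea column
    within the central quarter of the width, thickness and vessel count by
    +/-15 %, tilt by +/-3 degrees.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n)
    samples: list[SyntheticSample] = []
    for child in children:
        rng = np.random.default_rng(child)
        sample_seed = int(rng.integers(0, _MAX_SEED))
        jcfg = replace(
            config,
            seed=sample_seed,
            choroid_mean_thickness=config.choroid_mean_thickness
            * rng.uniform(0.85, 1.15),
            vessel_count=max(int(round(config.vessel_count * rng.uniform(0.85, 1.15))), 0),
            tilt_degrees=config.tilt_degrees + rng.uniform(-3.0, 3.0),
        )
        sample = generate_bscan(jcfg)
        # recentre the fovea within the central quarter of the image width
        shift = int(round(rng.uniform(-0.125, 0.125) * config.width))
        if shift:
            sample = _shift_columns(sample, shift)
        samples.append(sample)
    return samples


def _shift_columns(sample: SyntheticSample, shift: int) -> SyntheticSample:
    """Roll a sample laterally (wrapping) to move the fovea off-centre."""
    roll = lambda a: np.roll(a, shift, axis=-1)  # noqa: E731
    return SyntheticSample(
        image=roll(sample.image),
        region_mask=roll(sample.region_mask),
        vessel_mask=roll(sample.vessel_mask),
        fovea_col=(sample.fovea_col + shift) % sample.image.shape[1],
        fovea_row=sample.fovea_row,
        scale_x=sample.scale_x,
        scale_y=sample.scale_y,
        thickness_px=roll(sample.thickness_px),
        band_top_px=roll(sample.band_top_px),
        vessel_area_tally=sample.vessel_area_tally,
        config=sample.config,
    )


def degrade_to_probability_maps(
    sample: SyntheticSample,
    blur_sigma: float,
    noise_sigma: float,
    seed: int,
    fovea_config: FoveaTargetConfig | None = None,
) -> SegmentationOutput:
    """Turn exact masks into model-like soft maps (blur + additive noise).

    With both sigmas zero the region/vessel channels equal the binary masks
    and the fovea channel equals the clean training target.
    """
    if blur_sigma < 0 or noise_sigma < 0:
        raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)

    def degrade(channel: np.ndarray) -> np.ndarray:
        out = channel.astype(np.float64)
        if blur_sigma > 0:
            out = gaussian_filter(out, blur_sigma)
        if noise_sigma > 0:
            out = out + rng.normal(0.0, noise_sigma, size=out.shape)
        return np.clip(out, 0.0, 1.0)

    target = build_fovea_target(
        sample.shape, sample.fovea_col, sample.fovea_row, fovea_config
    )
    return SegmentationOutput(
        region_prob=degrade(sample.region_mask),
        vessel_prob=degrade(sample.vessel_mask),
        fovea_prob=degrade(target),
    )
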