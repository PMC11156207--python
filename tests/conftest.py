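"""Shared fixtures: small, fast synthetic phantoms with known truth."""

from __future__ import annotations

import numpy as np
import pytest

from choroidpipe.synthetic import GeneratorConfig, generate_bscan


def phantom_config(seed: int = 0, speckle: float = 0.05, **overrides) -> GeneratorConfig:
    """A 192 x 192 phantom at 10 µm/px with a thick, densely vascularised band.

    The vessel density is chosen so the planted vessel fraction sits in
    the physiological vascularity band (~0.45-0.55).
    """
    kwargs = dict(
        height=192,
        width=192,
        scale_x=10.0,
        scale_y=10.0,
        choroid_mean_thickness=800.0,
        vessel_count=95,
        vessel_radius_range=(25.0, 90.0),
        retina_thickness=250.0,
        band_top_fraction=0.35,
        fovea_pit_depth=100.0,
        speckle_sigma=speckle,
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def make_phantom(seed: int = 0, speckle: float = 0.05, **overrides):
    return generate_bscan(phantom_config(seed=seed, speckle=speckle, **overrides))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: vessels at 0.2 inside a 0.8 stroma band."""
    return make_phantom(seed=3, speckle=0.0)


@pytest.fixture(scope="session")
def speckled_phantom():
    """The same geometry under 5% multiplicative speckle."""
    return make_phantom(seed=3, speckle=0.05)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * (a & b).sum() / denom
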