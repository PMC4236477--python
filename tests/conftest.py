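"""Shared fixtures: small rendered scenes and study tables."""

import numpy as np
import pytest

from ricecanopyn.synthetic import (
    RenderConfig,
    default_calibration_design,
    render_canopy_image,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def clean_scene():
    """One rendered canopy scene: moderate noise, no white spots."""
    cfg = RenderConfig(shape=(128, 128), leaf_noise_sd=5.0, seed=42)
    image, truth = render_canopy_image(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def noiseless_scene():
    """Constant-color leaves: exact channel recovery is possible."""
    cfg = RenderConfig(shape=(96, 96), leaf_noise_sd=0.0, seed=7)
    image, truth = render_canopy_image(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def calibration_table():
    """Model 2 study table at the full design size (n = 240)."""
    return simulate_dataset(default_calibration_design(model_id=2, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
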