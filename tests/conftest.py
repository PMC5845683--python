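"""Shared fixtures: small synthetic inputs generated at test time."""

import numpy as np
import pytest

from nucdyn import simulate
from nucdyn.simulate import SyntheticConfig


def small_nucleus_config(**overrides) -> SyntheticConfig:
    """A fast nucleus-movie configuration (short movie, small field)."""
    cfg = SyntheticConfig(
        frames=20,
        image_size=(192, 192),
        drift_speed=0.2,
        seed=0,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture(scope="session")
def nucleus_movie():
    """One rendered small nucleus movie with its masks and truth."""
    cfg = small_nucleus_config(seed=7)
    movie, masks, truth = simulate.generate_nucleus_movie(cfg)
    return cfg, movie, masks, truth


@pytest.fixture(scope="session")
def frozen_nucleus_movie():
    """A nucleus with all dynamics frozen: only camera noise varies."""
    cfg = small_nucleus_config(
        seed=11, area_fluct_target=0.0, drift_speed=0.0, texture_turnover=0.0
    )
    movie, masks, truth = simulate.generate_nucleus_movie(cfg)
    return cfg, movie, masks, truth


@pytest.fixture(scope="session")
def brightfield_movie():
    """A small bright-field migration movie (4 cells, 60 frames)."""
    cfg = simulate.condition_preset("unstrained", "1h", modality="brightfield")
    cfg.seed = 5
    movie, truth = simulate.generate_brightfield_movie(cfg, 4)
    return cfg, movie, truth


def disc_mask(shape=(64, 64), center=(32.0, 32.0), radius=20.0) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
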