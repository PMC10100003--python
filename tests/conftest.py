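"""Shared fixtures: small synthetic scenes, quiet warnings from clipping."""

import numpy as np
import pandas as pd
import pytest

from amazonagc import (NoiseConfig, SceneConfig, generate_lvod_series,
                       generate_scene)


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """A fast 4x4-cell scene with the default (noisy) study conditions."""
    return SceneConfig(n_coarse_x=4, n_coarse_y=4, fine_per_coarse=16,
                       years=tuple(range(2011, 2018)), seed=42)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def clean_config() -> SceneConfig:
    """Noise-free limit of the small scene (clean observation stream)."""
    return SceneConfig(n_coarse_x=4, n_coarse_y=4, fine_per_coarse=16,
                       years=tuple(range(2011, 2018)), seed=42,
                       noise=NoiseConfig.zero())


@pytest.fixture(scope="session")
def clean_scene(clean_config):
    return generate_scene(clean_config)


@pytest.fixture(scope="session")
def clean_obs(clean_scene, clean_config):
    scene, truth = clean_scene
    return generate_lvod_series(scene, truth, clean_config)


@pytest.fixture(scope="session")
def static_config() -> SceneConfig:
    """A clean stream in the strict sense: no noise artefacts and no
    land-cover change, so no filter has anything to reject."""
    return SceneConfig(n_coarse_x=4, n_coarse_y=4, fine_per_coarse=16,
                       years=tuple(range(2011, 2018)), seed=42,
                       deforestation_rate=0.0, degradation_rate=0.0,
                       regrowth_rate=0.0, noise=NoiseConfig.zero())


@pytest.fixture(scope="session")
def static_scene(static_config):
    return generate_scene(static_config)


@pytest.fixture(scope="session")
def static_obs(static_scene, static_config):
    scene, truth = static_scene
    return generate_lvod_series(scene, truth, static_config)


def make_obs(rows) -> pd.DataFrame:
    """Observation frame from (cell_id, date, orbit, vod, tb_rmse, flag) rows."""
    df = pd.DataFrame(rows, columns=["cell_id", "date", "orbit", "vod",
                                     "tb_rmse", "flag"])
    df["date"] = pd.to_datetime(df["date"])
    return df
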