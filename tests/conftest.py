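"""Shared fixtures: filter banks and synthetic scenes reused across modules."""

import numpy as np
import pytest

import dte


@pytest.fixture(scope="session")
def bank():
    """The default 38-kernel RFS bank (built once per session)."""
    return dte.build_rfs_bank()


@pytest.fixture(scope="session")
def noiseless_scene():
    """A small scene with every corruption switched off (two-valued image)."""
    cfg = dte.SceneConfig(
        image_size=(256, 256),
        n_secondary=5,
        noise_sd=0.0,
        n_granules=0,
        illumination_gradient=0.0,
        blur_sigma_px=0.0,
        seed=11,
    )
    return dte.generate_scene(cfg)


@pytest.fixture(scope="session")
def default_scene():
    """One scene at the default (noisy) study conditions, 256 px for speed."""
    return dte.generate_scene(
        dte.SceneConfig(image_size=(256, 256), n_secondary=5, seed=3)
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Six small scenes for training/evaluation tests."""
    base = dte.SceneConfig(image_size=(256, 256), n_secondary=5, seed=7)
    dataset, somas = dte.generate_dataset(6, base_config=base)
    return dataset, somas


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
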