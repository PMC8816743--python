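import numpy as np
import pytest

from aismito.synthetic import SceneConfig


def noise_free(**overrides) -> SceneConfig:
    """Scene config with all noise sources off (and no constant background)."""
    base = dict(poisson_scale=0.0, gaussian_sd=0.0, background_level=0.0)
    base.update(overrides)
    return SceneConfig(**base)


def movie_config(seed: int, **overrides) -> SceneConfig:
    """Compact, nearly straight axon geometry used for time-lapse movies."""
    base = dict(
        seed=seed,
        image_size_px=(96, 448),
        pixel_size_um=0.3,
        axon_length_um=100.0,
        n_dendrites=0,
        dendrite_length_um=0.0,
        soma_radius_um=6.0,
        curvature_sd_rad=0.005,
        heading_jitter_rad=0.03,
        poisson_scale=0.0,
        gaussian_sd=0.0,
        background_level=0.0,
    )
    base.update(overrides)
    return SceneConfig(**base)


def tau_config(seed: int, fold: float, **overrides) -> SceneConfig:
    """Compact scene used for somatic-intensity experiments."""
    base = dict(
        seed=seed,
        tau_somatic_fold=fold,
        image_size_px=(320, 384),
        axon_length_um=30.0,
        ais_length_um=15.0,
        dendrite_length_um=18.0,
        soma_radius_um=7.0,
    )
    base.update(overrides)
    return SceneConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
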