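import numpy as np
import pytest

from exoquant import SceneSpec, generate_cls_scene


def small_cls_spec(**overrides) -> SceneSpec:
    """A 64x64 scene spec that fits one adipocyte plus a few macrophages."""
    defaults = dict(
        image_shape=(64, 64),
        n_adipocytes=1,
        n_macrophages=3,
        adipocyte_radius_px=14.0,
        macrophage_radius_px=5.0,
        nucleus_radius_px=2.0,
        geometry="crown",
        membrane_signal_mean=100.0,
        noise_sd=5.0,
        background_level=10.0,
        seed=0,
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)


@pytest.fixture
def clean_scene():
    """Noise-free, background-free two-cell scene with known totals."""
    spec = SceneSpec(
        image_shape=(128, 128),
        n_adipocytes=1,
        n_macrophages=2,
        noise_sd=0.0,
        background_level=0.0,
        signal_cv=0.0,
        permeable_fraction=0.0,
        seed=3,
    )
    stack, truth = generate_cls_scene(spec)
    return spec, stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
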