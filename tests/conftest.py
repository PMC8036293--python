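import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kerato3d.io import Image2D
from kerato3d.phantom import EyePhantomSpec, generate_cohort, render_frontal, render_lateral

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def textured_image() -> Image2D:
    """Seeded blob texture: rich in scale-space features, fully reproducible."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(2024)
    base = gaussian_filter(rng.normal(size=(160, 160)), sigma=3.0)
    base = (base - base.min()) / (base.max() - base.min()) * 255.0
    return Image2D(base.astype(np.float32))


@pytest.fixture(scope="session")
def clean_cohort():
    """40 noise-free phantom cases, 10 per stage, default guard-banded ranges."""
    return generate_cohort(10, seed=11, noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """8 mildly noisy 128-px cases for fast bookkeeping tests."""
    return generate_cohort(2, seed=3, noise_sigma=2.0, image_size=128, volume_size=48)


@pytest.fixture()
def mild_spec() -> EyePhantomSpec:
    return EyePhantomSpec(steepness_angle_deg=43.0, stage_label="mild", noise_sigma=0.0)


@pytest.fixture()
def normal_spec() -> EyePhantomSpec:
    return EyePhantomSpec(steepness_angle_deg=35.0, stage_label="normal", noise_sigma=0.0)
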