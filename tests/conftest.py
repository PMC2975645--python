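import numpy as np
import pytest

from nirquant import NIRImage, NoiseModel, PhantomTruth, RegionSpec, generate_phantom


@pytest.fixture(scope="session")
def default_truth() -> PhantomTruth:
    return PhantomTruth()


@pytest.fixture(scope="session")
def small_truth() -> PhantomTruth:
    """32x32 phantom with one tumor and a hip patch, noise off."""
    return PhantomTruth(
        image_shape=(32, 32),
        body_center=(16, 16),
        body_radii=(10, 13),
        regions=[
            RegionSpec("tumor", "disc", (14, 22), (3, 3), c_max=20.0,
                       k_in=2.0, k_out=0.1),
            RegionSpec("hip_ref", "disc", (20, 12), (2, 2), c_max=0.0),
        ],
        psf_sigma=1.5,
        noise=NoiseModel.off(),
    )


@pytest.fixture(scope="session")
def default_frame(default_truth):
    """One noisy default frame at 1 h with its ground-truth regions."""
    return generate_phantom(default_truth, 1.0)


@pytest.fixture(scope="session")
def noise_free_frame(default_truth):
    return generate_phantom(default_truth.with_noise_off(), 1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_image(rng: np.random.Generator, shape=(32, 32),
                 integral: bool = False) -> NIRImage:
    if integral:
        px = rng.integers(0, 5000, size=shape).astype(np.float64)
    else:
        px = rng.gamma(2.0, 50.0, size=shape)
    return NIRImage(px)


def random_mask(rng: np.random.Generator, shape=(32, 32)) -> np.ndarray:
    mask = rng.random(shape) < 0.4
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask
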