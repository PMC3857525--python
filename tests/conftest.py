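import numpy as np
import pytest

from wmhseg.image_core import AffineTransform, BinaryMask, Volume
from wmhseg.phantom import LesionSpec, PhantomSpec, generate_phantom


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A 48x48x32 phantom with one ~140-voxel WM lesion; fast to process."""
    fields = dict(
        grid_shape=(48, 48, 32),
        lesions=[LesionSpec((33.0, 24.0, 20.0), (4.0, 3.0, 3.0))],
        seed=3,
    )
    fields.update(overrides)
    return PhantomSpec(**fields)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_phantom(small_phantom_spec())


@pytest.fixture(scope="session")
def small_bundle_noise_free():
    return generate_phantom(small_phantom_spec(noise_sd=0.0))


@pytest.fixture(scope="session")
def default_bundle():
    """The full default phantom (96x96x60, cohort-scaled lesion load)."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture
def unit_volume():
    """8x8x8 volume of ramp values on a 1 mm isotropic grid."""
    rng = np.random.default_rng(42)
    return Volume(rng.uniform(1.0, 10.0, (8, 8, 8)), np.eye(4))


def mask_from(arr, affine=None):
    affine = np.eye(4) if affine is None else affine
    return BinaryMask.from_bool(np.asarray(arr, dtype=bool), affine)


def translation(t):
    return AffineTransform.from_translation(t)
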