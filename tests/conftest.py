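import numpy as np
import pytest

from infatlas.phantom import PhantomConfig, generate_cohort
from infatlas.volumes_io import SpaceDef, Volume


@pytest.fixture(scope="session")
def small_space() -> SpaceDef:
    return SpaceDef((32, 32, 32), (2.0, 2.0, 2.0), (16, 16, 16))


@pytest.fixture(scope="session")
def clean_subject(small_space):
    """One noiseless, bias-free phantom subject on a 32^3 grid."""
    cfg = PhantomConfig(n_subjects=1, grid=small_space, seed=7,
                        noise_sigma=0.0, bias_amplitude=0.0)
    return generate_cohort(cfg)[0]


@pytest.fixture(scope="session")
def noisy_subject(small_space):
    """One subject at the default degradation level."""
    cfg = PhantomConfig(n_subjects=1, grid=small_space, seed=21)
    return generate_cohort(cfg)[0]


@pytest.fixture()
def ramp_volume(small_space):
    """A smooth separable ramp, handy as an analytic resampling oracle."""
    idx = np.indices(small_space.dims).astype(np.float64)
    data = idx[0] + 0.5 * idx[1] + 0.25 * idx[2]
    return Volume(data, small_space.affine)
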