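import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drrseal import PhantomSpec, Volume, generate_phantom, read_series, sort_slices

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: low PBKDF2 iteration count for unit tests (crypto correctness is
#: iteration-independent); acceptance tests use the production default.
FAST_KDF = 1000


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec():
    """Tiny phantom (fast): 32x32 pixels, 10 slices, no interpolation."""
    return PhantomSpec(rows=32, cols=32, n_slices=10, slice_spacing=1.0,
                       pixel_spacing=1.0, noise_sigma=0.0, seed=3)


@pytest.fixture(scope="session")
def small_series_dir(tmp_path_factory, small_spec):
    out = tmp_path_factory.mktemp("small-series")
    generate_phantom(small_spec, out)
    return out


@pytest.fixture(scope="session")
def small_slices(small_series_dir):
    return sort_slices(read_series(small_series_dir))


def random_volume(rng, shape=None, max_extent=8):
    if shape is None:
        shape = tuple(rng.integers(1, max_extent + 1, size=3))
    hu = rng.uniform(-1024.0, 3072.0, size=shape)
    return Volume(hu=hu, spacing=1.0, n_slices_original=shape[0],
                  provenance=[f"uid{i}" for i in range(shape[0])])


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
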