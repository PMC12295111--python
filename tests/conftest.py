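import numpy as np
import pytest

from lvhquant.aha import APEX, LEVELS, LandmarkSet, build_partition
from lvhquant.phantom import PhantomSpec, generate_phantom, piecewise_profile


def small_spec(**overrides) -> PhantomSpec:
    """Noiseless 96-px phantom used across the suite."""
    defaults = dict(
        image_size=96,
        pixel_spacing=1.25,
        cavity_radius=20.0,
        n_slices_per_level=1,
        noise_sd=0.0,
        rv_insertion_angles=(0.0, 120.0),
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def uniform_phantom():
    """Constant 10 mm wall, anchor at 0 degrees."""
    return generate_phantom(small_spec(seed=11))


@pytest.fixture(scope="session")
def focal_phantom():
    """26 mm wall on the first basal bin [0, 20), 10 mm elsewhere."""
    focal = piecewise_profile([0.0, 20.0], [26.0, 10.0])
    flat = 10.0
    spec = small_spec(
        seed=12,
        thickness_profile={"basal": focal, "mid": flat, "apical": flat},
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def partition49():
    lm = LandmarkSet((48.0, 48.0), 0.0, 120.0)
    return build_partition(lm, list(LEVELS) + [APEX], mode=49)


@pytest.fixture(scope="session")
def partition17():
    lm = LandmarkSet((48.0, 48.0), 0.0, 120.0)
    return build_partition(lm, list(LEVELS) + [APEX], mode=17)
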