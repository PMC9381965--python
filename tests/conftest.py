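import numpy as np
import pytest
from hypothesis import settings

from hodasym.phantom import PhantomSpec, generate_phantom

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

ZERO_NOISE = {"PD": 0.0, "T2": 0.0, "FLAIR": 0.0, "FA": 0.0, "MD": 0.0}


def noiseless_spec(**overrides) -> PhantomSpec:
    kwargs = dict(noise_sd=dict(ZERO_NOISE))
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Noiseless phantom with no planted lesion (left/right symmetric)."""
    return generate_phantom(noiseless_spec(hod_side="none"))


@pytest.fixture(scope="session")
def hod_right_phantom():
    """Noiseless phantom with a 10% right-sided olivary intensity effect."""
    spec = noiseless_spec(hod_side="right", hod_intensity_effect=0.10)
    return spec, generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
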