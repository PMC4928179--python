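import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import saxsflex as sf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def guinier_profile():
    """Noiseless ideal Guinier curve: Rg = 20 Å, I(0) = 7.0."""
    q = np.linspace(0.005, 0.05, 100)
    return sf.ScatteringProfile(q, 7.0 * np.exp(-(q**2) * 20.0**2 / 3.0), label="guinier20")


@pytest.fixture(scope="session")
def lognormal_profile():
    """Noiseless RgD profile from truth (μ=3.0, σ=0.25)."""
    spec = sf.EnsembleSpec(components=(sf.Component(1.0, "lognormal", mu=3.0, sigma=0.25),))
    profile, truth = sf.generate_profile(spec)
    return profile, truth


@pytest.fixture(scope="session")
def lognormal_fit(lognormal_profile):
    """The (expensive) noiseless reference fit, shared across tests."""
    profile, truth = lognormal_profile
    return sf.fit_rgd(profile), truth


@pytest.fixture(scope="session")
def noisy_profile():
    """Same truth with 1% multiplicative Gaussian noise and sigma column."""
    spec = sf.EnsembleSpec(
        components=(sf.Component(1.0, "lognormal", mu=3.0, sigma=0.25),),
        noise="multiplicative_gaussian",
        noise_level=0.01,
        seed=1,
    )
    profile, truth = sf.generate_profile(spec)
    return profile, truth


@pytest.fixture(scope="session")
def noisy_fit(noisy_profile):
    profile, truth = noisy_profile
    return sf.fit_rgd(profile), truth
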