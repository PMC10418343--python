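import numpy as np
import pytest

from ircmech import synthetic as syn


@pytest.fixture(scope="session")
def aromatic_spec():
    return syn.aromatic_like(seed=1)


@pytest.fixture(scope="session")
def aliphatic_spec():
    return syn.aliphatic_like(seed=1)


@pytest.fixture(scope="session")
def aromatic_data(aromatic_spec):
    profile, truth = syn.make_profile(aromatic_spec)
    return aromatic_spec, profile, truth


@pytest.fixture(scope="session")
def aliphatic_data(aliphatic_spec):
    profile, truth = syn.make_profile(aliphatic_spec)
    return aliphatic_spec, profile, truth


@pytest.fixture(scope="session")
def gaussian_spec():
    """Pure Gaussian barrier A=20, w=0.5 on a dense grid (analytic oracle)."""
    return syn.SyntheticSpec(
        barrier_height=20.0, barrier_width=0.5, step_E_RI=0.0, n_points=2001
    )


@pytest.fixture(scope="session")
def gaussian_data(gaussian_spec):
    profile, truth = syn.make_profile(gaussian_spec)
    return gaussian_spec, profile, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
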