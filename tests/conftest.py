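import numpy as np
import pytest

import glycotrait as gt
from glycotrait.simulate import SpectrumRenderParams


@pytest.fixture(scope="session")
def library():
    return gt.default_library()


@pytest.fixture(scope="session")
def small_cohort():
    """A 3+3 cohort with profiles and truth, shared across tests."""
    design = gt.CohortDesign(n_high=3, n_low=3, seed=7)
    profiles, truth = gt.generate_profiles(design)
    return design, profiles, truth


@pytest.fixture(scope="session")
def render_params():
    """Narrow m/z range for fast rendering in tests (library max ~3650 Da)."""
    return SpectrumRenderParams(mz_range=(1000.0, 4000.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
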