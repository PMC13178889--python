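import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording():
    """Two spatially separate footprints active in different frame windows."""
    from pedoperm.footio import PressureRecording

    frames = np.zeros((30, 40, 20))
    # footprint 1: rows 2-9, frames 3-17
    frames[3:18, 2:10, 3:9] = 50.0
    # footprint 2: rows 25-33, frames 12-27
    frames[12:28, 25:34, 10:17] = 80.0
    return PressureRecording(frames, pitch=5.0, rate=100.0, id="fixture")


@pytest.fixture(scope="session")
def default_stance():
    """One generated stance with its ground truth (session-cached)."""
    from pedoperm.synthcohort import StanceProfile, generate_stance

    return generate_stance(StanceProfile(), seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 female / 3 male synthetic cohort with truth (session-cached)."""
    from pedoperm.synthcohort import SynthCohortConfig, generate_cohort

    return generate_cohort(SynthCohortConfig(n_female=4, n_male=3, seed=11))
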