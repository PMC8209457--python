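import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Multinomial study at survey depths, no sequences (fast, session-wide)."""
    from beetscreen.simulate import StudyDesign, simulate_study

    design = StudyDesign(seed=3, n_otus=40)
    return simulate_study(design, include_sequences=False, include_inoculation=False)


@pytest.fixture(scope="session")
def seq_study():
    """Tiny study with emitted sequences for clustering round-trips."""
    from beetscreen.simulate import StudyDesign, simulate_study

    design = StudyDesign(
        seed=5, n_otus=15, fixed_depth=12, alignment_length=600
    )
    return simulate_study(design, include_inoculation=False)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
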