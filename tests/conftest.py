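import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_synthetic():
    """A short noise-free synthetic trajectory on a mixed U/C sequence."""
    from rrmscan.synthetic_data import SynthConfig, generate

    return generate(SynthConfig(seq="UUCUU", n_frames=300, seed=42))


def make_frame(coords):
    """Bare Frame over ad-hoc coordinates (topology-free geometry tests)."""
    from rrmscan.trajectory_io import Frame

    return Frame(index=0, time_ns=0.0, coords=np.asarray(coords, dtype=float))
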