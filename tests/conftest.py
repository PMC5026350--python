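import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def uniform_pwm():
    from crmseg.pwm import Pwm

    return Pwm("uni", np.full((3, 4), 0.25), pseudocount=0.0)


@pytest.fixture
def strong_pwm():
    """A near-deterministic width-4 motif (consensus ACGT)."""
    from crmseg.pwm import Pwm

    mat = np.full((4, 4), 0.02)
    for i in range(4):
        mat[i, i] = 0.94
    return Pwm("acgt", mat, pseudocount=0.0)
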