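import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hetmc import AssociationMatrix, SyntheticSpec, generate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_assoc() -> AssociationMatrix:
    """Three pairs over 2 diseases x 2 lncRNAs: (d1,l1), (d1,l2), (d2,l1)."""
    return AssociationMatrix(
        np.array([[1.0, 1.0], [1.0, 0.0]]), ["d1", "d2"], ["l1", "l2"]
    )


@pytest.fixture(scope="session")
def synth_small():
    """A small planted dataset shared by evaluation/model tests."""
    return generate(SyntheticSpec(m=20, n=15, r=3, density=0.5, prevalence=0.08, seed=1))


@pytest.fixture(scope="session")
def synth_medium():
    """The medium planted dataset used for pipeline-level checks."""
    return generate(SyntheticSpec(m=40, n=30, r=4, density=0.4, prevalence=0.02, seed=7))
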