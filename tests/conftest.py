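import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stemdem.geometry import ParticleSpec, StemModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table6_results():
    """Response surface fitted to the published CCD responses."""
    from stemdem.datasets import table6_design
    from stemdem.doe import fit_quadratic

    return fit_quadratic(table6_design())


def make_chain(n: int, pitch_mm: float = 1.0, radius_mm: float = 0.5) -> StemModel:
    """Straight bonded chain of n particles along z."""
    parts = [
        ParticleSpec(i, (0.0, 0.0, i * pitch_mm), radius_mm, i) for i in range(n)
    ]
    return StemModel(particles=parts, length=n * pitch_mm, diameter=2 * radius_mm)


@pytest.fixture
def two_particle_model() -> StemModel:
    return make_chain(2)
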