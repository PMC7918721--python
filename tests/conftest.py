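import numpy as np
import pytest

from eprnano import (
    DomainParams,
    MagneticTensors,
    SpectrometerSettings,
)


@pytest.fixture(scope="session")
def tensors() -> MagneticTensors:
    return MagneticTensors()


@pytest.fixture(scope="session")
def settings() -> SpectrometerSettings:
    return SpectrometerSettings()


@pytest.fixture(scope="session")
def three_domains() -> list[DomainParams]:
    """A well-separated three-domain composition used across tests."""
    return [
        DomainParams(S=0.62, tau_c=2.5, pA=0.99, W=0.12, d=0.45),
        DomainParams(S=0.37, tau_c=0.8, pA=1.00, W=0.10, d=0.33),
        DomainParams(S=0.12, tau_c=0.5, pA=1.02, W=0.08, d=0.22),
    ]


@pytest.fixture(scope="session")
def random_domains():
    """Seeded random single-domain parameter sets within fit bounds."""
    rng = np.random.default_rng(20260929)

    def draw(n):
        out = []
        for _ in range(n):
            out.append(DomainParams(
                S=rng.uniform(0.0, 0.9),
                tau_c=rng.uniform(0.1, 4.0),
                pA=rng.uniform(0.9, 1.1),
                pg=rng.uniform(0.999, 1.001),
                W=rng.uniform(0.03, 0.3),
                d=1.0))
        return out

    return draw
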