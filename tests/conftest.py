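"""Shared fixtures: reference parameters and generated gaits.

The reference conditions shared by all three synthetic gaits: step length
0.77 m, leg length 1.07 m, average speed 1.4 m/s, mass 94 kg, b = 0.2,
g = 9.81 m/s^2; sinusoidal amplitude 0.02 m.
"""

import pytest

from comwalk import (
    GaitParameters,
    SyntheticGaitSpec,
    gen_level,
    gen_pendular,
    gen_sinusoidal,
)

# reference per-step values for the shared conditions
LEVEL_W_POS = 127.64          # J
SINUSOIDAL_W_POS = 109.15     # J
PENDULAR_E_LOSS = 64.80       # J
C_PENDULAR = 0.11
C_LEVEL = 0.22


@pytest.fixture(scope="session")
def params() -> GaitParameters:
    return GaitParameters(m=94.0, g=9.81, b=0.2, l0=1.07)


def _spec(kind: str, sample_rate: float = 1000.0, n_steps: int = 4) -> SyntheticGaitSpec:
    return SyntheticGaitSpec(
        kind=kind, d=0.77, l0=1.07, v0=1.4, a=0.02,
        n_steps=n_steps, sample_rate=sample_rate,
    )


@pytest.fixture(scope="session")
def level_gait():
    return gen_level(_spec("level"))


@pytest.fixture(scope="session")
def sinusoidal_gait():
    return gen_sinusoidal(_spec("sinusoidal"))


@pytest.fixture(scope="session")
def pendular_gait(params):
    return gen_pendular(_spec("pendular"), params)


@pytest.fixture(scope="session")
def sinusoidal_gait_200hz():
    """Motion-capture-like sampling for the noisy-pipeline tests."""
    return gen_sinusoidal(_spec("sinusoidal", sample_rate=200.0))
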