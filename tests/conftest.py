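"""Shared fixtures: the printed model constants used across the suite."""

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nefire import (
    EnvelopeParams,
    FiringThreshold,
    ReleaseAmount,
    SphereGeometry,
    Surface,
)


@pytest.fixture(scope="session")
def geom() -> SphereGeometry:
    return SphereGeometry(radius=8.0)


@pytest.fixture(scope="session")
def release() -> ReleaseAmount:
    return ReleaseAmount(sigma_mol=2.0e-20)


@pytest.fixture(scope="session")
def threshold() -> FiringThreshold:
    return FiringThreshold(c_th=0.0425, alpha=0.15)


@pytest.fixture(scope="session")
def envelope() -> EnvelopeParams:
    return EnvelopeParams(delta_m=0.01, D_P=20.0)


@pytest.fixture(scope="session")
def inner_surface() -> Surface:
    return Surface("inner", D=5.0, k_s=1.0)


@pytest.fixture(scope="session")
def outer_surface() -> Surface:
    return Surface("outer", D=20.0, k_s=1.0)
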