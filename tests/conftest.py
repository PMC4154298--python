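import numpy as np
import pytest

from fatekinetics import (
    N2B27,
    AC,
    PopulationState,
    Protocol,
    PulseChaseDesign,
    RateParameters,
    paper_like_params,
)


@pytest.fixture(scope="session")
def params() -> RateParameters:
    """Calibrated default parameters used throughout the suite."""
    return paper_like_params()


@pytest.fixture(scope="session")
def n2b27_6d() -> Protocol:
    return Protocol([(6.0, N2B27)])


@pytest.fixture(scope="session")
def ac_6d() -> Protocol:
    return Protocol([(6.0, AC)])


@pytest.fixture(scope="session")
def pulse_design() -> PulseChaseDesign:
    """6 days of N2B27 with single 1-day AC pulses starting on days 0-5."""
    return PulseChaseDesign()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def random_params(rng: np.random.Generator, *, degenerate: bool = False) -> RateParameters:
    """A random valid parameter set, optionally with Lambda ~= lambda_D."""
    lam_d = float(np.exp(rng.uniform(np.log(1e-2), np.log(5.0))))
    if degenerate:
        lam_n = lam_d * (1.0 + rng.uniform(-1e-10, 1e-10))
        lam_m_high = 0.0
    else:
        lam_n = float(np.exp(rng.uniform(np.log(1e-2), np.log(5.0))))
        lam_m_high = float(np.exp(rng.uniform(np.log(1e-2), np.log(10.0))))
    theta = float(rng.uniform(0.05, 0.95))
    return RateParameters(
        lambda_D=lam_d,
        lambda_N=max(lam_n, 0.0),
        lambda_M_low=0.0,
        lambda_M_high=lam_m_high,
        theta=theta,
    )


def random_protocol(rng: np.random.Generator) -> Protocol:
    """A random 1-4 segment protocol over N2B27/AC, total 2-8 days."""
    n_seg = int(rng.integers(1, 5))
    segments = []
    for _ in range(n_seg):
        condition = AC if rng.random() < 0.5 else N2B27
        segments.append((float(rng.uniform(0.5, 2.5)), condition))
    return Protocol(segments)


@pytest.fixture(scope="session")
def fully_pluripotent() -> PopulationState:
    return PopulationState.pluripotent()
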