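import numpy as np
import pytest

from sirs_turing import EpidemicParams, SteadyState


@pytest.fixture
def base_params() -> EpidemicParams:
    """Base parameter set of the stability and pattern analyses."""
    return EpidemicParams(b=1.0, d=1.0, beta0=35.0, gamma=1.5, D1=10.0, D2=1.0, D3=0.2)


def draw_params(rng: np.random.Generator) -> EpidemicParams:
    """A random but physically sensible parameter set."""
    return EpidemicParams(
        b=rng.uniform(0.5, 2.0),
        d=rng.uniform(0.5, 2.0),
        beta0=rng.uniform(5.0, 60.0),
        alpha=rng.uniform(0.0, 3.0),
        mu=rng.uniform(0.0, 1.0),
        gamma=rng.uniform(0.5, 3.0),
        D1=rng.uniform(0.0, 15.0),
        D2=rng.uniform(0.1, 3.0),
        D3=rng.uniform(0.0, 1.0),
        C_I=rng.uniform(0.0, 0.1),
    )


def draw_point(rng: np.random.Generator) -> SteadyState:
    """A random positive state (not necessarily an equilibrium) for
    derivative checks."""
    return SteadyState(
        S0=rng.uniform(0.05, 2.0),
        I0=rng.uniform(0.05, 2.0),
        R0=rng.uniform(0.05, 2.0),
        stable=False,
    )
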