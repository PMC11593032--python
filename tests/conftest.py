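"""Shared fixtures and hypothesis strategies for the crimodyn test suite."""

from __future__ import annotations

import hypothesis.strategies as st
import pytest
from hypothesis import HealthCheck, settings

from crimodyn import ModelParameters

settings.register_profile(
    "crimodyn",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("crimodyn")


@pytest.fixture
def fig1_params() -> ModelParameters:
    """Case-1 parameter set of the published figures (alpha = 30)."""
    return ModelParameters(alpha=30.0, beta=0.0, gamma=10.0, delta=8.0,
                           eta=0.1, kappa=50.0, rho=0.0, sigma=20.0, phi=0.2)


@pytest.fixture
def fig3_params(fig1_params) -> ModelParameters:
    """Case-4 parameter set of the published figures (alpha = 6)."""
    return fig1_params.replace(alpha=6.0, beta=30.0, rho=0.1)


@pytest.fixture
def fig5_params() -> ModelParameters:
    """Real-world parameterisation (time in years, densities per 1000 km^2)."""
    return ModelParameters(alpha=1 / 40, beta=1 / 6, gamma=1 / 3, delta=1 / 50,
                           eta=1 / 30, kappa=1 / 5, rho=1 / 40000, sigma=40.0,
                           phi=1 / 100)


def _positive(lo=1e-2, hi=50.0):
    return st.floats(min_value=lo, max_value=hi, allow_nan=False,
                     allow_infinity=False)


@st.composite
def parameter_sets(draw, rho_zero=False, beta_zero=False,
                   rho_range=(1e-3, 1.0), beta_frac_range=(1e-3, 1.0)):
    """Random valid parameter sets; beta is drawn as a fraction of kappa.

    ``rho_zero``/``beta_zero`` pin the structural case; otherwise rho is
    drawn from ``rho_range`` and beta as kappa times a fraction from
    ``beta_frac_range`` (so beta <= kappa holds by construction).
    """
    kappa = draw(_positive(0.1, 50.0))
    rho = 0.0 if rho_zero else draw(_positive(*rho_range))
    beta = 0.0 if beta_zero else kappa * draw(_positive(*beta_frac_range))
    return ModelParameters(
        alpha=draw(_positive()),
        beta=beta,
        gamma=draw(_positive(0.1, 50.0)),
        delta=draw(_positive(0.1, 50.0)),
        eta=draw(_positive(1e-2, 10.0)),
        kappa=kappa,
        rho=rho,
        sigma=draw(_positive(0.5, 100.0)),
        phi=draw(_positive(1e-3, 10.0)),
    )
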