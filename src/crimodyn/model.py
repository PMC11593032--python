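"""Core compartmental model: parameters, state, vector field and Jacobian.

The model tracks four interacting population densities (persons per area
unit): gang members ``G``, non-corrupt judges ``J``, corrupt judges ``C``
and prisoners ``P``.  Gang growth is logistic with carrying capacity
``sigma``; judges incarcerate gang members (a predator-prey interaction
with rate constant ``delta``) and are in turn co-opted by the gang (rate
constant ``rho``); corrupt judges are incarcerated by honest ones (rate
constant ``phi``); prisoners are released or die at rate ``kappa`` and a
fraction relapses into the gang at rate ``beta``::

    dG/dt = alpha*G*(sigma - G) - delta*G*J + beta*P
    dJ/dt = gamma - eta*J - rho*G*J
    dC/dt = rho*G*J - phi*C*J
    dP/dt = delta*G*J + phi*C*J - kappa*P

State ordering is fixed as (G, J, C, P) everywhere.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "ModelParameters",
    "StateVector",
    "CaseId",
    "validate_parameters",
    "evaluate_rhs",
    "evaluate_jacobian",
    "classify_case",
]

#: Canonical state ordering used by every array in the package.
STATE_NAMES = ("G", "J", "C", "P")

#: Parameter names in canonical (alphabetical, Greek) order.
PARAMETER_NAMES = (
    "alpha", "beta", "gamma", "delta", "eta", "kappa", "rho", "sigma", "phi",
)


class CaseId(enum.IntEnum):
    """Structural case of the model, selected by exact zeros of rho and beta.

    * Case 1: no judicial co-optation, no recidivism (rho=0, beta=0).
    * Case 2: recidivism only (rho=0, beta>0).
    * Case 3: judicial co-optation only (rho>0, beta=0).
    * Case 4: both mechanisms active (rho>0, beta>0).
    """

    NO_CORRUPTION_NO_RECIDIVISM = 1
    RECIDIVISM_ONLY = 2
    CORRUPTION_ONLY = 3
    CORRUPTION_AND_RECIDIVISM = 4


class ParameterDomainError(ValueError):
    """A parameter violates its positivity/domain constraint."""


class ParameterConstraintError(ValueError):
    """A joint constraint between parameters is violated (beta <= kappa)."""


@dataclass(frozen=True)
class ModelParameters:
    """The nine rate/capacity constants of the model.

    Parameters
    ----------
    alpha : float
        Intraspecific-competition coefficient of the gang's logistic
        growth, per (density * time); ``alpha*sigma`` is the low-density
        growth rate.
    beta : float
        Recidivism rate constant (ex-prisoners rejoining the gang), per
        time.  May be exactly 0; must satisfy ``beta <= kappa``.
    gamma : float
        Constant influx of judges into the judiciary, density per time.
    delta : float
        Incarceration rate constant of gang members by honest judges,
        per (density * time).
    eta : float
        Judge retirement/death rate constant, per time (career length
        ``1/eta``).
    kappa : float
        Prisoner release/death rate constant, per time.
    rho : float
        Judge co-optation (corruption) rate constant, per
        (density * time).  May be exactly 0.
    sigma : float
        Gang carrying capacity, density.
    phi : float
        Incarceration rate constant of corrupt judges by honest judges,
        per (density * time).
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    eta: float
    kappa: float
    rho: float
    sigma: float
    phi: float

    def __post_init__(self) -> None:
        validate_parameters(self)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with some parameters replaced (re-validated)."""
        d = self.as_dict()
        d.update(changes)
        return ModelParameters(**d)


@dataclass(frozen=True)
class StateVector:
    """Densities (G, J, C, P) in persons per area unit."""

    G: float
    J: float
    C: float
    P: float

    def to_array(self) -> np.ndarray:
        return np.array([self.G, self.J, self.C, self.P], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "StateVector":
        G, J, C, P = (float(x) for x in np.asarray(arr, dtype=float))
        return cls(G, J, C, P)

    @property
    def is_physical(self) -> bool:
        """True when every component is finite and non-negative."""
        a = self.to_array()
        return bool(np.all(np.isfinite(a)) and np.all(a >= 0.0))


def validate_parameters(params: ModelParameters) -> ModelParameters:
    """Validate the parameter set and return it unchanged.

    All nine constants must be finite; all must be strictly positive
    except ``rho`` and ``beta``, which may be exactly zero (they select
    the structural case).  ``beta <= kappa`` is required because
    ex-convicts cannot rejoin the gang faster than they leave prison.

    Raises
    ------
    ParameterDomainError
        If a required-positive parameter is <= 0, or rho/beta < 0, or
        any value is non-finite.
    ParameterConstraintError
        If ``beta > kappa``.
    """
    for name in PARAMETER_NAMES:
        value = getattr(params, name)
        if not math.isfinite(value):
            raise ParameterDomainError(f"parameter {name} must be finite, got {value!r}")
        if name in ("rho", "beta"):
            if value < 0.0:
                raise ParameterDomainError(f"parameter {name} must be >= 0, got {value}")
        elif value <= 0.0:
            raise ParameterDomainError(f"parameter {name} must be > 0, got {value}")
    if params.beta > params.kappa:
        raise ParameterConstraintError(
            f"beta ({params.beta}) must not exceed kappa ({params.kappa}): "
            "recidivism cannot outpace prisoner release"
        )
    return params


def classify_case(params: ModelParameters) -> CaseId:
    """Return the structural case id from exact-zero tests on rho and beta."""
    if params.rho == 0.0:
        return CaseId.NO_CORRUPTION_NO_RECIDIVISM if params.beta == 0.0 else CaseId.RECIDIVISM_ONLY
    return CaseId.CORRUPTION_ONLY if params.beta == 0.0 else CaseId.CORRUPTION_AND_RECIDIVISM


def _state_array(state) -> np.ndarray:
    if isinstance(state, StateVector):
        arr = state.to_array()
    else:
        arr = np.asarray(state, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"state must have shape (4,), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"state must be finite, got {arr}")
    return arr


def evaluate_rhs(state, params: ModelParameters) -> np.ndarray:
    """Evaluate the vector field (dG/dt, dJ/dt, dC/dt, dP/dt).

    Negative state components are accepted (no clamping) so integrator
    diagnostics can observe undershoot; physical validity is enforced at
    the trajectory level only.
    """
    G, J, C, P = _state_array(state)
    p = params
    dG = p.alpha * G * (p.sigma - G) - p.delta * G * J + p.beta * P
    dJ = p.gamma - p.eta * J - p.rho * G * J
    dC = p.rho * G * J - p.phi * C * J
    dP = p.delta * G * J + p.phi * C * J - p.kappa * P
    return np.array([dG, dJ, dC, dP])


def evaluate_jacobian(state, params: ModelParameters) -> np.ndarray:
    """Evaluate the 4x4 Jacobian of the vector field at an arbitrary state.

    Row/column order follows the canonical (G, J, C, P) ordering.  The
    (4,4) entry is the constant ``-kappa``.
    """
    G, J, C, P = _state_array(state)
    p = params
    a = p.alpha * p.sigma - 2.0 * p.alpha * G - p.delta * J
    b = -p.delta * G
    c = -p.rho * J
    d = -p.eta - p.rho * G
    e = p.rho * J
    f = p.rho * G - p.phi * C
    g = -p.phi * J
    h = p.delta * J
    j = p.delta * G + p.phi * C
    l = p.phi * J
    return np.array(
        [
            [a, b, 0.0, p.beta],
            [c, d, 0.0, 0.0],
            [e, f, g, 0.0],
            [h, j, l, -p.kappa],
        ]
    )
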