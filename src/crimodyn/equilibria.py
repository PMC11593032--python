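"""Closed-form equilibria, reproduction number and bifurcation thresholds.

Seven labelled steady states arise across the four structural cases:

* ``E0 = (0, gamma/eta, 0, 0)`` — the crime-free state, present always.
* ``E1`` (case 1) and ``E2`` (case 2) — endemic states with an honest
  judiciary, given by linear formulas in the basic reproduction number
  ``R0 = alpha*eta*sigma/(gamma*delta)``.
* ``E3``/``E4`` (case 3) and ``E5``/``E6`` (case 4) — endemic states with
  judicial corruption, whose gang coordinate solves the quadratic
  ``A*G**2 + B*G + const = 0`` with ``A = alpha*rho/(gamma*delta)``,
  ``B = alpha*(eta - rho*sigma)/(gamma*delta)`` and constant term
  ``D = 1 - R0`` (case 3) or ``H = 1 - R0 - (beta/kappa)*(1 + rho/delta)``
  (case 4).

The thresholds ``r = 4*eta*rho*sigma/(eta + rho*sigma)**2``,
``r2 = 1 - (beta/kappa)*(1 + rho/delta)`` and ``r1 = r*r2`` bound the
backward-bifurcation (bistability) window ``r1 <= R0 < r2`` in which a
stable endemic state coexists with the stable crime-free state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import CaseId, ModelParameters, StateVector, classify_case

__all__ = [
    "ThresholdSet",
    "QuadraticCoefficients",
    "EquilibriumPoint",
    "compute_R0",
    "compute_thresholds",
    "endemic_quadratic",
    "endemic_gang_roots",
    "analytic_equilibria",
    "r0_elasticities",
]

#: Discriminants within this band of zero are treated as an exact double
#: root, stabilising behaviour at the saddle-node point.
DISCRIMINANT_TOL = 1e-12


class UnsupportedCaseError(ValueError):
    """Operation requested for a structural case it is not defined in."""


@dataclass(frozen=True)
class ThresholdSet:
    """R0 and the bifurcation thresholds active for a parameter set.

    ``r`` is defined only when rho > 0 (cases 3-4); ``r1`` and ``r2``
    only in case 4.  ``no_bistability_window`` is set when r2 <= 0, i.e.
    when recidivism is so strong that the R0 >= r1 existence condition
    is vacuous and no saddle-node window exists.
    """

    R0: float
    case: CaseId
    r: Optional[float] = None
    r1: Optional[float] = None
    r2: Optional[float] = None
    no_bistability_window: bool = False


@dataclass(frozen=True)
class QuadraticCoefficients:
    """Coefficients of the endemic gang-density quadratic (cases 3-4).

    ``constant`` holds D = 1 - R0 in case 3 and
    H = 1 - R0 - (beta/kappa)(1 + rho/delta) in case 4; the two coincide
    when beta = 0.
    """

    A: float
    B: float
    constant: float
    case: CaseId

    @property
    def discriminant(self) -> float:
        return self.B * self.B - 4.0 * self.A * self.constant


@dataclass(frozen=True)
class EquilibriumPoint:
    """A labelled steady state with physical-existence flag.

    ``exists_physically`` is True when all four coordinates are real and
    non-negative.  Unphysical equilibria (negative gang density, complex
    roots mapped to NaN) are retained so bifurcation sweeps can draw the
    unphysical branches.
    """

    label: str
    coordinates: StateVector
    case: CaseId
    exists_physically: bool

    def to_array(self) -> np.ndarray:
        return self.coordinates.to_array()


def compute_R0(params: ModelParameters) -> float:
    """Basic reproduction number R0 = alpha*eta*sigma/(gamma*delta).

    R0 < 1 is necessary (cases 1) or not even sufficient (cases 2-4) for
    eradication of the criminal organisation; its role mirrors the
    epidemiological basic reproduction number.
    """
    p = params
    return p.alpha * p.eta * p.sigma / (p.gamma * p.delta)


def compute_thresholds(params: ModelParameters) -> ThresholdSet:
    """Compute R0 and the case-appropriate bifurcation thresholds.

    * r (saddle-node threshold on R0) when rho > 0,
    * r2 (endemic-existence threshold) and r1 = r*r2 in case 4.

    When r2 <= 0 the set is flagged ``no_bistability_window`` and r1/r2
    are withheld.
    """
    p = params
    case = classify_case(p)
    R0 = compute_R0(p)
    r = r1 = r2 = None
    no_window = False
    if p.rho > 0.0:
        m, n = p.eta, p.rho * p.sigma
        r = 4.0 * m * n / (m + n) ** 2
        if case == CaseId.CORRUPTION_AND_RECIDIVISM:
            r2_val = 1.0 - (p.beta / p.kappa) * (1.0 + p.rho / p.delta)
            if r2_val <= 0.0:
                no_window = True
            else:
                r2 = r2_val
                r1 = r * r2_val
    return ThresholdSet(R0=R0, case=case, r=r, r1=r1, r2=r2,
                        no_bistability_window=no_window)


def endemic_quadratic(params: ModelParameters) -> QuadraticCoefficients:
    """Coefficients of A*G**2 + B*G + const = 0 for the endemic states.

    Requires rho > 0; with rho = 0 the quadratic degenerates and the
    endemic equilibria follow the linear case-1/2 formulas instead.
    """
    p = params
    case = classify_case(p)
    if p.rho == 0.0:
        raise UnsupportedCaseError(
            "endemic quadratic requires rho > 0 (cases 3-4); "
            "cases 1-2 use the linear closed forms"
        )
    A = p.alpha * p.rho / (p.gamma * p.delta)
    B = p.alpha * (p.eta - p.rho * p.sigma) / (p.gamma * p.delta)
    const = 1.0 - compute_R0(p)
    if case == CaseId.CORRUPTION_AND_RECIDIVISM:
        const -= (p.beta / p.kappa) * (1.0 + p.rho / p.delta)
    return QuadraticCoefficients(A=A, B=B, constant=const, case=case)


def endemic_gang_roots(params: ModelParameters) -> tuple[float, float, float]:
    """Roots (G_plus, G_minus) of the endemic quadratic and its discriminant.

    G_plus maps to G3*/G5* (the larger root, stable branch) and G_minus
    to G4*/G6* (unstable branch).  Complex roots are reported as NaN.
    Discriminants within ±1e-12 of zero are treated as exactly zero
    (double root at the saddle-node).
    """
    q = endemic_quadratic(params)
    disc = q.discriminant
    if abs(disc) <= DISCRIMINANT_TOL:
        disc = 0.0
    if disc < 0.0:
        return math.nan, math.nan, disc
    sqrt_disc = math.sqrt(disc)
    g_plus = (-q.B + sqrt_disc) / (2.0 * q.A)
    g_minus = (-q.B - sqrt_disc) / (2.0 * q.A)
    return g_plus, g_minus, disc


def _corrupt_branch_point(label: str, g_star: float, params: ModelParameters,
                          case: CaseId) -> EquilibriumPoint:
    """Build an E3..E6 point from its gang coordinate G*.

    J* = gamma/(eta + rho G*), C* = rho G*/phi,
    P* = (delta + rho) gamma G* / (kappa (eta + rho G*)).
    """
    p = params
    if math.isnan(g_star):
        coords = StateVector(math.nan, math.nan, math.nan, math.nan)
        return EquilibriumPoint(label, coords, case, exists_physically=False)
    denom = p.eta + p.rho * g_star
    j_star = p.gamma / denom
    c_star = p.rho * g_star / p.phi
    p_star = (p.delta + p.rho) * p.gamma * g_star / (p.kappa * denom)
    coords = StateVector(g_star, j_star, c_star, p_star)
    return EquilibriumPoint(label, coords, case,
                            exists_physically=coords.is_physical)


def analytic_equilibria(params: ModelParameters) -> list[EquilibriumPoint]:
    """All closed-form equilibria of the active structural case.

    Case 1 returns [E0, E1]; case 2 [E0, E2]; case 3 [E0, E3, E4];
    case 4 [E0, E5, E6].  Equilibria with negative or complex coordinates
    are included with ``exists_physically=False``.
    """
    p = params
    case = classify_case(p)
    R0 = compute_R0(p)
    e0 = EquilibriumPoint(
        "E0", StateVector(0.0, p.gamma / p.eta, 0.0, 0.0), case, True
    )
    out = [e0]
    if case in (CaseId.NO_CORRUPTION_NO_RECIDIVISM, CaseId.RECIDIVISM_ONLY):
        # Linear closed forms; case 2 shifts the threshold by beta/kappa.
        shift = p.beta / p.kappa if case == CaseId.RECIDIVISM_ONLY else 0.0
        label = "E1" if case == CaseId.NO_CORRUPTION_NO_RECIDIVISM else "E2"
        excess = R0 - 1.0 + shift
        g = excess * p.gamma * p.delta / (p.alpha * p.eta)
        p_star = excess * (p.gamma * p.delta) ** 2 / (p.alpha * p.kappa * p.eta**2)
        coords = StateVector(g, p.gamma / p.eta, 0.0, p_star)
        out.append(EquilibriumPoint(label, coords, case, coords.is_physical))
    else:
        g_plus, g_minus, _ = endemic_gang_roots(p)
        plus_label, minus_label = (
            ("E3", "E4") if case == CaseId.CORRUPTION_ONLY else ("E5", "E6")
        )
        out.append(_corrupt_branch_point(plus_label, g_plus, p, case))
        out.append(_corrupt_branch_point(minus_label, g_minus, p, case))
    return out


def r0_elasticities(params: ModelParameters) -> dict[str, float]:
    """Normalised sensitivities (dR0/dp)(p/R0) of R0 to each parameter.

    Because R0 = alpha*eta*sigma/(gamma*delta) is a monomial, the
    elasticities are exactly +1 for alpha, eta, sigma, -1 for gamma and
    delta, and 0 for the parameters R0 does not contain.
    """
    del params  # elasticities of a monomial are parameter-independent
    return {
        "alpha": 1.0, "eta": 1.0, "sigma": 1.0,
        "gamma": -1.0, "delta": -1.0,
        "beta": 0.0, "kappa": 0.0, "rho": 0.0, "phi": 0.0,
    }
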