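"""Stability classification: numeric eigenvalues and closed-form criteria.

Two complementary routes are provided.  ``numeric_eigenvalues`` computes
the spectrum of the full 4x4 Jacobian at an equilibrium and is the
authoritative classifier in every case.  ``analytic_eigenvalues`` and
``analytic_charpoly`` expose the closed-form eigenvalue factorisations:
exact in cases 1-3 (the Jacobian is block-triangular there), but in
case 4 derived under the smallness assumptions rho << 1 and phi << 1,
so case-4 analytic reports are labelled approximate and gated by a
configurable regime check.

Verdicts use a marginality band of eps = 1e-9 on eigenvalue real parts:
``stable`` iff every real part < -eps, ``unstable`` iff some real part
> +eps, ``marginal`` otherwise (e.g. exactly at a bifurcation point).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .equilibria import EquilibriumPoint, UnsupportedCaseError, endemic_quadratic
from .model import CaseId, ModelParameters, classify_case, evaluate_jacobian

__all__ = [
    "CharPolyCoefficients",
    "StabilityReport",
    "RegimeError",
    "numeric_eigenvalues",
    "analytic_charpoly",
    "analytic_eigenvalues",
    "routh_hurwitz_cubic",
    "EPS_MARGINAL",
    "RHO_SMALL_DEFAULT",
    "PHI_SMALL_DEFAULT",
]

EPS_MARGINAL = 1e-9
#: Default smallness bounds under which the case-4 closed-form spectrum
#: is considered a usable approximation.
RHO_SMALL_DEFAULT = 1e-3
PHI_SMALL_DEFAULT = 1e-2


class RegimeError(ValueError):
    """Case-4 analytic spectrum requested outside the small-rho/phi regime."""


@dataclass(frozen=True)
class CharPolyCoefficients:
    """Closed-form characteristic-polynomial coefficients at an equilibrium.

    Only the fields of the active case/equilibrium are populated:

    * case 2 (and case 4, approximately), E0: quadratic ``u1, u2``;
    * case 2, E2: quadratic ``v1, v2``;
    * case 3, E3: quadratic ``p1, p2``; E4: ``q1, q2``;
    * case 4, E5/E6: cubic ``y1, y2, y3`` and the Routh-Hurwitz
      determinant ``delta = y1*y2 - y3``.
    """

    case: CaseId
    label: str
    u1: Optional[float] = None
    u2: Optional[float] = None
    v1: Optional[float] = None
    v2: Optional[float] = None
    p1: Optional[float] = None
    p2: Optional[float] = None
    q1: Optional[float] = None
    q2: Optional[float] = None
    y1: Optional[float] = None
    y2: Optional[float] = None
    y3: Optional[float] = None
    delta: Optional[float] = None


@dataclass(frozen=True)
class StabilityReport:
    equilibrium: EquilibriumPoint
    eigenvalues: tuple[complex, ...]
    verdict: str  # "stable" | "unstable" | "marginal"
    method: str  # "numeric" | "analytic"
    analytic_regime_ok: bool = True


def _verdict(eigenvalues, eps: float = EPS_MARGINAL) -> str:
    real_parts = np.real(np.asarray(eigenvalues, dtype=complex))
    if np.any(real_parts > eps):
        return "unstable"
    if np.all(real_parts < -eps):
        return "stable"
    return "marginal"


def numeric_eigenvalues(eq: EquilibriumPoint, params: ModelParameters,
                        eps: float = EPS_MARGINAL) -> StabilityReport:
    """Spectrum of the Jacobian at the equilibrium; the ground-truth verdict."""
    coords = eq.to_array()
    if not np.all(np.isfinite(coords)):
        raise ValueError(
            f"equilibrium {eq.label} has non-real coordinates; "
            "cannot classify numerically"
        )
    jac = evaluate_jacobian(coords, params)
    eig = scipy.linalg.eigvals(jac)
    return StabilityReport(
        equilibrium=eq,
        eigenvalues=tuple(sorted(eig, key=lambda z: (z.real, z.imag))),
        verdict=_verdict(eig, eps),
        method="numeric",
    )


def analytic_charpoly(eq: EquilibriumPoint, params: ModelParameters) -> CharPolyCoefficients:
    """Closed-form characteristic-polynomial coefficients for cases 2-4.

    Case 1 is rejected: its eigenvalues are fully explicit (see
    ``analytic_eigenvalues``) and no reduced polynomial is needed.  The
    case-4 cubic coefficients use the rewritten forms
    ``y2 = kappa(alpha G + eta) + beta delta eta J/kappa + gamma delta G (2AG+B)``
    and ``y3 = gamma delta kappa G (2AG+B)``, which at the endemic roots
    make ``2AG+B = +/- sqrt(B^2 - 4AH)`` explicit; when beta = kappa the
    exact total-recidivism reductions are used instead.
    """
    p = params
    case = classify_case(p)
    if case == CaseId.NO_CORRUPTION_NO_RECIDIVISM:
        raise UnsupportedCaseError(
            "case 1 eigenvalues are fully explicit; no reduced "
            "characteristic polynomial is defined"
        )
    label = eq.label
    g, j = eq.coordinates.G, eq.coordinates.J

    if label == "E0":
        # Reduced quadratic on the (G, P) block; exact for rho = 0 and an
        # O(rho*phi) approximation in case 4.
        u1 = p.kappa + p.gamma * p.delta / p.eta - p.alpha * p.sigma
        u2 = (-p.alpha * p.sigma * p.kappa
              + (p.kappa - p.beta) * p.gamma * p.delta / p.eta)
        return CharPolyCoefficients(case=case, label=label, u1=u1, u2=u2)

    if case == CaseId.RECIDIVISM_ONLY:  # E2
        v1 = p.alpha * g + p.kappa + p.beta * p.gamma * p.delta / (p.eta * p.kappa)
        v2 = p.alpha * p.kappa * g
        return CharPolyCoefficients(case=case, label=label, v1=v1, v2=v2)

    quad = endemic_quadratic(p)
    sqrt_disc_signed = 2.0 * quad.A * g + quad.B  # = +sqrt(disc) on the plus root

    if case == CaseId.CORRUPTION_ONLY:  # E3 / E4
        lin = p.eta + (p.alpha + p.rho) * g
        quad_term = p.gamma * p.delta * g * sqrt_disc_signed
        if label == "E3":
            return CharPolyCoefficients(case=case, label=label, p1=lin, p2=quad_term)
        return CharPolyCoefficients(case=case, label=label, q1=lin, q2=quad_term)

    # Case 4, E5/E6 cubic (small-rho/phi factorisation).
    if p.beta == p.kappa:
        y1 = p.alpha * g + p.eta + p.delta * j + p.kappa
        y2 = (p.kappa * (p.alpha * g + p.eta)
              + p.alpha * g * (p.eta + p.rho * g)
              + p.delta * p.eta * j)
        y3 = p.kappa * p.alpha * g * (p.eta + p.rho * g)
    else:
        y1 = p.alpha * g + p.eta + p.beta * p.delta * j / p.kappa + p.kappa
        y2 = (p.kappa * (p.alpha * g + p.eta)
              + p.beta * p.delta * p.eta * j / p.kappa
              + p.gamma * p.delta * g * sqrt_disc_signed)
        y3 = p.gamma * p.delta * p.kappa * g * sqrt_disc_signed
    return CharPolyCoefficients(case=case, label=label, y1=y1, y2=y2, y3=y3,
                                delta=y1 * y2 - y3)


def _quad_roots(b: float, c: float) -> list[complex]:
    """Roots of lambda^2 + b*lambda + c = 0."""
    return list(np.roots([1.0, b, c]).astype(complex))


def analytic_eigenvalues(eq: EquilibriumPoint, params: ModelParameters,
                         rho_small: float = RHO_SMALL_DEFAULT,
                         phi_small: float = PHI_SMALL_DEFAULT,
                         strict: bool = False,
                         eps: float = EPS_MARGINAL) -> StabilityReport:
    """The closed-form eigenvalue set at an equilibrium.

    Cases 1-3 are exact.  In case 4 the factorisation (one eigenvalue
    ``-phi*J*`` plus a cubic) holds only for rho << 1 and phi << 1;
    ``analytic_regime_ok`` records whether the parameters satisfy the
    configured smallness bounds, and with ``strict=True`` a request
    outside that regime raises ``RegimeError``.
    """
    p = params
    case = classify_case(p)
    label = eq.label
    g = eq.coordinates.G
    regime_ok = True

    if case == CaseId.NO_CORRUPTION_NO_RECIDIVISM:
        from .equilibria import compute_R0

        R0 = compute_R0(p)
        lam1 = ((R0 - 1.0) if label == "E0" else (1.0 - R0)) * p.gamma * p.delta / p.eta
        eig = [lam1, -p.eta, -p.gamma * p.phi / p.eta, -p.kappa]
    elif case == CaseId.RECIDIVISM_ONLY:
        cp = analytic_charpoly(eq, p)
        if label == "E0":
            eig = _quad_roots(cp.u1, cp.u2)
        else:
            eig = _quad_roots(cp.v1, cp.v2)
        eig += [-p.eta, -p.gamma * p.phi / p.eta]
    elif case == CaseId.CORRUPTION_ONLY:
        if label == "E0":
            from .equilibria import compute_R0

            lam1 = (compute_R0(p) - 1.0) * p.gamma * p.delta / p.eta
            eig = [lam1, -p.eta, -p.gamma * p.phi / p.eta, -p.kappa]
        else:
            cp = analytic_charpoly(eq, p)
            b, c = (cp.p1, cp.p2) if label == "E3" else (cp.q1, cp.q2)
            eig = _quad_roots(b, c)
            eig += [-p.phi * p.gamma / (p.eta + p.rho * g), -p.kappa]
    else:
        regime_ok = p.rho <= rho_small and p.phi <= phi_small
        if strict and not regime_ok:
            raise RegimeError(
                f"case-4 analytic spectrum requires rho <= {rho_small} and "
                f"phi <= {phi_small}; got rho={p.rho}, phi={p.phi}"
            )
        if label == "E0":
            cp = analytic_charpoly(eq, p)
            eig = _quad_roots(cp.u1, cp.u2)
            eig += [-p.eta, -p.gamma * p.phi / p.eta]
        else:
            cp = analytic_charpoly(eq, p)
            eig = list(np.roots([1.0, cp.y1, cp.y2, cp.y3]).astype(complex))
            eig += [-p.phi * eq.coordinates.J]

    eig = [complex(z) for z in eig]
    return StabilityReport(
        equilibrium=eq,
        eigenvalues=tuple(sorted(eig, key=lambda z: (z.real, z.imag))),
        verdict=_verdict(eig, eps),
        method="analytic",
        analytic_regime_ok=regime_ok,
    )


def routh_hurwitz_cubic(y1: float, y2: float, y3: float) -> bool:
    """Routh-Hurwitz test for lambda^3 + y1 l^2 + y2 l + y3.

    True iff every root has negative real part: y1 > 0, y2 > 0, y3 > 0
    and delta = y1*y2 - y3 > 0.
    """
    if not all(math.isfinite(v) for v in (y1, y2, y3)):
        raise ValueError("coefficients must be finite")
    return y1 > 0.0 and y2 > 0.0 and y3 > 0.0 and (y1 * y2 - y3) > 0.0
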