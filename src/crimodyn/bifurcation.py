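"""Bifurcation diagrams in the gang growth parameter alpha.

Because R0 = alpha*eta*sigma/(gamma*delta) is linear in alpha while the
thresholds r, r1, r2 do not involve alpha, every critical alpha follows
from the exact inversion alpha = target * gamma*delta/(eta*sigma):

* transcritical exchange of the crime-free state with the endemic
  branch at R0 = 1 (case 1), R0 = 1 - beta/kappa (case 2) or R0 = r2
  (cases 3-4, where r2 degenerates to 1 when beta = 0);
* saddle-node (backward bifurcation, coalescence of the two endemic
  roots) at R0 = r (case 3) or R0 = r1 (case 4).

Branches are assembled from the closed-form equilibria on an alpha
grid — no numerical continuation is needed — with numeric-eigenvalue
stability at every grid point and unphysical (negative-G) segments
retained but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .equilibria import analytic_equilibria, compute_thresholds
from .model import ModelParameters, classify_case, CaseId
from .stability import numeric_eigenvalues

__all__ = [
    "BifurcationBranch",
    "CriticalAlphas",
    "critical_alphas",
    "sweep_alpha",
    "branches_to_dataframe",
]


@dataclass(frozen=True)
class CriticalAlphas:
    """Critical values of alpha for the active case (each optional).

    ``no_bistability_window`` is set in case 4 when r2 <= 0, in which
    case neither threshold exists (the crime-free state is never
    restabilised by lowering alpha alone).
    """

    transcritical: Optional[float] = None
    saddle_node: Optional[float] = None
    no_bistability_window: bool = False


@dataclass(frozen=True)
class BifurcationBranch:
    """One equilibrium branch sampled on the alpha grid.

    ``g_values`` may contain negative values (unphysical but displayed,
    as on the case-1 diagram where the endemic G* < 0 below the
    transcritical point) or NaN where the root is complex.
    ``stability`` holds "stable"/"unstable"/"marginal" per grid point,
    or "undefined" where coordinates are not real.
    """

    label: str
    alphas: np.ndarray
    g_values: np.ndarray
    j_values: np.ndarray
    c_values: np.ndarray
    p_values: np.ndarray
    stability: tuple[str, ...]
    physical: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.alphas)
        if not (len(self.g_values) == len(self.stability) == len(self.physical) == n):
            raise ValueError("branch arrays must share length")


def _alpha_at_R0(params: ModelParameters, target: float) -> float:
    return target * params.gamma * params.delta / (params.eta * params.sigma)


def critical_alphas(params: ModelParameters) -> CriticalAlphas:
    """Exact critical alphas obtained by inverting R0(alpha) = target.

    The alpha entry of ``params`` is irrelevant (alpha is the swept
    parameter); r, r1 and r2 are alpha-independent, so the inversion is
    closed-form.
    """
    case = classify_case(params)
    if case == CaseId.NO_CORRUPTION_NO_RECIDIVISM:
        return CriticalAlphas(transcritical=_alpha_at_R0(params, 1.0))
    if case == CaseId.RECIDIVISM_ONLY:
        target = 1.0 - params.beta / params.kappa
        trans = _alpha_at_R0(params, target) if target > 0.0 else None
        return CriticalAlphas(transcritical=trans)
    thr = compute_thresholds(params)
    if case == CaseId.CORRUPTION_ONLY:
        return CriticalAlphas(
            transcritical=_alpha_at_R0(params, 1.0),
            saddle_node=_alpha_at_R0(params, thr.r),
        )
    if thr.no_bistability_window:
        return CriticalAlphas(no_bistability_window=True)
    return CriticalAlphas(
        transcritical=_alpha_at_R0(params, thr.r2),
        saddle_node=_alpha_at_R0(params, thr.r1),
    )


def sweep_alpha(params: ModelParameters,
                alpha_range: tuple[float, float],
                n_points: int = 500) -> dict[str, BifurcationBranch]:
    """Assemble equilibrium branches over a uniform alpha grid.

    Critical alphas inside the range are inserted into the grid exactly
    so diagrams show the branch-touching points.  Stability at each grid
    point comes from numeric eigenvalues of the full Jacobian; points
    with complex coordinates get stability "undefined".
    """
    lo, hi = alpha_range
    if not (0.0 < lo < hi):
        raise ValueError(f"alpha range must satisfy 0 < lo < hi, got {alpha_range}")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(lo, hi, n_points)
    crit = critical_alphas(params)
    inserts = [a for a in (crit.transcritical, crit.saddle_node)
               if a is not None and lo < a < hi]
    if inserts:
        grid = np.unique(np.concatenate([grid, np.asarray(inserts)]))

    per_label: dict[str, dict[str, list]] = {}
    for alpha in grid:
        p_alpha = params.replace(alpha=float(alpha))
        for eq in analytic_equilibria(p_alpha):
            rec = per_label.setdefault(
                eq.label,
                {"alpha": [], "G": [], "J": [], "C": [], "P": [],
                 "stab": [], "phys": []},
            )
            coords = eq.to_array()
            rec["alpha"].append(float(alpha))
            rec["G"].append(coords[0])
            rec["J"].append(coords[1])
            rec["C"].append(coords[2])
            rec["P"].append(coords[3])
            if np.all(np.isfinite(coords)):
                rec["stab"].append(numeric_eigenvalues(eq, p_alpha).verdict)
            else:
                rec["stab"].append("undefined")
            rec["phys"].append(bool(eq.exists_physically))

    return {
        label: BifurcationBranch(
            label=label,
            alphas=np.asarray(rec["alpha"]),
            g_values=np.asarray(rec["G"]),
            j_values=np.asarray(rec["J"]),
            c_values=np.asarray(rec["C"]),
            p_values=np.asarray(rec["P"]),
            stability=tuple(rec["stab"]),
            physical=np.asarray(rec["phys"], dtype=bool),
        )
        for label, rec in per_label.items()
    }


def branches_to_dataframe(branches: dict[str, BifurcationBranch]):
    """Flatten branches into the canonical export table.

    Columns: label, alpha, G_star, J_star, C_star, P_star, stable,
    physical.
    """
    import pandas as pd

    frames = []
    for label in sorted(branches):
        br = branches[label]
        frames.append(pd.DataFrame({
            "label": label,
            "alpha": br.alphas,
            "G_star": br.g_values,
            "J_star": br.j_values,
            "C_star": br.c_values,
            "P_star": br.p_values,
            "stable": [s == "stable" for s in br.stability],
            "physical": br.physical,
        }))
    return pd.concat(frames, ignore_index=True)
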