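"""Fixed-step RK4 integration, attractor detection and basin probing.

The model admits no limit cycles (the Routh-Hurwitz determinant of the
endemic cubic is strictly positive, ruling out Hopf bifurcations), so
every bounded trajectory settles onto an equilibrium; the classic
4th-order Runge-Kutta scheme with a fixed step of 0.01 time units
resolves all time scales of the shipped scenarios comfortably.

In the bistable window r1 <= R0 < r2 two attractors coexist and the
initial condition decides between eradication (E0) and persistence (E5);
``probe_basin`` maps a batch of initial conditions to their attractors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .equilibria import EquilibriumPoint
from .model import ModelParameters, StateVector, evaluate_rhs

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "IntegrationError",
    "integrate_rk4",
    "detect_attractor",
    "probe_basin",
]

#: Trajectories may undershoot zero by at most this much before the
#: integrator aborts; small negative excursions are numerical noise,
#: larger ones indicate the step size is too coarse.
NEGATIVITY_TOL = 1e-6


class IntegrationError(RuntimeError):
    """Trajectory left the physical region or diverged."""


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for a fixed-step RK4 run.

    ``convergence_window`` is the trailing fraction of the trajectory
    over which the state must be quasi-stationary for attractor
    detection; ``convergence_tol`` is the relative tolerance used both
    for the stationarity check and for matching a candidate equilibrium.
    """

    initial_state: StateVector
    t_end: float
    dt: float = 0.01
    convergence_tol: float = 1e-4
    convergence_window: float = 0.1
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_end < self.dt:
            raise ValueError(f"t_end ({self.t_end}) must be >= dt ({self.dt})")
        if self.convergence_tol <= 0.0:
            raise ValueError("convergence_tol must be > 0")
        if not (0.0 < self.convergence_window <= 1.0):
            raise ValueError("convergence_window must lie in (0, 1]")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class Trajectory:
    """A time-indexed solution: times (n,), states (n, 4) in (G, J, C, P)."""

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters
    config: SimulationConfig
    converged_to: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")

    @property
    def final_state(self) -> StateVector:
        return StateVector.from_array(self.states[-1])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "G": self.states[:, 0],
                "J": self.states[:, 1],
                "C": self.states[:, 2],
                "P": self.states[:, 3],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rk4_step(y: np.ndarray, dt: float, params: ModelParameters) -> np.ndarray:
    k1 = evaluate_rhs(y, params)
    k2 = evaluate_rhs(y + 0.5 * dt * k1, params)
    k3 = evaluate_rhs(y + 0.5 * dt * k2, params)
    k4 = evaluate_rhs(y + dt * k3, params)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate_rk4(params: ModelParameters, config: SimulationConfig) -> Trajectory:
    """Integrate the model with classic 4-stage RK4 at fixed step ``dt``.

    The trajectory is recorded at every step (or every ``record_every``
    steps, always including the final state).  The run aborts with
    ``IntegrationError`` if any component drops below -1e-6 (advice:
    reduce ``dt``) or becomes non-finite.
    """
    y0 = config.initial_state.to_array()
    if np.any(y0 < 0.0):
        raise ValueError(f"initial state must be non-negative, got {y0}")
    # Scalar inner loop: dataclass/array plumbing per step dominates the
    # cost otherwise on 10^4-10^5-step runs.
    al, be, ga, de, et, ka, rh, si, ph = (
        params.alpha, params.beta, params.gamma, params.delta, params.eta,
        params.kappa, params.rho, params.sigma, params.phi,
    )
    dt = config.dt

    def rhs(G, J, C, P):
        return (
            al * G * (si - G) - de * G * J + be * P,
            ga - et * J - rh * G * J,
            rh * G * J - ph * C * J,
            de * G * J + ph * C * J - ka * P,
        )

    n_steps = int(round(config.t_end / dt))
    G, J, C, P = (float(v) for v in y0)
    times = [0.0]
    states = [(G, J, C, P)]
    for i in range(1, n_steps + 1):
        a1, b1, c1, d1 = rhs(G, J, C, P)
        h = 0.5 * dt
        a2, b2, c2, d2 = rhs(G + h * a1, J + h * b1, C + h * c1, P + h * d1)
        a3, b3, c3, d3 = rhs(G + h * a2, J + h * b2, C + h * c2, P + h * d2)
        a4, b4, c4, d4 = rhs(G + dt * a3, J + dt * b3, C + dt * c3, P + dt * d3)
        w = dt / 6.0
        G += w * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        J += w * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        C += w * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
        P += w * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        lo = min(G, J, C, P)
        if not (math.isfinite(G) and math.isfinite(J)
                and math.isfinite(C) and math.isfinite(P)):
            raise IntegrationError(
                f"trajectory diverged (non-finite state) at t={i * dt:g}"
            )
        if lo < -NEGATIVITY_TOL:
            raise IntegrationError(
                f"state component fell below -{NEGATIVITY_TOL:g} at "
                f"t={i * dt:g} (state={(G, J, C, P)}); reduce dt"
            )
        if i % config.record_every == 0 or i == n_steps:
            times.append(i * dt)
            states.append((G, J, C, P))
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        params=params,
        config=config,
    )


def detect_attractor(traj: Trajectory,
                     candidates: Sequence[EquilibriumPoint]) -> str:
    """Label of the candidate equilibrium the trajectory settled onto.

    The trailing ``convergence_window`` fraction of the recorded states
    must be quasi-stationary (peak-to-peak variation below
    ``convergence_tol`` relative to 1 + |mean|); the window mean is then
    matched against each candidate component-wise with relative
    tolerance ``convergence_tol`` and an absolute floor of 1e-6 for
    zero coordinates.  Returns ``"not converged"`` when the trajectory
    is still moving or matches no candidate.
    """
    if len(candidates) == 0:
        raise ValueError("candidate equilibrium list is empty")
    cfg = traj.config
    n = len(traj.states)
    window = max(2, int(np.ceil(cfg.convergence_window * n)))
    tail = traj.states[-window:]
    mean = tail.mean(axis=0)
    spread = tail.max(axis=0) - tail.min(axis=0)
    if np.any(spread > cfg.convergence_tol * (1.0 + np.abs(mean))):
        return "not converged"
    for eq in candidates:
        coords = eq.to_array()
        if not np.all(np.isfinite(coords)):
            continue
        tol = cfg.convergence_tol * np.abs(coords) + 1e-6
        if np.all(np.abs(mean - coords) <= tol):
            return eq.label
    return "not converged"


def probe_basin(params: ModelParameters,
                initial_states: Sequence[StateVector],
                config: SimulationConfig,
                candidates: Optional[Sequence[EquilibriumPoint]] = None,
                ) -> dict[tuple[float, float, float, float], str]:
    """Map each initial condition to the attractor it converges to.

    Integration errors for individual initial states are recorded as
    ``"error: ..."`` labels without aborting the batch.  Candidates
    default to the closed-form equilibria of the active case.
    """
    if candidates is None:
        from .equilibria import analytic_equilibria

        candidates = analytic_equilibria(params)
    result: dict[tuple[float, float, float, float], str] = {}
    for state in initial_states:
        key = tuple(state.to_array())
        try:
            traj = integrate_rk4(params, config.replace(initial_state=state))
        except (IntegrationError, ValueError) as exc:
            result[key] = f"error: {exc}"
            continue
        result[key] = detect_attractor(traj, candidates)
    return result
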