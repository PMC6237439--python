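"""Integration of the community ODE system and trajectory summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    STATE_NAMES,
    ModelParameters,
    Strain,
    SystemState,
    make_rhs,
)

__all__ = [
    "SolverConfig",
    "Trajectory",
    "EndpointSummary",
    "IntegrationError",
    "simulate",
    "lag_from_Q0",
    "Q0_from_lag",
    "endpoint_summary",
]

DEFAULT_T_END = 48.0  # h, the fermentation duration


class IntegrationError(RuntimeError):
    """Integration failed; carries the last time reached."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last good time: {t_last:.4g} h)")
        self.t_last = t_last


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive-solver settings.

    LSODA switches between non-stiff and stiff modes; Monod terms with
    small half-saturation constants make the system moderately stiff near
    substrate exhaustion, so tight default tolerances are used.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf


@dataclass
class Trajectory:
    """Solution of the community model on a time grid.

    ``states`` has shape (n_times, 13) in :data:`~synthgut.model.STATE_NAMES`
    order; provenance (parameters, initial state, solver settings) is kept
    so a run can be reproduced.
    """

    t: np.ndarray
    states: np.ndarray
    params: ModelParameters
    initial_state: SystemState
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.t.size, len(STATE_NAMES)):
            raise ValueError("states must be (n_times, 13)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def __getitem__(self, name: str) -> np.ndarray:
        """Time series of one state variable, e.g. ``traj["X_RI"]``."""
        return self.states[:, STATE_NAMES.index(name)]

    def at(self, t: float) -> np.ndarray:
        """State vector linearly interpolated at time ``t`` (h)."""
        if t < self.t[0] or t > self.t[-1]:
            raise ValueError(
                f"t={t} outside trajectory span [{self.t[0]}, {self.t[-1]}]"
            )
        return np.array(
            [np.interp(t, self.t, self.states[:, j]) for j in range(self.states.shape[1])]
        )

    def state_at(self, t: float) -> SystemState:
        return SystemState.from_vector(np.maximum(self.at(t), 0.0), t=t)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: columns time_h, variable, value."""
        frames = []
        for j, name in enumerate(STATE_NAMES):
            frames.append(
                pd.DataFrame(
                    {"time_h": self.t, "variable": name, "value": self.states[:, j]}
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class EndpointSummary:
    """End-point abundances, the FP/RI ratio and the dominance ordering."""

    t_e: float
    X: dict[Strain, float]
    ratio_FP_RI: float
    dominance: tuple[Strain, ...]
    tie: bool = False

    @property
    def dominant(self) -> Strain:
        return self.dominance[0]


def simulate(
    params: ModelParameters,
    initial_state: SystemState,
    t_grid: np.ndarray | None = None,
    solver: SolverConfig | None = None,
) -> Trajectory:
    """Integrate the community model over ``t_grid`` (hours, starting at 0).

    Raises :class:`IntegrationError` on solver failure, carrying the last
    time the solver reached.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, DEFAULT_T_END, 481)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    solver = solver or SolverConfig()
    y0 = initial_state.to_vector()
    sol = solve_ivp(
        make_rhs(params),
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method=solver.method,
        rtol=solver.rtol,
        atol=solver.atol,
        max_step=solver.max_step,
    )
    if not sol.success:
        t_last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"solver failed: {sol.message}", t_last)
    return Trajectory(
        t=sol.t, states=sol.y.T, params=params, initial_state=initial_state,
        solver=solver,
    )


def lag_from_Q0(Q0: float, mu: float) -> float:
    """Lag duration (h) implied by the initial lag variable: -ln(Q0)/mu.

    The lag is the time at which Gamma(Q) = 1/2, i.e. Q reaches 1 under
    dQ/dt = mu*Q.  Negative when Q0 > 1 (no lag).
    """
    if Q0 <= 0:
        raise ValueError("Q0 must be > 0")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return -math.log(Q0) / mu


def Q0_from_lag(lag: float, mu: float) -> float:
    """Initial lag variable producing a given lag duration: exp(-mu*lag)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return math.exp(-mu * lag)


def endpoint_summary(traj: Trajectory, t_e: float = DEFAULT_T_END) -> EndpointSummary:
    """Summarize a trajectory at time ``t_e``: abundances, FP/RI ratio,
    dominance ordering (descending abundance; exact ties broken RI<FP<BH
    and flagged)."""
    y = traj.at(t_e)
    X = {Strain.RI: float(y[0]), Strain.FP: float(y[1]), Strain.BH: float(y[2])}
    x_ri, x_fp = X[Strain.RI], X[Strain.FP]
    if x_ri > 0:
        ratio = x_fp / x_ri
    else:
        ratio = math.inf if x_fp > 0 else math.nan
    order = [Strain.RI, Strain.FP, Strain.BH]  # fixed tie-break order
    dominance = tuple(sorted(order, key=lambda s: (-X[s], order.index(s))))
    values = sorted(X.values(), reverse=True)
    tie = values[0] == values[1]
    return EndpointSummary(
        t_e=float(t_e), X=X, ratio_FP_RI=float(ratio), dominance=dominance, tie=tie
    )
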