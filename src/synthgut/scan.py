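"""Dominance scans: end-point FP/RI abundance ratio over grids of lag
phases or initial abundances.

In batch tri-culture the acetogen BH is always dominant and either RI or
FP co-dominates; which one wins is sensitive to initial abundances and
lag phases.  These scans map that sensitivity: each grid cell is one full
tri-culture simulation, summarized by log10(X_FP(t_e)/X_RI(t_e)) —
positive for FP dominance, negative for RI dominance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParameters, Strain, SystemState
from .simulate import (
    DEFAULT_T_END,
    Q0_from_lag,
    EndpointSummary,
    SolverConfig,
    endpoint_summary,
    simulate,
)

__all__ = [
    "ScanGrid",
    "scan_lag",
    "scan_init",
    "classify_dominance",
    "DEFAULT_SCAN_INITS",
    "DEFAULT_SCAN_LAGS",
]

#: default fixed initial abundances (1e8 counts/mL) for lag scans:
#: the average inoculum across the tri-culture experiments
DEFAULT_SCAN_INITS = {Strain.RI: 0.58, Strain.FP: 0.04, Strain.BH: 0.21}

#: default fixed lag phases (h) for initial-abundance scans
DEFAULT_SCAN_LAGS = {Strain.RI: 0.33, Strain.FP: 0.08, Strain.BH: 0.1}


@dataclass
class ScanGrid:
    """Result of a 2-D dominance scan.

    ``log_ratio[i, j]`` is log10(X_FP/X_RI) at ``t_e`` for ``x_values[j]``
    (columns) and ``y_values[i]`` (rows); cells where one strain's
    end-point abundance is zero hold +/-inf; failed simulations hold NaN
    and are flagged in ``failed``.
    """

    x_name: str
    y_name: str
    x_values: np.ndarray
    y_values: np.ndarray
    x_scale: str
    y_scale: str
    log_ratio: np.ndarray
    summaries: list[list[EndpointSummary | None]]
    failed: np.ndarray
    t_e: float
    fixed: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export with per-strain end-point abundances."""
        rows = []
        for i, yv in enumerate(self.y_values):
            for j, xv in enumerate(self.x_values):
                s = self.summaries[i][j]
                rows.append(
                    {
                        self.x_name: xv,
                        self.y_name: yv,
                        "log10_ratio_FP_RI": self.log_ratio[i, j],
                        "X_RI": s.X[Strain.RI] if s else np.nan,
                        "X_FP": s.X[Strain.FP] if s else np.nan,
                        "X_BH": s.X[Strain.BH] if s else np.nan,
                        "failed": bool(self.failed[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_matrix(self) -> pd.DataFrame:
        """Matrix export: rows ``y_values``, columns ``x_values``."""
        return pd.DataFrame(
            self.log_ratio, index=self.y_values, columns=self.x_values
        ).rename_axis(index=self.y_name, columns=self.x_name)


def _log_ratio(summary: EndpointSummary) -> float:
    x_fp, x_ri = summary.X[Strain.FP], summary.X[Strain.RI]
    if x_fp > 0 and x_ri > 0:
        return math.log10(x_fp / x_ri)
    if x_fp == 0 and x_ri == 0:
        return math.nan
    return math.inf if x_fp > 0 else -math.inf


def _run_grid(cell_fn, x_values, y_values, t_e):
    nx, ny = len(x_values), len(y_values)
    log_ratio = np.full((ny, nx), np.nan)
    failed = np.zeros((ny, nx), dtype=bool)
    summaries: list[list[EndpointSummary | None]] = [
        [None] * nx for _ in range(ny)
    ]
    for i, yv in enumerate(y_values):
        for j, xv in enumerate(x_values):
            try:
                traj = cell_fn(xv, yv)
                s = endpoint_summary(traj, t_e)
            except Exception:
                failed[i, j] = True
                continue
            summaries[i][j] = s
            log_ratio[i, j] = _log_ratio(s)
    return log_ratio, summaries, failed


def scan_lag(
    params: ModelParameters,
    base_init: dict[Strain, float] | None = None,
    lag_RI_values: np.ndarray | None = None,
    lag_FP_values: np.ndarray | None = None,
    lag_BH: float = DEFAULT_SCAN_LAGS[Strain.BH],
    t_e: float = DEFAULT_T_END,
    initial_substrates: dict | None = None,
    solver: SolverConfig | None = None,
) -> ScanGrid:
    """Tri-culture dominance over a (lag_RI x lag_FP) grid.

    Lags (h) are converted to initial lag variables via each strain's
    fitted maximal growth rate.  Fixed conditions default to the average
    tri-culture inoculum (:data:`DEFAULT_SCAN_INITS`).
    """
    base_init = dict(DEFAULT_SCAN_INITS if base_init is None else base_init)
    if any(v <= 0 for v in base_init.values()):
        raise ValueError("base initial abundances must be > 0")
    if lag_RI_values is None:
        lag_RI_values = np.linspace(0.0, 8.0, 25)
    if lag_FP_values is None:
        lag_FP_values = np.linspace(0.0, 8.0, 25)
    subs = initial_substrates or {}

    def cell(lag_ri, lag_fp):
        Q0 = {
            Strain.RI: Q0_from_lag(lag_ri, params.mu[Strain.RI]),
            Strain.FP: Q0_from_lag(lag_fp, params.mu[Strain.FP]),
            Strain.BH: Q0_from_lag(lag_BH, params.mu[Strain.BH]),
        }
        state = SystemState.initial(X=base_init, Q=Q0, **subs)
        grid = np.unique(np.concatenate((np.linspace(0.0, t_e, 97), [t_e])))
        return simulate(params, state, grid, solver)

    log_ratio, summaries, failed = _run_grid(
        lambda x, y: cell(y, x), lag_FP_values, lag_RI_values, t_e
    )
    return ScanGrid(
        x_name="lag_FP_h", y_name="lag_RI_h",
        x_values=np.asarray(lag_FP_values, float),
        y_values=np.asarray(lag_RI_values, float),
        x_scale="linear", y_scale="linear",
        log_ratio=log_ratio, summaries=summaries, failed=failed,
        t_e=t_e,
        fixed={"init": dict(base_init), "lag_BH": lag_BH, **subs},
    )


def scan_init(
    params: ModelParameters,
    lags: dict[Strain, float] | None = None,
    init_RI_values: np.ndarray | None = None,
    init_FP_values: np.ndarray | None = None,
    init_BH: float = DEFAULT_SCAN_INITS[Strain.BH],
    t_e: float = DEFAULT_T_END,
    initial_substrates: dict | None = None,
    solver: SolverConfig | None = None,
) -> ScanGrid:
    """Tri-culture dominance over an (init_RI x init_FP) grid.

    Initial-abundance axes are log-spaced by default; fixed lag phases
    default to the average estimated tri-culture lags
    (:data:`DEFAULT_SCAN_LAGS`).
    """
    lags = dict(DEFAULT_SCAN_LAGS if lags is None else lags)
    if init_RI_values is None:
        init_RI_values = np.logspace(-3, 0.5, 25)
    if init_FP_values is None:
        init_FP_values = np.logspace(-3, 0.5, 25)
    if np.any(np.asarray(init_RI_values) <= 0) or np.any(
        np.asarray(init_FP_values) <= 0
    ):
        raise ValueError("initial-abundance axes must be positive")
    subs = initial_substrates or {}
    Q0 = {s: Q0_from_lag(lags[s], params.mu[s]) for s in Strain}

    def cell(init_fp, init_ri):
        X = {Strain.RI: init_ri, Strain.FP: init_fp, Strain.BH: init_BH}
        state = SystemState.initial(X=X, Q=Q0, **subs)
        grid = np.unique(np.concatenate((np.linspace(0.0, t_e, 97), [t_e])))
        return simulate(params, state, grid, solver)

    log_ratio, summaries, failed = _run_grid(cell, init_FP_values, init_RI_values, t_e)
    return ScanGrid(
        x_name="init_FP", y_name="init_RI",
        x_values=np.asarray(init_FP_values, float),
        y_values=np.asarray(init_RI_values, float),
        x_scale="log", y_scale="log",
        log_ratio=log_ratio, summaries=summaries, failed=failed,
        t_e=t_e,
        fixed={"lags": dict(lags), "init_BH": init_BH, **subs},
    )


def classify_dominance(
    summary: EndpointSummary, observed: Strain | None = None
) -> tuple[str, bool | None]:
    """Classify the RI-vs-FP end-point outcome of one tri-culture.

    Returns ``("FP", ...)`` when the FP/RI ratio exceeds 1, ``("RI", ...)``
    below 1, ``("tie", ...)`` at exactly 1.  When an observed dominant
    strain is supplied, the second element flags agreement.
    """
    if summary.ratio_FP_RI > 1:
        label = "FP"
    elif summary.ratio_FP_RI < 1:
        label = "RI"
    else:
        label = "tie"
    agreement = None
    if observed is not None:
        agreement = label == observed.value
    return label, agreement
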