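"""Parameter estimation for the community model from batch time series.

Two protocols are provided, mirroring how the model is parameterized in
practice:

* :func:`parameterization1` fits each strain's parameters to its
  mono-culture experiments only.
* :func:`parameterization2` is a staged protocol using mono- and
  bi-cultures: FP from its mono-cultures; BH's yield parameters, then its
  growth kinetics, from FP/BH bi-cultures with initial acetate; finally
  RI's full parameter set from an RI/BH bi-culture with initial acetate.
  Fitting everything at once does not converge because of the nonlinear
  growth functions, hence the staging.

The objective is a normalized root-mean-square error: residuals of each
observed variable are scaled by that variable's per-experiment maximum
(putting counts and mM on one scale), pooled over variables and times
into one RMSE per experiment, and averaged over the experiments of a
stage.  Samples flagged as declining (post-log-phase) are excluded from
the abundance residuals.  Minimization is derivative-free (Nelder-Mead
simplex) in log10 parameter space, which enforces positivity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .model import ConfigurationError, ModelParameters, Strain
from .simulate import SolverConfig, Trajectory, simulate

__all__ = [
    "FermentationExperiment",
    "FitStage",
    "FitConfig",
    "FitResult",
    "FitError",
    "exclude_decline",
    "normalized_rmse",
    "fit_parameters",
    "parameterization1",
    "parameterization2",
    "estimate_Q0",
    "exhaustive_replicate_selection",
]

DECLINE_FRACTION = 0.9  # post-peak samples below this fraction of peak decline

#: solver settings used inside objective evaluations (speed over polish)
FIT_SOLVER = SolverConfig(rtol=1e-6, atol=1e-8)

# variables the model can be compared against
_MODEL_VARIABLES = {
    "X_RI", "X_FP", "X_BH",
    "S_fructose", "S_formate", "S_acetate", "S_butyrate", "S_H2", "S_CO2",
}


class FitError(RuntimeError):
    """Fitting failed (non-finite objective, missing data, divergence)."""


class DataWarning(UserWarning):
    """A data issue handled by a guard (e.g. an all-zero variable skipped)."""


@dataclass
class FermentationExperiment:
    """One batch fermentation: design, sample times and observations.

    ``observations[variable]`` is an (n_times, n_replicates) array of
    technical replicates (NaN for missing).  ``initial`` holds the design
    initial condition: inoculum abundances per strain (1e8 counts/mL) and
    initial fructose/acetate/formate/unknown concentrations (mM).
    ``excluded[variable]`` is a boolean per-time decline flag filled in by
    :func:`exclude_decline`.
    """

    id: str
    strains: tuple[Strain, ...]
    times: np.ndarray
    observations: dict[str, np.ndarray]
    initial: dict
    excluded: dict[str, np.ndarray] = field(default_factory=dict)
    truth: dict | None = None  # ground truth for synthetic experiments

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.id}: times must be non-negative and sorted")
        if not set(self.strains) <= set(Strain):
            raise ValueError(f"{self.id}: unknown strains")
        for var, obs in self.observations.items():
            obs = np.asarray(obs, dtype=float)
            if obs.ndim == 1:
                obs = obs[:, None]
            if obs.shape[0] != self.times.size:
                raise ValueError(f"{self.id}/{var}: observation/time mismatch")
            if np.nanmin(obs) < 0 if np.isfinite(obs).any() else False:
                raise ValueError(f"{self.id}/{var}: negative observation")
            self.observations[var] = obs

    def replicate_mean(self, variable: str) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            return np.nanmean(self.observations[variable], axis=1)

    def abundance_variables(self) -> list[str]:
        return [v for v in self.observations if v.startswith("X_")]

    def metabolite_variables(self) -> list[str]:
        return [v for v in self.observations if v.startswith("S_")]

    def included_mask(self, variable: str) -> np.ndarray:
        excl = self.excluded.get(variable)
        if excl is None:
            return np.ones(self.times.size, dtype=bool)
        return ~np.asarray(excl, dtype=bool)

    def initial_state(self, Q0: dict[Strain, float] | None = None):
        """Design initial condition as a :class:`~synthgut.model.SystemState`."""
        from .model import SystemState

        Q0 = Q0 or {}
        X = {s: float(self.initial.get("X", {}).get(s, 0.0)) for s in Strain}
        return SystemState.initial(
            X=X,
            Q={s: float(Q0.get(s, 1.0)) for s in Strain},
            fructose=float(self.initial.get("fructose", 50.0)),
            acetate=float(self.initial.get("acetate", 0.0)),
            formate=float(self.initial.get("formate", 0.0)),
            unknown=float(self.initial.get("unknown", 30.0)),
        )


def exclude_decline(exp: FermentationExperiment) -> FermentationExperiment:
    """Flag post-log-phase abundance samples as excluded from fitting.

    For each strain, samples strictly after the peak of the
    replicate-mean abundance whose mean falls below 90% of that peak are
    flagged as declining.  A post-peak plateau (>= 90% of peak) is not
    decline.  Metabolite observations are never excluded.
    """
    excluded = dict(exp.excluded)
    for var in exp.abundance_variables():
        mean = exp.replicate_mean(var)
        finite = np.isfinite(mean)
        flags = np.zeros(exp.times.size, dtype=bool)
        if finite.any():
            peak_idx = int(np.nanargmax(mean))
            peak = mean[peak_idx]
            after = np.arange(exp.times.size) > peak_idx
            flags = after & finite & (mean < DECLINE_FRACTION * peak)
        excluded[var] = flags
    return replace(exp, excluded=excluded)


def normalized_rmse(
    traj: Trajectory,
    exp: FermentationExperiment,
    pool: str = "experiment",
) -> float:
    """Normalized RMSE of a model trajectory against one experiment.

    Residuals per variable are (model - replicate-mean observation)
    divided by the per-experiment maximum of that variable's
    replicate-mean; ``pool="experiment"`` (default) pools all
    variable-time residuals into one RMSE, ``pool="variable"`` averages
    per-variable RMSEs.  Variables with an all-zero maximum are skipped
    with a warning; variables the model does not describe (e.g. lactate)
    are ignored.
    """
    per_var: list[np.ndarray] = []
    for var in exp.observations:
        if var not in _MODEL_VARIABLES:
            continue
        mean = exp.replicate_mean(var)
        mask = exp.included_mask(var) & np.isfinite(mean)
        if not mask.any():
            continue
        norm = float(np.max(mean[mask]))
        if norm == 0.0:
            warnings.warn(
                f"{exp.id}/{var}: all-zero observations, skipped", DataWarning
            )
            continue
        t = exp.times[mask]
        if t[-1] > traj.t[-1] + 1e-9:
            raise FitError(
                f"{exp.id}: trajectory span {traj.t[-1]} h does not cover "
                f"sample time {t[-1]} h"
            )
        model = np.interp(t, traj.t, traj[var])
        per_var.append((model - mean[mask]) / norm)
    if not per_var:
        raise FitError(f"{exp.id}: no comparable observations")
    if pool == "experiment":
        r = np.concatenate(per_var)
        return float(np.sqrt(np.mean(r * r)))
    if pool == "variable":
        return float(np.mean([np.sqrt(np.mean(r * r)) for r in per_var]))
    raise ValueError(f"unknown pooling mode: {pool}")


@dataclass
class FitStage:
    """One stage of a staged fit: which experiments, which free parameters,
    and whose lag variables (Q0) are co-estimated per experiment."""

    name: str
    experiment_ids: list[str]
    free_params: list[str]
    q0_strains: dict[str, list[Strain]] | None = None  # default: all present
    max_evaluations: int | None = None  # override the config-wide budget


@dataclass
class FitConfig:
    """Optimizer budget and bounds for a (staged) fit."""

    stages: list[FitStage]
    max_evaluations: int = 2000
    restarts: int = 2  # simplex passes per stage, re-seeded at the best point
    kinetics_polish: bool = False  # extra passes over mu/K/omega/Q0 only
    xatol: float = 1e-4
    fatol: float = 1e-7
    q0_bounds: tuple[float, float] = (1e-6, 10.0)
    pool: str = "experiment"
    solver: SolverConfig = field(default_factory=lambda: FIT_SOLVER)

    def __post_init__(self) -> None:
        valid = set(ModelParameters.flat_keys())
        for stage in self.stages:
            bad = set(stage.free_params) - valid
            if bad:
                raise ConfigurationError(
                    f"stage {stage.name}: unknown free parameters {sorted(bad)}"
                )


@dataclass
class StageResult:
    name: str
    objective: float
    n_evaluations: int
    converged: bool


@dataclass
class FitResult:
    """Outcome of a (staged) fit."""

    params: ModelParameters
    Q0: dict[str, dict[Strain, float]]  # per experiment, per strain
    per_experiment_rmse: dict[str, float]
    objective_trace: np.ndarray  # best-so-far objective per evaluation
    converged: bool
    stages: list[StageResult] = field(default_factory=list)

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def _simulate_experiment(
    params: ModelParameters,
    exp: FermentationExperiment,
    Q0: dict[Strain, float],
    solver: SolverConfig,
) -> Trajectory:
    t_end = max(float(exp.times[-1]), 1e-6)
    grid = np.unique(np.concatenate(([0.0, t_end], exp.times)))
    return simulate(params, exp.initial_state(Q0), grid, solver)


def _stage_objective_factory(
    experiments: list[FermentationExperiment],
    free_params: list[str],
    q0_slots: list[tuple[str, Strain]],
    base_params: ModelParameters,
    base_q0: dict[str, dict[Strain, float]],
    config: FitConfig,
):
    def objective(logx: np.ndarray) -> float:
        values = 10.0 ** np.asarray(logx, dtype=float)
        params = base_params.updated(dict(zip(free_params, values[: len(free_params)])))
        q0 = {eid: dict(q) for eid, q in base_q0.items()}
        lo, hi = config.q0_bounds
        for (eid, strain), v in zip(q0_slots, values[len(free_params):]):
            q0.setdefault(eid, {})[strain] = float(np.clip(v, lo, hi))
        total = 0.0
        # the division-guard warning would otherwise repeat once per
        # objective evaluation; it still fires on direct calls
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DataWarning)
            for exp in experiments:
                try:
                    traj = _simulate_experiment(
                        params, exp, q0.get(exp.id, {}), config.solver
                    )
                    rmse = normalized_rmse(traj, exp, pool=config.pool)
                except Exception:
                    return 1e6  # failed integration: penalized, not fatal
                total += rmse
        return total / len(experiments)

    return objective


def fit_parameters(
    experiments: dict[str, FermentationExperiment],
    config: FitConfig,
    init: ModelParameters,
    init_Q0: dict[str, dict[Strain, float]] | None = None,
) -> FitResult:
    """Run the staged derivative-free fit defined by ``config``.

    Parameters fitted in earlier stages are frozen (at their fitted
    values) in later stages.  Returns the combined parameter set,
    per-experiment lag variables, per-experiment normalized RMSE and the
    best-so-far objective trace.  Deterministic: identical inputs, init
    and budget give identical results.
    """
    params = init.copy()
    q0: dict[str, dict[Strain, float]] = {
        eid: dict(v) for eid, v in (init_Q0 or {}).items()
    }
    trace: list[float] = []
    stage_results: list[StageResult] = []
    converged = True

    for stage in config.stages:
        missing = [eid for eid in stage.experiment_ids if eid not in experiments]
        if missing:
            raise ConfigurationError(
                f"stage {stage.name}: experiments not available: {missing}"
            )
        exps = [experiments[eid] for eid in stage.experiment_ids]
        q0_slots: list[tuple[str, Strain]] = []
        for exp in exps:
            strains = (
                stage.q0_strains.get(exp.id, list(exp.strains))
                if stage.q0_strains is not None
                else list(exp.strains)
            )
            q0_slots.extend((exp.id, s) for s in strains)

        x0 = np.array(
            [math.log10(max(params.get_flat(k), 1e-12)) for k in stage.free_params]
            + [
                math.log10(q0.get(eid, {}).get(s, 1.0))
                for eid, s in q0_slots
            ]
        )
        objective = _stage_objective_factory(
            exps, stage.free_params, q0_slots, params, q0, config
        )

        if x0.size == 0:
            # empty free mask: evaluate and return init unchanged
            f0 = objective(x0)
            trace.append(f0)
            stage_results.append(StageResult(stage.name, f0, 1, True))
            continue

        f0 = objective(x0)
        if not np.isfinite(f0):
            raise FitError(
                f"stage {stage.name}: non-finite objective at initial guess "
                f"(experiments {stage.experiment_ids})"
            )

        best = {"x": x0.copy(), "f": f0}
        stage_trace: list[float] = []

        def tracked(logx, _objective=objective, _best=best, _trace=stage_trace):
            f = _objective(logx)
            if f < _best["f"]:
                _best["f"] = f
                _best["x"] = np.array(logx, dtype=float)
            _trace.append(_best["f"])
            return f

        n_passes = max(config.restarts, 1)
        budget = stage.max_evaluations or config.max_evaluations
        per_pass = max(budget // n_passes, 1)
        success = False
        # re-seeded simplex passes with shrinking edge length (log10 units):
        # the first explores, later ones polish the flat valley
        steps = [0.08 * (0.25**k) for k in range(n_passes)]
        for step in steps:
            xb = best["x"]
            simplex = np.vstack([xb] + [xb + step * e for e in np.eye(xb.size)])
            res = minimize(
                tracked,
                xb,
                method="Nelder-Mead",
                options={
                    "maxfev": per_pass,
                    "xatol": config.xatol,
                    "fatol": config.fatol,
                    "adaptive": xb.size > 6,
                    "initial_simplex": simplex,
                },
            )
            success = bool(res.success)
        if config.kinetics_polish:
            # yield parameters (nu, alpha) converge essentially exactly;
            # the growth-kinetics subspace (mu, K, omega, Q0) is the
            # ill-conditioned part, so polish it alone with fresh simplexes
            kin_idx = [
                i for i, k in enumerate(stage.free_params)
                if k.split(".")[0] in ("mu", "K", "omega")
            ] + list(range(len(stage.free_params), x0.size))
            if kin_idx:
                kin_idx = np.array(kin_idx)

                def sub_obj(z, _full=objective, _best=best, _idx=kin_idx,
                            _trace=stage_trace):
                    x = _best["x"].copy()
                    x[_idx] = z
                    fv = _full(x)
                    if fv < _best["f"]:
                        _best["f"] = fv
                        _best["x"] = x
                    _trace.append(_best["f"])
                    return fv

                for step in steps:
                    z0 = best["x"][kin_idx]
                    simplex = np.vstack(
                        [z0] + [z0 + step * e for e in np.eye(z0.size)]
                    )
                    minimize(
                        sub_obj,
                        z0,
                        method="Nelder-Mead",
                        options={
                            "maxfev": per_pass,
                            "xatol": config.xatol,
                            "fatol": config.fatol,
                            "adaptive": z0.size > 6,
                            "initial_simplex": simplex,
                        },
                    )

        if best["f"] >= 1e6:
            raise FitError(f"stage {stage.name} diverged (objective {best['f']:g})")
        xbest = best["x"]
        values = 10.0 ** xbest
        params = params.updated(
            dict(zip(stage.free_params, values[: len(stage.free_params)]))
        )
        lo, hi = config.q0_bounds
        for (eid, strain), v in zip(q0_slots, values[len(stage.free_params):]):
            q0.setdefault(eid, {})[strain] = float(np.clip(v, lo, hi))
        trace.extend(stage_trace)
        stage_results.append(
            StageResult(stage.name, best["f"], len(stage_trace), success)
        )
        converged = converged and success

    # final per-experiment diagnostics under the combined parameters
    per_exp: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DataWarning)
        for stage in config.stages:
            for eid in stage.experiment_ids:
                if eid in per_exp:
                    continue
                exp = experiments[eid]
                traj = _simulate_experiment(params, exp, q0.get(eid, {}), config.solver)
                per_exp[eid] = normalized_rmse(traj, exp, pool=config.pool)

    if not trace:
        trace = [float(np.mean(list(per_exp.values())))]
    return FitResult(
        params=params,
        Q0=q0,
        per_experiment_rmse=per_exp,
        objective_trace=np.minimum.accumulate(np.asarray(trace, dtype=float)),
        converged=converged,
        stages=stage_results,
    )


def _strain_params(strain: Strain) -> list[str]:
    return [
        k
        for k in ModelParameters.flat_keys()
        if k.split(".")[1] == strain.value
    ]


def _select(experiments, predicate, label) -> list[str]:
    ids = [eid for eid, e in experiments.items() if predicate(e)]
    if not ids:
        raise ConfigurationError(f"no experiments available for {label}")
    return sorted(ids)


def parameterization1(
    experiments: dict[str, FermentationExperiment],
    init: ModelParameters,
    max_evaluations: int = 2000,
    **config_kwargs,
) -> FitResult:
    """Mono-culture-only protocol: each strain's full parameter set is
    fitted to its mono-culture experiments, lag variables jointly."""
    stages = []
    for strain in (Strain.RI, Strain.FP, Strain.BH):
        ids = _select(
            experiments,
            lambda e, s=strain: e.strains == (s,),
            f"{strain.value} monoculture",
        )
        stages.append(
            FitStage(
                name=f"{strain.value}_mono",
                experiment_ids=ids,
                free_params=_strain_params(strain),
            )
        )
    config = FitConfig(stages=stages, max_evaluations=max_evaluations, **config_kwargs)
    return fit_parameters(experiments, config, init)


PARAM2_STAGE_ORDER = ("FP_mono", "BH_yields", "BH_kinetics", "RI_full")


def parameterization2(
    experiments: dict[str, FermentationExperiment],
    init: ModelParameters,
    max_evaluations: int = 2000,
    stage_order: tuple[str, ...] = PARAM2_STAGE_ORDER,
    stage_budgets: dict[str, int] | None = None,
    **config_kwargs,
) -> FitResult:
    """Staged mono+bi-culture protocol.

    1. FP's parameters from FP mono-cultures;
    2. BH's yield parameters (nu, alpha) from FP/BH bi-cultures with
       initial acetate;
    3. BH's growth kinetics (mu, K, omega) from the same bi-cultures;
    4. RI's full parameter set from an RI/BH bi-culture with initial
       acetate.

    Earlier stages' parameters are frozen in later stages.  Running the
    stages in a different order is a protocol deviation: it is allowed
    but warned about.
    """
    fp_monos = _select(
        experiments, lambda e: e.strains == (Strain.FP,), "FP monoculture"
    )
    fp_bh = _select(
        experiments,
        lambda e: set(e.strains) == {Strain.FP, Strain.BH}
        and e.initial.get("acetate", 0.0) > 0,
        "FP/BH bi-culture with acetate",
    )
    ri_bh = _select(
        experiments,
        lambda e: set(e.strains) == {Strain.RI, Strain.BH}
        and e.initial.get("acetate", 0.0) > 0,
        "RI/BH bi-culture with acetate",
    )
    bh = Strain.BH
    stage_map = {
        "FP_mono": FitStage("FP_mono", fp_monos, _strain_params(Strain.FP)),
        "BH_yields": FitStage(
            "BH_yields",
            fp_bh,
            [f"nu.BH.{s}" for s in ("fructose", "formate")]
            + [f"alpha.BH.{s}" for s in ("acetate", "H2", "CO2")],
        ),
        "BH_kinetics": FitStage(
            "BH_kinetics",
            fp_bh,
            ["mu.BH", "K.BH.fructose", "K.BH.formate", "omega.BH"],
        ),
        "RI_full": FitStage("RI_full", ri_bh, _strain_params(Strain.RI)),
    }
    if set(stage_order) != set(PARAM2_STAGE_ORDER):
        raise ConfigurationError(
            f"stage_order must be a permutation of {PARAM2_STAGE_ORDER}"
        )
    if tuple(stage_order) != PARAM2_STAGE_ORDER:
        warnings.warn(
            "parameterization 2 stages permuted from the standard order: "
            "protocol deviation", UserWarning,
        )
    for name, budget in (stage_budgets or {}).items():
        stage_map[name].max_evaluations = budget
    config = FitConfig(
        stages=[stage_map[name] for name in stage_order],
        max_evaluations=max_evaluations,
        **config_kwargs,
    )
    return fit_parameters(experiments, config, init)


def predict_experiment(
    params: ModelParameters,
    exp: FermentationExperiment,
    Q0: dict[Strain, float] | None = None,
    solver: SolverConfig | None = None,
) -> Trajectory:
    """Forward-simulate an experiment's design under fixed parameters,
    without any refitting (validation contract for held-out cultures)."""
    return _simulate_experiment(params, exp, Q0 or {}, solver or FIT_SOLVER)


def exhaustive_replicate_selection(
    experiments: dict[str, FermentationExperiment],
    candidate_ids: list[str],
    runner,
    *runner_args,
    **runner_kwargs,
) -> tuple[tuple[str, ...], FitResult]:
    """Fit every non-empty subset of candidate biological replicates and
    return the subset with the best objective.

    Makes the usual trial-and-error choice of which replicate(s) to fit
    explicit and reproducible: ``runner`` (e.g. a protocol function or a
    ``fit_parameters`` closure) is called with the study restricted to
    each subset of ``candidate_ids`` (non-candidates always included).
    Exhaustive in the number of candidates — intended for the handful of
    biological replicates per culture type.
    """
    from itertools import combinations

    missing = [eid for eid in candidate_ids if eid not in experiments]
    if missing:
        raise ConfigurationError(f"candidate experiments not available: {missing}")
    rest = {k: v for k, v in experiments.items() if k not in candidate_ids}
    best: tuple[tuple[str, ...], FitResult] | None = None
    for r in range(1, len(candidate_ids) + 1):
        for subset in combinations(candidate_ids, r):
            study = dict(rest)
            study.update({eid: experiments[eid] for eid in subset})
            try:
                result = runner(study, *runner_args, **runner_kwargs)
            except (FitError, ConfigurationError):
                continue  # subset lacks an experiment some stage needs
            if best is None or result.objective < best[1].objective:
                best = (subset, result)
    if best is None:
        raise FitError("no candidate subset produced a successful fit")
    return best


def estimate_Q0(
    exp: FermentationExperiment,
    strain: Strain,
    mu: float,
    params: ModelParameters,
    other_Q0: dict[Strain, float] | None = None,
    bounds: tuple[float, float] = (1e-6, 10.0),
    n_grid: int = 61,
) -> float:
    """Estimate one strain's initial lag variable by 1-D grid search.

    All kinetic parameters are held fixed; the grid (log-spaced within
    ``bounds``) minimizes the normalized residuals of that strain's
    abundance.  Replaces the by-eye reading of log-scale growth plots
    with a reproducible procedure.
    """
    var = f"X_{strain.value}"
    if var not in exp.observations:
        raise FitError(f"{exp.id}: no abundance observations for {strain.value}")
    mean = exp.replicate_mean(var)
    mask = exp.included_mask(var) & np.isfinite(mean)
    if mask.sum() < 3:
        raise FitError(
            f"{exp.id}/{var}: need >= 3 included abundance points, "
            f"have {int(mask.sum())}"
        )
    if mu <= 0:
        raise ValueError("mu must be > 0")
    params = params.updated({f"mu.{strain.value}": mu})
    norm = float(np.max(mean[mask]))
    if norm == 0:
        raise FitError(f"{exp.id}/{var}: all-zero abundances")
    grid = np.logspace(math.log10(bounds[0]), math.log10(bounds[1]), n_grid)
    losses = np.empty(n_grid)
    for i, q in enumerate(grid):
        q0 = dict(other_Q0 or {})
        q0[strain] = float(q)
        traj = _simulate_experiment(params, exp, q0, FIT_SOLVER)
        model = np.interp(exp.times[mask], traj.t, traj[var])
        r = (model - mean[mask]) / norm
        losses[i] = np.sqrt(np.mean(r * r))
    best = int(np.argmin(losses))
    if best in (0, n_grid - 1):
        warnings.warn(
            f"{exp.id}/{var}: Q0 estimate at search bound {grid[best]:g}",
            UserWarning,
        )
    return float(grid[best])
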