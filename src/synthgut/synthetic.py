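"""Synthetic batch-fermentation data with the structure the fitting
pipeline expects.

Experiments are simulated under a fixed, documented "fixture" parameter
set and then corrupted the way the real measurements are: sampled on the
irregular fermentation grid (10 min, then 2-48 h), observed in technical
triplicates, with multiplicative log-normal noise on qPCR-style counts
and additive Gaussian noise on HPLC/GC-style concentrations, and with an
exponential decline tail appended to the counts after growth stops (the
model itself assumes negligible death, but real stationary-phase counts
decline, and the fitting pipeline must be able to exclude them).

Ground truth (parameters, lag variables, noiseless trajectory) is stored
on each experiment so parameter-recovery tests can compare against it.
The unknown co-factor is modeled but never emitted as an observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fit import FermentationExperiment
from .model import (
    OBSERVED_METABOLITES,
    ModelParameters,
    Strain,
    SystemState,
)
from .simulate import Q0_from_lag, SolverConfig, Trajectory, simulate

__all__ = [
    "FERMENTATION_SAMPLING_TIMES",
    "NoiseConfig",
    "ExperimentDesign",
    "fixture_params",
    "generate_experiment",
    "generate_study",
    "default_study_designs",
]

#: the standard fermentation sampling grid (h): 10 min, then 2-48 h
FERMENTATION_SAMPLING_TIMES = np.array(
    [1 / 6, 2, 3, 5, 6, 7, 9, 10, 11, 13, 14, 15, 17, 18, 24, 30, 48.0]
)

_TRUTH_SOLVER = SolverConfig()  # tight tolerances for ground truth


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise model for synthetic observations.

    ``abundance_cv``: coefficient of variation of the multiplicative
    log-normal noise on counts (default 10%, the order of the technical
    scatter of the qPCR triplicates).  ``metabolite_sd``: additive
    Gaussian noise on concentrations in mM (default 0.5 mM), floored at
    zero.  ``decline_rate``: exponential decay (1/h) applied to counts
    after growth stops, emulating stationary-phase decline.  ``seed``
    fixes all randomness.
    """

    abundance_cv: float = 0.10
    metabolite_sd: float = 0.5
    replicates: int = 3
    decline_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abundance_cv < 0 or self.metabolite_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one batch fermentation.

    ``lags`` are lag-phase durations in hours per strain (converted to
    initial lag variables through the strain's maximal growth rate).
    Substrate defaults follow the fermentation protocol: 50 mM fructose,
    co-substrates (acetate/formate) at 50 mM where added, the unknown
    co-factor at 30 mM.
    """

    id: str
    strains: tuple[Strain, ...]
    inoculum: dict[Strain, float]
    lags: dict[Strain, float] = field(default_factory=dict)
    fructose: float = 50.0
    acetate: float = 0.0
    formate: float = 0.0
    unknown: float = 30.0
    times: np.ndarray = field(
        default_factory=lambda: FERMENTATION_SAMPLING_TIMES.copy()
    )

    def initial_dict(self) -> dict:
        return {
            "X": {s: self.inoculum.get(s, 0.0) for s in self.strains},
            "fructose": self.fructose,
            "acetate": self.acetate,
            "formate": self.formate,
            "unknown": self.unknown,
        }

    def initial_state(self, params: ModelParameters) -> SystemState:
        Q = {
            s: Q0_from_lag(self.lags.get(s, 0.0), params.mu[s])
            for s in self.strains
        }
        X = {s: self.inoculum.get(s, 0.0) for s in self.strains}
        return SystemState.initial(
            X=X, Q=Q, fructose=self.fructose, acetate=self.acetate,
            formate=self.formate, unknown=self.unknown,
        )


def fixture_params() -> ModelParameters:
    """The fixed, versioned fixture parameter set.

    Magnitudes are chosen to be realistic for the system: maximal growth
    rates of 0.45-0.9 1/h, half-saturation constants of 8-40 mM (on the
    scale of the substrate pools, so each Monod factor traverses its
    curved range over a batch run and remains estimable from the data),
    and yields sized so that ~50 mM fructose supports a few 1e8
    counts/mL of biomass.  Under this set, RI and FP deplete 50 mM
    fructose in mono-culture within 48 h, BH consumes formate, and
    tri-culture dominance flips across the lag/initial-abundance scan
    grids.
    """
    RI, FP, BH = Strain.RI, Strain.FP, Strain.BH
    return ModelParameters(
        mu={RI: 0.55, FP: 0.90, BH: 0.45},
        # half-saturation constants on the scale of the substrate pools
        # (tens of mM), so the Monod factors traverse their curved range
        # over a batch run
        K={
            RI: {"fructose": 8.0, "acetate": 40.0},
            FP: {"unknown": 20.0, "fructose": 10.0, "acetate": 40.0},
            BH: {"fructose": 12.0, "formate": 20.0},
        },
        omega={RI: 2.0, FP: 1.5, BH: 0.8},
        nu={
            RI: {"fructose": 10.0, "acetate": 16.0},
            FP: {"fructose": 6.0, "acetate": 10.0, "unknown": 3.0},
            BH: {"fructose": 8.0, "formate": 15.0},
        },
        alpha={
            RI: {"formate": 5.0, "butyrate": 12.0, "H2": 15.0, "CO2": 17.0},
            FP: {"formate": 6.0, "butyrate": 8.0, "CO2": 5.0},
            BH: {"acetate": 15.0, "H2": 12.0, "CO2": 10.0},
        },
    )


def _decline_onsets(
    traj: Trajectory, strains: tuple[Strain, ...]
) -> dict[Strain, float]:
    """Time growth effectively stops per strain: first time the abundance
    reaches 99.9% of its final (plateau) value."""
    onsets = {}
    for s in strains:
        x = traj[f"X_{s.value}"]
        final = x[-1]
        if final <= 0 or final < 1.001 * x[0]:
            onsets[s] = float(traj.t[-1])  # never grew: no decline
            continue
        idx = int(np.argmax(x >= 0.999 * final))
        onsets[s] = float(traj.t[idx])
    return onsets


def generate_experiment(
    params: ModelParameters,
    design: ExperimentDesign,
    noise: NoiseConfig = NoiseConfig(),
) -> FermentationExperiment:
    """Simulate a design under ``params`` and corrupt it into observations.

    Counts receive the decline tail, then per-replicate log-normal noise;
    concentrations receive additive Gaussian noise floored at zero.  The
    noiseless truth (parameters, lag variables, trajectory) travels with
    the experiment.
    """
    rng = np.random.default_rng(noise.seed)
    grid = np.unique(
        np.concatenate(([0.0], np.linspace(0.0, design.times[-1], 193), design.times))
    )
    traj = simulate(params, design.initial_state(params), grid, _TRUTH_SOLVER)
    onsets = _decline_onsets(traj, design.strains)

    observations: dict[str, np.ndarray] = {}
    t = design.times
    for s in design.strains:
        truth = np.interp(t, traj.t, traj[f"X_{s.value}"])
        tail = np.exp(-noise.decline_rate * np.maximum(t - onsets[s], 0.0))
        signal = truth * tail
        if noise.abundance_cv > 0:
            sigma = math.sqrt(math.log(1.0 + noise.abundance_cv**2))
            factors = rng.lognormal(
                -0.5 * sigma**2, sigma, size=(t.size, noise.replicates)
            )
        else:
            factors = np.ones((t.size, noise.replicates))
        observations[f"X_{s.value}"] = signal[:, None] * factors
    for m in OBSERVED_METABOLITES:
        truth = np.interp(t, traj.t, traj[f"S_{m.value}"])
        eps = (
            rng.normal(0.0, noise.metabolite_sd, size=(t.size, noise.replicates))
            if noise.metabolite_sd > 0
            else np.zeros((t.size, noise.replicates))
        )
        observations[f"S_{m.value}"] = np.maximum(truth[:, None] + eps, 0.0)

    truth_Q0 = {
        s: Q0_from_lag(design.lags.get(s, 0.0), params.mu[s])
        for s in design.strains
    }
    return FermentationExperiment(
        id=design.id,
        strains=design.strains,
        times=t,
        observations=observations,
        initial=design.initial_dict(),
        truth={
            "params": params.copy(),
            "Q0": truth_Q0,
            "trajectory": traj,
            "design": design,
            "decline_onsets": onsets,
        },
    )


def default_study_designs() -> list[ExperimentDesign]:
    """The full mono/bi/tri design matrix.

    Mono-cultures of each strain (RI and FP with 50 mM initial acetate,
    BH with 50 mM initial formate), the five bi-culture designs (RI/FP
    with acetate; RI/BH and FP/BH each with and without acetate) and six
    tri-cultures with varied inoculum proportions spanning the RI/FP
    dominance boundary, so both outcomes occur under the fixture truth.
    """
    RI, FP, BH = Strain.RI, Strain.FP, Strain.BH
    lags = {RI: 0.33, FP: 0.08, BH: 0.1}
    d: list[ExperimentDesign] = []

    def mono(eid, s, inoc, **kw):
        d.append(ExperimentDesign(eid, (s,), {s: inoc}, lags={s: lags[s]}, **kw))

    # inocula deliberately span an order of magnitude across biological
    # replicates: replicates with different starting abundances trace
    # different substrate-vs-biomass paths, which is what makes the
    # kinetic constants identifiable from batch data
    mono("RI_8", RI, 0.04, acetate=50.0)
    mono("RI_14", RI, 0.40, acetate=50.0)
    mono("FP_4", FP, 0.04, acetate=50.0)
    mono("FP_15", FP, 0.40, acetate=50.0)
    mono("BH_14", BH, 0.10, formate=50.0)

    def bi(eid, s1, s2, x1, x2, **kw):
        d.append(
            ExperimentDesign(
                eid, (s1, s2), {s1: x1, s2: x2},
                lags={s1: lags[s1], s2: lags[s2]}, **kw,
            )
        )

    bi("RI_FP_1", RI, FP, 0.10, 0.05, acetate=50.0)
    bi("RI_FP_2", RI, FP, 0.12, 0.06, acetate=50.0)
    bi("RI_BH_4", RI, BH, 0.05, 0.20, acetate=50.0)
    bi("RI_BH_5", RI, BH, 0.40, 0.05, acetate=50.0)
    bi("RI_BH_6", RI, BH, 0.10, 0.10)  # no initial acetate
    bi("FP_BH_1", FP, BH, 0.04, 0.20, acetate=50.0)
    bi("FP_BH_2", FP, BH, 0.40, 0.05, acetate=50.0)
    bi("FP_BH_3", FP, BH, 0.05, 0.10)  # no initial acetate

    # tri-cultures: inoculum proportions straddle the dominance boundary
    tri_inocula = [
        (0.60, 0.01, 0.20),  # strongly RI-favored
        (0.58, 0.04, 0.21),  # the average tri-culture inoculum
        (0.30, 0.10, 0.20),
        (0.10, 0.10, 0.20),
        (0.05, 0.20, 0.20),  # FP-favored
        (0.02, 0.30, 0.20),
    ]
    for k, (x_ri, x_fp, x_bh) in enumerate(tri_inocula, start=1):
        d.append(
            ExperimentDesign(
                f"TRI_{k}", (RI, FP, BH),
                {RI: x_ri, FP: x_fp, BH: x_bh}, lags=dict(lags),
            )
        )
    return d


def generate_study(
    params: ModelParameters | None = None,
    noise: NoiseConfig = NoiseConfig(),
    designs: list[ExperimentDesign] | None = None,
) -> dict[str, FermentationExperiment]:
    """Generate the full study.  Per-experiment seeds are derived from
    ``noise.seed`` so the whole collection is reproducible."""
    params = params or fixture_params()
    designs = designs if designs is not None else default_study_designs()
    study: dict[str, FermentationExperiment] = {}
    for k, design in enumerate(designs):
        exp_noise = replace(noise, seed=(noise.seed * 10007 + k) % (2**31 - 1))
        study[design.id] = generate_experiment(params, design, exp_noise)
    return study
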