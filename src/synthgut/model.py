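"""Kinetic model of the three-strain synthetic gut community.

The community consists of two butyrate producers, *Roseburia intestinalis*
L1-82 (RI) and *Faecalibacterium prausnitzii* A2-165 (FP), and the
acetogen *Blautia hydrogenotrophica* S5a33 (BH), grown in batch on
fructose.  Growth follows Monod kinetics with a lag phase.  Substrates are
either obligatory (a multiplicative Monod factor: no growth without them)
or facultative (an additive or multiplicative ``1 + omega * Monod`` term:
growth is enhanced but possible without them):

* RI grows on fructose (obligatory), stimulated by acetate (facultative).
* FP requires both an unidentified medium co-factor ("unknown compound")
  and fructose, and is likewise stimulated by acetate.
* BH grows on fructose and formate additively; formate carries the
  facultative weight ``omega_BH``, so BH grows on formate alone.

Cross-feeding: RI and FP excrete formate (consumed by BH) and consume
acetate (excreted by BH); both excrete butyrate.  Hydrogen and carbon
dioxide are tracked as cumulative amounts in mM of the liquid volume;
gas consumption by BH is not part of the model.

Units: abundances X_i in 1e8 counts/mL, concentrations S in mM, ``mu`` in
1/h, ``K`` in mM, yields ``nu``/``alpha`` in mM per (1e8 counts/mL),
``omega`` dimensionless.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "Strain",
    "Metabolite",
    "MODEL_METABOLITES",
    "OBSERVED_METABOLITES",
    "ModelParameters",
    "SystemState",
    "LagSpec",
    "ConfigurationError",
    "lag_weight",
    "growth_rate",
    "acetate_uptake_rate",
    "bh_partial_rates",
    "ode_rhs",
    "make_rhs",
    "STATE_NAMES",
]


class ConfigurationError(ValueError):
    """A parameter document is incomplete or contains unknown keys."""


class Strain(str, enum.Enum):
    """The three community members (closed enumeration)."""

    RI = "RI"  # R. intestinalis L1-82
    FP = "FP"  # F. prausnitzii A2-165
    BH = "BH"  # B. hydrogenotrophica S5a33

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Metabolite(str, enum.Enum):
    """Metabolites with an explicit rate equation, plus measured-only ones."""

    fructose = "fructose"
    formate = "formate"
    acetate = "acetate"
    butyrate = "butyrate"
    unknown = "unknown"
    H2 = "H2"
    CO2 = "CO2"
    # measured in the observation layer, not modeled
    lactate = "lactate"
    ethanol = "ethanol"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: the seven metabolites with a dS/dt equation
MODEL_METABOLITES = (
    Metabolite.fructose,
    Metabolite.formate,
    Metabolite.acetate,
    Metabolite.butyrate,
    Metabolite.unknown,
    Metabolite.H2,
    Metabolite.CO2,
)

#: modeled metabolites that are observable (the unknown compound is not)
OBSERVED_METABOLITES = tuple(
    m for m in MODEL_METABOLITES if m is not Metabolite.unknown
)

# which substrates enter each strain's Monod terms (K), which are consumed
# (nu) and which are produced (alpha)
K_SUBSTRATES = {
    Strain.RI: ("fructose", "acetate"),
    Strain.FP: ("unknown", "fructose", "acetate"),
    Strain.BH: ("fructose", "formate"),
}
NU_SUBSTRATES = {
    Strain.RI: ("fructose", "acetate"),
    Strain.FP: ("fructose", "acetate", "unknown"),
    Strain.BH: ("fructose", "formate"),
}
ALPHA_PRODUCTS = {
    Strain.RI: ("formate", "butyrate", "H2", "CO2"),
    Strain.FP: ("formate", "butyrate", "CO2"),
    Strain.BH: ("acetate", "H2", "CO2"),
}


@dataclass
class ModelParameters:
    """All kinetic constants of the community model.

    ``mu[strain]`` (1/h), ``K[strain][substrate]`` (mM), ``omega[strain]``
    (dimensionless facultative-substrate weight), ``nu[strain][metabolite]``
    and ``alpha[strain][metabolite]`` (mM per 1e8 counts/mL) for consumed
    and produced metabolites respectively.
    """

    mu: dict[Strain, float]
    K: dict[Strain, dict[str, float]]
    omega: dict[Strain, float]
    nu: dict[Strain, dict[str, float]]
    alpha: dict[Strain, dict[str, float]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check completeness, positivity and schema of the parameter set."""
        for strain in Strain:
            for table, name in ((self.mu, "mu"), (self.omega, "omega")):
                if strain not in table:
                    raise ConfigurationError(f"missing {name}.{strain.value}")
                if table[strain] < 0:
                    raise ConfigurationError(
                        f"{name}.{strain.value} must be >= 0"
                    )
            for expected, table, name in (
                (K_SUBSTRATES, self.K, "K"),
                (NU_SUBSTRATES, self.nu, "nu"),
                (ALPHA_PRODUCTS, self.alpha, "alpha"),
            ):
                got = table.get(strain)
                if got is None:
                    raise ConfigurationError(f"missing {name}.{strain.value}")
                if set(got) != set(expected[strain]):
                    raise ConfigurationError(
                        f"{name}.{strain.value} keys must be exactly "
                        f"{sorted(expected[strain])}, got {sorted(got)}"
                    )
                for sub, value in got.items():
                    if name == "K":
                        if value <= 0:
                            raise ConfigurationError(
                                f"K.{strain.value}.{sub} must be > 0"
                            )
                    elif value < 0:
                        raise ConfigurationError(
                            f"{name}.{strain.value}.{sub} must be >= 0"
                        )

    # -- flat key/value serialization (``mu.RI``, ``K.RI.fructose``, ...) --

    def to_flat(self) -> dict[str, float]:
        flat: dict[str, float] = {}
        for strain in Strain:
            flat[f"mu.{strain.value}"] = float(self.mu[strain])
            flat[f"omega.{strain.value}"] = float(self.omega[strain])
            for sub in K_SUBSTRATES[strain]:
                flat[f"K.{strain.value}.{sub}"] = float(self.K[strain][sub])
            for sub in NU_SUBSTRATES[strain]:
                flat[f"nu.{strain.value}.{sub}"] = float(self.nu[strain][sub])
            for sub in ALPHA_PRODUCTS[strain]:
                flat[f"alpha.{strain.value}.{sub}"] = float(
                    self.alpha[strain][sub]
                )
        return flat

    @classmethod
    def from_flat(cls, flat: dict[str, float]) -> "ModelParameters":
        """Build from a flat key/value document; unknown keys are rejected."""
        expected = set(cls.flat_keys())
        unknown = set(flat) - expected
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        missing = expected - set(flat)
        if missing:
            raise ConfigurationError(f"missing parameter keys: {sorted(missing)}")
        mu = {s: float(flat[f"mu.{s.value}"]) for s in Strain}
        omega = {s: float(flat[f"omega.{s.value}"]) for s in Strain}
        K = {
            s: {sub: float(flat[f"K.{s.value}.{sub}"]) for sub in K_SUBSTRATES[s]}
            for s in Strain
        }
        nu = {
            s: {sub: float(flat[f"nu.{s.value}.{sub}"]) for sub in NU_SUBSTRATES[s]}
            for s in Strain
        }
        alpha = {
            s: {sub: float(flat[f"alpha.{s.value}.{sub}"]) for sub in ALPHA_PRODUCTS[s]}
            for s in Strain
        }
        return cls(mu=mu, K=K, omega=omega, nu=nu, alpha=alpha)

    @classmethod
    def flat_keys(cls) -> list[str]:
        keys = []
        for s in Strain:
            keys.append(f"mu.{s.value}")
            keys.append(f"omega.{s.value}")
            keys.extend(f"K.{s.value}.{sub}" for sub in K_SUBSTRATES[s])
            keys.extend(f"nu.{s.value}.{sub}" for sub in NU_SUBSTRATES[s])
            keys.extend(f"alpha.{s.value}.{sub}" for sub in ALPHA_PRODUCTS[s])
        return keys

    def updated(self, flat_updates: dict[str, float]) -> "ModelParameters":
        """Return a copy with the given flat keys replaced."""
        flat = self.to_flat()
        for key, value in flat_updates.items():
            if key not in flat:
                raise ConfigurationError(f"unknown parameter key: {key}")
            flat[key] = float(value)
        return ModelParameters.from_flat(flat)

    def get_flat(self, key: str) -> float:
        flat = self.to_flat()
        if key not in flat:
            raise ConfigurationError(f"unknown parameter key: {key}")
        return flat[key]

    def copy(self) -> "ModelParameters":
        return ModelParameters.from_flat(self.to_flat())

    def save(self, path) -> None:
        """Write the flat document as YAML (JSON-compatible)."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ModelParameters":
        with open(path) as fh:
            text = fh.read()
        try:
            flat = json.loads(text)
        except json.JSONDecodeError:
            flat = yaml.safe_load(text)
        if not isinstance(flat, dict):
            raise ConfigurationError(f"{path} is not a flat parameter mapping")
        return cls.from_flat(flat)


#: canonical ordering of the 13 state variables
STATE_NAMES = (
    "X_RI",
    "X_FP",
    "X_BH",
    "Q_RI",
    "Q_FP",
    "Q_BH",
    "S_fructose",
    "S_formate",
    "S_acetate",
    "S_butyrate",
    "S_unknown",
    "S_H2",
    "S_CO2",
)


@dataclass
class SystemState:
    """State of the bioreactor at one time point.

    X_i in 1e8 counts/mL, Q_i dimensionless lag variables, S in mM.
    """

    X: dict[Strain, float]
    Q: dict[Strain, float]
    S: dict[str, float]
    t: float = 0.0

    def __post_init__(self) -> None:
        for s in Strain:
            if self.X.get(s, 0.0) < 0:
                raise ValueError(f"X_{s.value} must be >= 0")
            if self.Q.get(s, 1.0) <= 0:
                raise ValueError(f"Q_{s.value} must be > 0")
        for m in MODEL_METABOLITES:
            if self.S.get(m.value, 0.0) < 0:
                raise ValueError(f"S_{m.value} must be >= 0")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.X[Strain.RI], self.X[Strain.FP], self.X[Strain.BH],
             self.Q[Strain.RI], self.Q[Strain.FP], self.Q[Strain.BH]]
            + [self.S[m.value] for m in MODEL_METABOLITES],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, y: np.ndarray, t: float = 0.0) -> "SystemState":
        y = np.asarray(y, dtype=float)
        X = {Strain.RI: y[0], Strain.FP: y[1], Strain.BH: y[2]}
        Q = {Strain.RI: y[3], Strain.FP: y[4], Strain.BH: y[5]}
        S = {m.value: y[6 + i] for i, m in enumerate(MODEL_METABOLITES)}
        return cls(X=X, Q=Q, S=S, t=t)

    @classmethod
    def initial(
        cls,
        X: dict[Strain, float] | None = None,
        Q: dict[Strain, float] | None = None,
        fructose: float = 50.0,
        acetate: float = 0.0,
        formate: float = 0.0,
        unknown: float = 30.0,
    ) -> "SystemState":
        """Convenience constructor for a batch initial condition.

        Defaults match the fermentation design: 50 mM fructose as the
        energy source, the unknown co-factor initialized at 30 mM, no
        fermentation products at t=0.
        """
        X = {s: float((X or {}).get(s, 0.0)) for s in Strain}
        Q = {s: float((Q or {}).get(s, 1.0)) for s in Strain}
        S = {
            "fructose": float(fructose),
            "formate": float(formate),
            "acetate": float(acetate),
            "butyrate": 0.0,
            "unknown": float(unknown),
            "H2": 0.0,
            "CO2": 0.0,
        }
        return cls(X=X, Q=Q, S=S, t=0.0)


@dataclass(frozen=True)
class LagSpec:
    """Lag phase of one strain, as either Q(0) or a lag duration in hours.

    The two are interconvertible given the strain's maximal growth rate:
    lag = -ln(Q0)/mu, the time at which Gamma(Q) reaches 1/2.
    """

    Q0: float | None = None
    lag_h: float | None = None

    def __post_init__(self) -> None:
        if (self.Q0 is None) == (self.lag_h is None):
            raise ValueError("specify exactly one of Q0 or lag_h")
        if self.Q0 is not None and self.Q0 <= 0:
            raise ValueError("Q0 must be > 0")

    def q0(self, mu: float) -> float:
        if self.Q0 is not None:
            return self.Q0
        if mu <= 0:
            raise ValueError("mu must be > 0 to convert a lag duration")
        return math.exp(-mu * self.lag_h)

    def lag(self, mu: float) -> float:
        if self.lag_h is not None:
            return self.lag_h
        if mu <= 0:
            raise ValueError("mu must be > 0 to convert Q0")
        return -math.log(self.Q0) / mu


def lag_weight(Q: float) -> float:
    """Lag-phase weighting Gamma(Q) = Q/(1+Q), in [0, 1).

    Q grows exponentially from Q(0), so Gamma ramps from near 0 (deep lag)
    to near 1 (lag over); Gamma = 1/2 at Q = 1 defines the lag duration.
    """
    if Q < 0:
        raise ValueError("Q must be >= 0")
    return Q / (1.0 + Q)


def _monod(S: float, K: float) -> float:
    # max(S, 0): adaptive solvers may step slightly below zero
    S = max(S, 0.0)
    return S / (K + S)


def growth_rate(strain: Strain, state: SystemState, params: ModelParameters) -> float:
    """Specific growth rate Phi_i (1/h) of one strain at a given state.

    RI: Gamma*mu * Monod(fructose) * (1 + omega*Monod(acetate))
    FP: Gamma*mu * Monod(unknown) * Monod(fructose) * (1 + omega*Monod(acetate))
    BH: Gamma*mu * (Monod(fructose) + omega*Monod(formate))
    """
    g = lag_weight(state.Q[strain]) * params.mu[strain]
    K = params.K[strain]
    S = state.S
    if strain is Strain.RI:
        return (
            g
            * _monod(S["fructose"], K["fructose"])
            * (1.0 + params.omega[strain] * _monod(S["acetate"], K["acetate"]))
        )
    if strain is Strain.FP:
        return (
            g
            * _monod(S["unknown"], K["unknown"])
            * _monod(S["fructose"], K["fructose"])
            * (1.0 + params.omega[strain] * _monod(S["acetate"], K["acetate"]))
        )
    # BH: additive; formate is the weighted facultative term
    return g * (
        _monod(S["fructose"], K["fructose"])
        + params.omega[strain] * _monod(S["formate"], K["formate"])
    )


def acetate_uptake_rate(
    strain: Strain, state: SystemState, params: ModelParameters
) -> float:
    """Auxiliary rate Phi_{i,acetate} (1/h) driving acetate consumption.

    Defined for RI and FP only: the product of the lag weight, mu, the
    facultative weight omega, the strain's obligatory Monod factor(s) and
    the acetate Monod factor.
    """
    if strain is Strain.BH:
        raise ValueError("acetate uptake rate is defined for RI and FP only")
    g = lag_weight(state.Q[strain]) * params.mu[strain] * params.omega[strain]
    K = params.K[strain]
    S = state.S
    rate = g * _monod(S["fructose"], K["fructose"]) * _monod(S["acetate"], K["acetate"])
    if strain is Strain.FP:
        rate *= _monod(S["unknown"], K["unknown"])
    return rate


def bh_partial_rates(
    state: SystemState, params: ModelParameters
) -> tuple[float, float]:
    """BH's growth rate split into its fructose and formate components.

    Phi_BH,fructose = Gamma*mu*Monod(fructose);
    Phi_BH,formate = Gamma*mu*omega*Monod(formate).
    Their sum equals ``growth_rate(BH, ...)``.
    """
    g = lag_weight(state.Q[Strain.BH]) * params.mu[Strain.BH]
    K = params.K[Strain.BH]
    S = state.S
    return (
        g * _monod(S["fructose"], K["fructose"]),
        g * params.omega[Strain.BH] * _monod(S["formate"], K["formate"]),
    )


#: fixed packing order of the 23 kinetic constants for the compiled kernel
_PARAM_ORDER = (
    "mu.RI", "mu.FP", "mu.BH",
    "omega.RI", "omega.FP", "omega.BH",
    "K.RI.fructose", "K.RI.acetate",
    "K.FP.unknown", "K.FP.fructose", "K.FP.acetate",
    "K.BH.fructose", "K.BH.formate",
    "nu.RI.fructose", "nu.RI.acetate",
    "nu.FP.fructose", "nu.FP.acetate", "nu.FP.unknown",
    "nu.BH.fructose", "nu.BH.formate",
    "alpha.RI.formate", "alpha.RI.butyrate", "alpha.RI.H2", "alpha.RI.CO2",
    "alpha.FP.formate", "alpha.FP.butyrate", "alpha.FP.CO2",
    "alpha.BH.acetate", "alpha.BH.H2", "alpha.BH.CO2",
)


def params_to_array(params: ModelParameters) -> np.ndarray:
    flat = params.to_flat()
    return np.array([flat[k] for k in _PARAM_ORDER])


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap


@_njit(cache=True)
def _rhs_kernel(t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:  # pragma: no cover - exercised via ode_rhs
    (mu_ri, mu_fp, mu_bh, om_ri, om_fp, om_bh,
     k_ri_f, k_ri_a, k_fp_u, k_fp_f, k_fp_a, k_bh_f, k_bh_o,
     nu_ri_f, nu_ri_a, nu_fp_f, nu_fp_a, nu_fp_u, nu_bh_f, nu_bh_o,
     al_ri_o, al_ri_b, al_ri_h, al_ri_c,
     al_fp_o, al_fp_b, al_fp_c,
     al_bh_a, al_bh_h, al_bh_c) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
        p[11], p[12], p[13], p[14], p[15], p[16], p[17], p[18], p[19],
        p[20], p[21], p[22], p[23], p[24], p[25], p[26], p[27], p[28], p[29],
    )
    x_ri, x_fp, x_bh = y[0], y[1], y[2]
    q_ri, q_fp, q_bh = y[3], y[4], y[5]
    # max(S, 0): adaptive solvers may step slightly below zero
    s_fru = y[6] if y[6] > 0.0 else 0.0
    s_for = y[7] if y[7] > 0.0 else 0.0
    s_ace = y[8] if y[8] > 0.0 else 0.0
    s_unk = y[10] if y[10] > 0.0 else 0.0

    g_ri = (q_ri / (1.0 + q_ri)) * mu_ri if q_ri > 0 else 0.0
    g_fp = (q_fp / (1.0 + q_fp)) * mu_fp if q_fp > 0 else 0.0
    g_bh = (q_bh / (1.0 + q_bh)) * mu_bh if q_bh > 0 else 0.0

    m_ri_f = s_fru / (k_ri_f + s_fru)
    m_ri_a = s_ace / (k_ri_a + s_ace)
    m_fp_u = s_unk / (k_fp_u + s_unk)
    m_fp_f = s_fru / (k_fp_f + s_fru)
    m_fp_a = s_ace / (k_fp_a + s_ace)
    m_bh_f = s_fru / (k_bh_f + s_fru)
    m_bh_o = s_for / (k_bh_o + s_for)

    phi_ri = g_ri * m_ri_f * (1.0 + om_ri * m_ri_a)
    phi_fp = g_fp * m_fp_u * m_fp_f * (1.0 + om_fp * m_fp_a)
    phi_bh_f = g_bh * m_bh_f
    phi_bh_o = g_bh * om_bh * m_bh_o
    phi_bh = phi_bh_f + phi_bh_o

    phi_ri_a = g_ri * om_ri * m_ri_f * m_ri_a
    phi_fp_a = g_fp * om_fp * m_fp_u * m_fp_f * m_fp_a

    t_ri = phi_ri * x_ri
    t_fp = phi_fp * x_fp
    t_bh = phi_bh * x_bh

    dy = np.empty(13)
    dy[0] = t_ri
    dy[1] = t_fp
    dy[2] = t_bh
    dy[3] = mu_ri * q_ri
    dy[4] = mu_fp * q_fp
    dy[5] = mu_bh * q_bh
    # fructose: consumed by all three; BH via its fructose partial rate
    dy[6] = -nu_ri_f * t_ri - nu_fp_f * t_fp - nu_bh_f * phi_bh_f * x_bh
    # formate: produced by RI/FP, consumed by BH via its formate partial rate
    dy[7] = al_ri_o * t_ri + al_fp_o * t_fp - nu_bh_o * phi_bh_o * x_bh
    # acetate: RI/FP uptake via the auxiliary rates, produced by BH
    dy[8] = (
        -nu_ri_a * phi_ri_a * x_ri - nu_fp_a * phi_fp_a * x_fp + al_bh_a * t_bh
    )
    dy[9] = al_ri_b * t_ri + al_fp_b * t_fp
    dy[10] = -nu_fp_u * t_fp
    dy[11] = al_ri_h * t_ri + al_bh_h * t_bh
    dy[12] = al_ri_c * t_ri + al_fp_c * t_fp + al_bh_c * t_bh
    return dy


def make_rhs(params: ModelParameters):
    """Bind a parameter set into a fast ODE right-hand-side callable.

    The kinetic constants are packed into a flat array once and the
    arithmetic runs in a compiled kernel; the returned function has the
    ``solve_ivp`` signature ``f(t, y) -> dy``.
    """
    p = params_to_array(params)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return _rhs_kernel(t, y, p)

    return rhs


def ode_rhs(t: float, y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Right-hand side of the 13-variable community ODE system.

    State ordering is :data:`STATE_NAMES`.  Negative concentrations that
    an adaptive solver steps into are clipped to zero inside the Monod
    terms; the function never raises during integration.  For repeated
    evaluation under fixed parameters prefer :func:`make_rhs`.
    """
    return make_rhs(params)(t, y)
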