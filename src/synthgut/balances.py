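"""Fermentation mass balances: net metabolite deltas, carbon recovery
and the oxidation/reduction (O/R) balance.

The balances use the classical fermentation-balance conventions: carbon
recovery is the percentage of carbon atoms in consumed substrates that is
accounted for by measured products, and the O/R balance compares
oxidized-product equivalents (CO2, formate) with reduced-product
equivalents (butyrate, H2, ethanol); a ratio near 1 indicates redox
closure.  Biomass carbon and the unobservable co-factor are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StoichiometryTables",
    "BalanceReport",
    "BalanceError",
    "net_deltas",
    "carbon_recovery",
    "or_balance",
    "balance_report",
]


class BalanceError(ValueError):
    """A balance is undefined for the given deltas (e.g. nothing consumed)."""


@dataclass(frozen=True)
class StoichiometryTables:
    """Carbon atoms per molecule and O/R values per molecule.

    O/R values follow the classical "available hydrogen" bookkeeping:
    fully oxidized carbon (CO2) counts +2, formate +1; transfer-neutral
    compounds (acetate, lactate, fructose per hexose unit) count 0;
    reduced products count negative (butyrate -2, ethanol -2, H2 -1).
    """

    carbon: dict[str, int] = field(
        default_factory=lambda: {
            "fructose": 6,
            "butyrate": 4,
            "lactate": 3,
            "acetate": 2,
            "ethanol": 2,
            "formate": 1,
            "CO2": 1,
            "H2": 0,
        }
    )
    redox: dict[str, int] = field(
        default_factory=lambda: {
            "CO2": 2,
            "formate": 1,
            "acetate": 0,
            "lactate": 0,
            "fructose": 0,
            "butyrate": -2,
            "ethanol": -2,
            "H2": -1,
        }
    )

    def check_covers(self, metabolites) -> None:
        missing = [m for m in metabolites if m not in self.carbon or m not in self.redox]
        if missing:
            raise BalanceError(f"no stoichiometry entries for: {missing}")


DEFAULT_TABLES = StoichiometryTables()


@dataclass
class BalanceReport:
    """Net deltas (mM; consumption negative), carbon recovery (%) and
    O/R balance for one experiment."""

    deltas: dict[str, float]
    carbon_recovery: float
    or_balance: float | None
    tables: StoichiometryTables = field(default_factory=StoichiometryTables)


def net_deltas(exp) -> dict[str, float]:
    """Net concentration change per metabolite: final minus first sample,
    averaged over technical replicates.  Consumption is negative,
    production positive.  Transients (produced then re-consumed) cancel.
    """
    deltas: dict[str, float] = {}
    for var in exp.metabolite_variables():
        series = exp.replicate_mean(var)
        finite = np.flatnonzero(np.isfinite(series))
        if finite.size < 2:
            warnings.warn(f"{var}: fewer than 2 samples, omitted from deltas")
            continue
        name = var[2:] if var.startswith("S_") else var
        deltas[name] = float(series[finite[-1]] - series[finite[0]])
    return deltas


def carbon_recovery(
    deltas: dict[str, float], tables: StoichiometryTables = DEFAULT_TABLES
) -> float:
    """Carbon recovery in percent.

    100 x (carbon in net-produced metabolites) / (carbon in net-consumed
    metabolites).  Biomass and the unknown co-factor are excluded.
    """
    tables.check_covers(deltas)
    consumed = sum(-d * tables.carbon[m] for m, d in deltas.items() if d < 0)
    produced = sum(d * tables.carbon[m] for m, d in deltas.items() if d > 0)
    if consumed <= 0:
        raise BalanceError("carbon recovery undefined: no consumed carbon")
    return 100.0 * produced / consumed


def or_balance(
    deltas: dict[str, float], tables: StoichiometryTables = DEFAULT_TABLES
) -> float:
    """O/R balance: oxidized equivalents over reduced equivalents.

    Oxidized sum: net CO2 x 2 plus net formate x 1 (consumed formate
    enters negatively).  Reduced sum: produced butyrate x 2, H2 x 1,
    ethanol x 2.  Undefined (raises) when the reduced sum is zero.
    """
    tables.check_covers(deltas)
    oxidized = sum(
        d * tables.redox[m] for m, d in deltas.items() if tables.redox[m] > 0
    )
    reduced = sum(
        d * -tables.redox[m]
        for m, d in deltas.items()
        if tables.redox[m] < 0 and d > 0
    )
    if reduced <= 0:
        raise BalanceError("O/R balance undefined: no reduced equivalents")
    return oxidized / reduced


def balance_report(
    exp, tables: StoichiometryTables = DEFAULT_TABLES
) -> BalanceReport:
    """Full balance report for one fermentation experiment."""
    deltas = net_deltas(exp)
    recovery = carbon_recovery(deltas, tables)
    try:
        ratio = or_balance(deltas, tables)
    except BalanceError:
        ratio = None
    return BalanceReport(
        deltas=deltas, carbon_recovery=recovery, or_balance=ratio, tables=tables
    )
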