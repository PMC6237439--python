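"""Tidy-table and configuration I/O shared by all pipeline stages.

Observations travel as a comma-separated table with columns
``experiment_id, time_h, variable, replicate, value[, excluded]`` plus a
small YAML manifest per study describing each experiment's strains and
initial design.  Model parameters travel as a flat key/value YAML/JSON
document (``mu.RI``, ``K.RI.fructose``, ...) with strict schema
validation.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fit import FermentationExperiment
from .model import Strain

__all__ = [
    "VALID_VARIABLES",
    "ObservationTableError",
    "write_observations",
    "read_observations",
    "write_manifest",
    "read_manifest",
    "RunManifest",
    "write_run_manifest",
]

#: variables admitted in an observation table (lactate is measured but
#: not modeled; the unknown co-factor is modeled but never observed)
VALID_VARIABLES = (
    "X_RI", "X_FP", "X_BH",
    "S_fructose", "S_formate", "S_acetate", "S_butyrate", "S_lactate",
    "S_H2", "S_CO2",
)

_COLUMNS = ["experiment_id", "time_h", "variable", "replicate", "value"]


class ObservationTableError(ValueError):
    """An observation table violates the schema."""


def write_observations(
    experiments: dict[str, FermentationExperiment], path
) -> None:
    """Write a study as one tidy CSV (RFC-4180, UTF-8, decimal point)."""
    rows = []
    for eid in sorted(experiments):
        exp = experiments[eid]
        for var in sorted(exp.observations):
            obs = exp.observations[var]
            excl = exp.excluded.get(var)
            for i, t in enumerate(exp.times):
                for r in range(obs.shape[1]):
                    v = obs[i, r]
                    if not np.isfinite(v):
                        continue
                    rows.append(
                        {
                            "experiment_id": eid,
                            "time_h": t,
                            "variable": var,
                            "replicate": r + 1,
                            "value": v,
                            "excluded": bool(excl[i]) if excl is not None else False,
                        }
                    )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_observations(path, manifest: dict | None = None) -> dict[str, FermentationExperiment]:
    """Read a tidy observation table back into experiments.

    ``manifest`` (see :func:`read_manifest`) supplies each experiment's
    strain membership and initial design; without it, strains are
    inferred from the abundance variables present and the initial design
    defaults to the standard 50 mM fructose batch.  Schema violations
    are reported with the offending row number and column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ObservationTableError(f"missing required columns: {missing}")
    bad_var = df[~df["variable"].isin(VALID_VARIABLES)]
    if len(bad_var):
        row = bad_var.index[0] + 2  # header is line 1
        raise ObservationTableError(
            f"row {row}: unknown variable {bad_var['variable'].iloc[0]!r}; "
            f"valid names: {', '.join(VALID_VARIABLES)}"
        )
    for col, ok in (
        ("time_h", df["time_h"] >= 0),
        ("value", df["value"] >= 0),
        ("replicate", df["replicate"] >= 1),
    ):
        bad = df[~ok]
        if len(bad):
            raise ObservationTableError(
                f"row {bad.index[0] + 2}: invalid {col} value "
                f"{bad[col].iloc[0]!r}"
            )

    manifest = manifest or {}
    experiments: dict[str, FermentationExperiment] = {}
    for eid, sub in df.groupby("experiment_id", sort=True):
        times = np.array(sorted(sub["time_h"].unique()))
        t_index = {t: i for i, t in enumerate(times)}
        observations: dict[str, np.ndarray] = {}
        excluded: dict[str, np.ndarray] = {}
        for var, vsub in sub.groupby("variable"):
            n_rep = int(vsub["replicate"].max())
            arr = np.full((times.size, n_rep), np.nan)
            for _, row in vsub.iterrows():
                arr[t_index[row["time_h"]], int(row["replicate"]) - 1] = row["value"]
            observations[var] = arr
            if "excluded" in vsub.columns:
                flags = np.zeros(times.size, dtype=bool)
                for t, tsub in vsub.groupby("time_h"):
                    flags[t_index[t]] = bool(tsub["excluded"].any())
                if flags.any():
                    excluded[var] = flags
        meta = manifest.get(eid, {})
        if "strains" in meta:
            strains = tuple(Strain(s) for s in meta["strains"])
        else:
            strains = tuple(
                s for s in Strain if f"X_{s.value}" in observations
            )
        initial = dict(meta.get("initial", {}))
        if "X" in initial:
            initial["X"] = {Strain(k): float(v) for k, v in initial["X"].items()}
        experiments[str(eid)] = FermentationExperiment(
            id=str(eid),
            strains=strains,
            times=times,
            observations=observations,
            initial=initial,
            excluded=excluded,
        )
    return experiments


def write_manifest(experiments: dict[str, FermentationExperiment], path) -> None:
    doc = {}
    for eid in sorted(experiments):
        exp = experiments[eid]
        initial = dict(exp.initial)
        if "X" in initial:
            initial["X"] = {s.value: float(v) for s, v in initial["X"].items()}
        doc[eid] = {
            "strains": [s.value for s in exp.strains],
            "initial": initial,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ObservationTableError(f"{path} is not an experiment manifest")
    return doc


@dataclass
class RunManifest:
    """Provenance of one CLI run: enough to reproduce its outputs."""

    command: str
    config_hash: str
    seed: int | None
    package_version: str
    timestamp: str
    platform: str


def write_run_manifest(out_dir, command: str, config: dict, seed: int | None) -> RunManifest:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = RunManifest(
        command=command,
        config_hash=hashlib.sha256(blob).hexdigest()[:16],
        seed=seed,
        package_version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        platform=platform.platform(),
    )
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return manifest
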