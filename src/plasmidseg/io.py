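"""Plain-text serialisation: parameters and strategies to YAML/JSON/TSV,
generator matrices and analysis tables to TSV, division records to TSV with
a JSON sidecar carrying the provenance (parameters, seed, schema version).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    EnvironmentSchedule,
    GeneratorSystem,
    ModelParameters,
    SegregationStrategy,
)

__all__ = [
    "strategy_to_tsv",
    "strategy_from_tsv",
    "params_to_yaml",
    "params_from_yaml",
    "schedule_from_dict",
    "schedule_to_dict",
    "generator_to_tsv",
    "records_to_tsv",
    "records_from_tsv",
    "write_json",
]

RECORD_SCHEMA_VERSION = 1


def strategy_to_tsv(strategy: SegregationStrategy, path: str | Path) -> None:
    """Write the strategy as a two-column TSV (z, p_z)."""
    df = pd.DataFrame({"z": np.arange(1, strategy.z_hat + 1), "p_z": strategy.p})
    df.to_csv(path, sep="\t", index=False)


def strategy_from_tsv(path: str | Path) -> SegregationStrategy:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("z")
    z = df["z"].to_numpy()
    if not np.array_equal(z, np.arange(1, len(z) + 1)):
        raise ValueError(f"{path}: column z must enumerate 1..z_hat")
    return SegregationStrategy(df["p_z"].to_numpy(float))


def params_to_yaml(params: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def params_from_yaml(path: str | Path) -> ModelParameters:
    return ModelParameters.from_dict(yaml.safe_load(Path(path).read_text()))


def schedule_to_dict(schedule: EnvironmentSchedule) -> dict:
    return {"segments": [[d, a] for d, a in schedule.segments]}


def schedule_from_dict(d: dict | int) -> EnvironmentSchedule:
    """Accepts {"constant": alpha} or {"segments": [[hours, alpha], ...]}
    (or a bare alpha)."""
    if isinstance(d, int):
        return EnvironmentSchedule.constant(d)
    if "constant" in d:
        return EnvironmentSchedule.constant(int(d["constant"]))
    return EnvironmentSchedule(tuple((float(x[0]), int(x[1])) for x in d["segments"]))


def generator_to_tsv(system: GeneratorSystem, path: str | Path) -> None:
    """Dense A with B as an extra row labelled z=0 (flux to the plasmid-free
    class), columns and rows labelled by copy number."""
    zh = system.z_hat
    cols = [f"z{z}" for z in range(1, zh + 1)]
    df = pd.DataFrame(np.vstack([system.B, system.A]), columns=cols)
    df.insert(0, "row", ["B"] + cols)
    df.to_csv(path, sep="\t", index=False)


def records_to_tsv(result, path: str | Path) -> None:
    """Write division records as TSV plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    result.records.to_csv(path, sep="\t", index=False)
    meta = {
        "schema_version": RECORD_SCHEMA_VERSION,
        "params": result.params.to_dict(),
        "strategy_p": list(map(float, result.strategy.p)),
        "seed": result.seed,
        "n_subsamples": result.n_subsamples,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def records_from_tsv(path: str | Path) -> tuple[pd.DataFrame, dict | None]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return df, meta


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
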