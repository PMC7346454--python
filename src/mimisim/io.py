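"""Plain-text configuration and result I/O.

Scenario configurations and grid specifications are YAML mappings;
datasets, per-replicate estimates and summaries are delimited text with a
header row. A JSON run-metadata sidecar records package version, seeds and
the documented methodological conventions so a stored run is
self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import yaml

from .dgm import ScenarioConfig
from .engine import GridSpec

PathLike = Union[str, Path]

METHOD_FLAGS = {
    "percentile_rule": "linear interpolation between order statistics",
    "mi_df_rule": "Barnard-Rubin adjusted degrees of freedom",
    "ci_rule": "t interval; residual df for single fits, adjusted df for pooled",
    "missing_indicator_coding": "1 - R_A in both indicator models",
    "beta0_solver": "Gauss-Hermite quadrature (64 nodes) + bracketed root-finding",
}


def load_scenario_config(path: PathLike) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScenarioConfig.from_dict(data)


def dump_scenario_config(config: ScenarioConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_grid_spec(path: PathLike) -> GridSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key, val in data.items():
        if isinstance(val, list):
            data[key] = tuple(val)
    return GridSpec(**data)


def dump_grid_spec(spec: GridSpec, path: PathLike) -> None:
    d = dataclasses.asdict(spec)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def run_metadata(study_seed: int, replicates: int, m: int, **extra) -> dict:
    from . import __version__

    meta = {
        "package": "mimisim",
        "version": __version__,
        "study_seed": study_seed,
        "replicates": replicates,
        "imputations": m,
        "conventions": METHOD_FLAGS,
    }
    meta.update(extra)
    return meta


def write_metadata(meta: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=False)
        fh.write("\n")
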