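"""Reading and writing trial tables and scenario files.

A trial is stored as five plain CSV files plus a JSON meta file:

    climate.csv          dat, doy, t_mean, solar, co2
    node_obs.csv         plant, dat, node_count, flower_nodes (';'-joined)
    leaf_obs.csv         plant (stem id), dat, leaf, width_cm, length_cm
    destructive_obs.csv  plant, dat, leaf_dw, stem_dw, fruit_dw,
                         harvested_fruit_dm, trimmed_leaf_dm
    harvest_events.csv   plant, stem, dat, fruit_fw_g, premature
    meta.json            geometry, density, cohorts, scenario parameters

Scenario files are YAML mappings of the CultivarScenario fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .scenarios import CultivarScenario
from .simulate import TrialDataset

_TABLES = ("climate", "node_obs", "leaf_obs", "destructive_obs", "harvest_events")


def write_trial(trial: TrialDataset, out_dir: str | Path) -> Path:
    """Write a trial's five tables and meta file; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(trial, name).to_csv(out / f"{name}.csv", index=False)
    (out / "meta.json").write_text(json.dumps(trial.meta, indent=2, sort_keys=True))
    return out


def read_trial(in_dir: str | Path) -> TrialDataset:
    """Load a trial previously written by :func:`write_trial`."""
    src = Path(in_dir)
    frames = {}
    for name in _TABLES:
        path = src / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing trial table {path}")
        frames[name] = pd.read_csv(path)
    if "flower_nodes" in frames["node_obs"].columns:
        frames["node_obs"]["flower_nodes"] = (
            frames["node_obs"]["flower_nodes"].fillna("").astype(str)
        )
    meta_path = src / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TrialDataset(meta=meta, **frames)


def write_scenario(scenario: CultivarScenario, path: str | Path) -> None:
    d = dataclasses.asdict(scenario)
    d["partition_schedule"] = list(d["partition_schedule"])
    d["noise_sd"] = dict(d["noise_sd"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_scenario(path: str | Path) -> CultivarScenario:
    d = yaml.safe_load(Path(path).read_text())
    d["partition_schedule"] = tuple(d["partition_schedule"])
    return CultivarScenario(**d)
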