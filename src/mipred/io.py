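"""CSV/YAML serialization of datasets, variable specs and scenario configs.

CSV conventions: one header row, one row per individual, missing cells
written as empty fields.  A variable-spec catalogue travels alongside each
CSV as YAML so that transforms and roles survive the round trip.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .datagen import CompleteDataset, VariableSpec
from .exceptions import InvalidArgumentError
from .missingness import MissingDataset
from .simulate import ScenarioConfig


def specs_to_yaml(specs, path):
    payload = []
    for s in specs:
        d = dataclasses.asdict(s)
        if d.get("probs") is not None:
            d["probs"] = {str(k): float(v) for k, v in d["probs"].items()}
        payload.append({k: v for k, v in d.items() if v is not None})
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def specs_from_yaml(path) -> list[VariableSpec]:
    payload = yaml.safe_load(Path(path).read_text())
    specs = []
    for d in payload:
        probs = d.get("probs")
        if probs is not None:
            # restore integer labels where possible (e.g. centre levels)
            probs = {int(k) if str(k).lstrip("-").isdigit() else k: v for k, v in probs.items()}
        specs.append(
            VariableSpec(
                d["name"],
                d["role"],
                d["dtype"],
                d.get("transform", "none"),
                d.get("mean"),
                d.get("sd"),
                probs,
            )
        )
    return specs


def write_dataset(data, csv_path, specs_path=None):
    """Write a complete or missing dataset to CSV (masked cells empty)."""
    df = data.observed_df() if isinstance(data, MissingDataset) else data.df
    df.to_csv(csv_path, index=False)
    if specs_path is not None:
        specs = data.data.specs if isinstance(data, MissingDataset) else data.specs
        specs_to_yaml(specs, specs_path)


def read_dataset(csv_path, specs_path):
    """Read a CSV + spec catalogue; returns CompleteDataset or MissingDataset."""
    specs = specs_from_yaml(specs_path)
    df = pd.read_csv(csv_path)
    for s in specs:
        if s.name in df.columns and s.dtype in ("binary", "categorical"):
            if df[s.name].notna().all():
                df[s.name] = df[s.name].astype(int)
    if df.isna().any().any():
        mask = df.isna()
        filled = df.copy()
        for col in df.columns:
            if mask[col].any():
                filled[col] = df[col].fillna(df[col].dropna().iloc[0])
        complete = CompleteDataset(filled, specs)
        return MissingDataset(complete, mask)
    return CompleteDataset(df, specs)


def scenario_from_yaml(path) -> ScenarioConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise InvalidArgumentError(f"scenario file {path} is not a mapping")
    allowed = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(d) - allowed
    if unknown:
        raise InvalidArgumentError(f"unknown scenario keys: {sorted(unknown)}")
    for key in ("methods", "measures"):
        if key in d:
            d[key] = tuple(d[key])
    return ScenarioConfig(**d)


def scenario_to_yaml(config: ScenarioConfig, path):
    d = dataclasses.asdict(config)
    d["methods"] = list(d["methods"])
    d["measures"] = list(d["measures"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
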