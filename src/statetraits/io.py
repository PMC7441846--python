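"""CSV readers/writers and run manifests.

All interchange is plain CSV with a header row. The state-score layout is one
row per unit: a ``unit`` column, one numeric column per trait, and an ``n``
participant count — the same rectangular shape as published supplementary
state-score tables, so externally published tables can be read directly.
Manifests are deterministic JSON (seed, parameters, versions; no timestamps),
so a fixed-seed run is byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import (
    CensusTables,
    InventorySpec,
    ResponseTable,
    SociodemoSpec,
    SyntheticConfig,
)

__all__ = [
    "SchemaError",
    "read_state_scores",
    "write_state_scores",
    "read_item_bank",
    "write_item_bank",
    "read_responses",
    "write_responses",
    "read_weights",
    "write_weights",
    "read_sociodemo",
    "write_sociodemo",
    "read_config",
    "write_config",
    "write_manifest",
]


class SchemaError(ValueError):
    """A CSV does not match the expected column schema."""


def write_state_scores(table: pd.DataFrame, path) -> None:
    out = table.reset_index()
    out.to_csv(path, index=False, float_format="%.10g")


def read_state_scores(path, traits: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "unit" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'unit'")
    if df["unit"].duplicated().any():
        dups = df.loc[df["unit"].duplicated(), "unit"].tolist()
        raise SchemaError(f"{path}: duplicate unit labels {dups}")
    df = df.set_index("unit")
    if traits is not None:
        missing = [t for t in traits if t not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing trait column(s) {missing}")
    value_cols = [c for c in df.columns]
    for c in value_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            raise SchemaError(
                f"{path}: non-numeric value(s) in column {c!r} at units {df.index[bad].tolist()}"
            )
        df[c] = coerced
    if "n" in df.columns:
        df.attrs["k"] = float(df["n"].mean())
    return df


def write_item_bank(bank: pd.DataFrame, path) -> None:
    bank.to_csv(path, index=False)


def read_item_bank(path) -> pd.DataFrame:
    bank = pd.read_csv(path)
    required = {"item_id", "inventory", "trait", "keying", "sampling_rate"}
    missing = required - set(bank.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    if not set(np.unique(bank["keying"])) <= {-1, 1}:
        raise SchemaError(f"{path}: keying must be +1 or -1")
    bank["keying"] = bank["keying"].astype(np.int8)
    return bank


def write_responses(table: ResponseTable, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    table.participants.reset_index().to_csv(d / "participants.csv", index=False)
    table.responses.to_csv(d / "responses.csv", index=False)
    meta = {"likert_min": table.likert_min, "likert_max": table.likert_max}
    (d / "responses_meta.json").write_text(json.dumps(meta, sort_keys=True) + "\n")


def read_responses(directory) -> ResponseTable:
    d = Path(directory)
    participants = pd.read_csv(d / "participants.csv")
    if "participant_id" not in participants.columns:
        raise SchemaError(f"{d}: participants.csv missing 'participant_id'")
    participants = participants.set_index("participant_id")
    responses = pd.read_csv(d / "responses.csv")
    required = {"participant_id", "item_id", "value"}
    missing = required - set(responses.columns)
    if missing:
        raise SchemaError(f"{d}: responses.csv missing column(s) {sorted(missing)}")
    meta_path = d / "responses_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    responses["value"] = responses["value"].astype(np.int8)
    return ResponseTable(
        participants=participants,
        responses=responses,
        likert_min=int(meta.get("likert_min", 1)),
        likert_max=int(meta.get("likert_max", 6)),
    )


def write_weights(weights: pd.Series, path) -> None:
    weights.rename("population").rename_axis("unit").reset_index().to_csv(path, index=False)


def read_weights(path) -> pd.Series:
    df = pd.read_csv(path)
    if "unit" not in df.columns or "population" not in df.columns:
        raise SchemaError(f"{path}: expected columns 'unit' and 'population'")
    if df["unit"].duplicated().any():
        raise SchemaError(f"{path}: duplicate unit labels")
    return df.set_index("unit")["population"].astype(float)


def write_sociodemo(table: pd.DataFrame, path) -> None:
    table.rename_axis("unit").reset_index().to_csv(path, index=False, float_format="%.10g")


def read_sociodemo(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "unit" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'unit'")
    if df["unit"].duplicated().any():
        raise SchemaError(f"{path}: duplicate unit labels")
    return df.set_index("unit")


def _config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["unit_weights"] = [float(x) for x in config.unit_weights]
    d["unit_labels"] = list(config.unit_labels)
    d["inventories"] = [dataclasses.asdict(i) for i in config.inventories]
    d["sociodemo_specs"] = [
        {"name": s.name, "trait_r": dict(s.trait_r), "noise_sd": s.noise_sd}
        for s in config.sociodemo_specs
    ]
    d["trait_names"] = list(config.trait_names)
    return d


def write_config(config: SyntheticConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))


def read_config(path) -> SyntheticConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["inventories"] = tuple(InventorySpec(**i) for i in d.get("inventories", []))
    d["sociodemo_specs"] = tuple(SociodemoSpec(**s) for s in d.get("sociodemo_specs", []))
    return SyntheticConfig(**d)


def write_manifest(path, *, seed=None, **params) -> None:
    """Deterministic machine-readable record of a run (no timestamps)."""
    manifest = {
        "package": "statetraits",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": seed,
        "parameters": _jsonable(params),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
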