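"""Readers and writers for the tabular interchange formats.

Isolate and substrate tables travel as CSV/TSV, consumer parameter sets
as JSON, configuration as YAML. Validation is strict and errors name the
offending rows.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .closure import ConsumerParameters
from .config import RunConfig
from .fixtures import CLASSES
from .genome import IsolateTraits, ResponseGroup
from .substrates import parse_formula

__all__ = [
    "TableValidationError",
    "read_isolates",
    "read_substrates",
    "write_table",
    "isolate_traits_from_row",
    "traits_from_table",
    "consumer_to_dict",
    "write_consumers_json",
]

ISOLATE_REQUIRED = {"isolate_id", "genome_size_bp", "rrn_copies", "r_max", "z_X"}
SUBSTRATE_REQUIRED = {"name", "class", "formula", "charge"}


class TableValidationError(ValueError):
    """Input table failed schema validation; message lists offending rows."""


def _read_any(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_isolates(path: str | Path) -> pd.DataFrame:
    """Read and validate an isolate trait table (CSV/TSV)."""
    df = _read_any(path)
    missing = ISOLATE_REQUIRED - set(df.columns)
    if missing:
        raise TableValidationError(f"isolate table missing column(s): {sorted(missing)}")
    bad = df.index[(df["rrn_copies"] < 1) | (df["genome_size_bp"] <= 0) | (df["r_max"] <= 0) | (df["z_X"] < 0)]
    if len(bad):
        raise TableValidationError(f"invalid trait values in row(s): {list(bad)}")
    return df


def read_substrates(path: str | Path) -> pd.DataFrame:
    """Read and validate a substrate table (CSV/TSV); formulas are parsed."""
    df = _read_any(path)
    missing = SUBSTRATE_REQUIRED - set(df.columns)
    if missing:
        raise TableValidationError(f"substrate table missing column(s): {sorted(missing)}")
    errors = []
    for idx, row in df.iterrows():
        try:
            parse_formula(str(row["formula"]), int(row["charge"]))
        except Exception as exc:
            errors.append(f"row {idx}: {exc}")
        if row["class"] not in CLASSES:
            errors.append(f"row {idx}: unknown class {row['class']!r}")
    if errors:
        raise TableValidationError("; ".join(errors))
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def isolate_traits_from_row(row: pd.Series) -> IsolateTraits:
    """Build an :class:`IsolateTraits` from one validated table row."""
    z_rho = {
        c: float(row[f"z_rho_{c}"])
        for c in CLASSES
        if f"z_rho_{c}" in row.index and pd.notna(row[f"z_rho_{c}"])
    }
    total = sum(z_rho.values())
    if total > 0:
        z_rho = {c: v / total for c, v in z_rho.items()}
    return IsolateTraits(
        isolate_id=str(row["isolate_id"]),
        genome_size_bp=float(row["genome_size_bp"]),
        rrn_copies=int(row["rrn_copies"]),
        r_max=float(row["r_max"]),
        z_rho=z_rho,
        z_X=float(row["z_X"]),
        response_group=ResponseGroup(row.get("response_group", "undefined")),
    )


def traits_from_table(df: pd.DataFrame) -> list[IsolateTraits]:
    return [isolate_traits_from_row(row) for _, row in df.iterrows()]


def consumer_to_dict(params: ConsumerParameters) -> dict:
    """JSON-serializable view of a closed consumer parameter set."""
    geom = dataclasses.asdict(params.geometry)
    return {
        "isolate_id": params.isolate_id,
        "k_E": params.k_E,
        "y_VE": params.y_VE,
        "y_EV": params.y_EV,
        "k_M": params.k_M,
        "z_X_rate": params.z_X_rate,
        "mu_E": params.mu_E,
        "lambda_B": params.lambda_B,
        "rho_porter": params.rho_porter,
        "rho_total": params.rho_total,
        "y_ED": params.y_ED,
        "gamma0": params.gamma0,
        "B_ref": params.B_ref,
        "response_group": params.response_group,
        "geometry": geom,
        "r_max": params.extras.get("r_max"),
    }


def write_consumers_json(
    consumers: list[ConsumerParameters], path: str | Path, config: RunConfig | None = None
) -> None:
    payload = {
        "config_hash": (config or RunConfig()).config_hash,
        "consumers": [consumer_to_dict(p) for p in consumers],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
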