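"""File formats: trace/layout/sweep CSV, hit TSV with provenance, QC JSON.

Result tables carry a ``#``-prefixed provenance header (version, seed,
parameters) so any output can be regenerated exactly; the companion readers
skip and parse these headers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import LAYOUT_COLUMNS, TRACE_COLUMNS
from .errors import TableFormatError
from .traces import KineticTrace

__all__ = [
    "read_trace_table",
    "read_layout_table",
    "write_hit_table",
    "read_hit_table",
    "write_sweep_table",
    "read_sweep_table",
    "write_qc_json",
    "load_config",
]

HIT_FLOAT_FMT = "%.6g"


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")


def read_trace_table(path) -> dict[tuple[int, str, str], KineticTrace]:
    """Read a long-format trace CSV into per-well traces.

    Returns a dict keyed by (replicate, plate, well).  Validates the schema,
    duplicate samples and the uniform time grid; errors cite data-row numbers
    (1-based, excluding the header).  An empty file yields an empty dict with
    a warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: no trace rows", stacklevel=2)
        return {}
    if df.empty:
        warnings.warn(f"{path}: no trace rows", stacklevel=2)
        return {}
    _require_columns(df, TRACE_COLUMNS, path)
    dup = df.duplicated(subset=["replicate", "plate", "well", "time_s"])
    if dup.any():
        row = int(df.index[dup][0]) + 1
        raise TableFormatError(f"{path}: duplicate sample at data row {row}")
    out: dict[tuple[int, str, str], KineticTrace] = {}
    for (rep, plate, well), g in df.groupby(["replicate", "plate", "well"], sort=True):
        g = g.sort_values("time_s")
        t = g["time_s"].to_numpy(dtype=float)
        try:
            trace = KineticTrace(t, g["fluorescence"].to_numpy(dtype=float), well=str(well))
        except ValueError as exc:
            row = int(g.index[0]) + 1
            raise TableFormatError(
                f"{path}: invalid trace for well {well} "
                f"(first data row {row}): {exc}"
            ) from exc
        out[(int(rep), str(plate), str(well))] = trace
    return out


def read_layout_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, LAYOUT_COLUMNS, path)
    return df


# ------------------------------------------------------------------ hit tables


def write_hit_table(
    gene_table: pd.DataFrame,
    path,
    seed: Optional[int] = None,
    params: Optional[dict] = None,
) -> None:
    """Ranked gene TSV with a provenance comment header."""
    path = Path(path)
    lines = [f"# asorpipe hit table v{__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for key in sorted(params or {}):
        lines.append(f"# {key}: {params[key]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        gene_table.to_csv(fh, sep="\t", index=False, float_format=HIT_FLOAT_FMT)


def read_hit_table(path) -> Tuple[pd.DataFrame, dict]:
    """Read a hit TSV; returns (table, provenance dict)."""
    meta = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
        df = pd.read_csv(fh, sep="\t")
    if "rank" in df.columns:
        df["rank"] = df["rank"].astype("Int64")
    return df, meta


# ------------------------------------------------------------------ sweep tables


SWEEP_COLUMNS = ["sweep", "time_s", "voltage_mV", "current_pA"]


def write_sweep_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, SWEEP_COLUMNS, path)
    df.to_csv(path, index=False, float_format="%.6g")


def read_sweep_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SWEEP_COLUMNS, path)
    return df


# ------------------------------------------------------------------ misc


def write_qc_json(qc: pd.DataFrame, path, seed: Optional[int] = None,
                  params: Optional[dict] = None) -> None:
    payload = {
        "version": __version__,
        "seed": seed,
        "params": _jsonable(params or {}),
        "plates": _jsonable(qc.to_dict(orient="records")),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def load_config(path) -> dict:
    """Flat key: value configuration file (YAML subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TableFormatError(f"{path}: config must be flat key: value pairs")
    return cfg
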