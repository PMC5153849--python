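"""Readers and writers for the package's plain-text formats.

All tables are tidy UTF-8 CSVs with LF line endings and deterministic
row/column order, so that identical inputs produce byte-identical files.
Formats:

* plate CSV — ``well, time_s, od`` (one row per well per timepoint);
* dilution CSV — ``concentration_per_ml, od, replicate_id``;
* counts CSV — ``field_id, count``;
* calibration JSON — schema-versioned curve artifact
  (see :class:`odcal.calibration.CalibrationCurve`);
* instrument config JSON — path length, volume-correction table,
  saturation level, single-scattering threshold.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .calibration import DilutionSeries
from .forward_model import (
    DEFAULT_VOLUME_CORRECTION,
    PathConfig,
    SINGLE_SCATTER_OD_THRESHOLD,
)
from .growth import GrowthCurve

__all__ = [
    "SchemaError",
    "read_plate_csv",
    "write_plate_csv",
    "read_dilution_csv",
    "write_dilution_csv",
    "read_counts_csv",
    "write_counts_csv",
    "read_instrument_config",
    "write_json",
]

PathLike = Union[str, Path]

FLOAT_FMT = "%.10g"  # >= 9 significant digits survive a round trip


class SchemaError(ValueError):
    """File violates the documented column/uniqueness contract."""


def _require_columns(df: pd.DataFrame, required: set[str], path: PathLike) -> None:
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")


# ---------------------------------------------------------------------------
# plate CSV
# ---------------------------------------------------------------------------


def read_plate_csv(path: PathLike) -> pd.DataFrame:
    """Read a tidy plate-reader table (well, time_s, od).

    Unknown columns are preserved; duplicate (well, time_s) pairs and
    negative times are schema errors.
    """
    df = pd.read_csv(path)
    _require_columns(df, {"well", "time_s", "od"}, path)
    df["time_s"] = df["time_s"].astype(float)
    df["od"] = df["od"].astype(float)
    bad = df[df["time_s"] < 0]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +2: header + 1-based
        raise SchemaError(f"{path}: negative time_s at lines {lines}")
    dup = df.duplicated(subset=["well", "time_s"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise SchemaError(f"{path}: duplicate (well, time_s) at lines {lines}")
    return df


def write_plate_csv(table: Union[pd.DataFrame, GrowthCurve], path: PathLike) -> None:
    """Write a plate table sorted by (well, time_s), LF line endings."""
    df = table.to_tidy() if isinstance(table, GrowthCurve) else table.copy()
    _require_columns(df, {"well", "time_s", "od"}, path)
    df = df.sort_values(["well", "time_s"], kind="stable")
    cols = ["well", "time_s", "od"] + [
        c for c in df.columns if c not in ("well", "time_s", "od")
    ]
    df[cols].to_csv(
        path, index=False, float_format=FLOAT_FMT, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# dilution CSV
# ---------------------------------------------------------------------------


def read_dilution_csv(
    path: PathLike, instrument_id: str = "unknown"
) -> DilutionSeries:
    df = pd.read_csv(path)
    _require_columns(df, {"concentration_per_ml", "od"}, path)
    return DilutionSeries.from_frame(df, instrument_id=instrument_id)


def write_dilution_csv(series: DilutionSeries, path: PathLike) -> None:
    df = series.to_frame().sort_values(
        ["concentration_per_ml", "replicate_id"], kind="stable"
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# counts CSV
# ---------------------------------------------------------------------------


def read_counts_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, {"field_id", "count"}, path)
    if (df["count"] < 0).any():
        raise SchemaError(f"{path}: negative counts")
    return df


def write_counts_csv(counts: Union[pd.DataFrame, np.ndarray], path: PathLike) -> None:
    if isinstance(counts, np.ndarray):
        counts = pd.DataFrame(
            {"field_id": np.arange(counts.size), "count": counts}
        )
    _require_columns(counts, {"field_id", "count"}, path)
    counts.sort_values("field_id", kind="stable").to_csv(
        path, index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# config / JSON
# ---------------------------------------------------------------------------


def read_instrument_config(path: PathLike) -> dict:
    """Instrument config: path length, volume corrections, thresholds."""
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    vc = {int(k): float(v) for k, v in cfg.get(
        "volume_correction", DEFAULT_VOLUME_CORRECTION
    ).items()}
    return {
        "instrument_id": cfg.get("instrument_id", "unknown"),
        "path": PathConfig(
            path_length_cm=float(cfg.get("path_length_cm", 1.0)),
            volume_correction=vc,
        ),
        "od_saturation": float(cfg.get("od_saturation", 3.5)),
        "single_scatter_threshold": float(
            cfg.get("single_scatter_threshold", SINGLE_SCATTER_OD_THRESHOLD)
        ),
    }


def write_json(obj: dict, path: PathLike) -> None:
    """Deterministic JSON (sorted keys, trailing newline)."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
            from dataclasses import asdict, is_dataclass

            if is_dataclass(o):
                return asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
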