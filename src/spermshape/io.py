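"""CSV/TIFF/JSON input-output with schema validation.

All tables are comma-separated UTF-8 with a header row and '.' decimals.
Validation errors name the offending rows (1-based, counting the header
as line 1).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morpho import FEATURE_NAMES
from .segment import PerimeterTrace
from .synth import FertilityRecord

__all__ = [
    "SchemaError",
    "write_traces",
    "read_traces",
    "write_features",
    "read_features",
    "write_fertility",
    "read_fertility",
    "write_harmonics",
    "write_image",
    "read_image",
    "write_json",
]

TRACE_COLUMNS = ["ram_id", "object_label", "vertex_index", "x_um", "y_um"]
FERTILITY_COLUMNS = ["ram_id", "conception_rate"]


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _bad_rows(mask: pd.Series) -> str:
    lines = (np.nonzero(mask.to_numpy())[0] + 2).tolist()  # +2: header + 1-based
    return f"rows (file lines) {lines[:20]}"


def write_traces(traces: list[PerimeterTrace], path) -> None:
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.vertices):
            rows.append((t.ram_id, t.label, i, x, y))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_traces(path, pixel_size_um: float = 0.11) -> list[PerimeterTrace]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)
    df["ram_id"] = df["ram_id"].fillna("").astype(str)
    for col in ("x_um", "y_um"):
        bad = ~np.isfinite(df[col].to_numpy(float))
        if bad.any():
            raise SchemaError(f"{path}: non-finite {col} at {_bad_rows(pd.Series(bad))}")
    out = []
    for (ram_id, label), g in df.groupby(["ram_id", "object_label"], sort=False):
        g = g.sort_values("vertex_index")
        verts = g[["x_um", "y_um"]].to_numpy(float)
        # tolerate an explicitly closed polygon on disk
        if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        out.append(
            PerimeterTrace(
                vertices=verts,
                pixel_size_um=pixel_size_um,
                ram_id=str(ram_id),
                label=int(label),
            )
        )
    return out


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=True, index_label="ram_id")


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["ram_id"], path)
    df = df.set_index("ram_id")
    present = [c for c in FEATURE_NAMES if c in df.columns]
    for col in present:
        vals = df[col].to_numpy(float)
        bad = ~np.isfinite(vals)
        if bad.any():
            raise SchemaError(f"{path}: non-finite {col} at {_bad_rows(pd.Series(bad))}")
    if "area" in df.columns and (df["area"] <= 0).any():
        raise SchemaError(
            f"{path}: non-positive area at {_bad_rows(df['area'] <= 0)}"
        )
    return df


def write_fertility(records: list[FertilityRecord], path) -> None:
    pd.DataFrame(
        [
            {"ram_id": r.ram_id, "conception_rate": r.conception_rate, "group": r.group}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_fertility(path) -> list[FertilityRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, FERTILITY_COLUMNS, path)
    rates = df["conception_rate"].to_numpy(float)
    bad = ~np.isfinite(rates) | (rates < 0) | (rates > 100)
    if bad.any():
        raise SchemaError(
            f"{path}: conception_rate outside [0, 100] at {_bad_rows(pd.Series(bad))}"
        )
    groups = df["group"] if "group" in df.columns else ["unassigned"] * len(df)
    return [
        FertilityRecord(ram_id=str(r), conception_rate=float(c), group=str(g))
        for r, c, g in zip(df["ram_id"], rates, groups)
    ]


def write_harmonics(rows: list[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), image)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
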