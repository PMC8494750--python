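"""Plain-text readers and writers for the package's tabular artefacts.

Point patterns travel as CSV (columns ``x_um, y_um``) with a JSON sidecar
describing the observation window and metadata; K curves as CSV with columns
``r_um, K_um2, K_over_r2``; results and manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spatial_stats import KCurve, PointPattern, k_over_r2

__all__ = [
    "write_pattern",
    "read_pattern",
    "write_kcurve",
    "read_kcurve",
    "write_json",
    "read_json",
]


def write_pattern(pattern: PointPattern, csv_path) -> Path:
    """Write a pattern CSV plus a ``.json`` sidecar with window and meta."""
    csv_path = Path(csv_path)
    pd.DataFrame(pattern.points, columns=["x_um", "y_um"]).to_csv(csv_path, index=False)
    sidecar = {"window_um": list(pattern.window), "meta": _jsonable(pattern.meta)}
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_pattern(csv_path, window=None) -> PointPattern:
    """Read a pattern CSV; window from the sidecar unless given explicitly."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if not {"x_um", "y_um"}.issubset(df.columns):
        raise ValueError(f"{csv_path}: expected columns x_um, y_um")
    meta = {}
    sidecar = csv_path.with_suffix(".json")
    if window is None:
        if not sidecar.exists():
            raise ValueError(f"{csv_path}: no window given and no sidecar {sidecar}")
        info = json.loads(sidecar.read_text())
        window = tuple(info["window_um"])
        meta = info.get("meta", {})
    return PointPattern(df[["x_um", "y_um"]].to_numpy(), tuple(window), meta=meta)


def write_kcurve(curve: KCurve, csv_path) -> Path:
    csv_path = Path(csv_path)
    pd.DataFrame({"r_um": curve.r, "K_um2": curve.K,
                  "K_over_r2": k_over_r2(curve)}).to_csv(csv_path, index=False)
    return csv_path


def read_kcurve(csv_path, N: float = 0, area: float = 0,
                edge_correction: str = "none") -> KCurve:
    df = pd.read_csv(csv_path)
    return KCurve(df["r_um"].to_numpy(), df["K_um2"].to_numpy(),
                  N=N, area=area, edge_correction=edge_correction)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=1))
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
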