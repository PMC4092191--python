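"""Tidy CSV and JSON-sidecar I/O for simulation and morphometry data.

All files are long-format CSV with µm/hour units; every randomized output
gets a JSON metadata sidecar carrying the resolved parameters, seed and
package version so a run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import SchemaError
from .morphometry import EdgeTrace, TrackSet

TRACKS_COLUMNS = ("time_h", "cell_id", "x_um", "y_um")
EVENTS_COLUMNS = ("x_um",)
EDGES_COLUMNS = ("step", "time_h", "side", "edge_x_um")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file missing columns: {missing}")
    if len(df) == 0:
        raise SchemaError(f"{what} file has no rows")
    for c in required:
        if c in ("side",):
            continue
        if not np.issubdtype(df[c].dtype, np.number):
            raise SchemaError(f"{what} column {c!r} is not numeric")
        if df[c].isna().any():
            raise SchemaError(f"{what} column {c!r} contains missing values")


def read_tracks(path, injury: tuple[float, float], metadata=None) -> TrackSet:
    df = pd.read_csv(path)
    _require_columns(df, TRACKS_COLUMNS, "tracks")
    return TrackSet(tracks=df, injury=injury, metadata=metadata or {})


def write_tracks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_events(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, EVENTS_COLUMNS, "events")
    return df["x_um"].to_numpy(dtype=float)


def write_events(events, path, time_h=None) -> None:
    data = {"x_um": np.asarray(events, dtype=float)}
    if time_h is not None:
        data["time_h"] = np.asarray(time_h, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False)


def read_edges(path) -> dict[str, EdgeTrace]:
    """Read an edge-trace CSV into one :class:`EdgeTrace` per side.

    The left edge advances toward +x (proximal side), the right toward -x
    (distal side).
    """
    df = pd.read_csv(path)
    _require_columns(df, EDGES_COLUMNS, "edges")
    out = {}
    for side, g in df.groupby("side"):
        g = g.sort_values("time_h")
        orientation = "proximal" if side == "left" else "distal"
        out[str(side)] = EdgeTrace(
            time_h=g["time_h"].to_numpy(),
            x_um=g["edge_x_um"].to_numpy(),
            side=orientation,
        )
    return out


def write_metadata(path, **fields) -> None:
    payload = {"package": "epirepair", "version": __version__}
    payload.update(fields)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())
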