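"""Plain-text interchange formats for tracks and hauls.

ARGOS records travel as CSV with columns ``animal_id, timestamp (ISO
8601 UTC), lon, lat, lc``; haul records as ``date, lon, lat, catch_t[,
gear]``; regularized tracks as ``animal_id, segment_id, timestamp, lon,
lat, x_km, y_km, var_x, var_y``. Covariate stacks round-trip through
NetCDF (see :meth:`sealhab.grids.CovariateStack.to_netcdf`).
"""

from __future__ import annotations

import pandas as pd


def write_argos_csv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    cols = ["animal_id", "timestamp", "lon", "lat", "lc"]
    out[cols].to_csv(path, index=False)


def read_argos_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str, "lc": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_hauls_csv(hauls: pd.DataFrame, path) -> None:
    out = hauls.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    cols = [c for c in ("date", "lon", "lat", "catch_t", "gear") if c in out]
    out[cols].to_csv(path, index=False)


def read_hauls_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_regularized_csv(tracks, path) -> None:
    frames = []
    for tr in tracks:
        df = tr.data.copy()
        df.insert(0, "animal_id", tr.animal_id)
        df.insert(1, "segment_id", tr.segment_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)
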