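"""ARGOS track quality control for the winter fishing season.

Cleans raw ARGOS records into at-sea winter track segments: invalid
class-Z fixes are dropped, records outside the May-September fishing
season are removed, implausible positions are removed by an iterative
speed-distance-angle (SDA) filter (maximum speed 10 m/s; out-and-back
spike geometry with internal angle < 15 deg when both adjacent steps
exceed 2.5 km, or < 25 deg when both exceed 5 km), on-land positions are
removed against the depth raster, and tracks are split wherever the gap
between successive uplinks exceeds 3 days.

Record tables are pandas DataFrames with columns ``animal_id``,
``timestamp`` (UTC), ``lon``, ``lat``, ``lc``; extra columns are carried
through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .projection import haversine_km

VALID_CLASSES = {"3", "2", "1", "0", "A", "B", "Z"}
CLASS_QUALITY = {"3": 0, "2": 1, "1": 2, "0": 3, "A": 4, "B": 5, "Z": 6}
VMAX_MS = 10.0
WINTER_WINDOW = (5, 9)


@dataclass
class TrackSegment:
    """A gap-free run of cleaned records for one animal."""

    animal_id: str
    segment_id: int
    records: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)


def _check_classes(records: pd.DataFrame) -> None:
    bad = set(records["lc"].astype(str)) - VALID_CLASSES
    if bad:
        raise ValueError(f"unknown ARGOS location class(es): {sorted(bad)}")


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicate timestamps within an animal.

    Keeps the higher-quality class (3 > 2 > 1 > 0 > A > B > Z), then the
    first occurrence, and returns records sorted by animal and time.
    """
    if records.empty:
        return records.reset_index(drop=True)
    _check_classes(records)
    df = records.copy()
    df["_q"] = df["lc"].astype(str).map(CLASS_QUALITY)
    df = (df.sort_values(["animal_id", "timestamp", "_q"], kind="stable")
            .drop_duplicates(["animal_id", "timestamp"], keep="first")
            .drop(columns="_q"))
    return df.reset_index(drop=True)


def filter_quality(records: pd.DataFrame) -> pd.DataFrame:
    """Remove invalid (class Z) fixes; every other class is retained."""
    if records.empty:
        return records.reset_index(drop=True)
    _check_classes(records)
    return records[records["lc"].astype(str) != "Z"].reset_index(drop=True)


def clip_winter(records: pd.DataFrame, window=WINTER_WINDOW) -> pd.DataFrame:
    """Keep records whose calendar month lies in the fishing season."""
    if records.empty:
        return records.reset_index(drop=True)
    month = pd.DatetimeIndex(records["timestamp"]).month
    keep = (month >= window[0]) & (month <= window[1])
    return records[keep].reset_index(drop=True)


def remove_on_land(records: pd.DataFrame, stack) -> pd.DataFrame:
    """Drop records whose position falls in a land cell of the depth raster.

    Cell membership is half-open ([edge, edge + d) in both axes); points
    off the grid are treated as at-sea (nothing to test them against).
    """
    if records.empty:
        return records.reset_index(drop=True)
    land = stack.is_land(records["lon"].to_numpy(float), records["lat"].to_numpy(float))
    return records[~land].reset_index(drop=True)


# ---------------------------------------------------------------------------
# speed-distance-angle filter


def _internal_angles(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Internal angle (deg) at each interior vertex from great-circle sides."""
    a = haversine_km(lon[:-2], lat[:-2], lon[1:-1], lat[1:-1])   # prev -> vertex
    b = haversine_km(lon[1:-1], lat[1:-1], lon[2:], lat[2:])     # vertex -> next
    c = haversine_km(lon[:-2], lat[:-2], lon[2:], lat[2:])       # prev -> next
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (a**2 + b**2 - c**2) / (2.0 * a * b)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[(a == 0) | (b == 0)] = 180.0
    return ang


def _sda_one_animal(df: pd.DataFrame, vmax_ms: float,
                    angle_thresholds, distance_thresholds) -> pd.DataFrame:
    if len(df) < 3:
        return df
    keep = df.reset_index(drop=True)
    ang_lo, ang_hi = angle_thresholds
    dist_lo, dist_hi = distance_thresholds
    vmax_kmh = vmax_ms * 3.6
    while True:
        n = len(keep)
        if n < 3:
            break
        lon = keep["lon"].to_numpy(float)
        lat = keep["lat"].to_numpy(float)
        t = pd.DatetimeIndex(keep["timestamp"]).asi8 / 3.6e12   # hours
        d = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        dt = np.diff(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(dt > 0, d / dt, np.inf)
        # speed rule: interior points implausibly fast relative to BOTH
        # neighbours; the double condition protects a spike's neighbours
        bad = np.zeros(n, dtype=bool)
        bad[1:-1] = (v[:-1] > vmax_kmh) & (v[1:] > vmax_kmh)
        if bad.any():
            keep = keep[~bad].reset_index(drop=True)
            continue
        # angle rule: out-and-back geometry at interior vertices; remove
        # only the sharpest offending vertex per pass — removing a spike
        # often repairs the geometry at its neighbours, so greedy
        # one-at-a-time removal is the minimal (and standard) behaviour
        ang = _internal_angles(lon, lat)
        spike = (((d[:-1] > dist_lo) & (d[1:] > dist_lo) & (ang < ang_lo))
                 | ((d[:-1] > dist_hi) & (d[1:] > dist_hi) & (ang < ang_hi)))
        if spike.any():
            worst = int(np.argmin(np.where(spike, ang, np.inf))) + 1
            keep = keep.drop(index=worst).reset_index(drop=True)
            continue
        # endpoints: speed-only, checked once interior points are stable
        bad = np.zeros(n, dtype=bool)
        bad[0] = v[0] > vmax_kmh
        bad[-1] = v[-1] > vmax_kmh
        if bad.any():
            keep = keep[~bad].reset_index(drop=True)
            continue
        break
    return keep


def sda_filter(records: pd.DataFrame, vmax_ms: float = VMAX_MS,
               angle_thresholds=(15.0, 25.0),
               distance_thresholds=(2.5, 5.0)) -> pd.DataFrame:
    """Iterative speed-distance-angle filter, per animal, to convergence.

    Removes interior positions whose implied speed to both temporal
    neighbours exceeds ``vmax_ms``, then out-and-back spikes (internal
    angle below ``angle_thresholds`` when both adjacent great-circle step
    lengths exceed the corresponding ``distance_thresholds``), repeating
    until stable. First/last positions are only ever removed by the speed
    rule. Tracks with fewer than three records pass through unchanged.
    """
    if records.empty or len(records) < 3:
        return records.reset_index(drop=True)
    parts = [
        _sda_one_animal(grp, vmax_ms, angle_thresholds, distance_thresholds)
        for _, grp in records.groupby("animal_id", sort=False)
    ]
    return pd.concat(parts, ignore_index=True)


def split_segments(records: pd.DataFrame, max_gap_hours: float = 72.0) -> list[TrackSegment]:
    """Split each animal's records wherever the uplink gap *exceeds* the cap.

    A gap of exactly ``max_gap_hours`` does not split (the rule is strict).
    """
    segments: list[TrackSegment] = []
    for animal, grp in records.groupby("animal_id", sort=False):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        if grp.empty:
            continue
        t = pd.DatetimeIndex(grp["timestamp"]).asi8 / 3.6e12
        breaks = np.nonzero(np.diff(t) > max_gap_hours)[0] + 1
        for seg_id, chunk in enumerate(np.split(np.arange(len(grp)), breaks)):
            segments.append(TrackSegment(
                animal_id=str(animal), segment_id=seg_id,
                records=grp.iloc[chunk].reset_index(drop=True)))
    return segments


def clean_tracks(records: pd.DataFrame, stack, vmax_ms: float = VMAX_MS,
                 max_gap_hours: float = 72.0, window=WINTER_WINDOW):
    """Full QC pipeline; returns (segments, per-filter removal log)."""
    log = {"input": len(records)}
    df = deduplicate(records)
    log["after_dedup"] = len(df)
    df = clip_winter(df, window=window)
    log["after_winter_clip"] = len(df)
    df = filter_quality(df)
    log["after_quality"] = len(df)
    df = sda_filter(df, vmax_ms=vmax_ms)
    log["after_sda"] = len(df)
    df = remove_on_land(df, stack)
    log["after_land"] = len(df)
    segments = split_segments(df, max_gap_hours=max_gap_hours)
    log["n_segments"] = len(segments)
    return segments, log


# ---------------------------------------------------------------------------
# deployment summaries


@dataclass
class DeploymentSummary:
    """Per-animal deployment table plus per-group duration statistics."""

    per_animal: pd.DataFrame     # animal_id, group, n_locations, start, end, duration_days
    group_stats: pd.DataFrame    # group, n, mean_days, sd_days (sample SD, rounded)


def _duration_stats(durations: np.ndarray) -> tuple[int, float]:
    mean = float(np.mean(durations))
    sd = float(np.std(durations, ddof=1)) if len(durations) > 1 else float("nan")
    return mean, sd


def summarize_from_table(table: pd.DataFrame) -> DeploymentSummary:
    """Duration arithmetic from a per-animal table of start/end dates.

    ``table`` needs columns animal_id, group, n_locations, start_date,
    end_date (datetime-like). Durations are whole days (end - start);
    group and combined means/SDs use the sample (n-1) SD and are rounded
    to the nearest integer for reporting.
    """
    per = table.copy()
    start = pd.to_datetime(per["start_date"])
    end = pd.to_datetime(per["end_date"])
    per["duration_days"] = (end.dt.normalize() - start.dt.normalize()).dt.days
    if (per["duration_days"] < 0).any():
        raise ValueError("end date precedes start date")
    def _round(v):
        return round(v) if np.isfinite(v) else float("nan")

    rows = []
    for group, grp in per.groupby("group", sort=True):
        mean, sd = _duration_stats(grp["duration_days"].to_numpy(float))
        rows.append({"group": str(group), "n": len(grp),
                     "mean_days": _round(mean), "sd_days": _round(sd)})
    mean, sd = _duration_stats(per["duration_days"].to_numpy(float))
    rows.append({"group": "combined", "n": len(per),
                 "mean_days": _round(mean), "sd_days": _round(sd)})
    return DeploymentSummary(per_animal=per.reset_index(drop=True),
                             group_stats=pd.DataFrame(rows))


def summarize_deployments(records: pd.DataFrame, groups: dict[str, str]) -> DeploymentSummary:
    """Deployment summary from (winter-clipped) records.

    ``groups`` maps animal_id to a group label (e.g. deployment year).
    Animals with zero records are omitted with a warning.
    """
    rows = []
    seen = set()
    for animal, grp in records.groupby("animal_id", sort=True):
        seen.add(animal)
        ts = pd.DatetimeIndex(grp["timestamp"]).sort_values()
        rows.append({"animal_id": str(animal), "group": groups.get(str(animal), "all"),
                     "n_locations": len(grp),
                     "start_date": ts[0].normalize(), "end_date": ts[-1].normalize()})
    missing = set(groups) - seen
    if missing:
        warnings.warn(f"animals with zero records omitted: {sorted(missing)}")
    if not rows:
        raise ValueError("no records to summarize")
    return summarize_from_table(pd.DataFrame(rows))


def load_deployment_table() -> pd.DataFrame:
    """Published 1999/2003 Bird Island PTT deployment metadata.

    Columns: year, animal_id, n_locations, start_date, end_date (parsed
    from dd/mm/yyyy) and the published duration_days column, kept for
    cross-checking the recomputed durations.
    """
    with resources.files("sealhab.data").joinpath("bird_island_deployments.csv").open() as fh:
        df = pd.read_csv(fh)
    for col in ("start_date", "end_date"):
        df[col] = pd.to_datetime(df[col], format="%d/%m/%Y")
    return df
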