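"""Model domain, pseudo-absence sampling and the presence/absence table.

The model domain is the sea area between a northern front line (the
Polar Front in the real system) and a southern ice-extent line,
represented as a boolean mask over the covariate grid with exact
spherical cell areas. For every presence point, three pseudo-absence
points (the default ratio) are drawn uniformly over the domain area;
each inherits the month of its presence so that dynamic covariates and
monthly cross-validation blocks are defined for it. Covariates are
attached by containing-cell lookup, CDIST as great-circle distance to
the nearest colony, and pairwise-correlated covariates are screened by
removing the higher-VIF member of any pair with |r| above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import CovariateStack, GridSpec, covariate_frame

MODEL_COVARIATES = ("DEPTH", "SLOPE", "SLOPE_SD", "ASPECT", "CDIST", "SST", "CHL", "CURL")


@dataclass
class ModelDomain:
    """Sea cells between the front and ice lines, with their total area."""

    grid: GridSpec
    mask: np.ndarray             # True inside the domain
    area_km2: float

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.grid.cell_index(lon, lat)
        out = np.zeros(np.shape(row), dtype=bool)
        inside = row >= 0
        out[inside] = self.mask[row[inside], col[inside]]
        return out


@dataclass
class PresenceAbsenceTable:
    """Model-ready rows: label (1 presence / 0 absence), month, coords, covariates."""

    data: pd.DataFrame
    dropped_missing: int = 0
    dropped_outside: int = 0

    @property
    def covariate_names(self) -> list[str]:
        reserved = {"label", "animal_id", "month", "lon", "lat"}
        return [c for c in self.data.columns if c not in reserved]


def _line_lat_at(line, lon) -> np.ndarray:
    pts = np.asarray(line, dtype=float)
    order = np.argsort(pts[:, 0])
    return np.interp(lon, pts[order, 0], pts[order, 1])


def build_domain(front_line, ice_line, stack: CovariateStack) -> ModelDomain:
    """Sea cells whose centre lies between the ice line (S) and front (N).

    ``front_line`` and ``ice_line`` are lon/lat polylines spanning the
    grid's longitude range. Lines that cross (front south of ice
    anywhere on the grid) are rejected.
    """
    grid = stack.grid
    lons = grid.lon_centers
    front = _line_lat_at(front_line, lons)
    ice = _line_lat_at(ice_line, lons)
    if np.any(front <= ice):
        raise ValueError("front line lies south of the ice line: degenerate domain")
    lat = grid.lat_centers[:, None]
    mask = (lat <= front[None, :]) & (lat >= ice[None, :]) & ~stack.land_mask
    area = float(grid.cell_areas_km2()[mask].sum())
    if area <= 0:
        raise ValueError("domain has zero area")
    return ModelDomain(grid=grid, mask=mask, area_km2=area)


def presences_from_tracks(tracks, domain: ModelDomain) -> tuple[pd.DataFrame, int]:
    """Collect regularized positions inside the domain as presence points.

    ``tracks`` is a list of RegularizedTrack. Returns (presences, number
    dropped for falling outside the domain).
    """
    frames = []
    for tr in tracks:
        df = tr.data[["timestamp", "lon", "lat"]].copy()
        df["animal_id"] = tr.animal_id
        frames.append(df)
    allp = pd.concat(frames, ignore_index=True)
    allp["month"] = pd.DatetimeIndex(allp["timestamp"]).month
    inside = domain.contains(allp["lon"].to_numpy(float), allp["lat"].to_numpy(float))
    dropped = int((~inside).sum())
    return allp[inside].reset_index(drop=True), dropped


def sample_pseudo_absences(presences: pd.DataFrame, domain: ModelDomain,
                           ratio: int = 3, seed: int = 0) -> pd.DataFrame:
    """``ratio`` pseudo-absences per presence, uniform over the domain area.

    Sampling is by rejection: longitude uniform, latitude uniform in
    sin(latitude) (area-true on the sphere), accepted if the containing
    cell is in the domain. Each pseudo-absence inherits its presence's
    month. Deterministic given the seed.
    """
    n = len(presences) * ratio
    if n == 0:
        return pd.DataFrame(columns=["lon", "lat", "month"])
    rng = np.random.default_rng(seed)
    grid = domain.grid
    lo_lon, hi_lon = grid.lon_edges[0], grid.lon_edges[-1]
    s_lo, s_hi = np.sin(np.radians(grid.lat_edges[[0, -1]]))
    months = np.repeat(presences["month"].to_numpy(), ratio)
    out_lon = np.empty(n)
    out_lat = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        lon = rng.uniform(lo_lon, hi_lon, m)
        lat = np.degrees(np.arcsin(rng.uniform(s_lo, s_hi, m)))
        ok = domain.contains(lon, lat)
        take = min(int(ok.sum()), n - filled)
        out_lon[filled:filled + take] = lon[ok][:take]
        out_lat[filled:filled + take] = lat[ok][:take]
        filled += take
    return pd.DataFrame({"lon": out_lon, "lat": out_lat, "month": months})


def extract_covariates(presences: pd.DataFrame, absences: pd.DataFrame,
                       stack: CovariateStack, colonies,
                       covariates=MODEL_COVARIATES) -> PresenceAbsenceTable:
    """Attach covariates to presence and pseudo-absence points.

    Static layers are sampled at the containing cell, dynamic layers from
    the layer matching each point's month, CDIST as great-circle distance
    to the nearest colony (CHL is already log-scale in the stack). Rows
    with any missing covariate are dropped and counted.
    """
    parts = []
    for label, pts in ((1, presences), (0, absences)):
        if len(pts) == 0:
            continue
        cov = covariate_frame(stack, pts["lon"].to_numpy(float),
                              pts["lat"].to_numpy(float),
                              pts["month"].to_numpy(), colonies)
        cov = cov[[c for c in covariates if c in cov.columns]]
        block = pd.concat([pts[["lon", "lat", "month"]].reset_index(drop=True), cov], axis=1)
        block.insert(0, "label", label)
        block["animal_id"] = pts["animal_id"].to_numpy() if "animal_id" in pts else None
        parts.append(block)
    table = pd.concat(parts, ignore_index=True)
    cov_cols = [c for c in covariates if c in table.columns]
    complete = table[cov_cols].notna().all(axis=1)
    dropped = int((~complete).sum())
    return PresenceAbsenceTable(data=table[complete].reset_index(drop=True),
                                dropped_missing=dropped)


def variance_inflation_factors(X: pd.DataFrame) -> pd.Series:
    """VIF of each column against all the others (OLS R-squared based)."""
    out = {}
    Xc = X - X.mean()
    for name in X.columns:
        others = Xc.drop(columns=name)
        if others.shape[1] == 0:
            out[name] = 1.0
            continue
        A = np.column_stack([np.ones(len(Xc)), others.to_numpy(float)])
        y = Xc[name].to_numpy(float)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
        out[name] = 1.0 / max(1.0 - r2, 1e-12)
    return pd.Series(out)


def screen_collinearity(table: PresenceAbsenceTable | pd.DataFrame,
                        threshold: float = 0.7,
                        covariates=None) -> tuple[list[str], list[tuple[str, str]]]:
    """Iterative pairwise-correlation screen with VIF tie resolution.

    Finds the pair with the largest |Pearson r|; if above ``threshold``,
    removes the member with the higher VIF against the remaining
    covariates; repeats until no pair exceeds the threshold. Returns
    (retained names, removal log of (removed, partner) pairs).
    """
    df = table.data if isinstance(table, PresenceAbsenceTable) else table
    if covariates is None:
        covariates = (table.covariate_names if isinstance(table, PresenceAbsenceTable)
                      else list(df.columns))
    kept = [c for c in covariates]
    removed: list[tuple[str, str]] = []
    while len(kept) > 1:
        corr = df[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        if corr.values[i, j] <= threshold:
            break
        a, b = kept[i], kept[j]
        vif = variance_inflation_factors(df[kept])
        if abs(vif[a] - vif[b]) > 1e-6 * max(vif[a], vif[b]):
            drop = a if vif[a] > vif[b] else b
        else:
            # VIF tie (e.g. exact duplicates): drop the higher overall
            # correlate, then the alphabetically later name
            ra, rb = corr.loc[a].sum(), corr.loc[b].sum()
            if abs(ra - rb) > 1e-9:
                drop = a if ra > rb else b
            else:
                drop = max(a, b)
        removed.append((drop, b if drop == a else a))
        kept.remove(drop)
    return kept, removed


def build_dataset(tracks, domain: ModelDomain, stack: CovariateStack, colonies,
                  ratio: int = 3, seed: int = 0,
                  covariates=MODEL_COVARIATES) -> PresenceAbsenceTable:
    """Presences from regularized tracks + pseudo-absences + covariates."""
    presences, dropped_outside = presences_from_tracks(tracks, domain)
    absences = sample_pseudo_absences(presences, domain, ratio=ratio, seed=seed)
    tab = extract_covariates(presences, absences, stack, colonies, covariates=covariates)
    tab.dropped_outside = dropped_outside
    return tab
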