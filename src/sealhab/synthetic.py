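"""Synthetic study system: covariate rasters, seal movement, ARGOS noise, fishery.

Every downstream stage (track QC, state-space regularization, habitat
modelling, fishery overlap) is exercised against data produced here, with
known ground truth: a gridded environment containing one island with a
surrounding shelf, seals released from coastal colonies that move by a
biased correlated random walk with a *known* habitat preference, ARGOS
corruption with class-dependent error and planted artefacts, and a krill
fleet clustered on the shelf break.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import CovariateStack, GridSpec, WINTER_MONTHS
from .projection import DEFAULT_PROJECTION, LambertAzimuthalEqualArea, haversine_km

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")


# ---------------------------------------------------------------------------
# error model


@dataclass
class ArgosErrorModel:
    """Class mix, per-class isotropic location error, uplink cadence, spikes.

    ``class_sds_km`` are one-axis Gaussian SDs; the Z class is an invalid
    fix and is given a large nominal error. ``uplink_mean_hours`` of None
    means observations are taken exactly at the true track's time steps
    (no thinning or jitter). ``spike_rate`` is the fraction of interior
    observations displaced far enough that the implied speed from both
    temporal neighbours exceeds 10 m/s.
    """

    class_probabilities: dict[str, float] = field(default_factory=lambda: {
        "3": 0.10, "2": 0.15, "1": 0.20, "0": 0.15, "A": 0.20, "B": 0.15, "Z": 0.05,
    })
    class_sds_km: dict[str, float] = field(default_factory=lambda: {
        "3": 0.25, "2": 0.5, "1": 1.0, "0": 2.0, "A": 2.5, "B": 5.0, "Z": 15.0,
    })
    uplink_mean_hours: float | None = 6.0
    spike_rate: float = 0.0

    def __post_init__(self):
        total = sum(self.class_probabilities.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"class probabilities sum to {total}, expected 1")
        ordered = [self.class_sds_km[c] for c in ("3", "2", "1", "0", "A", "B")]
        if any(sd <= 0 for sd in self.class_sds_km.values()):
            raise ValueError("class SDs must be strictly positive")
        if any(b < a for a, b in zip(ordered, ordered[1:])):
            raise ValueError("class SDs must be non-decreasing from class 3 to B")
        if not 0.0 <= self.spike_rate < 1.0:
            raise ValueError("spike_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# covariate stack


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="nearest")
    s = z.std()
    return z / s if s > 0 else z


def derive_terrain(depth: np.ndarray, grid: GridSpec):
    """Slope (deg), 3x3 slope SD and downslope aspect from a depth raster.

    Gradients are central differences on the metric (metre) scale, with
    east-west spacing shrinking as cos(latitude). Aspect is the compass
    bearing of the downslope direction (0 = facing north, clockwise);
    cells with zero gradient have undefined aspect and are set to NaN.
    """
    if depth.shape[0] < 3 or depth.shape[1] < 3:
        raise ValueError("grid too small to compute slope (need at least 3x3)")
    from .projection import EARTH_RADIUS_KM

    dlat_m = EARTH_RADIUS_KM * 1000.0 * math.radians(grid.cell_deg)
    coslat = np.cos(np.radians(grid.lat_centers))[:, None]
    gy, gx = np.gradient(depth)          # rows (south->north), cols (west->east)
    gy = gy / dlat_m
    gx = gx / (dlat_m * coslat)
    mag = np.hypot(gx, gy)
    slope = np.degrees(np.arctan(mag))
    # downslope direction = -gradient; bearing clockwise from north
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(mag > 1e-12, aspect, np.nan)
    m1 = ndimage.uniform_filter(slope, size=3, mode="nearest")
    m2 = ndimage.uniform_filter(slope**2, size=3, mode="nearest")
    slope_sd = np.sqrt(np.clip(m2 - m1**2, 0.0, None))
    return slope, slope_sd, aspect


def generate_covariate_stack(grid: GridSpec, seed: int,
                             island_frac=(0.45, 0.55),
                             island_radius_km: float = 40.0,
                             shelf_radius_km: float = 100.0) -> CovariateStack:
    """Depth with a contiguous island + shelf, derived terrain, monthly fields.

    The island is a cone rising above sea level at ``island_frac`` of the
    grid extent, so the land region (depth >= 0) is a single disk. Monthly
    SST/CHL/CURL layers vary smoothly from month to month (a fixed spatial
    base plus a seasonal trend and a slowly rotating anomaly field).
    """
    if grid.n_rows < 50 or grid.n_cols < 50:
        raise ValueError("grid too small: need at least 50x50 cells")
    rng = np.random.default_rng(seed)

    lon_c = grid.lon0 + grid.cell_deg * grid.n_cols * island_frac[0]
    lat_c = grid.lat0 + grid.cell_deg * grid.n_rows * island_frac[1]
    glon, glat = np.meshgrid(grid.lon_centers, grid.lat_centers)
    r_km = haversine_km(glon, glat, lon_c, lat_c)
    # local km offsets from the island centre (for anisotropic features)
    dx_km = haversine_km(glon, lat_c, lon_c, lat_c) * np.sign(glon - lon_c)
    dy_km = haversine_km(lon_c, glat, lon_c, lat_c) * np.sign(glat - lat_c)

    base = _smooth_field(rng, (grid.n_rows, grid.n_cols), sigma_cells=5.0)
    # shelf elongated east-west around the island, an offshore rise to the
    # north-west (shallow but far from any colony) and a trough south of
    # the island (deep but close) keep depth and colony distance from
    # being near-duplicates of each other
    r_shelf = np.hypot(dx_km / 1.6, dy_km)
    r_rise_nw = np.hypot(dx_km + 140.0, dy_km - 200.0)
    r_rise_se = np.hypot(dx_km - 180.0, dy_km + 240.0)
    r_trough = np.hypot(dx_km / 1.5, dy_km + 150.0)
    sea = (-3200.0 + 1200.0 * base
           + 2800.0 * np.exp(-0.5 * (r_shelf / shelf_radius_km) ** 2)
           + 3300.0 * np.exp(-0.5 * (r_rise_nw / 130.0) ** 2)
           + 2800.0 * np.exp(-0.5 * (r_rise_se / 110.0) ** 2)
           - 1500.0 * np.exp(-0.5 * (r_trough / 80.0) ** 2))
    # smooth saturation of shallow banks toward -15 m: keeps the seabed
    # strictly below sea level away from the island without creating
    # perfectly flat (undefined-aspect) plateaus
    sea = sea - 30.0 * np.logaddexp(0.0, (sea + 15.0) / 30.0)
    cone = 700.0 * (1.0 - r_km / island_radius_km)
    depth = np.maximum(sea, cone)

    slope, slope_sd, aspect = derive_terrain(depth, grid)
    # islands have no defined aspect either way; keep raster values on land
    static = {"DEPTH": depth, "SLOPE": slope, "SLOPE_SD": slope_sd, "ASPECT": aspect}

    lat_rel = (glat - glat.mean()) / max(glat.max() - glat.min(), 1e-9)
    sst_base = 1.8 + 3.0 * lat_rel + 0.6 * _smooth_field(rng, depth.shape, 6.0)
    chl_base = -0.4 + 0.8 * _smooth_field(rng, depth.shape, 6.0) \
        + 0.8 * np.exp(-0.5 * (r_km / shelf_radius_km) ** 2)
    curl_base = 0.8 * _smooth_field(rng, depth.shape, 7.0)
    anom = {name: _smooth_field(rng, depth.shape, 6.0) for name in ("SST", "CHL", "CURL")}

    dynamic = {"SST": {}, "CHL": {}, "CURL": {}}
    for m in WINTER_MONTHS:
        t = (m - 7.0) / 2.0                       # -1 .. +1 across May..September
        dynamic["SST"][m] = sst_base - 0.8 * t + 0.4 * t * anom["SST"]
        dynamic["CHL"][m] = chl_base - 0.3 * t + 0.3 * t * anom["CHL"]
        dynamic["CURL"][m] = curl_base + 0.3 * t * anom["CURL"]

    return CovariateStack(grid=grid, static=static, dynamic=dynamic)


# ---------------------------------------------------------------------------
# world


@dataclass
class SyntheticWorld:
    """A complete synthetic study system with known habitat preference.

    ``true_preference`` holds log-odds-per-SD weights over covariate names
    (covariates are standardized over sea cells inside the movement
    simulator, so weights are comparable across layers). ``front_line``
    and ``ice_line`` are lon/lat polylines bounding the model domain
    north and south.
    """

    grid: GridSpec
    stack: CovariateStack
    colonies: list[tuple[float, float]]
    true_preference: dict[str, float]
    front_line: list[tuple[float, float]]
    ice_line: list[tuple[float, float]]
    seed: int
    projection: LambertAzimuthalEqualArea = field(default_factory=lambda: DEFAULT_PROJECTION)


def _coastal_sea_cell(stack: CovariateStack, direction: int) -> tuple[float, float]:
    """Centre of the first sea cell walking east/west from the island peak."""
    grid = stack.grid
    land = stack.land_mask
    r0, c0 = np.unravel_index(np.argmax(stack.static["DEPTH"]), land.shape)
    c = c0
    while 0 <= c < grid.n_cols and land[r0, c]:
        c += direction
    c = min(max(c, 0), grid.n_cols - 1)
    return float(grid.lon_centers[c]), float(grid.lat_centers[r0])


def default_world(seed: int = 0, n_rows: int = 60, n_cols: int = 70,
                  cell_deg: float = 0.1,
                  true_preference: dict[str, float] | None = None) -> SyntheticWorld:
    """Build the standard synthetic study system.

    The default preference mimics the documented coastal/shelf affinity of
    post-breeding female fur seals: strong attraction to the colony
    (negative weight on CDIST) and to shallow water (positive weight on
    elevation-convention DEPTH); all other covariates carry no signal.
    """
    grid = GridSpec(lon0=-40.0, lat0=-57.5, cell_deg=cell_deg,
                    n_rows=n_rows, n_cols=n_cols)
    stack = generate_covariate_stack(grid, seed)
    colonies = [_coastal_sea_cell(stack, -1), _coastal_sea_cell(stack, +1)]
    lat_top = grid.lat0 + cell_deg * (n_rows - 1.0)
    lat_bot = grid.lat0 + cell_deg * 1.0
    lon_l, lon_r = grid.lon0 - 1.0, grid.lon0 + cell_deg * n_cols + 1.0
    if true_preference is None:
        true_preference = {"CDIST": -3.0, "DEPTH": 2.5}
    return SyntheticWorld(
        grid=grid, stack=stack, colonies=colonies,
        true_preference=true_preference,
        front_line=[(lon_l, lat_top - 0.2), (lon_r, lat_top + 0.2)],
        ice_line=[(lon_l, lat_bot + 0.1), (lon_r, lat_bot - 0.1)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# movement


def _standardizers(world: SyntheticWorld) -> dict[str, tuple[float, float]]:
    sea = ~world.stack.land_mask
    out = {}
    for name in world.stack.static:
        vals = world.stack.static[name][sea]
        vals = vals[np.isfinite(vals)]
        out[name] = (float(vals.mean()), float(vals.std() + 1e-12))
    for name in world.stack.dynamic:
        vals = np.concatenate([world.stack.dynamic[name][m][sea]
                               for m in world.stack.months])
        out[name] = (float(vals.mean()), float(vals.std() + 1e-12))
    # CDIST standardizer from distances of sea cells to nearest colony
    glon, glat = np.meshgrid(world.grid.lon_centers, world.grid.lat_centers)
    cl = np.array(world.colonies, dtype=float)
    d = haversine_km(glon[sea][:, None], glat[sea][:, None],
                     cl[None, :, 0], cl[None, :, 1]).min(axis=1)
    out["CDIST"] = (float(d.mean()), float(d.std() + 1e-12))
    return out


def simulate_seal_tracks(world: SyntheticWorld, n_seals: int,
                         duration_days: float = 150.0, step_hours: float = 3.0,
                         seed: int = 0, year: int = 1999,
                         start: str = "colony",
                         step_km_mean: float = 10.0,
                         persistence: float = 3.0) -> list[pd.DataFrame]:
    """Biased correlated random walks over the covariate field.

    At each step a fan of candidate headings is scored by the planted
    preference (log-odds over standardized covariates at the candidate
    endpoint) plus a directional-persistence bonus, and the destination is
    drawn from the softmax of those scores. Candidates on land or outside
    the grid are inadmissible, so tracks never occupy land cells.

    Returns one DataFrame per seal with regular ``step_hours`` timestamps
    and both projected (km) and geographic coordinates.
    """
    if n_seals == 0:
        return []
    if not world.colonies:
        raise ValueError("world has no colonies to release seals from")
    rng = np.random.default_rng(seed)
    proj = world.projection
    stds = _standardizers(world)
    weights = {k: v for k, v in world.true_preference.items() if v != 0.0}
    headings = np.linspace(-np.pi, np.pi, 16, endpoint=False)
    n_steps = int(round(duration_days * 24.0 / step_hours))
    t0 = pd.Timestamp(year=year, month=5, day=1, tz="UTC")
    times = t0 + pd.to_timedelta(np.arange(n_steps + 1) * step_hours, unit="h")
    months = times.month.to_numpy()

    sea = ~world.stack.land_mask
    sea_rows, sea_cols = np.nonzero(sea)
    cl = np.array(world.colonies, dtype=float)

    tracks = []
    for s in range(n_seals):
        if start == "colony":
            lon0, lat0 = world.colonies[s % len(world.colonies)]
        elif start == "random":
            i = rng.integers(len(sea_rows))
            lon0 = float(world.grid.lon_centers[sea_cols[i]])
            lat0 = float(world.grid.lat_centers[sea_rows[i]])
        else:
            raise ValueError(f"unknown start mode {start!r}")
        x, y = proj.forward(lon0, lat0)
        pos = np.array([float(x), float(y)])
        theta = rng.uniform(-np.pi, np.pi)
        xs = np.empty(n_steps + 1)
        ys = np.empty(n_steps + 1)
        xs[0], ys[0] = pos
        for i in range(1, n_steps + 1):
            L = rng.gamma(4.0, step_km_mean / 4.0)
            cand_theta = theta + headings
            cx = pos[0] + L * np.cos(cand_theta)
            cy = pos[1] + L * np.sin(cand_theta)
            clon, clat = proj.inverse(cx, cy)
            ok = world.grid.contains(clon, clat) & ~world.stack.is_land(clon, clat)
            score = persistence * np.cos(headings)
            if weights:
                month = int(months[i])
                z = np.zeros(len(headings))
                for name, w in weights.items():
                    if name == "CDIST":
                        vals = haversine_km(clon[:, None], clat[:, None],
                                            cl[None, :, 0], cl[None, :, 1]).min(axis=1)
                    elif name in world.stack.static:
                        vals = world.stack.sample(name, clon, clat)
                    else:
                        vals = world.stack.sample(name, clon, clat, month=month)
                    mu, sd = stds[name]
                    z = z + w * (np.nan_to_num(vals, nan=mu) - mu) / sd
                score = score + z
            score = np.where(ok, score, -np.inf)
            if not ok.any():
                xs[i], ys[i] = pos       # boxed in: rest in place
                continue
            p = np.exp(score - score[ok].max())
            p[~ok] = 0.0
            p /= p.sum()
            j = rng.choice(len(headings), p=p)
            pos = np.array([cx[j], cy[j]])
            theta = cand_theta[j]
            xs[i], ys[i] = pos
        lon, lat = proj.inverse(xs, ys)
        tracks.append(pd.DataFrame({
            "animal_id": f"SIM{s:03d}", "timestamp": times,
            "lon": lon, "lat": lat, "x_km": xs, "y_km": ys,
        }))
    return tracks


# ---------------------------------------------------------------------------
# ARGOS corruption

VMAX_KMH = 36.0   # 10 m/s, the plausibility limit the QC stage enforces


def argosify(true_track: pd.DataFrame, error_model: ArgosErrorModel,
             seed: int = 0,
             projection: LambertAzimuthalEqualArea = DEFAULT_PROJECTION) -> pd.DataFrame:
    """Corrupt a true track into ARGOS-like records.

    Observation times are drawn with exponential inter-uplink gaps (mean
    ``uplink_mean_hours``) and the true position linearly interpolated in
    the projected plane; a location class is sampled per record and the
    position perturbed with the class SD. A ``spike_rate`` fraction of
    interior records is displaced far enough that the implied speed to
    both neighbours exceeds 10 m/s. Provenance flags ``is_spike`` and
    ``is_Z`` are carried for test assertions.
    """
    rng = np.random.default_rng(seed)
    t = (true_track["timestamp"] - true_track["timestamp"].iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    if "x_km" in true_track:
        tx = true_track["x_km"].to_numpy(float)
        ty = true_track["y_km"].to_numpy(float)
    else:
        tx, ty = projection.forward(true_track["lon"].to_numpy(float),
                                    true_track["lat"].to_numpy(float))

    if error_model.uplink_mean_hours is None:
        obs_t = t.copy()
    else:
        gaps = rng.exponential(error_model.uplink_mean_hours, size=max(16, int(4 * t[-1])))
        obs_t = np.concatenate([[0.0], np.cumsum(gaps)])
        obs_t = obs_t[obs_t <= t[-1]]
    ox = np.interp(obs_t, t, tx)
    oy = np.interp(obs_t, t, ty)
    n = len(obs_t)

    classes = list(error_model.class_probabilities)
    probs = np.array([error_model.class_probabilities[c] for c in classes])
    lc = rng.choice(classes, size=n, p=probs)
    sds = np.array([error_model.class_sds_km[c] for c in lc])
    ox = ox + rng.normal(0.0, 1.0, n) * sds
    oy = oy + rng.normal(0.0, 1.0, n) * sds

    is_spike = np.zeros(n, dtype=bool)
    if error_model.spike_rate > 0 and n >= 3:
        interior = np.arange(1, n - 1)
        is_spike[interior] = rng.random(len(interior)) < error_model.spike_rate
        # spikes are never planted on or next to an invalid (Z) fix: once
        # the Z record is dropped upstream the widened gap would void the
        # planted speed guarantee
        near_z = (lc == "Z")
        near_z[:-1] |= lc[1:] == "Z"
        near_z[1:] |= lc[:-1] == "Z"
        is_spike &= ~near_z
        for i in np.nonzero(is_spike)[0]:
            dtp = obs_t[i] - obs_t[i - 1]
            dtn = obs_t[i + 1] - obs_t[i]
            dprev = math.hypot(ox[i] - ox[i - 1], oy[i] - oy[i - 1])
            dnext = math.hypot(ox[i + 1] - ox[i], oy[i + 1] - oy[i])
            # displacement guaranteeing > vmax implied speed on both sides
            D = 2.0 * VMAX_KMH * (dtp + dtn) + dprev + dnext
            ang = rng.uniform(-np.pi, np.pi)
            ox[i] += D * math.cos(ang)
            oy[i] += D * math.sin(ang)

    lon, lat = projection.inverse(ox, oy)
    stamps = true_track["timestamp"].iloc[0] + pd.to_timedelta(obs_t, unit="h")
    return pd.DataFrame({
        "animal_id": true_track["animal_id"].iloc[0],
        "timestamp": stamps, "lon": lon, "lat": lat, "lc": lc,
        "is_spike": is_spike, "is_Z": lc == "Z",
    })


# ---------------------------------------------------------------------------
# fishery


def simulate_fishery(world: SyntheticWorld, n_hauls: int, seed: int = 0,
                     year: int = 2003, depth_band=(-2000.0, -200.0),
                     cell_mask: np.ndarray | None = None,
                     catch_logmean: float = 2.8,
                     catch_logsd: float = 0.7) -> pd.DataFrame:
    """Krill hauls clustered on the synthetic shelf break.

    Haul start positions fall in sea cells whose depth lies in
    ``depth_band`` (optionally further restricted by ``cell_mask``), with
    dates uniform over the May-September season of ``year`` and catches
    log-normal in tonnes.
    """
    if n_hauls == 0:
        return pd.DataFrame(columns=["date", "lon", "lat", "catch_t", "gear"])
    rng = np.random.default_rng(seed)
    grid = world.grid
    depth = world.stack.static["DEPTH"]
    eligible = (depth < 0) & (depth >= depth_band[0]) & (depth <= depth_band[1])
    if cell_mask is not None:
        eligible &= cell_mask
    rows, cols = np.nonzero(eligible)
    if len(rows) == 0:
        raise ValueError("no sea cells in the requested depth band")
    idx = rng.integers(len(rows), size=n_hauls)
    u = rng.uniform(0.05, 0.95, size=(n_hauls, 2))
    lon = grid.lon0 + grid.cell_deg * (cols[idx] + u[:, 0])
    lat = grid.lat0 + grid.cell_deg * (rows[idx] + u[:, 1])
    day = rng.integers(0, 153, size=n_hauls)       # days within May 1 .. Sep 30
    dates = pd.Timestamp(year=year, month=5, day=1) + pd.to_timedelta(day, unit="D")
    catch = rng.lognormal(catch_logmean, catch_logsd, size=n_hauls)
    gear = np.where(rng.random(n_hauls) < 0.8, "conventional", "continuous")
    return pd.DataFrame({"date": dates, "lon": lon, "lat": lat,
                         "catch_t": catch, "gear": gear})
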