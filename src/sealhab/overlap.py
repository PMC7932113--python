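"""Spatial prediction surfaces, probability thresholds and fishery overlap.

The selected habitat model is applied over every domain cell with CDIST
substituted by distance to the *nearest of all supplied colonies* (not
just the tagging site), giving a probability-of-occurrence surface.
Masks at the >0.50 and >0.95 probability levels (strict) define the
predicted core habitat; overlap with the krill fleet is summarised as
the fishery footprint (area of mask cells containing at least one haul
start), the catch taken inside the mask, and both as percentages of the
modelled (mask) area and of a reference total catch. A catch-weighted
Gaussian kernel density on the projected plane illustrates the fleet's
spatial concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ModelDomain
from .gam import HabitatModel
from .grids import CovariateStack, covariate_frame
from .projection import DEFAULT_PROJECTION

THRESHOLD_LEVELS = (0.50, 0.95)


@dataclass
class PredictionSurface:
    """Predicted probability of occurrence per domain cell (NaN = blank)."""

    domain: ModelDomain
    probabilities: np.ndarray      # (n_rows, n_cols), NaN outside/blank
    month: int | str = "pooled"
    n_blank: int = 0


@dataclass
class ThresholdMask:
    """Cells with predicted probability strictly above ``level``."""

    level: float
    mask: np.ndarray
    area_km2: float
    grid_resolution_km: float


@dataclass
class OverlapSummary:
    """Fishery overlap statistics for one threshold mask."""

    level: float
    model_area_km2: float
    footprint_km2: float
    catch_within_t: float
    total_catch_t: float
    footprint_pct_of_model_area: float
    catch_pct_of_total: float
    n_hauls_within: int
    n_hauls_outside_grid: int
    grid_resolution_km: float


def predict_surface(model: HabitatModel, stack: CovariateStack, colonies,
                    domain: ModelDomain, month="pooled") -> PredictionSurface:
    """Apply the model over the domain grid.

    ``month`` selects the dynamic covariate layer; ``"pooled"`` uses the
    across-month mean layer (the single-surface-per-period convention).
    Cells with any missing covariate are left blank (NaN) and never count
    toward areas.
    """
    grid = domain.grid
    rows, cols = np.nonzero(domain.mask)
    lon = grid.lon_centers[cols]
    lat = grid.lat_centers[rows]
    if month == "pooled":
        pooled = CovariateStack(
            grid=grid,
            static={**stack.static,
                    **{name: stack.monthly_mean(name) for name in stack.dynamic}},
            dynamic={}, months=stack.months)
        cov = covariate_frame(pooled, lon, lat, None, colonies)
    else:
        cov = covariate_frame(stack, lon, lat, int(month), colonies)
    needed = [c for c in model.covariates]
    ok = cov[needed].notna().all(axis=1).to_numpy() if needed else np.ones(len(cov), bool)
    probs = np.full(grid.cell_areas_km2().shape, np.nan)
    if ok.any():
        probs[rows[ok], cols[ok]] = model.predict(cov[ok])
    return PredictionSurface(domain=domain, probabilities=probs, month=month,
                             n_blank=int((~ok).sum()))


def threshold_mask(surface: PredictionSurface, level: float) -> ThresholdMask:
    """Cells strictly above ``level``; area from spherical cell areas."""
    with np.errstate(invalid="ignore"):
        mask = surface.probabilities > level
    areas = surface.domain.grid.cell_areas_km2()
    return ThresholdMask(level=level, mask=mask,
                         area_km2=float(areas[mask].sum()),
                         grid_resolution_km=float(np.sqrt(areas.mean())))


def overlap_summary(mask: ThresholdMask, hauls: pd.DataFrame,
                    domain: ModelDomain,
                    total_catch_reference: float | None = None) -> OverlapSummary:
    """Table-style overlap statistics between a mask and a haul record set.

    Hauls are assigned to grid cells by start position. The fishery
    footprint is the area of mask cells containing at least one haul;
    catch-within sums the catch of hauls in mask cells. Hauls outside
    the grid count toward total catch only. With no reference given, the
    percentage base is the total catch of ``hauls``.
    """
    grid = domain.grid
    areas = grid.cell_areas_km2()
    total_catch = float(hauls["catch_t"].sum()) if len(hauls) else 0.0
    reference = total_catch_reference if total_catch_reference is not None else total_catch
    if len(hauls) == 0:
        return OverlapSummary(level=mask.level, model_area_km2=mask.area_km2,
                              footprint_km2=0.0, catch_within_t=0.0,
                              total_catch_t=0.0, footprint_pct_of_model_area=0.0,
                              catch_pct_of_total=0.0, n_hauls_within=0,
                              n_hauls_outside_grid=0,
                              grid_resolution_km=mask.grid_resolution_km)
    row, col = grid.cell_index(hauls["lon"].to_numpy(float),
                               hauls["lat"].to_numpy(float))
    ingrid = row >= 0
    inmask = np.zeros(len(hauls), dtype=bool)
    inmask[ingrid] = mask.mask[row[ingrid], col[ingrid]]
    cells = set(zip(row[inmask].tolist(), col[inmask].tolist()))
    footprint = float(sum(areas[r, c] for r, c in cells))
    catch_within = float(hauls.loc[inmask, "catch_t"].sum())
    return OverlapSummary(
        level=mask.level, model_area_km2=mask.area_km2,
        footprint_km2=footprint, catch_within_t=catch_within,
        total_catch_t=total_catch,
        footprint_pct_of_model_area=(100.0 * footprint / mask.area_km2
                                     if mask.area_km2 > 0 else 0.0),
        catch_pct_of_total=(100.0 * catch_within / reference if reference > 0 else 0.0),
        n_hauls_within=int(inmask.sum()),
        n_hauls_outside_grid=int((~ingrid).sum()),
        grid_resolution_km=mask.grid_resolution_km)


def catch_kernel_density(hauls: pd.DataFrame, domain: ModelDomain,
                         bandwidth_km: float = 25.0,
                         projection=DEFAULT_PROJECTION) -> np.ndarray:
    """Catch-weighted 2-D Gaussian kernel density on the domain grid.

    Returns tonnes per km^2 per cell; the integral over the grid equals
    the total catch up to the mass lying outside the grid's extent.
    """
    grid = domain.grid
    glon, glat = np.meshgrid(grid.lon_centers, grid.lat_centers)
    gx, gy = projection.forward(glon.ravel(), glat.ravel())
    hx, hy = projection.forward(hauls["lon"].to_numpy(float),
                                hauls["lat"].to_numpy(float))
    w = hauls["catch_t"].to_numpy(float)
    h2 = bandwidth_km**2
    d2 = (gx[:, None] - hx[None, :])**2 + (gy[:, None] - hy[None, :])**2
    dens = (np.exp(-0.5 * d2 / h2) @ w) / (2.0 * np.pi * h2)
    return dens.reshape(glat.shape)
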