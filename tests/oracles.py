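"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately written from first principles (joint
multivariate-normal construction, exhaustive pair counting, per-haul
loops) and shares no code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal

from sealhab.ctcrw import initial_state, transition_matrices


def mvn_joint(times, beta, sigma, x0):
    """Joint mean/covariance of the latent states at the given times."""
    n = len(times)
    m0, P0 = initial_state(beta, sigma, x0)
    means = np.empty((n, 2))
    covs = np.zeros((n, n, 2, 2))
    means[0] = m0
    covs[0, 0] = P0
    for i in range(1, n):
        T, Q = transition_matrices(beta, sigma, times[i] - times[i - 1])
        means[i] = T @ means[i - 1]
        covs[i, i] = T @ covs[i - 1, i - 1] @ T.T + Q
        for j in range(i):
            covs[i, j] = T @ covs[i - 1, j]
            covs[j, i] = covs[i, j].T
    return means, covs


def mvn_loglik_axis(times, obs, sds, beta, sigma):
    """Log-density of one axis's observations from the joint MVN."""
    means, covs = mvn_joint(times, beta, sigma, obs[0])
    n = len(times)
    C = np.array([[covs[i, j][0, 0] for j in range(n)] for i in range(n)])
    C = C + np.diag(np.asarray(sds, dtype=float) ** 2)
    return float(multivariate_normal.logpdf(obs, mean=means[:, 0], cov=C))


def mvn_smoothed_positions_axis(times, obs, sds, beta, sigma):
    """Conditional mean of latent positions given all observations."""
    means, covs = mvn_joint(times, beta, sigma, obs[0])
    n = len(times)
    Cpp = np.array([[covs[i, j][0, 0] for j in range(n)] for i in range(n)])
    Cyy = Cpp + np.diag(np.asarray(sds, dtype=float) ** 2)
    mu = means[:, 0]
    return mu + Cpp @ np.linalg.solve(Cyy, obs - mu)


def auc_pair_fraction(scores, labels):
    """AUC as exhaustive concordant-pair fraction with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def overlap_by_haul_loop(mask, grid, hauls, reference):
    """Per-haul loop: footprint area, catch inside the mask, percentages."""
    areas = grid.cell_areas_km2()
    cells = set()
    catch_in = 0.0
    for _, h in hauls.iterrows():
        row, col = grid.cell_index(h["lon"], h["lat"])
        row, col = int(row), int(col)
        if row < 0:
            continue
        if mask[row, col]:
            cells.add((row, col))
            catch_in += float(h["catch_t"])
    footprint = sum(float(areas[r, c]) for r, c in cells)
    return footprint, catch_in, 100.0 * catch_in / reference if reference > 0 else 0.0


def central_difference_slope(depth, grid, row, col):
    """Slope in degrees at one interior cell by direct central differences."""
    from sealhab.projection import EARTH_RADIUS_KM

    dlat_m = EARTH_RADIUS_KM * 1000.0 * np.radians(grid.cell_deg)
    dlon_m = dlat_m * np.cos(np.radians(grid.lat_centers[row]))
    gy = (depth[row + 1, col] - depth[row - 1, col]) / (2.0 * dlat_m)
    gx = (depth[row, col + 1] - depth[row, col - 1]) / (2.0 * dlon_m)
    return float(np.degrees(np.arctan(np.hypot(gx, gy))))
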