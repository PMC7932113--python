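"""Continuous-time correlated random walk (CTCRW) track regularization.

The movement model is the integrated Ornstein-Uhlenbeck process: per
axis, velocity follows dv = -beta * v dt + sigma dW and position is its
integral. Observations are the projected ARGOS positions with a fixed,
class-dependent isotropic measurement SD. An exact Kalman filter over
the irregular uplink times gives the Gaussian likelihood; (beta, sigma)
are estimated per track segment by quasi-Newton optimisation on the log
scale, and a Kalman (RTS) smoother emits positions on a regular 3-hour
grid - the "presence" points used by the habitat models.

The stationary velocity SD is sigma / sqrt(2 * beta); beta has units
1/h, sigma km h^-3/2, positions km in the study's equal-area plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .projection import DEFAULT_PROJECTION, LambertAzimuthalEqualArea

#: Fixed per-class one-axis measurement SDs (km), of the order of
#: published ARGOS error calibrations; configurable everywhere.
DEFAULT_CLASS_SDS = {"3": 0.3, "2": 0.5, "1": 1.0, "0": 3.0, "A": 5.0, "B": 10.0}

MIN_OBS_TO_FIT = 10


@dataclass
class CtcrwParams:
    """Fitted CTCRW parameters for one track segment."""

    beta: float                  # velocity autocorrelation decay (1/h)
    sigma: float                 # velocity process scale (km h^-1.5)
    class_sds: dict[str, float]
    log_likelihood: float = np.nan
    converged: bool = True
    grad_norm: float = np.nan

    def __post_init__(self):
        if self.beta <= 0 or self.sigma <= 0:
            raise ValueError("beta and sigma must be strictly positive")


@dataclass
class RegularizedTrack:
    """Smoothed positions at a fixed step for one segment."""

    animal_id: str
    segment_id: int
    data: pd.DataFrame           # timestamp, x_km, y_km, var_x, var_y, lon, lat
    modelled: bool = True
    params: CtcrwParams | None = None


# ---------------------------------------------------------------------------
# state-space matrices


def transition_matrices(beta: float, sigma: float, dt: float):
    """Discrete transition T and innovation covariance Q for a gap dt (h)."""
    e = np.exp(-beta * dt)
    e2 = np.exp(-2.0 * beta * dt)
    T = np.array([[1.0, (1.0 - e) / beta],
                  [0.0, e]])
    s2 = sigma**2
    qvv = s2 / (2.0 * beta) * (1.0 - e2)
    qxv = s2 / (2.0 * beta**2) * (1.0 - 2.0 * e + e2)
    qxx = s2 / beta**2 * (dt - 2.0 * (1.0 - e) / beta + (1.0 - e2) / (2.0 * beta))
    Q = np.array([[qxx, qxv],
                  [qxv, qvv]])
    return T, Q


def initial_state(beta: float, sigma: float, x0: float,
                  pos_sd_km: float = 100.0):
    """Diffuse position prior centred on the first fix; stationary velocity."""
    m = np.array([x0, 0.0])
    P = np.diag([pos_sd_km**2, sigma**2 / (2.0 * beta)])
    return m, P


def _filter_one_axis(times, obs, obs_var, has_obs, beta, sigma, smooth=False):
    """Kalman filter (and optional RTS smoother) on one coordinate axis.

    ``obs``/``obs_var`` are aligned with ``times``; entries where
    ``has_obs`` is False are skipped (prediction only). Returns
    (loglik, smoothed_mean, smoothed_var) - the latter two are the
    filtered quantities when ``smooth`` is False.
    """
    n = len(times)
    first = int(np.argmax(has_obs))
    m, P = initial_state(beta, sigma, obs[first])
    loglik = 0.0
    mf = np.empty((n, 2))
    Pf = np.empty((n, 2, 2))
    mp = np.empty((n, 2))
    Pp = np.empty((n, 2, 2))
    Ts = np.empty((n, 2, 2))
    for i in range(n):
        if i > 0:
            T, Q = transition_matrices(beta, sigma, times[i] - times[i - 1])
            m = T @ m
            P = T @ P @ T.T + Q
            Ts[i] = T
        mp[i], Pp[i] = m, P
        if has_obs[i]:
            S = P[0, 0] + obs_var[i]
            innov = obs[i] - m[0]
            loglik += -0.5 * (np.log(2.0 * np.pi * S) + innov * innov / S)
            K = P[:, 0] / S
            m = m + K * innov
            P = P - np.outer(K, P[0, :])
            P = 0.5 * (P + P.T)
        mf[i], Pf[i] = m, P
    if not smooth:
        return loglik, mf[:, 0], Pf[:, 0, 0]
    ms = mf.copy()
    Ps = Pf.copy()
    for i in range(n - 2, -1, -1):
        C = Pf[i] @ Ts[i + 1].T @ np.linalg.inv(Pp[i + 1])
        ms[i] = mf[i] + C @ (ms[i + 1] - mp[i + 1])
        Ps[i] = Pf[i] + C @ (Ps[i + 1] - Pp[i + 1]) @ C.T
    return loglik, ms[:, 0], np.clip(Ps[:, 0, 0], 0.0, None)


# ---------------------------------------------------------------------------
# public operations


def _segment_arrays(segment: pd.DataFrame, class_sds):
    t = pd.DatetimeIndex(segment["timestamp"]).asi8 / 3.6e12   # hours
    t = t - t[0]
    x = segment["x_km"].to_numpy(float)
    y = segment["y_km"].to_numpy(float)
    sd = segment["lc"].astype(str).map(class_sds).to_numpy(float)
    if np.isnan(sd).any():
        raise ValueError("segment contains a class with no measurement SD")
    return t, x, y, sd


def ctcrw_loglik(params: CtcrwParams, segment: pd.DataFrame) -> float:
    """Exact Gaussian log-likelihood of a projected segment.

    ``segment`` needs columns timestamp, x_km, y_km, lc and at least
    three observations. The two axes are independent, so the total is
    the sum of the per-axis Kalman log-likelihoods.
    """
    if len(segment) < 3:
        raise ValueError("need at least 3 observations")
    t, x, y, sd = _segment_arrays(segment, params.class_sds)
    has = np.ones(len(t), dtype=bool)
    ll_x, _, _ = _filter_one_axis(t, x, sd**2, has, params.beta, params.sigma)
    ll_y, _, _ = _filter_one_axis(t, y, sd**2, has, params.beta, params.sigma)
    return float(ll_x + ll_y)


def fit_ctcrw(segment: pd.DataFrame, class_sds=None,
              init: tuple[float, float] | None = None,
              beta_starts=(0.1, 1.0, 5.0)) -> CtcrwParams | None:
    """Maximum-likelihood (beta, sigma) for one segment.

    Optimises on the (log beta, log sigma) scale with L-BFGS-B from
    multiple beta starts. Segments with fewer than 10 observations are
    not modelled: returns None (caller passes them through flagged).
    """
    if class_sds is None:
        class_sds = DEFAULT_CLASS_SDS
    if len(segment) < MIN_OBS_TO_FIT:
        warnings.warn(f"segment with {len(segment)} obs passed through unmodelled")
        return None
    t, x, y, sd = _segment_arrays(segment, class_sds)
    has = np.ones(len(t), dtype=bool)
    var = sd**2

    def nll(theta):
        beta = float(np.exp(np.clip(theta[0], -10.0, 6.0)))
        sigma = float(np.exp(np.clip(theta[1], -10.0, 8.0)))
        ll_x, _, _ = _filter_one_axis(t, x, var, has, beta, sigma)
        ll_y, _, _ = _filter_one_axis(t, y, var, has, beta, sigma)
        return -(ll_x + ll_y)

    # crude velocity-scale guess for sigma at each beta start
    dt = np.diff(t)
    good = dt > 0
    vels = np.hypot(np.diff(x), np.diff(y))[good] / dt[good]
    vel_scale = max(float(np.median(vels)), 1e-3)

    starts = []
    if init is not None:
        starts.append((np.log(init[0]), np.log(init[1])))
    for b0 in beta_starts:
        starts.append((np.log(b0), np.log(vel_scale * np.sqrt(2.0 * b0))))

    best = None
    for s in starts:
        res = optimize.minimize(nll, np.asarray(s), method="L-BFGS-B",
                                options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    beta = float(np.exp(np.clip(best.x[0], -10.0, 6.0)))
    sigma = float(np.exp(np.clip(best.x[1], -10.0, 8.0)))
    return CtcrwParams(beta=beta, sigma=sigma, class_sds=dict(class_sds),
                       log_likelihood=float(-best.fun), converged=bool(best.success),
                       grad_norm=float(np.linalg.norm(getattr(best, "jac", np.nan))))


def predict_positions(params: CtcrwParams, segment: pd.DataFrame,
                      step_hours: float = 3.0,
                      projection: LambertAzimuthalEqualArea = DEFAULT_PROJECTION,
                      animal_id: str | None = None,
                      segment_id: int = 0) -> RegularizedTrack:
    """Kalman-smoothed positions on the regular grid spanning the segment.

    The smoother runs over the union of observation times and the grid
    (first observation + k * step, within the segment span); only grid
    times are returned, with per-axis smoothing variances.
    """
    t, x, y, sd = _segment_arrays(segment, params.class_sds)
    t_grid = np.arange(0.0, t[-1] + 1e-9, step_hours)
    all_t = np.unique(np.concatenate([t, t_grid]))
    # map observations onto the union timeline
    has = np.zeros(len(all_t), dtype=bool)
    ox = np.zeros(len(all_t))
    oy = np.zeros(len(all_t))
    ovar = np.zeros(len(all_t))
    idx = np.searchsorted(all_t, t)
    has[idx] = True
    ox[idx], oy[idx], ovar[idx] = x, y, sd**2
    _, sx, vx = _filter_one_axis(all_t, ox, ovar, has, params.beta, params.sigma, smooth=True)
    _, sy, vy = _filter_one_axis(all_t, oy, ovar, has, params.beta, params.sigma, smooth=True)
    gi = np.searchsorted(all_t, t_grid)
    lon, lat = projection.inverse(sx[gi], sy[gi])
    stamps = segment["timestamp"].iloc[0] + pd.to_timedelta(t_grid, unit="h")
    data = pd.DataFrame({"timestamp": stamps, "x_km": sx[gi], "y_km": sy[gi],
                         "var_x": vx[gi], "var_y": vy[gi], "lon": lon, "lat": lat})
    if animal_id is None and "animal_id" in segment:
        animal_id = str(segment["animal_id"].iloc[0])
    return RegularizedTrack(animal_id=animal_id or "", segment_id=segment_id,
                            data=data, modelled=True, params=params)


def regularize_segments(segments, class_sds=None, step_hours: float = 3.0,
                        projection: LambertAzimuthalEqualArea = DEFAULT_PROJECTION):
    """Fit and smooth every QC'd segment; short segments pass through flagged.

    ``segments`` is the output of :func:`sealhab.telemetry.clean_tracks`.
    Returns a list of :class:`RegularizedTrack`.
    """
    if class_sds is None:
        class_sds = DEFAULT_CLASS_SDS
    out = []
    for seg in segments:
        rec = seg.records.copy()
        xs, ys = projection.forward(rec["lon"].to_numpy(float), rec["lat"].to_numpy(float))
        rec["x_km"], rec["y_km"] = xs, ys
        if len(rec) < MIN_OBS_TO_FIT:
            data = rec[["timestamp", "x_km", "y_km", "lon", "lat"]].copy()
            data["var_x"] = np.nan
            data["var_y"] = np.nan
            out.append(RegularizedTrack(animal_id=seg.animal_id,
                                        segment_id=seg.segment_id,
                                        data=data, modelled=False, params=None))
            continue
        params = fit_ctcrw(rec, class_sds=class_sds)
        if params is None or not np.isfinite(params.log_likelihood):
            warnings.warn(f"segment {seg.animal_id}/{seg.segment_id} not modelled")
            continue
        out.append(predict_positions(params, rec, step_hours=step_hours,
                                     projection=projection,
                                     animal_id=seg.animal_id,
                                     segment_id=seg.segment_id))
    return out


# ---------------------------------------------------------------------------
# simulation (ground truth for tests and recovery studies)


def simulate_ctcrw(beta: float, sigma: float, times_hours, seed: int = 0,
                   x0=(0.0, 0.0)) -> pd.DataFrame:
    """Exact draw of the CTCRW at arbitrary times (both axes).

    Velocity starts in its stationary distribution. Returns a DataFrame
    with columns t_hours, x_km, y_km (noise-free true positions).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times_hours, dtype=float)
    vel_sd = sigma / np.sqrt(2.0 * beta)
    state = np.array([[x0[0], rng.normal(0, vel_sd)],
                      [x0[1], rng.normal(0, vel_sd)]])   # (axis, [pos, vel])
    xs = np.empty((len(t), 2))
    xs[0] = state[:, 0]
    for i in range(1, len(t)):
        T, Q = transition_matrices(beta, sigma, t[i] - t[i - 1])
        L = np.linalg.cholesky(Q + 1e-12 * np.eye(2))
        for axis in range(2):
            state[axis] = T @ state[axis] + L @ rng.standard_normal(2)
        xs[i] = state[:, 0]
    return pd.DataFrame({"t_hours": t, "x_km": xs[:, 0], "y_km": xs[:, 1]})
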