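"""Binomial GAMs with shrinkage splines, blocked CV and stepwise selection.

Habitat preference is modelled as presence/pseudo-absence ~ s(x1) + ...
+ s(xp) with a logit link. Each smooth is a cubic regression spline with
k = 4 knots placed at quantiles, penalized by its integrated squared
second derivative; the penalty's null space (constant + linear parts)
receives a small additional eigenvalue so that a large smoothing
parameter can shrink a smooth entirely to zero (soft variable
selection). Smoothing parameters minimise an AIC/UBRE-type prediction
criterion, fitted by penalized IRLS.

Evaluation follows the month-blocked scheme used for winter telemetry:
for each calendar month the model is trained on that month alone and
scored on all remaining months; AUC is the rank (Mann-Whitney)
statistic with half-credit ties, and sensitivity/specificity are taken
at the Youden-optimal threshold by default. Forward stepwise selection
adds the covariate that most improves the aggregate cross-validated AUC
and stops when no candidate improves it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import rankdata

DEFAULT_K = 4
STEPWISE_TOL = 1e-4


# ---------------------------------------------------------------------------
# cubic regression spline basis


class CubicRegressionSpline:
    """Natural cubic regression spline parameterized by values at knots.

    The basis follows the classic knot-value parameterization: the j-th
    basis function is the natural cubic spline interpolating 1 at knot j
    and 0 elsewhere. The wiggliness penalty is the exact integrated
    squared second derivative, S = D' B^-1 D; with ``shrinkage`` the two
    zero eigenvalues of S (its constant/linear null space) are raised to
    a small fraction of the smallest positive eigenvalue, so the whole
    smooth can be penalized to zero. Evaluation extends linearly beyond
    the boundary knots.
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if len(knots) < 3 or np.any(np.diff(knots) <= 0):
            raise ValueError("need >= 3 strictly increasing knots")
        self.knots = knots
        k = len(knots)
        h = np.diff(knots)
        D = np.zeros((k - 2, k))
        B = np.zeros((k - 2, k - 2))
        for i in range(k - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        Binv = np.linalg.inv(B)
        self._F = np.zeros((k, k))            # maps knot values -> 2nd derivs
        self._F[1:-1] = Binv @ D
        self.S = D.T @ Binv @ D

    @classmethod
    def from_data(cls, x: np.ndarray, k: int = DEFAULT_K) -> "CubicRegressionSpline":
        """Knots at evenly spaced quantiles of the unique data values."""
        ux = np.unique(x[np.isfinite(x)])
        if len(ux) < k:
            raise ValueError(f"covariate has {len(ux)} unique values; need >= {k}")
        knots = np.quantile(ux, np.linspace(0.0, 1.0, k))
        knots = np.unique(knots)
        if len(knots) < 3:
            raise ValueError("degenerate knot sequence")
        return cls(knots)

    def design(self, x) -> np.ndarray:
        """Evaluate the k basis functions at x (n x k)."""
        x = np.asarray(x, dtype=float)
        kts, F = self.knots, self._F
        k = len(kts)
        h = np.diff(kts)
        X = np.zeros((len(x), k))
        inside = (x >= kts[0]) & (x <= kts[-1])
        xi = x[inside]
        j = np.clip(np.searchsorted(kts, xi, side="right") - 1, 0, k - 2)
        hj = h[j]
        lo = (kts[j + 1] - xi)
        hi = (xi - kts[j])
        a_lo = lo / hj
        a_hi = hi / hj
        c_lo = (lo**3 / hj - hj * lo) / 6.0
        c_hi = (hi**3 / hj - hj * hi) / 6.0
        rows = np.zeros((len(xi), k))
        ar = np.arange(len(xi))
        rows[ar, j] += a_lo
        rows[ar, j + 1] += a_hi
        rows += c_lo[:, None] * F[j] + c_hi[:, None] * F[j + 1]
        X[inside] = rows
        # linear extension beyond the boundary knots
        left = x < kts[0]
        if left.any():
            e0 = np.zeros(k); e0[0] = 1.0
            e1 = np.zeros(k); e1[1] = 1.0
            slope = (e1 - e0) / h[0] - h[0] / 6.0 * F[1]
            X[left] = e0 + (x[left] - kts[0])[:, None] * slope
        right = x > kts[-1]
        if right.any():
            em = np.zeros(k); em[-1] = 1.0
            ep = np.zeros(k); ep[-2] = 1.0
            slope = (em - ep) / h[-1] + h[-1] / 6.0 * F[-2]
            X[right] = em + (x[right] - kts[-1])[:, None] * slope
        return X

    def penalty(self, shrinkage: bool = True, eps: float = 0.1) -> np.ndarray:
        if not shrinkage:
            return self.S
        vals, vecs = np.linalg.eigh(self.S)
        pos = vals[vals > 1e-10 * vals.max()]
        floor = eps * pos.min()
        vals = np.where(vals > 1e-10 * vals.max(), vals, floor)
        return (vecs * vals) @ vecs.T


def _null_space_of_vector(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis of {v : c.v = 0}, k x (k-1)."""
    k = len(c)
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(k)]))
    return q[:, 1:k]


# ---------------------------------------------------------------------------
# the fitted model


@dataclass
class SmoothTerm:
    name: str
    basis: CubicRegressionSpline
    Z: np.ndarray                # centering constraint null-space (k x k-1)
    coef: np.ndarray             # (k-1,)
    lam: float
    edf: float

    def partial(self, x) -> np.ndarray:
        return self.basis.design(x) @ self.Z @ self.coef


@dataclass
class HabitatModel:
    """A fitted binomial GAM over named covariates."""

    covariates: list[str]
    intercept: float
    smooths: list[SmoothTerm]
    deviance: float = np.nan
    null_deviance: float = np.nan
    edf_total: float = np.nan
    vcov: np.ndarray | None = None   # penalized-fit posterior covariance

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(data), self.intercept)
        for sm in self.smooths:
            eta = eta + sm.partial(data[sm.name].to_numpy(float))
        return eta

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Probability of presence for each row."""
        return expit(self.linear_predictor(data))

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        doc = {"intercept": self.intercept, "covariates": self.covariates,
               "deviance": self.deviance, "smooths": []}
        for sm in self.smooths:
            doc["smooths"].append({
                "name": sm.name, "knots": sm.basis.knots.tolist(),
                "Z": sm.Z.tolist(), "coef": sm.coef.tolist(),
                "lambda": sm.lam, "edf": sm.edf})
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "HabitatModel":
        doc = json.loads(text)
        smooths = [SmoothTerm(name=d["name"],
                              basis=CubicRegressionSpline(np.asarray(d["knots"])),
                              Z=np.asarray(d["Z"]), coef=np.asarray(d["coef"]),
                              lam=d["lambda"], edf=d["edf"])
                   for d in doc["smooths"]]
        return cls(covariates=doc["covariates"], intercept=doc["intercept"],
                   smooths=smooths, deviance=doc.get("deviance", np.nan))


# ---------------------------------------------------------------------------
# fitting


def _binomial_deviance(y, mu):
    mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
    return float(2.0 * np.sum(y * np.log(np.where(y > 0, y / mu, 1.0))
                              + (1 - y) * np.log(np.where(y < 1, (1 - y) / (1 - mu), 1.0))))


def _pirls(X, y, S_blocks, lam, beta0=None, max_iter=60, tol=1e-9):
    """Penalized IRLS for a logit model; returns (beta, dev, edf, Vb)."""
    n, p = X.shape
    P = np.zeros((p, p))
    for (i0, i1, S), lm in zip(S_blocks, lam):
        P[i0:i1, i0:i1] = lm * S
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    if beta0 is None:
        beta[0] = logit(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    dev = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        A = XtW @ X + P
        beta_new = np.linalg.solve(A, XtW @ z)
        dev_new = _binomial_deviance(y, expit(X @ beta_new))
        # simple step-halving if the penalized objective worsens
        pen = lambda b, d: d + float(b @ P @ b)
        step = 1.0
        while (pen(beta_new, dev_new) > pen(beta, dev) + 1e-8 and step > 1e-4
               and np.isfinite(dev)):
            step *= 0.5
            beta_new = beta + step * (beta_new - beta)
            dev_new = _binomial_deviance(y, expit(X @ beta_new))
        done = abs(dev - dev_new) < tol * (abs(dev_new) + 0.1)
        beta, dev = beta_new, dev_new
        if done:
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    XtWX = (X.T * w) @ X
    A = XtWX + P
    Ainv = np.linalg.inv(A)
    edf_matrix = Ainv @ XtWX
    return beta, dev, edf_matrix, Ainv


def fit_binomial_gam(table, covariates, k: int = DEFAULT_K,
                     smooth_maxfev: int | None = None,
                     gamma: float = 1.4) -> HabitatModel:
    """Fit the presence/absence GAM with shrinkage smooths.

    ``table`` is a PresenceAbsenceTable or a DataFrame with a ``label``
    column; ``covariates`` the smooth terms to include (may be empty for
    an intercept-only model). Smoothing parameters minimise the
    UBRE-type criterion (deviance + 2 * gamma * edf) / n over
    log-lambda; ``gamma`` = 1.4 applies the standard inflation that
    counteracts the known undersmoothing of the gamma = 1 criterion.
    """
    df = table.data if hasattr(table, "data") else table
    y = df["label"].to_numpy(float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 < 10 or n0 < 10:
        raise ValueError(f"need >= 10 presences and absences (got {n1}/{n0})")
    covariates = list(covariates)

    if not covariates:
        p = y.mean()
        m = HabitatModel(covariates=[], intercept=float(logit(p)), smooths=[])
        m.deviance = _binomial_deviance(y, np.full_like(y, p))
        m.null_deviance = m.deviance
        m.edf_total = 1.0
        return m

    cols = [np.ones((len(df), 1))]
    blocks = []      # (start, stop, penalty) in stacked coordinates
    bases, Zs = [], []
    i0 = 1
    for name in covariates:
        x = df[name].to_numpy(float)
        if np.nanstd(x) == 0:
            raise ValueError(f"covariate {name} is constant")
        basis = CubicRegressionSpline.from_data(x, k=k)
        Xj = basis.design(x)
        Z = _null_space_of_vector(Xj.mean(axis=0))
        Xc = Xj @ Z
        Sc = Z.T @ basis.penalty(shrinkage=True) @ Z
        cols.append(Xc)
        blocks.append((i0, i0 + Xc.shape[1], Sc))
        bases.append(basis)
        Zs.append(Z)
        i0 += Xc.shape[1]
    X = np.hstack(cols)
    n = len(y)

    state = {"beta": None}

    def ubre(rho):
        lam = np.exp(np.clip(rho, -18.0, 18.0))
        beta, dev, edf_m, _ = _pirls(X, y, blocks, lam, beta0=state["beta"])
        state["beta"] = beta
        return (dev + 2.0 * gamma * np.trace(edf_m)) / n

    p = len(covariates)
    if smooth_maxfev is None:
        smooth_maxfev = 40 + 30 * p
    # coarse coordinate sweeps (the UBRE surface is flat and NM's default
    # simplex at 0 is degenerate), then a Nelder-Mead refinement
    grid = np.arange(-4.0, 15.0, 2.0)
    rho = np.zeros(p)
    for j in range(p):
        vals = []
        for g in grid:
            trial = rho.copy()
            trial[j] = g
            vals.append(ubre(trial))
        rho[j] = grid[int(np.argmin(vals))]
    res = optimize.minimize(
        ubre, rho, method="Nelder-Mead",
        options={"maxfev": smooth_maxfev, "xatol": 0.05, "fatol": 1e-9,
                 "initial_simplex": rho + np.vstack([np.zeros(p), np.eye(p)])})
    best_rho = res.x if res.fun <= ubre(rho) else rho
    lam = np.exp(np.clip(best_rho, -18.0, 18.0))
    beta, dev, edf_m, Vb = _pirls(X, y, blocks, lam)

    smooths = []
    for j, name in enumerate(covariates):
        i0, i1, _ = blocks[j]
        smooths.append(SmoothTerm(
            name=name, basis=bases[j], Z=Zs[j], coef=beta[i0:i1],
            lam=float(lam[j]), edf=float(np.trace(edf_m[i0:i1, i0:i1]))))
    model = HabitatModel(covariates=covariates, intercept=float(beta[0]),
                         smooths=smooths, deviance=dev,
                         null_deviance=_binomial_deviance(y, np.full_like(y, y.mean())),
                         edf_total=float(np.trace(edf_m)), vcov=Vb)
    return model


# ---------------------------------------------------------------------------
# ROC metrics


def roc_metrics(scores, labels, threshold="youden"):
    """AUC, sensitivity and specificity for presence scores.

    AUC uses the rank (Mann-Whitney) formulation with half credit for
    ties. Sensitivity/specificity are computed at the Youden-optimal
    threshold on these scores (``threshold="youden"``) or at a fixed
    probability (``threshold=0.5`` etc.); a point scores presence when
    its value is strictly above the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both presences and absences to score")
    r = rankdata(scores)
    auc = (r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    if threshold == "youden":
        uniq = np.unique(scores)
        cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0]) \
            if len(uniq) > 1 else np.array([uniq[0] - 1.0])
        best = (-np.inf, None)
        for thr in cands:
            pred = scores > thr
            sens = (pred & (labels == 1)).sum() / n1
            spec = (~pred & (labels == 0)).sum() / n0
            j = sens + spec
            if j > best[0] + 1e-12:
                best = (j, (sens, spec))
        sens, spec = best[1]
    else:
        pred = scores > float(threshold)
        sens = (pred & (labels == 1)).sum() / n1
        spec = (~pred & (labels == 0)).sum() / n0
    return float(auc), float(sens), float(spec)


# ---------------------------------------------------------------------------
# month-blocked cross-validation


@dataclass
class CvResult:
    """Per-fold and aggregate month-blocked CV metrics."""

    folds: pd.DataFrame          # train_month, auc, sensitivity, specificity
    auc: float
    sensitivity: float
    specificity: float


def cv_monthly(table, covariates, k: int = DEFAULT_K,
               threshold="youden") -> CvResult:
    """Train on each month, evaluate on the remaining months.

    The fold count equals the number of distinct months. A training
    month missing either class is skipped with a warning. Aggregates are
    unweighted means over folds.
    """
    df = table.data if hasattr(table, "data") else table
    months = np.sort(df["month"].unique())
    if len(months) < 2:
        raise ValueError("monthly CV needs at least 2 distinct months")
    rows = []
    for m in months:
        train = df[df["month"] == m]
        test = df[df["month"] != m]
        if train["label"].nunique() < 2:
            warnings.warn(f"month {m} has a single class; fold skipped")
            continue
        try:
            model = fit_binomial_gam(train, covariates, k=k)
        except ValueError as err:
            warnings.warn(f"month {m} fold skipped: {err}")
            continue
        auc, sens, spec = roc_metrics(model.predict(test),
                                      test["label"].to_numpy(int),
                                      threshold=threshold)
        rows.append({"train_month": int(m), "auc": auc,
                     "sensitivity": sens, "specificity": spec})
    if not rows:
        raise ValueError("no usable CV folds")
    folds = pd.DataFrame(rows)
    return CvResult(folds=folds, auc=float(folds["auc"].mean()),
                    sensitivity=float(folds["sensitivity"].mean()),
                    specificity=float(folds["specificity"].mean()))


# ---------------------------------------------------------------------------
# forward stepwise selection


@dataclass
class StepwiseTrace:
    """Selection path: single-covariate ranking plus accepted additions."""

    ranking: pd.DataFrame        # covariate, auc, sensitivity, specificity
    steps: pd.DataFrame          # step, covariate, auc (accepted path)
    selected: list[str]
    cv: CvResult                 # CV result of the final covariate set


def forward_stepwise(table, candidates, k: int = DEFAULT_K,
                     tol: float = STEPWISE_TOL, threshold="youden") -> StepwiseTrace:
    """Greedy covariate selection on aggregate cross-validated AUC.

    First ranks all single-covariate models (the per-covariate metric
    table), selects the best, then keeps adding the candidate that most
    increases aggregate CV AUC until no candidate improves it by more
    than ``tol``. Ties break alphabetically so the outcome does not
    depend on candidate order.
    """
    candidates = sorted(candidates)
    rank_rows = []
    cv_cache: dict[tuple, CvResult] = {}

    def cv_for(names):
        key = tuple(names)
        if key not in cv_cache:
            cv_cache[key] = cv_monthly(table, list(names), k=k, threshold=threshold)
        return cv_cache[key]

    for name in candidates:
        r = cv_for((name,))
        rank_rows.append({"covariate": name, "auc": r.auc,
                          "sensitivity": r.sensitivity, "specificity": r.specificity})
    ranking = (pd.DataFrame(rank_rows)
               .sort_values(["auc", "covariate"], ascending=[False, True])
               .reset_index(drop=True))

    selected = [ranking.loc[0, "covariate"]]
    best = cv_for(tuple(sorted(selected)))
    steps = [{"step": 0, "covariate": selected[0], "auc": best.auc}]
    remaining = [c for c in candidates if c not in selected]
    while remaining:
        trial = []
        for name in remaining:
            r = cv_for(tuple(sorted(selected + [name])))
            trial.append((r.auc, name, r))
        trial.sort(key=lambda t: (-t[0], t[1]))
        auc, name, r = trial[0]
        if auc <= best.auc + tol:
            break
        selected.append(name)
        best = r
        steps.append({"step": len(steps), "covariate": name, "auc": auc})
        remaining.remove(name)
    return StepwiseTrace(ranking=ranking, steps=pd.DataFrame(steps),
                         selected=selected, cv=best)


# ---------------------------------------------------------------------------
# response curves


def response_curve(model: HabitatModel, covariate: str,
                   grid: np.ndarray | None = None,
                   n_points: int = 100) -> pd.DataFrame:
    """Partial effect of one smooth on the linear predictor, with +/-2 SE.

    The curve is the smooth's centred contribution over ``grid`` (default:
    the knot span); standard errors come from the penalized-fit posterior
    covariance. An intercept-only model yields a flat zero curve.
    """
    if not model.smooths:
        grid = np.asarray(grid if grid is not None else np.linspace(0, 1, n_points))
        z = np.zeros(len(grid))
        return pd.DataFrame({covariate: grid, "effect": z, "lower": z, "upper": z})
    names = [s.name for s in model.smooths]
    if covariate not in names:
        raise KeyError(f"{covariate} not in model ({names})")
    j = names.index(covariate)
    sm = model.smooths[j]
    if grid is None:
        grid = np.linspace(sm.basis.knots[0], sm.basis.knots[-1], n_points)
    grid = np.asarray(grid, dtype=float)
    R = sm.basis.design(grid) @ sm.Z
    effect = R @ sm.coef
    if model.vcov is not None:
        i0 = 1 + sum(len(s.coef) for s in model.smooths[:j])
        V = model.vcov[i0:i0 + len(sm.coef), i0:i0 + len(sm.coef)]
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", R, V, R), 0.0, None))
    else:
        se = np.zeros(len(grid))
    return pd.DataFrame({covariate: grid, "effect": effect,
                         "lower": effect - 2.0 * se, "upper": effect + 2.0 * se})
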