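"""Geographic structure: PC-coordinate regressions, coordinate prediction,
the GEO similarity kernel and variance-component mixed models.

The mixed models are

    Model 1:  y = X b + g + e,          g ~ N(0, GRM * sg2)
    Model 2:  y = X b + g + s_geo + e,  s_geo ~ N(0, GEO * ss2)

where GEO is a similarity kernel in [0, 1] with unit diagonal built from
predicted geographic coordinates.  Variance components are estimated by
restricted maximum likelihood using average-information updates with
step-halving and a variance floor at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pca import PCAResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PC ~ coordinates regressions
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: np.ndarray):
    """OLS fit returning (beta, se, t, p, r2, f_p)."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - rank
    rss = resid @ resid
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    XtX = X.T @ X
    cov = np.linalg.pinv(XtX) * (rss / dof if dof > 0 else np.nan)
    se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    k_model = rank - 1  # slopes
    if k_model > 0 and dof > 0 and tss > 0:
        f = (tss - rss) / k_model / (rss / dof)
        f_p = stats.f.sf(f, k_model, dof)
    else:
        f_p = np.nan
    return beta, se, t, p, r2, f_p


def _align_coords(coords: pd.DataFrame, sample_ids: np.ndarray) -> pd.DataFrame:
    """Align a lat/lon frame with the PCA's samples.

    Frames indexed by sample id are reindexed; positionally aligned frames
    (default integer index) are relabelled.
    """
    if set(map(str, coords.index)) >= set(map(str, sample_ids)):
        return coords.set_index(coords.index.astype(str)).reindex(
            np.asarray(sample_ids).astype(str)
        ).set_axis(sample_ids)
    if len(coords) != len(sample_ids):
        raise ValueError("coords neither indexed by sample id nor aligned by position")
    return coords.set_axis(sample_ids)


def regress_pcs_on_coords(
    pca: PCAResult, coords: pd.DataFrame, k: int = 20
) -> pd.DataFrame:
    """Multiple regression of each PC on latitude and longitude jointly.

    *coords* must hold ``lat``/``lon`` columns indexed by (or aligned with)
    sample id; samples lacking coordinates are dropped.  Returns one row per
    PC: R^2, overall model p, and per-coefficient estimates and p-values.
    A constant coordinate column yields NA for that coefficient.
    """
    coords = _align_coords(coords, pca.sample_ids)
    ok = coords["lat"].notna() & coords["lon"].notna()
    if not ok.all():
        logger.info("geo regression: dropping %d samples without coordinates", (~ok).sum())
    lat = coords.loc[ok, "lat"].to_numpy(float)
    lon = coords.loc[ok, "lon"].to_numpy(float)
    k = min(k, pca.eigenvectors.shape[1])
    const_lat, const_lon = lat.std() == 0, lon.std() == 0
    rows = []
    for j in range(1, k + 1):
        y = pca.pc(j)[np.asarray(ok)]
        cols = [np.ones(y.size)]
        names = ["intercept"]
        if not const_lat:
            cols.append(lat)
            names.append("lat")
        if not const_lon:
            cols.append(lon)
            names.append("lon")
        X = np.column_stack(cols)
        beta, se, t, p, r2, f_p = _ols(y, X)
        row = {"pc": j, "r2": r2, "model_p": f_p,
               "beta_lat": np.nan, "p_lat": np.nan, "beta_lon": np.nan, "p_lon": np.nan}
        for name, b, pv in zip(names, beta, p):
            if name in ("lat", "lon"):
                row[f"beta_{name}"] = b
                row[f"p_{name}"] = pv
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Coordinate prediction
# ---------------------------------------------------------------------------

@dataclass
class CoordinatePredictor:
    """Two linear models (latitude, longitude), each on the first k PCs."""

    k: int
    coef_lat: np.ndarray
    coef_lon: np.ndarray
    intercept_lat: float
    intercept_lon: float

    def predict(self, pca: PCAResult | np.ndarray) -> pd.DataFrame:
        V = pca.eigenvectors if isinstance(pca, PCAResult) else np.asarray(pca)
        V = V[:, : self.k]
        lat = self.intercept_lat + V @ self.coef_lat
        lon = self.intercept_lon + V @ self.coef_lon
        idx = pca.sample_ids if isinstance(pca, PCAResult) else None
        return pd.DataFrame({"lat": lat, "lon": lon}, index=idx)


def fit_coordinate_predictor(
    pca: PCAResult, coords: pd.DataFrame, k: int = 20
) -> CoordinatePredictor:
    """Fit latitude and longitude on PCs 1..k as two separate least-squares
    models over the samples with known coordinates."""
    avail = pca.eigenvectors.shape[1]
    if k > avail:
        warnings.warn(f"k={k} exceeds available PCs ({avail}); clipped")
        k = avail
    coords = _align_coords(coords, pca.sample_ids)
    ok = (coords["lat"].notna() & coords["lon"].notna()).to_numpy()
    V = pca.eigenvectors[ok, :k]
    X = np.column_stack([np.ones(ok.sum()), V])
    fits = {}
    for axis in ("lat", "lon"):
        beta, *_ = np.linalg.lstsq(X, coords.loc[ok, axis].to_numpy(float), rcond=None)
        fits[axis] = beta
    return CoordinatePredictor(
        k=k,
        coef_lat=fits["lat"][1:],
        coef_lon=fits["lon"][1:],
        intercept_lat=float(fits["lat"][0]),
        intercept_lon=float(fits["lon"][0]),
    )


# ---------------------------------------------------------------------------
# GEO kernel
# ---------------------------------------------------------------------------

@dataclass
class GeoKernel:
    sample_ids: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, float)
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("GEO kernel must be symmetric")
        if (M < -1e-12).any() or (M > 1 + 1e-12).any():
            raise ValueError("GEO kernel entries must lie in [0, 1]")
        self.matrix = M


def build_geo_matrix(coords: pd.DataFrame, kernel: str = "linear", bandwidth: float | None = None) -> GeoKernel:
    """Similarity kernel from (predicted) coordinates.

    ``linear`` (default): 1 - d/d_max with d the Euclidean distance in degree
    space and d_max the maximum pairwise distance (all entries 1 when
    d_max = 0).  ``gaussian``: exp(-d^2 / (2 h^2)) with h = *bandwidth*
    (default: median pairwise distance).  Diagonal is exactly 1 either way;
    the linear form is translation- and scale-invariant.
    """
    pts = coords[["lat", "lon"]].to_numpy(float)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    dmax = d.max()
    if kernel == "linear":
        M = np.ones_like(d) if dmax == 0 else 1.0 - d / dmax
    elif kernel == "gaussian":
        h = bandwidth if bandwidth is not None else (np.median(d[d > 0]) if dmax > 0 else 1.0)
        M = np.exp(-(d**2) / (2 * h**2))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    np.fill_diagonal(M, 1.0)
    ids = coords.index.to_numpy() if coords.index.name is not None else np.arange(len(coords))
    return GeoKernel(sample_ids=ids, matrix=(M + M.T) / 2.0)


# ---------------------------------------------------------------------------
# REML variance components
# ---------------------------------------------------------------------------

class RemlError(RuntimeError):
    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class VarianceComponents:
    """REML estimates for y = Xb + sum_k u_k + e with u_k ~ N(0, K_k s2_k)."""

    estimates: np.ndarray  # kernel variances then residual
    se: np.ndarray
    proportions: np.ndarray  # share of phenotypic variance per component
    beta: np.ndarray
    beta_se: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    kernel_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        names = (self.kernel_names or [f"K{i+1}" for i in range(len(self.estimates) - 1)]) + ["residual"]
        return pd.DataFrame(
            {"component": names, "estimate": self.estimates, "se": self.se,
             "proportion": self.proportions}
        )


def _bend_psd(K: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-8:
        logger.warning("kernel bent to positive semi-definite (min eigenvalue %.3g)", w.min())
        w2, v = np.linalg.eigh(K)
        K = (v * np.clip(w2, 0, None)) @ v.T
        K = (K + K.T) / 2.0
    return K


def restricted_loglik(theta: np.ndarray, y: np.ndarray, X: np.ndarray, kernels: list[np.ndarray]) -> float:
    """Restricted log-likelihood at variance components *theta* (kernels + residual)."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], kernels):
        V = V + t * K
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    XtVinvX = X.T @ Vinv_X
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    return float(-0.5 * (logdetV + logdetX + y @ Py))


def fit_variance_components(
    y: np.ndarray,
    X: np.ndarray | None,
    kernels: list[np.ndarray],
    kernel_names: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    fixed_zero: list[int] | None = None,
) -> VarianceComponents:
    """Average-information REML for an arbitrary list of dense kernels.

    *X* defaults to an intercept.  Variances are constrained non-negative by
    projection to a small floor; convergence is declared when the relative
    change in restricted log-likelihood falls below *tol*.  ``fixed_zero``
    pins the listed kernel variances at zero (e.g. to reduce a mixed model to
    ordinary least squares).  Raises :class:`RemlError` with the iteration
    trace on non-convergence.
    """
    y = np.asarray(y, float)
    n = y.size
    X = np.ones((n, 1)) if X is None else np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    if not keep.all():
        y, X = y[keep], X[keep]
        kernels = [K[np.ix_(keep, keep)] for K in kernels]
        n = y.size
    kernels = [_bend_psd(np.asarray(K, float)) for K in kernels]
    m = len(kernels)
    vary = y.var()
    theta = np.full(m + 1, vary / (m + 1))
    floor = 1e-8 * vary
    if fixed_zero:
        theta[list(fixed_zero)] = 0.0
    Ks = kernels + [np.eye(n)]
    free = np.array([i for i in range(m + 1) if not (fixed_zero and i in fixed_zero)])
    ll = restricted_loglik(theta, y, X, kernels)
    trace = [(0, theta.copy(), ll)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = theta[-1] * np.eye(n)
        for t, K in zip(theta[:-1], kernels):
            V = V + t * K
        Vinv = np.linalg.inv(V)
        Vinv_X = Vinv @ X
        XtVinvX = X.T @ Vinv_X
        P = Vinv - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T)
        Py = P @ y
        grad_all = {
            i: -0.5 * (np.trace(P @ Ks[i]) - Py @ Ks[i] @ Py) for i in free
        }
        # active set: components pinned at the zero boundary with a
        # negative gradient stay put this iteration
        active = [i for i in free if theta[i] > 0 or grad_all[i] > 0]
        if not active:
            converged = True
            break
        grad = np.array([grad_all[i] for i in active])
        act = np.array(active)
        KPy = [Ks[i] @ Py for i in act]
        AI = 0.5 * np.array([[KPy[a] @ P @ KPy[b] for b in range(len(act))] for a in range(len(act))])
        try:
            delta = np.linalg.solve(AI + 1e-12 * np.eye(len(act)), grad)
        except np.linalg.LinAlgError:
            delta = grad / max(np.abs(grad).max(), 1.0)
        if not np.isfinite(delta).all() or np.linalg.cond(AI) > 1e12:
            warnings.warn("average-information matrix is near-singular; components may be unidentifiable")
            delta = np.where(np.isfinite(delta), delta, 0.0)
        def _project(t: np.ndarray) -> np.ndarray:
            t = np.clip(t, 0.0, None)
            t[:-1] = np.where(t[:-1] < floor, 0.0, t[:-1])
            t[-1] = max(t[-1], floor)  # keep the residual variance positive
            return t

        step = 1.0
        cand = theta
        new_ll = -np.inf
        improved = False
        for _ in range(30):
            cand = theta.copy()
            cand[act] = theta[act] + step * delta
            cand = _project(cand)
            new_ll = restricted_loglik(cand, y, X, kernels)
            if np.isfinite(new_ll) and new_ll >= ll:
                improved = True
                break
            step /= 2.0
        if not improved:
            # EM-REML fallback step (slow but uphill); if even that cannot
            # improve, the current point is a constrained stationary point
            cand = theta.copy()
            for i in free:
                cand[i] = theta[i] + (theta[i] ** 2 / n) * (
                    Py @ Ks[i] @ Py - np.trace(P @ Ks[i])
                )
            cand = _project(cand)
            new_ll = restricted_loglik(cand, y, X, kernels)
            if not np.isfinite(new_ll) or new_ll < ll:
                converged = True
                break
        theta = cand
        trace.append((it, theta.copy(), new_ll))
        if abs(new_ll - ll) < tol * max(1.0, abs(new_ll)):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        raise RemlError(f"REML did not converge in {max_iter} iterations", trace)
    # final quantities
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], kernels):
        V = V + t * K
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    beta_cov = np.linalg.inv(XtVinvX)
    Vinv_X = Vinv @ X
    P = Vinv - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T)
    Py = P @ y
    AI_full = np.zeros((m + 1, m + 1))
    KPy_all = [K @ Py for K in Ks]
    for a in range(m + 1):
        for b in range(m + 1):
            AI_full[a, b] = 0.5 * (KPy_all[a] @ P @ KPy_all[b])
    se = np.sqrt(np.clip(np.diag(np.linalg.pinv(AI_full)), 0, None))
    total = theta.sum()
    return VarianceComponents(
        estimates=theta,
        se=se,
        proportions=theta / total if total > 0 else np.full_like(theta, np.nan),
        beta=beta,
        beta_se=np.sqrt(np.diag(beta_cov)),
        log_likelihood=float(ll),
        n_iter=it,
        converged=converged,
        kernel_names=kernel_names or [],
    )


# ---------------------------------------------------------------------------
# Fixed effects under a polygenic kernel
# ---------------------------------------------------------------------------

def build_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; object/category columns are dummy-coded
    against a reference level; rank-deficient (aliased) columns are dropped
    with a log message."""
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    for name, col in covariates.items():
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dn in dummies.columns:
                cols.append(dummies[dn].to_numpy(float))
                names.append(dn)
        else:
            cols.append(col.to_numpy(float))
            names.append(name)
    X = np.column_stack(cols)
    # drop aliased columns by sequential rank checks
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            logger.info("design: dropping aliased column %s", names[j])
    return X[:, keep], [names[j] for j in keep]


def fit_fixed_effects(
    y: np.ndarray,
    covariates: pd.DataFrame,
    kernel: np.ndarray | None,
    fix_genetic_zero: bool = False,
) -> pd.DataFrame:
    """Model-1 fixed-effect estimates with Wald tests.

    Fits y = Xb + g + e with g ~ N(0, K sg2) (REML), then reports each
    covariate's estimate, standard error and two-sided Wald p.  With
    ``fix_genetic_zero`` (or kernel None) the genetic variance is pinned at
    zero and the fit reduces to ordinary least squares.
    """
    X, names = build_design(covariates)
    kernels = [] if kernel is None else [np.asarray(kernel, float)]
    fixed = [0] if (kernels and fix_genetic_zero) else None
    vc = fit_variance_components(y, X, kernels, fixed_zero=fixed)
    z = vc.beta / vc.beta_se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"covariate": names, "estimate": vc.beta, "se": vc.beta_se, "p": p})
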