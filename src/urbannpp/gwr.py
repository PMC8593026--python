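"""OLS baseline and geographically weighted regression (GWR).

GWR fits, at every location i with coordinates (u_i, v_i), the weighted
least-squares problem

    beta(u_i, v_i) = (X^T W_i X)^{-1} X^T W_i y,

where W_i is a diagonal matrix of bi-square kernel weights
w = (1 - (d/b)^2)^2 for d < b (0 beyond), evaluated on distances from
location i to every observation. With an adaptive bandwidth, b is the
distance to the k-th nearest observation of location i (the regression
point itself counts, at distance 0). The neighbor count k is selected by
minimizing an information criterion with a golden-section search over
integers. The default criterion is the small-sample-corrected AICc: with
the plain trace-form AIC the penalty grows only linearly in tr(S) and the
criterion degenerates toward the smallest admissible bandwidth, which is
why GWR software optimizes AICc. Plain AIC and leave-one-out CV are
offered as alternatives.

Diagnostics follow the standard GWR literature: hat-matrix diagonal
h_ii = x_i (X^T W_i X)^{-1} x_i^T w_ii, effective parameters tr(S),
AIC = 2n ln(sigma_hat) + n ln(2 pi) + n + tr(S), internally studentized
residuals r_i / (sigma_hat sqrt(1 - h_ii)), and an adjusted R^2 using
n - tr(S) residual degrees of freedom.

The estimator follows the scikit-learn API: the first two columns of X are
the projected coordinates (u, v) in meters and the remaining columns are
predictors, so it composes with sklearn model-selection tooling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# kernel
# --------------------------------------------------------------------------- #

def bisquare_weight(d, b):
    """Bi-square kernel: (1 - (d/b)^2)^2 for d < b, 0 beyond.

    Continuous, non-increasing, compactly supported; w(0) = 1, w(b) = 0.
    """
    b = float(b)
    if b <= 0:
        raise ValueError(f"bandwidth must be > 0, got {b}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    u = d / b
    w = np.where(u < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    return w if w.ndim else float(w)


# --------------------------------------------------------------------------- #
# OLS baseline
# --------------------------------------------------------------------------- #

@dataclass
class OlsResult:
    """Global least-squares fit: one coefficient per predictor plus intercept."""

    names: list
    coef: np.ndarray
    stderr: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    r2: float
    adj_r2: float
    aic: float
    n: int


def fit_ols(y, X, names: list | None = None) -> OlsResult:
    """Global OLS with classical standard errors and Gaussian-likelihood AIC."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    if names is None:
        names = [f"x{k}" for k in range(p)]
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name the first column whose removal restores full rank
        for k in range(p):
            if np.linalg.matrix_rank(np.delete(Xc, k + 1, axis=1)) == rank:
                raise ValueError(f"design matrix is rank deficient: column {names[k]!r} "
                                 "is collinear with the others")
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, Xc).fit()
    return OlsResult(
        names=["intercept"] + list(names),
        coef=np.asarray(fit.params),
        stderr=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        aic=float(fit.aic),
        n=n,
    )


# --------------------------------------------------------------------------- #
# GWR core
# --------------------------------------------------------------------------- #

def _pairwise_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def _kernel_matrix(D: np.ndarray, bandwidth, adaptive: bool) -> np.ndarray:
    """Row i holds kernel weights at regression point i over all observations."""
    if adaptive:
        k = int(bandwidth)
        if k < 1 or k > D.shape[1]:
            raise ValueError(f"adaptive bandwidth must be in [1, n], got {k}")
        b_i = np.partition(D, k - 1, axis=1)[:, k - 1]
        b_i = np.maximum(b_i, np.finfo(float).tiny)
        u = D / b_i[:, None]
    else:
        b = float(bandwidth)
        if b <= 0:
            raise ValueError(f"fixed bandwidth must be > 0, got {b}")
        u = D / b
    return np.where(u < 1.0, (1.0 - u ** 2) ** 2, 0.0)


def _gwr_solve(Xd: np.ndarray, y: np.ndarray, K: np.ndarray):
    """Batched WLS solves: returns coefficients (n, p) and local (X^T W X)^-1.

    Xd includes the intercept column. Rows of K are the per-location weights.
    Locations with a singular local design get NaN coefficients.
    """
    n, p = Xd.shape
    A = np.empty((n, p, p))
    for a in range(p):
        for b in range(a, p):
            cross = K @ (Xd[:, a] * Xd[:, b])
            A[:, a, b] = cross
            A[:, b, a] = cross
    Bv = np.empty((n, p))
    for a in range(p):
        Bv[:, a] = K @ (Xd[:, a] * y)
    coef = np.full((n, p), np.nan)
    Ainv = np.full((n, p, p), np.nan)
    ok = np.ones(n, dtype=bool)
    # batched solve with per-location fallback on singular systems
    try:
        Ainv_all = np.linalg.inv(A)
        bad = ~np.isfinite(Ainv_all).all(axis=(1, 2))
    except np.linalg.LinAlgError:
        Ainv_all = np.full((n, p, p), np.nan)
        bad = np.ones(n, dtype=bool)
    for i in range(n):
        if not bad[i]:
            continue
        try:
            Ainv_all[i] = np.linalg.inv(A[i])
            bad[i] = False
        except np.linalg.LinAlgError:
            ok[i] = False
    # condition screen: treat near-singular local designs as failures
    with np.errstate(invalid="ignore", over="ignore"):
        ok &= ~bad
    coef[ok] = np.einsum("ipq,iq->ip", Ainv_all[ok], Bv[ok])
    Ainv[ok] = Ainv_all[ok]
    return coef, Ainv, ok


class GWRegressor(RegressorMixin, BaseEstimator):
    """Geographically weighted regression with a bi-square kernel.

    Parameters
    ----------
    bandwidth : int, float or 'select'
        Adaptive neighbor count (``adaptive=True``), fixed kernel radius in
        meters (``adaptive=False``), or ``'select'`` to optimize the
        adaptive bandwidth by ``criterion``.
    adaptive : bool
        Adaptive (k-nearest-neighbor distance) vs fixed-distance bandwidth.
    criterion : {'aic', 'aicc', 'cv'}
        Bandwidth-selection criterion when ``bandwidth='select'``.
    search : {'golden', 'grid'}
        Golden-section search over integer neighbor counts, or exhaustive
        evaluation.
    max_fail_fraction : float
        Abort if more than this fraction of local solves is singular.

    The first two columns of ``X`` are the projected coordinates (u, v) in
    meters; remaining columns are predictors.
    """

    def __init__(
        self,
        bandwidth="select",
        adaptive: bool = True,
        kernel: str = "bisquare",
        criterion: str = "aicc",
        search: str = "golden",
        max_fail_fraction: float = 0.1,
    ):
        self.bandwidth = bandwidth
        self.adaptive = adaptive
        self.kernel = kernel
        self.criterion = criterion
        self.search = search
        self.max_fail_fraction = max_fail_fraction

    # ---------------------------------------------------------------- #

    def fit(self, X, y):
        if self.kernel != "bisquare":
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        X, y = check_X_y(X, y, ensure_min_features=3)
        coords = X[:, :2]
        pred = X[:, 2:]
        n, p_pred = pred.shape
        Xd = np.column_stack([np.ones(n), pred])
        p = Xd.shape[1]

        # coincident regression points make adaptive bandwidths ambiguous
        uniq = np.unique(coords, axis=0)
        if uniq.shape[0] < n:
            logger.warning("GWR: %d coincident locations detected", n - uniq.shape[0])

        D = _pairwise_dist(coords, coords)

        if isinstance(self.bandwidth, str) and self.bandwidth == "select":
            if not self.adaptive:
                raise ValueError("bandwidth='select' requires adaptive=True")
            bw, profile = select_bandwidth(
                coords, pred, y, criterion=self.criterion, search=self.search,
                _D=D,
            )
            self.criterion_profile_ = profile
        else:
            bw = self.bandwidth
            self.criterion_profile_ = None
        self.bandwidth_ = bw

        K = _kernel_matrix(D, bw, self.adaptive)
        coef, Ainv, ok = _gwr_solve(Xd, y, K)
        fail = 1.0 - ok.mean()
        if fail > self.max_fail_fraction:
            raise ValueError(
                f"{fail:.0%} of local designs are singular (limit "
                f"{self.max_fail_fraction:.0%}); widen the bandwidth"
            )
        if fail > 0:
            logger.warning("GWR: %d singular local solves flagged NaN", int((~ok).sum()))

        fitted = np.einsum("ip,ip->i", Xd, coef)
        resid = y - fitted
        # hat diagonal: h_ii = x_i A_i^{-1} x_i * w_ii (self-weight w(0)=1)
        self_w = K[np.arange(n), np.arange(n)]
        h = np.einsum("ip,ipq,iq->i", Xd, Ainv, Xd) * self_w
        tr_S = float(np.nansum(h))

        rss = float(np.nansum(resid[ok] ** 2))
        n_ok = int(ok.sum())
        sigma2_ml = rss / n_ok
        aic = 2 * n_ok * math.log(math.sqrt(sigma2_ml)) + n_ok * math.log(2 * math.pi) \
            + n_ok + tr_S
        denom = n_ok - 2.0 - tr_S
        aicc = (2 * n_ok * math.log(math.sqrt(sigma2_ml)) + n_ok * math.log(2 * math.pi)
                + n_ok * (n_ok + tr_S) / denom) if denom > 0 else float("inf")

        tss = float(((y[ok] - y[ok].mean()) ** 2).sum())
        r2 = 1.0 - rss / tss
        dof = max(n_ok - tr_S, 1e-12)
        adj_r2 = 1.0 - (rss / dof) / (tss / (n_ok - 1))

        sigma2 = rss / dof
        # local coefficient covariance: A^{-1} X^T W^2 X A^{-1} sigma^2
        C2 = np.empty((n, p, p))
        K2 = K ** 2
        for a in range(p):
            for b in range(a, p):
                cross = K2 @ (Xd[:, a] * Xd[:, b])
                C2[:, a, b] = cross
                C2[:, b, a] = cross
        cov = np.einsum("ipq,iqr,irs->ips", Ainv, C2, Ainv) * sigma2
        stderr = np.sqrt(np.clip(np.einsum("ipp->ip", cov), 0, None))

        with np.errstate(invalid="ignore"):
            std_resid = resid / np.sqrt(sigma2 * np.clip(1.0 - h, 1e-12, None))

        # local weighted R^2 around each regression point
        wsum = K.sum(axis=1)
        ybar_w = (K @ y) / wsum
        rss_w = K @ (resid ** 2)
        tss_w = (K @ (y ** 2)) - wsum * ybar_w ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            local_r2 = 1.0 - rss_w / tss_w

        self.n_features_in_ = X.shape[1]
        self.coords_ = coords
        self.X_design_ = Xd
        self.y_ = y
        self.local_coef_ = coef
        self.local_stderr_ = stderr
        self.valid_ = ok
        self.fitted_ = fitted
        self.residuals_ = resid
        self.std_residuals_ = std_resid
        self.hat_diag_ = h
        self.tr_S_ = tr_S
        self.sigma2_ = sigma2
        self.rss_ = rss
        self.aic_ = float(aic)
        self.aicc_ = float(aicc)
        self.r2_ = float(r2)
        self.adj_r2_ = float(adj_r2)
        self.local_r2_ = local_r2
        self.coef_names_ = ["intercept"] + [f"x{k}" for k in range(p_pred)]
        return self

    def predict(self, X):
        """Predict at new locations by local WLS against the training data."""
        check_is_fitted(self, "local_coef_")
        X = check_array(X)
        coords_new = X[:, :2]
        pred_new = X[:, 2:]
        Xd_new = np.column_stack([np.ones(len(X)), pred_new])
        D = _pairwise_dist(coords_new, self.coords_)
        K = _kernel_matrix(D, self.bandwidth_, self.adaptive)
        # local solves against training observations
        n_new, p = Xd_new.shape
        out = np.empty(n_new)
        Xd, y = self.X_design_, self.y_
        for i in range(n_new):
            w = K[i]
            A = (Xd * w[:, None]).T @ Xd
            b = (Xd * w[:, None]).T @ y
            try:
                beta = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                beta = np.full(p, np.nan)
            out[i] = Xd_new[i] @ beta
        return out


# --------------------------------------------------------------------------- #
# bandwidth selection
# --------------------------------------------------------------------------- #

def _criterion_value(
    Xd, y, D, k: int, criterion: str
) -> float:
    n = len(y)
    K = _kernel_matrix(D, k, adaptive=True)
    if criterion == "cv":
        K = K.copy()
        np.fill_diagonal(K, 0.0)
        coef, _, ok = _gwr_solve(Xd, y, K)
        pred = np.einsum("ip,ip->i", Xd, coef)
        if not ok.all():
            return float("inf")
        return float(((y - pred) ** 2).sum())
    coef, Ainv, ok = _gwr_solve(Xd, y, K)
    if not ok.all():
        return float("inf")
    fitted = np.einsum("ip,ip->i", Xd, coef)
    rss = float(((y - fitted) ** 2).sum())
    h = np.einsum("ip,ipq,iq->i", Xd, Ainv, Xd) * K[np.arange(n), np.arange(n)]
    tr_S = float(h.sum())
    sigma = math.sqrt(rss / n)
    if criterion == "aic":
        return 2 * n * math.log(sigma) + n * math.log(2 * math.pi) + n + tr_S
    if criterion == "aicc":
        denom = n - 2.0 - tr_S
        if denom <= 0:
            return float("inf")
        return 2 * n * math.log(sigma) + n * math.log(2 * math.pi) \
            + n * (n + tr_S) / denom
    raise ValueError(f"unknown criterion {criterion!r}")


def select_bandwidth(
    coords,
    X,
    y,
    criterion: str = "aicc",
    search: str = "golden",
    k_range: tuple[int, int] | None = None,
    _D: np.ndarray | None = None,
) -> tuple[int, dict]:
    """Select the adaptive bandwidth (neighbor count) minimizing a criterion.

    Returns the optimal k and the evaluated criterion profile {k: value}.
    Golden-section search assumes a unimodal profile; if the evaluated
    profile is not unimodal the global minimum over evaluated points is
    returned with a warning. ``search='grid'`` evaluates every integer.
    """
    coords = np.asarray(coords, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p_pred = X.shape
    Xd = np.column_stack([np.ones(n), X])
    p = Xd.shape[1]
    k_min, k_max = k_range if k_range is not None else (p + 2, n)
    k_min = max(k_min, p + 2)
    k_max = min(k_max, n)
    if k_min > k_max:
        raise ValueError(f"empty bandwidth range [{k_min}, {k_max}]")
    D = _D if _D is not None else _pairwise_dist(coords, coords)

    cache: dict[int, float] = {}

    def f(k: int) -> float:
        k = int(k)
        if k not in cache:
            cache[k] = _criterion_value(Xd, y, D, k, criterion)
        return cache[k]

    if search == "grid":
        for k in range(k_min, k_max + 1):
            f(k)
    elif search == "golden":
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = float(k_min), float(k_max)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        while b - a > 1.0:
            if f(round(c)) <= f(round(d)):
                b = d
            else:
                a = c
            c = b - invphi * (b - a)
            d = a + invphi * (b - a)
        f(round(a))
        f(round(b))
        f(k_min)
        f(k_max)
    else:
        raise ValueError(f"unknown search {search!r}")

    ks = sorted(cache)
    vals = [cache[k] for k in ks]
    best = ks[int(np.argmin(vals))]
    finite = np.asarray([v for v in vals if np.isfinite(v)])
    diffs = np.sign(np.diff(finite)) if finite.size > 1 else np.array([])
    if search == "golden" and np.count_nonzero(np.diff(diffs[diffs != 0])) > 1:
        logger.warning("bandwidth criterion profile is not unimodal; "
                       "returning the minimum over evaluated points")
    return int(best), dict(zip(ks, vals))


# --------------------------------------------------------------------------- #
# summaries and model comparison
# --------------------------------------------------------------------------- #

def summarize_gwr(model: GWRegressor, coefficient: str | int = 1) -> dict:
    """Descriptive statistics of one local coefficient surface.

    ``coefficient`` is a name from ``coef_names_`` or a column index
    (0 = intercept, 1 = first predictor). Reports min/max/mean of the local
    coefficient, the mean of its local standard errors, the share of
    internally studentized residuals inside (-2.5, 2.5) — the conventional
    high-reliability band — and the shares of strictly positive and
    strictly negative local coefficients.
    """
    check_is_fitted(model, "local_coef_")
    if isinstance(coefficient, str):
        try:
            j = model.coef_names_.index(coefficient)
        except ValueError:
            raise KeyError(f"unknown coefficient {coefficient!r}; "
                           f"available: {model.coef_names_}") from None
    else:
        j = int(coefficient)
        if not 0 <= j < model.local_coef_.shape[1]:
            raise KeyError(f"coefficient index {j} out of range")
    c = model.local_coef_[model.valid_, j]
    se = model.local_stderr_[model.valid_, j]
    sr = model.std_residuals_[model.valid_]
    n = c.size
    return {
        "min": float(c.min()),
        "max": float(c.max()),
        "mean": float(c.mean()),
        "std_err": float(se.mean()),
        "pct_stdres_in_band": float(100.0 * ((sr > -2.5) & (sr < 2.5)).mean()),
        "pct_positive": float(100.0 * (c > 0).mean()),
        "pct_negative": float(100.0 * (c < 0).mean()),
        "pct_zero": float(100.0 * (c == 0).mean()),
        "n": n,
    }


def compare_models(ols: OlsResult, gwr: GWRegressor) -> dict:
    """Adjusted R^2 / AIC comparison with the Delta-AIC > 3 decision rule.

    The verdict is 'GWR preferred' iff AIC_GWR < AIC_OLS - 3, symmetrically
    'OLS preferred', and 'indistinguishable' within the 3-unit band.
    """
    check_is_fitted(gwr, "aic_")
    if ols.n != len(gwr.y_):
        raise ValueError(f"models fitted on different supports: "
                         f"n_ols={ols.n}, n_gwr={len(gwr.y_)}")
    delta = gwr.aic_ - ols.aic
    if delta < -3.0:
        verdict = "GWR preferred"
    elif delta > 3.0:
        verdict = "OLS preferred"
    else:
        verdict = "indistinguishable"
    return {
        "adj_r2_ols": ols.adj_r2,
        "adj_r2_gwr": gwr.adj_r2_,
        "aic_ols": ols.aic,
        "aic_gwr": gwr.aic_,
        "delta_aic": float(delta),
        "verdict": verdict,
    }
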