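"""Elastic-net penalized logistic regression, written from first principles.

The fitter minimizes the penalized average negative log-likelihood

    (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
        + lambda * sum_j pf_j * ( alpha * |b_j| + (1 - alpha)/2 * b_j^2 )

with eta = b0 + X b, an unpenalized intercept, and per-column penalty factors
``pf``. The algorithm is the standard outer/inner scheme: an iteratively
re-weighted least-squares (IRLS) quadratic approximation around the current
linear predictor, solved by cyclic coordinate descent with soft-thresholding,
warm starts and an ever-active-set strategy. Columns are standardized to zero
mean and unit variance internally (lambda lives on the standardized scale);
coefficients are reported back on the original predictor scale.

A damped Newton-Raphson maximum-likelihood fitter is included as the
``lambda = 0`` reference, and :func:`kkt_check` certifies stationarity of any
fit via the subgradient conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import expit, logit

__all__ = [
    "ElasticNetFit",
    "lambda_path",
    "fit_enet_logistic",
    "kkt_check",
    "newton_logistic",
    "NewtonFit",
]

_W_FLOOR = 1e-5
_P_EPS = 1e-5


# ----------------------------------------------------------------------------
# Inner solver: penalized weighted least squares by cyclic coordinate descent
# ----------------------------------------------------------------------------

@njit(fastmath=True)
def _cd_solve(X, w, z, b, b0, l1, l2, tol, max_sweeps):  # pragma: no cover - jit
    """Minimize (1/2n) sum w_i (z_i - b0 - x_i.b)^2 + sum_j l1_j|b_j| + l2_j b_j^2/2.

    Mutates ``b`` in place; returns (b0, sweeps). Uses an ever-active-set
    strategy: full sweeps alternate with sweeps over coordinates that have
    ever been nonzero, and convergence is declared only after a clean full
    sweep.
    """
    n, p = X.shape
    r = np.empty(n)
    for i in range(n):
        s = z[i] - b0
        for j in range(p):
            if b[j] != 0.0:
                s -= X[i, j] * b[j]
        r[i] = s
    wsum = 0.0
    for i in range(n):
        wsum += w[i]
    xwx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        xwx[j] = s / n
    ever = np.zeros(p, np.bool_)
    for j in range(p):
        if b[j] != 0.0:
            ever[j] = True
    full_pass = True
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        dmax = 0.0
        for j in range(p):
            if not full_pass and not ever[j]:
                continue
            if xwx[j] <= 0.0:
                continue
            bj = b[j]
            g = 0.0
            for i in range(n):
                g += w[i] * X[i, j] * r[i]
            g = g / n + xwx[j] * bj
            if g > l1[j]:
                bn = (g - l1[j]) / (xwx[j] + l2[j])
            elif g < -l1[j]:
                bn = (g + l1[j]) / (xwx[j] + l2[j])
            else:
                bn = 0.0
            d = bn - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * X[i, j]
                b[j] = bn
                if bn != 0.0:
                    ever[j] = True
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
        gi = 0.0
        for i in range(n):
            gi += w[i] * r[i]
        d0 = gi / wsum
        if d0 != 0.0:
            b0 += d0
            for i in range(n):
                r[i] -= d0
            ad0 = abs(d0)
            if ad0 > dmax:
                dmax = ad0
        if dmax < tol:
            if full_pass:
                break
            full_pass = True
        else:
            full_pass = False
    return b0, sweeps


@njit(fastmath=True)
def _objective_nb(X, y, b, b0, lam, alpha, pf):  # pragma: no cover - jit
    n, p = X.shape
    nll = 0.0
    for i in range(n):
        eta = b0
        for j in range(p):
            if b[j] != 0.0:
                eta += X[i, j] * b[j]
        m = eta if eta > 0.0 else 0.0
        nll += m + math.log1p(math.exp(-abs(eta))) - y[i] * eta
    pen = 0.0
    for j in range(p):
        pen += pf[j] * (alpha * abs(b[j]) + 0.5 * (1.0 - alpha) * b[j] * b[j])
    return nll / n + lam * pen


@njit(fastmath=True)
def _irls_enet_nb(X, y, lam, alpha, pf, tol, max_outer, max_inner, b, b0):  # pragma: no cover
    """All-compiled IRLS + coordinate descent for one lambda (mutates b)."""
    n, p = X.shape
    l1 = lam * alpha * pf
    l2 = lam * (1.0 - alpha) * pf
    obj = _objective_nb(X, y, b, b0, lam, alpha, pf)
    converged = False
    w = np.empty(n)
    z = np.empty(n)
    b_old = np.empty(p)
    for _ in range(max_outer):
        for j in range(p):
            b_old[j] = b[j]
        b0_old = b0
        for i in range(n):
            eta = b0
            for j in range(p):
                if b[j] != 0.0:
                    eta += X[i, j] * b[j]
            pv = 1.0 / (1.0 + math.exp(-eta))
            if pv < _P_EPS:
                pv = 0.0
                w[i] = _W_FLOOR
            elif pv > 1.0 - _P_EPS:
                pv = 1.0
                w[i] = _W_FLOOR
            else:
                w[i] = pv * (1.0 - pv)
            z[i] = eta + (y[i] - pv) / w[i]
        b0, _ = _cd_solve(X, w, z, b, b0, l1, l2, tol, max_inner)
        new_obj = _objective_nb(X, y, b, b0, lam, alpha, pf)
        if new_obj > obj + 1e-12:
            # halve the offset from the previous iterate until descent
            for _h in range(30):
                for j in range(p):
                    b[j] = b_old[j] + 0.5 * (b[j] - b_old[j])
                b0 = b0_old + 0.5 * (b0 - b0_old)
                new_obj = _objective_nb(X, y, b, b0, lam, alpha, pf)
                if new_obj <= obj + 1e-12:
                    break
        delta = abs(b0 - b0_old)
        for j in range(p):
            d = abs(b[j] - b_old[j])
            if d > delta:
                delta = d
        if new_obj < obj:
            obj = new_obj
        if delta < tol:
            converged = True
            break
    return b0, converged, obj


@njit(fastmath=True)
def _path_nb(X, y, lambdas, alpha, pf, tol, max_outer, max_inner):  # pragma: no cover
    n, p = X.shape
    L = lambdas.shape[0]
    B0 = np.empty(L)
    B = np.empty((L, p))
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b0 = math.log(ybar / (1.0 - ybar))
    b = np.zeros(p)
    for k in range(L):
        b0, _, _ = _irls_enet_nb(X, y, lambdas[k], alpha, pf, tol, max_outer, max_inner, b, b0)
        B0[k] = b0
        for j in range(p):
            B[k, j] = b[j]
    return B0, B


def _objective(Xs, y, b, b0, lam, alpha, pf) -> float:
    eta = b0 + Xs @ b
    nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    pen = lam * float(np.sum(pf * (alpha * np.abs(b) + 0.5 * (1 - alpha) * b * b)))
    return nll + pen


def _irls_weights(eta, y):
    pv = expit(eta)
    lo = pv < _P_EPS
    hi = pv > 1 - _P_EPS
    pv = pv.copy()
    pv[lo] = 0.0
    pv[hi] = 1.0
    w = pv * (1 - pv)
    w[lo | hi] = _W_FLOOR
    z = eta + (y - pv) / w
    return w, z


def _irls_enet(Xs, y, lam, alpha, pf, tol, max_outer, max_inner, b, b0):
    """Outer IRLS loop on standardized predictors. Mutates ``b``.

    Returns (b0, n_iter, converged, objective, obj_trace). A step-halving
    safeguard keeps the penalized objective non-increasing across outer
    iterations.
    """
    l1 = lam * alpha * pf
    l2 = lam * (1 - alpha) * pf
    obj = _objective(Xs, y, b, b0, lam, alpha, pf)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        b_old = b.copy()
        b0_old = b0
        eta = b0 + Xs @ b
        w, z = _irls_weights(eta, y)
        b0, _ = _cd_solve(Xs, w, z, b, b0, l1, l2, tol, max_inner)
        new_obj = _objective(Xs, y, b, b0, lam, alpha, pf)
        if new_obj > obj + 1e-12:
            # quadratic approximation overshot: halve the step until descent
            step = 1.0
            direction = b - b_old
            d0 = b0 - b0_old
            for _ in range(30):
                step *= 0.5
                b[:] = b_old + step * direction
                b0 = b0_old + step * d0
                new_obj = _objective(Xs, y, b, b0, lam, alpha, pf)
                if new_obj <= obj + 1e-12:
                    break
        delta = max(np.max(np.abs(b - b_old)) if b.size else 0.0, abs(b0 - b0_old))
        obj = min(obj, new_obj)
        trace.append(obj)
        if delta < tol:
            converged = True
            break
    return b0, it, converged, obj, trace


# ----------------------------------------------------------------------------
# Public fitting interface
# ----------------------------------------------------------------------------

@dataclass
class ElasticNetFit:
    """A fitted elastic-net logistic model.

    ``coefs`` and ``intercept`` are on the original predictor scale;
    ``coefs_std``/``intercept_std`` are the internal standardized-scale
    solution on which the penalty (and :func:`kkt_check`) operate.
    """

    alpha: float
    lam: float
    intercept: float
    coefs: np.ndarray
    active_set: np.ndarray
    signs: np.ndarray
    n_iter: int
    converged: bool
    objective: float
    standardized: bool = True
    penalty_factors: np.ndarray | None = None
    coefs_std: np.ndarray | None = field(default=None, repr=False)
    intercept_std: float | None = field(default=None, repr=False)
    col_means: np.ndarray | None = field(default=None, repr=False)
    col_scales: np.ndarray | None = field(default=None, repr=False)
    objective_trace: list = field(default_factory=list, repr=False)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept + np.asarray(X, float) @ self.coefs)

    def to_dict(self, names: list[str] | None = None) -> dict:
        p = len(self.coefs)
        names = names if names is not None else [f"x{j}" for j in range(p)]
        return {
            "alpha": self.alpha,
            "lambda": self.lam,
            "intercept": self.intercept,
            "coefficients": {names[j]: float(self.coefs[j]) for j in range(p)},
            "active_set": [names[j] for j in self.active_set],
            "n_iter": self.n_iter,
            "converged": self.converged,
            "objective": self.objective,
        }


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns to unit (population) variance.

    Zero-variance columns get scale 1 so they become all-zero columns and
    their coefficients stay at zero.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    return (X - means) / scales, means, scales


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x p with len(y) == n")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate outcome: y is constant")
    return X, y


def lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    min_ratio: float = 0.01,
    penalty_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Descending log-equally-spaced penalty path.

    ``lambda_max = max_j |x~_j . (y - ybar)| / (n * alpha)`` on standardized
    columns, the smallest penalty at which every penalized coefficient is
    exactly zero. For ridge (alpha = 0) the same anchor is computed at
    alpha = 0.001 so paths stay comparable across the mixing grid.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, float)
    Xs, _, _ = standardize_columns(X)
    g = np.abs(Xs.T @ (y - y.mean())) / n
    with np.errstate(divide="ignore"):
        g_pf = np.where(pf > 0, g / np.where(pf > 0, pf, 1.0), 0.0)
    alpha_eff = max(alpha, 1e-3)
    lam_max = float(g_pf.max()) / alpha_eff
    if lam_max <= 0:
        raise ValueError("all penalized columns are orthogonal to the outcome")
    # tiny inflation keeps the top of the path on the all-zero side of the
    # KKT tie despite floating-point rounding
    lam_max *= 1 + 1e-9
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def fit_enet_logistic(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    penalty_factors: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 1000,
    max_inner: int = 1000,
    warm_start: tuple[float, np.ndarray] | None = None,
) -> ElasticNetFit:
    """Fit the elastic-net logistic model at a single (alpha, lambda).

    ``warm_start`` is an optional ``(intercept_std, coefs_std)`` pair on the
    standardized scale. Non-convergence (e.g. perfect separation at
    lambda = 0) is flagged via ``converged=False``, never silently hidden.
    """
    X, y = _validate_xy(X, y)
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, float)
    Xs, means, scales = standardize_columns(X)
    Xs = np.asfortranarray(Xs)
    if warm_start is not None:
        b0, b = float(warm_start[0]), np.array(warm_start[1], dtype=float)
    else:
        b0, b = float(logit(y.mean())), np.zeros(p)
    b0, n_iter, converged, obj, trace = _irls_enet(
        Xs, y, lam, alpha, pf, tol, max_iter, max_inner, b, b0
    )
    coefs = b / scales
    intercept = b0 - float(np.sum(b * means / scales))
    active = np.flatnonzero(b != 0.0)
    return ElasticNetFit(
        alpha=alpha,
        lam=lam,
        intercept=intercept,
        coefs=coefs,
        active_set=active,
        signs=np.sign(b[active]).astype(int),
        n_iter=n_iter,
        converged=converged,
        objective=obj,
        penalty_factors=pf,
        coefs_std=b,
        intercept_std=b0,
        col_means=means,
        col_scales=scales,
        objective_trace=trace,
    )


def kkt_check(fit: ElasticNetFit, X: np.ndarray, y: np.ndarray) -> float:
    """Maximum subgradient (stationarity) violation of a fit.

    On the standardized scale with average-log-loss gradient g: active
    coordinates must satisfy ``g_j + lam*(1-alpha)*pf_j*b_j +
    lam*alpha*pf_j*sign(b_j) = 0``; inactive ones ``|g_j| <= lam*alpha*pf_j``;
    the intercept score must vanish. Returns the largest violation.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    b = fit.coefs_std
    Xs = (X - fit.col_means) / fit.col_scales
    pv = expit(fit.intercept_std + Xs @ b)
    g = Xs.T @ (pv - y) / n
    lam, alpha, pf = fit.lam, fit.alpha, fit.penalty_factors
    active = b != 0.0
    viol = abs(float(np.mean(pv - y)))
    if active.any():
        resid = g[active] + lam * (1 - alpha) * pf[active] * b[active] \
            + lam * alpha * pf[active] * np.sign(b[active])
        viol = max(viol, float(np.max(np.abs(resid))))
    if (~active).any():
        slack = np.abs(g[~active]) - lam * alpha * pf[~active]
        viol = max(viol, float(max(0.0, np.max(slack))))
    return viol


# ----------------------------------------------------------------------------
# Unpenalized maximum likelihood (Newton-Raphson) — the lambda = 0 reference
# ----------------------------------------------------------------------------

@dataclass
class NewtonFit:
    intercept: float
    coefs: np.ndarray
    converged: bool
    n_iter: int
    cov: np.ndarray  # inverse observed information of (intercept, coefs)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept + np.asarray(X, float) @ self.coefs)


def newton_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> NewtonFit:
    """Damped Newton-Raphson logistic MLE with intercept.

    Raises on a numerically singular information matrix; flags
    non-convergence (e.g. complete separation) instead of returning silently.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    beta[0] = logit(y.mean())
    nll = lambda bb: float(np.mean(np.logaddexp(0.0, Z @ bb) - y * (Z @ bb)))
    f = nll(beta)
    converged = False
    it = 0
    H = np.eye(p + 1)
    for it in range(1, max_iter + 1):
        eta = Z @ beta
        pv = expit(eta)
        grad = Z.T @ (pv - y) / n
        w = np.maximum(pv * (1 - pv), 1e-10)
        H = (Z * w[:, None]).T @ Z / n
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular information matrix (collinear predictors)"
            ) from e
        t = 1.0
        for _ in range(40):
            cand = beta - t * step
            fc = nll(cand)
            if fc <= f - 1e-4 * t * float(grad @ step):
                break
            t *= 0.5
        beta = beta - t * step
        f_new = nll(beta)
        if np.max(np.abs(t * step)) < tol:
            converged = True
            f = f_new
            break
        f = f_new
    cov = np.linalg.inv(H) / n
    return NewtonFit(
        intercept=float(beta[0]), coefs=beta[1:], converged=converged, n_iter=it, cov=cov
    )


# Internal: warm-started path fitting on a pre-standardized design ------------

def _fit_path_std(Xs, y, lambdas, alpha, pf, tol, max_outer=1000, max_inner=1000):
    """Fit a descending lambda path on standardized columns with warm starts.

    Returns (B0, B): intercepts (L,) and coefficients (L, p), both on the
    standardized scale. ``Xs`` is used column-wise; Fortran order is fastest.
    """
    Xs = np.asfortranarray(Xs)
    return _path_nb(
        Xs,
        np.ascontiguousarray(y, dtype=np.float64),
        np.ascontiguousarray(lambdas, dtype=np.float64),
        float(alpha),
        np.ascontiguousarray(pf, dtype=np.float64),
        float(tol),
        int(max_outer),
        int(max_inner),
    )
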