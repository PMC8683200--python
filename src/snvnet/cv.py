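"""Leave-one-out cross-validated AUC model selection over the (alpha, lambda) grid.

Each sample is held out once; the model is refit on the remaining n-1
(standardization recomputed inside every training fold to avoid leakage,
warm starts along the descending lambda path), and the held-out predicted
probabilities are pooled into a single rank-based AUC per grid point —
per-fold AUC is undefined for single-sample folds, so pooling is the only
coherent leave-one-out reading. The selected point is the AUC argmax with
deterministic tie-breaking toward larger lambda (sparser) and then larger
alpha (more lasso-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .glm import _fit_path_std, _validate_xy, lambda_path, standardize_columns
from scipy.special import expit

__all__ = ["CVResult", "auc", "loo_cv_auc", "loo_path_scores", "grid_search"]

DEFAULT_ALPHAS = (0.0, 0.5, 1.0)
#: Convergence tolerance used inside cross-validation folds (standardized scale).
CV_TOL = 1e-5
#: Cap on outer IRLS iterations inside CV folds (warm starts make this ample).
CV_MAX_OUTER = 50


@dataclass
class CVResult:
    """Grid of (alpha, lambda) -> pooled LOO AUC with the selected optimum."""

    grid: list = field(repr=False)  # (alpha, lambda, auc) tuples
    best_alpha: float = 0.0
    best_lam: float = 0.0
    best_auc: float = 0.0
    n_folds: int = 0
    pooled: bool = True

    def grid_records(self) -> list[dict]:
        return [
            {"alpha": a, "lambda": l, "log_lambda": float(np.log(l)), "auc": u}
            for a, l, u in self.grid
        ]


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC: P(score+ > score-) + 0.5 * P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def loo_path_scores(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    penalty_factors: np.ndarray | None = None,
    tol: float = CV_TOL,
    max_outer: int = CV_MAX_OUTER,
) -> np.ndarray:
    """Held-out predicted probabilities, one row per sample, one column per lambda.

    For each fold, columns are re-standardized on the training samples and
    the whole descending path is fit with warm starts before predicting the
    single held-out sample at every lambda. Folds that hit the outer IRLS cap
    (e.g. quasi-separated fits at the smallest penalties) contribute their
    last iterate.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, float)
    lambdas = np.asarray(lambdas, dtype=float)
    out = np.empty((n, len(lambdas)))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if ytr.min() == ytr.max():
            raise ValueError("a training fold lost one outcome class")
        Xs, means, scales = standardize_columns(X[mask])
        B0, B = _fit_path_std(Xs, ytr, lambdas, alpha, pf, tol, max_outer=max_outer)
        xi = (X[i] - means) / scales
        out[i] = expit(B0 + B @ xi)
    return out


def loo_cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    penalty_factors: np.ndarray | None = None,
    tol: float = CV_TOL,
) -> float:
    """Pooled leave-one-out AUC at a single (alpha, lambda)."""
    if len(np.asarray(y)) < 10:
        raise ValueError("leave-one-out CV needs n >= 10")
    scores = loo_path_scores(X, y, alpha, np.array([lam]), penalty_factors, tol)
    return auc(scores[:, 0], y)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    n_lambda: int = 100,
    min_ratio: float = 0.01,
    penalty_factors: np.ndarray | None = None,
    tol: float = CV_TOL,
) -> CVResult:
    """Pooled LOO AUC over the full mixing x penalty grid.

    The lambda path is anchored per alpha on the full data (the study grid:
    3 mixing values x 100 penalties). Ties break toward larger lambda, then
    larger alpha.
    """
    X, y = _validate_xy(X, y)
    grid: list[tuple[float, float, float]] = []
    best = None  # (auc, lam, alpha)
    for alpha in alphas:
        lambdas = lambda_path(X, y, alpha, n_lambda, min_ratio, penalty_factors)
        scores = loo_path_scores(X, y, alpha, lambdas, penalty_factors, tol)
        for k, lam in enumerate(lambdas):
            u = auc(scores[:, k], y)
            grid.append((float(alpha), float(lam), u))
            key = (u, float(lam), float(alpha))
            if best is None or key > best:
                best = key
    return CVResult(
        grid=grid,
        best_alpha=best[2],
        best_lam=best[1],
        best_auc=best[0],
        n_folds=len(y),
        pooled=True,
    )
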