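"""Internal penalized least-squares machinery.

Objective (glmnet parameterization), for mixing parameter ``l1_ratio`` (the
elastic-net alpha) and overall penalty ``lam`` (lambda):

    (1/2N) ||y - b0 - X w||^2 + lam * [ (1-l1_ratio)/2 ||w||_2^2
                                        + l1_ratio ||w||_1 ]

Lasso/elastic-net solutions come from scikit-learn's coordinate descent,
which uses the same parameterization; pure ridge (l1_ratio = 0) is computed
in closed form through the SVD, which is exact and cheap enough to evaluate
whole lambda paths and thousands of bootstrap refits.

Cross-validation uses Gaussian deviance (held-out MSE). ``lambda_1se`` is
the largest lambda whose mean CV deviance is within one standard error of
the minimum — the conventional sparser-model rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

RIDGE_ALPHA_FLOOR = 1e-3  # stand-in l1_ratio when sizing the lambda grid at alpha=0


def lambda_grid(X: np.ndarray, y: np.ndarray, l1_ratio: float,
                n_lambda: int = 50, min_ratio: float | None = None) -> np.ndarray:
    """Descending log-spaced lambda path, glmnet-style.

    lambda_max = max |X' (y - ybar)| / (N * max(l1_ratio, 1e-3)); the floor
    keeps the grid finite for ridge. min_ratio defaults to 1e-2 when N < p
    and 1e-4 otherwise.
    """
    n, p = X.shape
    if min_ratio is None:
        min_ratio = 1e-2 if n < p else 1e-4
    yc = y - y.mean()
    lam_max = np.max(np.abs(X.T @ yc)) / (n * max(l1_ratio, RIDGE_ALPHA_FLOOR))
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambda)


def ridge_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form ridge coefficients along a lambda path.

    Solves (X_c' X_c + N*lam I) w = X_c' y_c for centered data via SVD.
    Returns (coefs with shape (p, L), intercepts with shape (L,)).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
    uty = U.T @ (y - y_mean)
    lambdas = np.asarray(lambdas, float)
    shrink = d[:, None] / (d[:, None] ** 2 + n * lambdas[None, :])
    coefs = Vt.T @ (shrink * uty[:, None])
    intercepts = y_mean - x_mean @ coefs
    return coefs, intercepts


def coef_path(X: np.ndarray, y: np.ndarray, l1_ratio: float,
              lambdas: np.ndarray, tol: float = 1e-4,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient path over a descending lambda grid.

    Returns (coefs (p, L), intercepts (L,)). Coordinate descent with warm
    starts for l1_ratio > 0; exact SVD ridge otherwise.
    """
    lambdas = np.asarray(lambdas, float)
    if l1_ratio <= 0:
        return ridge_path(X, y, lambdas)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    # pre-centered Fortran-ordered input lets the solver skip validation
    Xc = np.asfortranarray(X - x_mean, dtype=np.float64)
    yc = np.ascontiguousarray(y - y_mean, dtype=np.float64)
    _, coefs, _ = enet_path(Xc, yc, l1_ratio=l1_ratio, alphas=lambdas,
                            tol=tol, check_input=False)
    intercepts = y_mean - x_mean @ coefs
    return coefs, intercepts


@dataclass
class CvResult:
    """Cross-validated deviance profile along a lambda path."""

    l1_ratio: float
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray

    @property
    def i_min(self) -> int:
        return int(np.argmin(self.mean_deviance))

    @property
    def lambda_min(self) -> float:
        return float(self.lambdas[self.i_min])

    @property
    def deviance_min(self) -> float:
        return float(self.mean_deviance[self.i_min])

    @property
    def i_1se(self) -> int:
        cutoff = self.deviance_min + self.se_deviance[self.i_min]
        ok = np.where(self.mean_deviance <= cutoff)[0]
        # lambdas are descending: the first qualifying index is the largest lambda
        return int(ok[0])

    @property
    def lambda_1se(self) -> float:
        return float(self.lambdas[self.i_1se])

    @property
    def deviance_1se(self) -> float:
        return float(self.mean_deviance[self.i_1se])


def cv_deviance(X: np.ndarray, y: np.ndarray, l1_ratio: float,
                lambdas: np.ndarray | None = None, n_folds: int = 10,
                seed: int = 0, tol: float = 1e-4, n_lambda: int = 50,
                min_ratio: float | None = None,
                folds: list | None = None) -> CvResult:
    """K-fold CV of the elastic net along a lambda path.

    ``folds`` may be passed explicitly (list of (train, test) index arrays)
    so several l1_ratio values share one fold assignment.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if lambdas is None:
        lambdas = lambda_grid(X, y, l1_ratio, n_lambda=n_lambda,
                              min_ratio=min_ratio)
    if folds is None:
        if n < 2 * n_folds:
            raise ValueError(f"n={n} too small for {n_folds}-fold CV")
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(kf.split(X))
    fold_dev = np.empty((len(folds), len(lambdas)))
    for f, (tr, te) in enumerate(folds):
        coefs, intercepts = coef_path(X[tr], y[tr], l1_ratio, lambdas, tol=tol)
        pred = X[te] @ coefs + intercepts[None, :]
        fold_dev[f] = np.mean((y[te, None] - pred) ** 2, axis=0)
    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(len(folds))
    return CvResult(l1_ratio=float(l1_ratio), lambdas=np.asarray(lambdas, float),
                    mean_deviance=mean_dev, se_deviance=se_dev)


def cv_deviance_multi(X: np.ndarray, y: np.ndarray, l1_ratios: np.ndarray,
                      n_folds: int = 10, seed: int = 0, tol: float = 1e-4,
                      n_lambda: int = 25, min_ratio: float | None = 0.02,
                      ) -> list[CvResult]:
    """CV deviance profiles for several mixing values sharing one fold split.

    Per-fold Gram matrices and centered views are computed once and reused
    across the whole l1_ratio grid — the dominant cost when the same folds
    are cross-validated twenty-odd times per subsample. The lambda grid for
    each l1_ratio is the alpha=1 grid divided by max(l1_ratio, 1e-3),
    matching `lambda_grid` exactly.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if n < 2 * n_folds:
        raise ValueError(f"n={n} too small for {n_folds}-fold CV")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    base_grid = lambda_grid(X, y, 1.0, n_lambda=n_lambda, min_ratio=min_ratio)
    prepared = []
    for tr, te in folds:
        Xtr = X[tr]
        ytr = y[tr]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        Xc = np.asfortranarray(Xtr - xm)
        yc = np.ascontiguousarray(ytr - ym)
        # Gram-based descent pays off only when features fit under samples
        if Xc.shape[1] <= Xc.shape[0]:
            gram, xy = Xc.T @ Xc, Xc.T @ yc
        else:
            gram, xy = False, None
        prepared.append((Xc, yc, gram, xy, xm, ym, X[te], y[te]))
    out = []
    for l1 in np.asarray(l1_ratios, float):
        lambdas = base_grid / max(l1, RIDGE_ALPHA_FLOOR)
        fold_dev = np.empty((n_folds, n_lambda))
        for f, (Xc, yc, gram, xy, xm, ym, Xte, yte) in enumerate(prepared):
            if l1 <= 0:
                coefs, _ = ridge_path(Xc, yc, lambdas)
            else:
                _, coefs, _ = enet_path(Xc, yc, l1_ratio=float(l1),
                                        alphas=lambdas, tol=tol,
                                        precompute=gram, Xy=xy,
                                        check_input=False)
            intercepts = ym - xm @ coefs
            pred = Xte @ coefs + intercepts[None, :]
            fold_dev[f] = np.mean((yte[:, None] - pred) ** 2, axis=0)
        mean_dev = fold_dev.mean(axis=0)
        se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        out.append(CvResult(l1_ratio=float(l1), lambdas=lambdas,
                            mean_deviance=mean_dev, se_deviance=se_dev))
    return out


def fit_at(X: np.ndarray, y: np.ndarray, l1_ratio: float, lam: float,
           tol: float = 1e-4) -> tuple[float, np.ndarray]:
    """Single fit at (l1_ratio, lambda); returns (intercept, coefficients).

    For the l1 path a short warm-started path down to ``lam`` is used, which
    is how coordinate-descent solvers reach a stable solution quickly.
    """
    if l1_ratio <= 0:
        coefs, intercepts = ridge_path(X, y, np.array([lam]))
        return float(intercepts[0]), coefs[:, 0]
    path = lambda_grid(X, y, l1_ratio, n_lambda=10)
    path = np.append(path[path > lam], lam)
    coefs, intercepts = coef_path(X, y, l1_ratio, path, tol=tol)
    return float(intercepts[-1]), coefs[:, -1]
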