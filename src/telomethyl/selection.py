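"""Three-stage statistical-learning selection of CpGs and interactions.

Given EWAS-screened candidate CpGs, the selection proceeds:

1. **Adaptive lasso** on all candidates jointly, with per-CpG penalty weights
   set to the inverse absolute ridge coefficients (ridge spreads weight over
   correlated CpGs, so probes it shrinks hard are penalized harder still).
   Lambda is chosen by 10-fold CV with the one-standard-error rule.
2. **Interaction expansion**: all pairwise products of the standardized
   selected CpGs (products are NOT re-standardized) join the main effects.
3. **Stability elastic net**: B random subsamples (default 1000 draws of 85%
   of samples, without replacement); within each, the elastic-net mixing
   alpha is tuned over a 0..1 grid (step 0.05) by CV deviance at lambda_1se
   and the model refit at the winning pair; terms selected in at least 95%
   of subsamples are "active".

Active interactions then pull their member CpGs into the main-effect set
(term expansion), and the final weights come from a ridge fit on the whole
data with bootstrap-simulated p-values per coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._penalized import (cv_deviance, cv_deviance_multi, fit_at, lambda_grid,
                         ridge_path)
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "PenalizedFitConfig",
    "StabilityProfile",
    "FinalModel",
    "standardize",
    "adaptive_weights",
    "adaptive_lasso_select",
    "build_interactions",
    "tune_alpha",
    "stability_selection",
    "expand_terms",
    "final_ridge_fit",
    "bootstrap_pvalues",
]

INTERACTION_SEP = ":"


@dataclass
class PenalizedFitConfig:
    """Tuning knobs shared by the penalized-selection stages.

    alpha_step       grid resolution for the elastic-net mixing parameter
    n_folds          CV folds for every lambda/alpha choice
    convergence_tol  coordinate-descent convergence threshold
    n_lambda         length of each lambda path
    b_stability      subsampling replicates for stability selection
    subsample_fraction  fraction of samples per stability draw
    frequency_threshold selection frequency defining an "active" term
    b_bootstrap      bootstrap replicates for final-model p-values
    """

    alpha_step: float = 0.05
    n_folds: int = 10
    # coordinate-descent tolerance on the solver's relative duality gap; at
    # 1e-4 the gap bound implies coefficient accuracy beyond a 1e-7
    # coefficient-change rule, the convention other solvers use
    convergence_tol: float = 1e-4
    # looser tolerance for CV-grid deviance evaluation only: fold deviances
    # are means over held-out samples and insensitive to the last digits of
    # the training fit (verified to leave selected sets unchanged)
    cv_tol: float = 3e-3
    n_lambda: int = 25
    lambda_min_ratio: float = 0.02
    b_stability: int = 1000
    subsample_fraction: float = 0.85
    frequency_threshold: float = 0.95
    b_bootstrap: int = 10000
    seed: int = 0

    @property
    def alpha_grid(self) -> np.ndarray:
        n = int(round(1.0 / self.alpha_step))
        return np.linspace(0.0, 1.0, n + 1)


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center to mean 0 and scale to sd 1 (n-1 denominator) per column.

    Returns (standardized frame, means, sds) so fits can be back-transformed
    to the original beta scale.
    """
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = sds.index[(sds == 0) | ~np.isfinite(sds)]
    if len(bad):
        raise ValueError(f"constant column(s): {list(bad[:5])}")
    return (X - means) / sds, means, sds


def adaptive_weights(X_std: pd.DataFrame, y: np.ndarray,
                     config: PenalizedFitConfig | None = None,
                     floor: float = 1e-8) -> pd.Series:
    """Adaptive-lasso penalty weights: inverse absolute ridge coefficients.

    The ridge lambda is chosen by CV at minimum deviance. Coefficients with
    magnitude below ``floor`` are floored before inversion, capping the
    penalty at 1/floor rather than producing infinities.
    """
    config = config or PenalizedFitConfig()
    Xv = X_std.to_numpy(float)
    cv = cv_deviance(Xv, y, l1_ratio=0.0, n_folds=config.n_folds,
                     seed=config.seed, tol=config.convergence_tol,
                     n_lambda=config.n_lambda, min_ratio=config.lambda_min_ratio)
    coefs, _ = ridge_path(Xv, y, np.array([cv.lambda_min]))
    w = coefs[:, 0]
    if np.all(w == 0):
        raise ValueError("ridge fit returned all-zero coefficients")
    a = 1.0 / np.maximum(np.abs(w), floor)
    return pd.Series(a, index=X_std.columns, name="penalty_weight")


def adaptive_lasso_select(X_std: pd.DataFrame, y: np.ndarray, a: pd.Series,
                          config: PenalizedFitConfig | None = None,
                          ) -> tuple[list[str], pd.Series]:
    """Weighted-penalty lasso at lambda_1se; returns (selected ids, coefs).

    Implemented by the standard rescaling: columns are divided by their
    penalty weights, a plain lasso is fit, and coefficients are mapped back
    (w_k = w~_k / a_k). Selected ids are those with nonzero coefficients.
    """
    config = config or PenalizedFitConfig()
    if (a <= 0).any() or not np.isfinite(a).all():
        raise ValueError("penalty weights must be positive and finite")
    a = a.reindex(X_std.columns)
    Xs = X_std.to_numpy(float) / a.to_numpy()[None, :]
    yv = np.asarray(y, float)
    cv = cv_deviance(Xs, yv, l1_ratio=1.0, n_folds=config.n_folds,
                     seed=config.seed, tol=config.convergence_tol,
                     n_lambda=config.n_lambda, min_ratio=config.lambda_min_ratio)
    _, w_scaled = fit_at(Xs, yv, 1.0, cv.lambda_1se, tol=config.convergence_tol)
    w = w_scaled / a.to_numpy()
    coefs = pd.Series(w, index=X_std.columns)
    selected = [str(c) for c in X_std.columns[w_scaled != 0]]
    return selected, coefs


def interaction_id(s: str, t: str) -> str:
    lo, hi = sorted((str(s), str(t)))
    return f"{lo}{INTERACTION_SEP}{hi}"


def split_interaction(term: str) -> tuple[str, str]:
    s, t = term.split(INTERACTION_SEP)
    return s, t


def build_interactions(X_std: pd.DataFrame, ids: list[str]) -> pd.DataFrame:
    """All pairwise products of the standardized columns named in ``ids``.

    Products are not re-standardized. Columns are named "a:b" with the pair
    in lexicographic order, and the block is ordered lexicographically, so
    the construction is deterministic. k ids yield k(k-1)/2 columns.
    """
    ids = [str(i) for i in ids]
    if len(ids) < 2:
        logger.info("fewer than 2 ids: empty interaction block")
        return pd.DataFrame(index=X_std.index)
    ordered = sorted(ids)
    cols = {}
    for i, s in enumerate(ordered):
        xs = X_std[s].to_numpy()
        for t in ordered[i + 1:]:
            cols[interaction_id(s, t)] = xs * X_std[t].to_numpy()
    return pd.DataFrame(cols, index=X_std.index)


def tune_alpha(X: np.ndarray, y: np.ndarray, grid: np.ndarray,
               n_folds: int = 10, seed: int = 0, tol: float = 3e-3,
               fit_tol: float = 1e-4, n_lambda: int = 25,
               min_ratio: float | None = 0.02,
               ) -> tuple[float, float, float, int]:
    """Choose the elastic-net mixing alpha by CV deviance at lambda_1se.

    One fold assignment (fixed by ``seed``) is shared across the whole grid.
    Ties in deviance break toward larger alpha (the sparser model). Returns
    (alpha_star, lambda_1se at alpha_star, its deviance, n nonzero there).
    """
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("alpha grid is empty")
    results = cv_deviance_multi(X, y, grid, n_folds=n_folds, seed=seed,
                                tol=tol, n_lambda=n_lambda, min_ratio=min_ratio)
    best = None
    for cv in results:
        dev = cv.deviance_1se
        if best is None or dev <= best[2]:  # <=: later (larger) alpha wins ties
            best = (cv.l1_ratio, cv.lambda_1se, dev)
    alpha_star, lam_star, dev_star = best
    _, coef = fit_at(X, y, alpha_star, lam_star, tol=fit_tol)
    return alpha_star, lam_star, dev_star, int(np.count_nonzero(coef))


@dataclass
class StabilityProfile:
    """Selection frequencies over subsampled elastic-net fits."""

    frequency: pd.Series            # per term, in [0, 1]
    counts: pd.Series               # per term, integer <= B
    n_subsamples: int
    records: pd.DataFrame           # per subsample: alpha, lambda_1se, n_selected
    n_failures: int = 0

    def active(self, threshold: float = 0.95) -> list[str]:
        return [str(t) for t in self.frequency.index[self.frequency >= threshold]]


def subsample_size(n: int, fraction: float) -> int:
    return int(round(fraction * n))


def stability_selection(X_terms: pd.DataFrame, y: np.ndarray,
                        config: PenalizedFitConfig | None = None,
                        ) -> StabilityProfile:
    """Elastic-net stability selection over random subsamples.

    For each of B subsamples (fraction of samples, drawn without replacement,
    subsample b seeded as seed+b), alpha and lambda_1se are tuned by CV on
    the subsample, the elastic net is refit there, and nonzero terms are
    recorded. Frequencies over the B draws define the profile; fit failures
    are counted, never silently dropped.
    """
    config = config or PenalizedFitConfig()
    n = X_terms.shape[0]
    m = subsample_size(n, config.subsample_fraction)
    if m < 2 * config.n_folds:
        raise ValueError(f"subsample size {m} too small for {config.n_folds}-fold CV")
    Xv = X_terms.to_numpy(float)
    yv = np.asarray(y, float)
    counts = np.zeros(X_terms.shape[1], dtype=int)
    records, failures = [], 0
    for b in range(config.b_stability):
        rng = np.random.default_rng(config.seed + b)
        idx = rng.choice(n, size=m, replace=False)
        Xb, yb = Xv[idx], yv[idx]
        try:
            alpha_b, lam_b, _, _ = tune_alpha(
                Xb, yb, config.alpha_grid, n_folds=config.n_folds,
                seed=config.seed + b, tol=config.cv_tol,
                fit_tol=config.convergence_tol,
                n_lambda=config.n_lambda, min_ratio=config.lambda_min_ratio)
            _, coef = fit_at(Xb, yb, alpha_b, lam_b, tol=config.convergence_tol)
        except Exception as exc:  # noqa: BLE001 - accounted, not dropped
            logger.warning("subsample %d failed: %s", b, exc)
            failures += 1
            records.append((b, np.nan, np.nan, 0))
            continue
        nz = coef != 0
        counts += nz
        records.append((b, alpha_b, lam_b, int(nz.sum())))
    freq = counts / max(config.b_stability - failures, 1)
    return StabilityProfile(
        frequency=pd.Series(freq, index=X_terms.columns, name="frequency"),
        counts=pd.Series(counts, index=X_terms.columns, name="count"),
        n_subsamples=config.b_stability,
        records=pd.DataFrame(records, columns=["subsample", "alpha", "lambda_1se",
                                               "n_selected"]).set_index("subsample"),
        n_failures=failures,
    )


def expand_terms(active_mains: list[str], active_interactions: list[str],
                 ) -> tuple[list[str], list[str]]:
    """Add member CpGs of active interactions to the main-effect set.

    Returns (expanded mains, interactions). Mains keep their original order;
    new members are appended in the canonical order of the interaction list.
    """
    mains = [str(m) for m in active_mains]
    seen = set(mains)
    for term in active_interactions:
        for member in split_interaction(term):
            if member not in seen:
                mains.append(member)
                seen.add(member)
    return mains, [str(t) for t in active_interactions]


@dataclass
class FinalModel:
    """Ridge-estimated weighted-sum model over selected terms."""

    intercept: float
    weights: pd.Series               # over all terms (mains then interactions)
    lambda_: float
    r_pearson: float
    r_squared: float
    fitted: np.ndarray
    bootstrap_p: pd.Series | None = None
    term_ids: list[str] = field(default_factory=list)

    @property
    def main_weights(self) -> pd.Series:
        return self.weights[[t for t in self.weights.index
                             if INTERACTION_SEP not in t]]

    @property
    def interaction_weights(self) -> pd.Series:
        return self.weights[[t for t in self.weights.index
                             if INTERACTION_SEP in t]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"term": self.weights.index, "weight": self.weights.values})
        df["kind"] = ["interaction" if INTERACTION_SEP in t else "main"
                      for t in df["term"]]
        if self.bootstrap_p is not None:
            df["p_bootstrap"] = self.bootstrap_p.reindex(df["term"]).values
        return df


def final_ridge_fit(X_final: pd.DataFrame, y: np.ndarray,
                    config: PenalizedFitConfig | None = None) -> FinalModel:
    """Ridge fit of the final term set on the whole data.

    Lambda by CV at minimum deviance. Reports the Pearson correlation r
    between outcome and fitted weighted sum, and R^2 = r^2.
    """
    config = config or PenalizedFitConfig()
    Xv = X_final.to_numpy(float)
    yv = np.asarray(y, float)
    cv = cv_deviance(Xv, yv, l1_ratio=0.0, n_folds=config.n_folds,
                     seed=config.seed, tol=config.convergence_tol,
                     n_lambda=config.n_lambda, min_ratio=config.lambda_min_ratio)
    coefs, intercepts = ridge_path(Xv, yv, np.array([cv.lambda_min]))
    w = coefs[:, 0]
    fitted = Xv @ w + intercepts[0]
    r = float(np.corrcoef(yv, fitted)[0, 1])
    return FinalModel(intercept=float(intercepts[0]),
                      weights=pd.Series(w, index=X_final.columns, name="weight"),
                      lambda_=cv.lambda_min, r_pearson=r, r_squared=r * r,
                      fitted=fitted, term_ids=[str(c) for c in X_final.columns])


def bootstrap_pvalues(model: FinalModel, X_final: pd.DataFrame, y: np.ndarray,
                      b_bootstrap: int = 10000, seed: int = 0,
                      max_failure_fraction: float = 0.01) -> pd.Series:
    """Bootstrap p-values for the ridge coefficients.

    Nonparametric case resampling: samples are drawn with replacement, the
    ridge refit at the full-data lambda, and each coefficient's two-sided
    p-value taken as 2*min(P(w* <= 0), P(w* >= 0)) over replicates, floored
    at 1/B. Degenerate replicates (e.g. zero-variance columns) are counted;
    more than ``max_failure_fraction`` of them aborts.
    """
    Xv = X_final.to_numpy(float)
    yv = np.asarray(y, float)
    n, p = Xv.shape
    rng = np.random.default_rng(seed)
    boot = np.empty((b_bootstrap, p))
    failures = 0
    for b in range(b_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            coefs, _ = ridge_path(Xv[idx], yv[idx], np.array([model.lambda_]))
            boot[b] = coefs[:, 0]
        except np.linalg.LinAlgError:
            failures += 1
            boot[b] = np.nan
    if failures > max_failure_fraction * b_bootstrap:
        raise RuntimeError(f"{failures}/{b_bootstrap} bootstrap replicates failed")
    with np.errstate(invalid="ignore"):
        frac_le = np.nanmean(boot <= 0, axis=0)
        frac_ge = np.nanmean(boot >= 0, axis=0)
    p_val = 2.0 * np.minimum(frac_le, frac_ge)
    p_val = np.clip(p_val, 1.0 / b_bootstrap, 1.0)
    ps = pd.Series(p_val, index=X_final.columns, name="p_bootstrap")
    model.bootstrap_p = ps
    return ps
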