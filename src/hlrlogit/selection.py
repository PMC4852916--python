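"""Model selection: stratified K-fold cross-validation over a (λ, α) grid.

The hybrid penalty has two tuning parameters, so model selection scans a
two-dimensional surface: for each mixing weight α a descending λ path is
fitted per training fold (warm-started, leakage-free: standardization and
all solver state are recomputed inside each fold) and the held-out metric
is averaged across folds.  The default grids are 30 log-spaced λ values
from λ_max down to 0.01·λ_max at each α, and α ∈ {0.1, 0.3, 0.5, 0.7, 0.9}
for the two-parameter families.

Best-cell search (accuracy metric): cells within one held-out sample
(1/n) of the maximum mean accuracy count as tied; ties go to the smallest
α whose column contains a tied cell (the most grouped of the equally
scoring models), then to the smallest mean held-out deviance within that
column, then to the larger λ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


from .solver import HLRModel, fit_path, lambda_grid, lambda_max, logistic_prob
from .thresholding import Family, PenaltySpec

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "make_folds", "cross_validate", "accuracy", "auc",
           "DEFAULT_ALPHAS"]

DEFAULT_ALPHAS = (0.1, 0.3, 0.5, 0.7, 0.9)


def accuracy(y_true, y_pred) -> float:
    """Fraction of exact label matches."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    return float(np.mean(y_true == y_pred))


def auc(y_true, scores) -> float:
    """Area under the ROC curve (Mann–Whitney form; ties count 1/2)."""
    y_true = np.asarray(y_true).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch between y_true and scores")
    return float(roc_auc_score(y_true, scores))


def make_folds(y, k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: array of fold ids in {0, …, k-1}.

    Per-class fold sizes differ by at most one; deterministic given
    ``seed``.
    """
    y = np.asarray(y).ravel()
    n = y.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratified folds need >= k members per class (min is {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    assign = np.empty(n, dtype=int)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), y)):
        assign[test_idx] = fold_id
    return assign


@dataclass
class CVResult:
    """Cross-validation surface over (λ, α).

    ``lambda_grid`` has shape (L, A): each α has its own descending λ path
    (column ``a`` pairs with ``alpha_grid[a]``).  ``cv_score`` and
    ``cv_se`` are (L, A) matrices of the mean held-out metric and its
    standard error; ``best`` is the selected (λ, α) pair.
    """

    lambda_grid: np.ndarray
    alpha_grid: np.ndarray
    cv_score: np.ndarray
    cv_se: np.ndarray
    best: tuple
    rule: str
    metric: str
    family: Family
    best_index: tuple = (0, 0)
    model: Optional[HLRModel] = None


def _held_out_metric(betas, intercepts, X_te, y_te):
    """(accuracy, deviance) for every λ on one held-out fold; betas is (L, p)."""
    eta = intercepts[None, :] + X_te @ betas.T       # (n_te, L)
    prob = logistic_prob(eta)
    pred = (prob >= 0.5).astype(int)
    acc = np.mean(pred == y_te[:, None], axis=0)
    yy = y_te[:, None]
    dev = 2.0 * np.mean(np.logaddexp(0.0, eta) - yy * eta, axis=0)
    return acc, dev


def cross_validate(X, y, family: Family = Family.HLR, *,
                   lambda_grid_user=None, alpha_grid=None, k: int = 10,
                   seed: int = 0, metric: str = "accuracy",
                   rule: str = "min", n_lambda: int = 30,
                   lambda_min_ratio: float = 0.01, fit_intercept: bool = True,
                   tol: float = 1e-4, refit: bool = True) -> CVResult:
    """K-fold CV over the (λ, α) surface; optionally refit at the optimum.

    With ``refit=True`` the returned result carries ``model``: a fit on the
    full training data at the selected (λ, α), obtained from a warm-started
    path down to the selected λ.
    """
    family = Family(family)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if alpha_grid is None:
        if family in (Family.HLR, Family.EN):
            alpha_grid = DEFAULT_ALPHAS
        elif family is Family.L2:
            alpha_grid = (0.0,)
        else:
            alpha_grid = (1.0,)
    alphas = np.asarray(alpha_grid, dtype=float)
    A = alphas.shape[0]

    if lambda_grid_user is not None:
        lg = np.asarray(lambda_grid_user, dtype=float).ravel()
        uniq = np.unique(lg)[::-1]
        if uniq.shape[0] < lg.shape[0]:
            warnings.warn("duplicate lambda values removed from the grid",
                          UserWarning)
        if np.any(uniq <= 0):
            raise ValueError("lambda values must be positive")
        grids = np.tile(uniq[:, None], (1, A))
    else:
        cols = []
        for a in alphas:
            lmax = lambda_max(X, y, family, float(a),
                              fit_intercept=fit_intercept)
            cols.append(lambda_grid(lmax, n_lambda, lambda_min_ratio))
        grids = np.column_stack(cols)
    L = grids.shape[0]

    if metric not in ("accuracy", "deviance"):
        raise ValueError(f"unknown metric {metric!r}")
    assign = make_folds(y, k, seed)
    scores = np.full((L, A, k), np.nan)
    deviances = np.full((L, A, k), np.nan)
    for fold in range(k):
        tr = assign != fold
        te = ~tr
        y_tr, y_te = y[tr], y[te]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            warnings.warn(f"fold {fold} has a single class; skipped",
                          UserWarning)
            continue
        for a_idx, a in enumerate(alphas):
            betas, intercepts, _ = fit_path(
                X[tr], y_tr, family, float(a), grids[:, a_idx],
                fit_intercept=fit_intercept, tol=tol)
            acc_f, dev_f = _held_out_metric(betas, intercepts, X[te], y_te)
            scores[:, a_idx, fold] = acc_f
            deviances[:, a_idx, fold] = dev_f
    if np.all(np.isnan(scores)):
        raise RuntimeError("cross-validation failed on every fold")
    if metric == "deviance":
        scores = deviances
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv_score = np.nanmean(scores, axis=2)
        cv_dev = np.nanmean(deviances, axis=2)
        n_ok = np.sum(~np.isnan(scores), axis=2)
        cv_se = np.nanstd(scores, axis=2, ddof=1) / np.sqrt(np.maximum(n_ok, 1))

    maximize = metric == "accuracy"
    # Mean CV accuracy over (near-)equal folds moves in steps of one
    # held-out sample, i.e. has resolution 1/n: cells closer than that to
    # the maximum are statistically indistinguishable and count as tied.
    tie_tol = 1.0 / y.shape[0] + 1e-9 if maximize else 0.0
    best_l, best_a = _select_cell(cv_score, cv_se, cv_dev, maximize, rule,
                                  tie_tol)
    best = (float(grids[best_l, best_a]), float(alphas[best_a]))
    result = CVResult(lambda_grid=grids, alpha_grid=alphas,
                      cv_score=cv_score, cv_se=cv_se, best=best, rule=rule,
                      metric=metric, family=family,
                      best_index=(int(best_l), int(best_a)))
    if refit:
        betas, intercepts, info = fit_path(
            X, y, family, best[1], grids[: best_l + 1, best_a],
            fit_intercept=fit_intercept, tol=tol)
        pen = PenaltySpec(family, best[0], best[1])
        result.model = HLRModel(
            beta=betas[best_l], intercept=float(intercepts[best_l]),
            penalty=pen, n_outer_iters=0,
            converged=bool(info["converged"][best_l]),
            final_objective=float(info["objective"][best_l]),
            center=np.zeros(X.shape[1]), scale=np.ones(X.shape[1]),
            fit_intercept=fit_intercept)
    return result


def _select_cell(cv_score, cv_se, cv_dev, maximize, rule, tie_tol=0.0):
    """Best (λ-row, α-col) on the CV surface.

    With the accuracy metric the surface is often exactly tied over wide
    regions (held-out accuracy takes at most n/k+1 distinct values per
    fold), so ties among the top-scoring cells are resolved in two
    structural steps: first the smallest α whose column contains a tied
    cell — the most ridge-weighted, hence most grouped and most stable of
    the equally scoring models (correlated predictors enter or leave
    together) — then, within that column, the tied cell with the smallest
    mean held-out deviance (the natural continuous secondary criterion),
    with any remaining tie going to the larger λ.
    """
    score = cv_score if maximize else -cv_score
    flat_best = np.nanmax(score)
    if rule == "one_se":
        li, ai = _argbest(score, cv_dev, flat_best - tie_tol)
        thresh = flat_best - max(cv_se[li, ai], tie_tol)
        return _argbest(score, cv_dev, thresh)
    if rule != "min":
        raise ValueError(f"unknown rule {rule!r}")
    return _argbest(score, cv_dev, flat_best - tie_tol)


def _argbest(score, cv_dev, thresh):
    """Best admissible cell: smallest α column, then min deviance, then
    larger λ (rows are λ-descending)."""
    L, A = score.shape
    for ai in range(A):
        best = None
        best_dev = np.inf
        for li in range(L):
            s = score[li, ai]
            if np.isnan(s) or s < thresh - 1e-12:
                continue
            d = cv_dev[li, ai]
            if np.isnan(d):
                d = np.inf
            if best is None or d < best_dev - 1e-12:
                best = li
                best_dev = d
        if best is not None:
            return best, ai
    idx = np.unravel_index(np.nanargmax(score), score.shape)
    return int(idx[0]), int(idx[1])
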