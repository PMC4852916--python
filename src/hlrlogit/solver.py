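"""Penalized logistic (and Gaussian) regression solver.

The model
---------
For binary y and features X the logistic model is P(y=1|x) = f(x'β) with
f(x) = e^x/(1+e^x).  The HLR-penalized fit minimizes

    L(λ, α, β) = NLL(β) + λ( α·Σ|β_j|^(1/2) + (1-α)·Σ β_j² )

where NLL is the binomial negative log-likelihood.  The non-convex L1/2
part produces exact zeros (feature selection) with little shrinkage bias on
the survivors; the ridge part makes the criterion strictly convex in
correlated directions, which is what gives the grouping effect.

The algorithm is iteratively reweighted least squares (one-term Taylor
linearization with working responses Z_i and weights W_i = f(1-f)) wrapped
around cyclic coordinate descent, each coordinate update being an exact
univariate thresholding step (see `_kernels` for the formulas; they reduce
to the classical Half(ω, λα)/(1+λ(1-α)) form on unit-norm columns for the
pure L1/2 and ridge cases).  Soft-threshold families (Lasso, Elastic net)
use the glmnet objective convention NLL + λ(α·Σ|β_j| + (1-α)/2·Σβ_j²).

Features are standardized internally so that Σ_i x_ij² = 1 (centered first
when an intercept is fitted); the penalty applies on that standardized
scale and coefficients are reported back on the original scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from . import _kernels
from ._kernels import HALF_OP, SOFT_OP
from .thresholding import Family, PenaltySpec

logger = logging.getLogger(__name__)

__all__ = [
    "HLRModel",
    "IRLSState",
    "logistic_prob",
    "neg_log_likelihood",
    "penalty_value",
    "penalized_objective",
    "irls_refresh",
    "coordinate_omega",
    "fit",
    "fit_gaussian",
    "fit_path",
    "lambda_max",
    "lambda_grid",
    "predict",
    "save_model",
    "load_model",
]

#: glmnet-style floor on the IRLS weights, and probability clipping.
W_MIN = 1e-5
PROB_EPS = 1e-10


@dataclass
class HLRModel:
    """A fitted penalized model.

    ``beta`` and ``intercept`` are on the original feature scale;
    ``final_objective`` is the penalized objective on the standardized
    scale actually optimized by the solver.
    """

    beta: np.ndarray
    intercept: float
    penalty: PenaltySpec
    n_outer_iters: int
    converged: bool
    final_objective: float
    center: np.ndarray
    scale: np.ndarray
    fit_intercept: bool = True
    n_safeguard: int = 0
    feature_names: Optional[Sequence[str]] = None
    loss: str = "logistic"

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.beta))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.beta.shape[0]:
            raise ValueError(
                f"X has {X.shape[1] if X.ndim == 2 else '?'} features, "
                f"model expects {self.beta.shape[0]}"
            )
        return self.intercept + X @ self.beta


@dataclass
class IRLSState:
    """Working response Z, weights W and fitted probabilities of one
    IRLS linearization."""

    Z: np.ndarray
    W: np.ndarray
    fitted: np.ndarray


def logistic_prob(eta) -> np.ndarray:
    """Elementwise e^η/(1+e^η), overflow-safe, clipped away from {0, 1}."""
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    return np.clip(expit(eta), PROB_EPS, 1.0 - PROB_EPS)


def _check_Xy(X, y, binary=True):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if binary:
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("y must be coded {0, 1}")
    return X, y


def neg_log_likelihood(X, y, model: HLRModel) -> float:
    """Binomial negative log-likelihood of ``model`` on (X, y)."""
    X, y = _check_Xy(X, y)
    eta = model.linear_predictor(X)
    return float(_nll_np(eta, y))


def _nll_np(eta, y):
    # log(1+exp(eta)) - y*eta, computed stably
    out = np.logaddexp(0.0, eta) - y * eta
    return np.sum(out)


def penalty_value(penalty: PenaltySpec, beta) -> float:
    """Penalty term under the family's objective convention."""
    beta = np.asarray(beta, dtype=float)
    l1, l2 = penalty.lam1, penalty.lam2
    if penalty.uses_half:
        return float(l1 * np.sum(np.sqrt(np.abs(beta))) + l2 * np.sum(beta**2))
    return float(l1 * np.sum(np.abs(beta)) + 0.5 * l2 * np.sum(beta**2))


def penalized_objective(X, y, beta, intercept, penalty: PenaltySpec,
                        loss: str = "logistic") -> float:
    """Loss + penalty for explicit (β, intercept) on the given data.

    ``X`` is taken as-is (no standardization); this is the objective the
    solver minimizes when called with ``standardize=False``.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    eta = intercept + X @ beta
    y = np.asarray(y, dtype=float).ravel()
    if loss == "logistic":
        base = _nll_np(eta, y)
    elif loss == "gaussian":
        rss = float(np.sum((y - eta) ** 2))
        base = rss if penalty.uses_half else 0.5 * rss
    else:
        raise ValueError(f"unknown loss {loss!r}")
    return float(base) + penalty_value(penalty, beta)


def irls_refresh(X, y, beta_current, intercept: float = 0.0,
                 w_min: float = W_MIN, eps: float = PROB_EPS) -> IRLSState:
    """One IRLS linearization at the current coefficients.

    W_i = f(1-f) floored at ``w_min``; Z_i = η_i + (y_i - f_i)/W_i with the
    floored weight.
    """
    X, y = _check_Xy(X, y)
    beta_current = np.asarray(beta_current, dtype=float)
    eta = intercept + X @ beta_current
    f = np.clip(expit(eta), eps, 1.0 - eps)
    W = np.maximum(f * (1.0 - f), w_min)
    Z = eta + (y - f) / W
    return IRLSState(Z=Z, W=W, fitted=f)


def coordinate_omega(j: int, X, state: IRLSState, beta) -> float:
    """Weighted partial-residual correlation ω_j = Σ W_i x_ij (Z_i - Ž_i(j))."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    partial = X @ beta - X[:, j] * beta[j]
    return float(np.sum(state.W * X[:, j] * (state.Z - partial)))


def _standardize(X, fit_intercept, standardize):
    """Return (Xs Fortran-ordered, center, scale, kept mask)."""
    n, p = X.shape
    if not standardize:
        center = np.zeros(p)
        scale = np.ones(p)
        kept = np.ones(p, dtype=bool)
        return np.asfortranarray(X), center, scale, kept
    center = X.mean(axis=0) if fit_intercept else np.zeros(p)
    Xc = X - center
    scale = np.sqrt(np.sum(Xc * Xc, axis=0))
    kept = scale > 1e-12
    if not np.all(kept):
        warnings.warn(
            f"dropping {int((~kept).sum())} constant feature(s) from the fit",
            UserWarning,
        )
    Xs = np.asfortranarray(Xc[:, kept] / scale[kept])
    return Xs, center, scale, kept


def _op_code(penalty: PenaltySpec) -> int:
    return HALF_OP if penalty.uses_half else SOFT_OP


def _embed(beta_s, kept, scale):
    """Map standardized-scale coefficients back to the original scale."""
    p = kept.shape[0]
    beta = np.zeros(p)
    beta[kept] = beta_s / scale[kept]
    return beta


def fit(X, y, penalty: PenaltySpec, *, fit_intercept: bool = True,
        standardize: bool = True, tol: float = 1e-4, max_outer: int = 100,
        max_cycles: int = 100, warm_start: Optional[np.ndarray] = None,
        safeguard: bool = True, feature_names=None) -> HLRModel:
    """Fit HLR-penalized logistic regression by IRLS + coordinate descent.

    ``warm_start`` is a coefficient vector on the *standardized* scale
    (as used along a λ path); fits are cold-started at β = 0 otherwise.
    A model with ``converged=False`` is returned (with a warning) when the
    iteration limits are reached.
    """
    X, y = _check_Xy(X, y)
    if X.shape[0] < 2 or len(np.unique(y)) < 2:
        raise ValueError("need at least 2 samples and both classes present")
    Xs, center, scale, kept = _standardize(X, fit_intercept, standardize)
    beta_s = (np.zeros(Xs.shape[1]) if warm_start is None
              else np.array(warm_start, dtype=float))
    ybar = float(np.mean(y))
    b0 = float(np.log(ybar / (1.0 - ybar))) if fit_intercept else 0.0
    b, n_outer, conv, obj, n_sg = _kernels.fit_logistic_cd(
        Xs, y, beta_s, b0, fit_intercept, _op_code(penalty),
        penalty.lam1, penalty.lam2, tol, max_outer, max_cycles,
        W_MIN, PROB_EPS, safeguard,
    )
    if not conv:
        warnings.warn("solver did not converge; increase max_outer or tol",
                      UserWarning)
    if n_sg:
        logger.info("non-convex safeguard engaged %d time(s)", n_sg)
    beta = _embed(beta_s, kept, scale)
    intercept = float(b - np.dot(beta, center)) if fit_intercept else float(b)
    return HLRModel(beta=beta, intercept=intercept, penalty=penalty,
                    n_outer_iters=n_outer, converged=bool(conv),
                    final_objective=float(obj), center=center, scale=scale,
                    fit_intercept=fit_intercept, n_safeguard=int(n_sg),
                    feature_names=feature_names, loss="logistic")


def fit_gaussian(X, y, penalty: PenaltySpec, *, fit_intercept: bool = True,
                 standardize: bool = True, tol: float = 1e-4,
                 max_outer: int = 100, max_cycles: int = 100,
                 warm_start: Optional[np.ndarray] = None,
                 safeguard: bool = True, feature_names=None) -> HLRModel:
    """Squared-error analogue of `fit` (no IRLS layer).

    Minimizes ``||y - Xβ||² + λ(α Σ|β|^(1/2) + (1-α) Σβ²)`` for the half
    families and the glmnet-convention elastic-net criterion for the soft
    families.
    """
    X, y = _check_Xy(X, y, binary=False)
    Xs, center, scale, kept = _standardize(X, fit_intercept, standardize)
    beta_s = (np.zeros(Xs.shape[1]) if warm_start is None
              else np.array(warm_start, dtype=float))
    b0 = float(np.mean(y)) if fit_intercept else 0.0
    b, n_outer, conv, obj, n_sg = _kernels.fit_gaussian_cd(
        Xs, y, beta_s, b0, fit_intercept, _op_code(penalty),
        penalty.lam1, penalty.lam2, tol, max_outer, max_cycles, safeguard,
    )
    if not conv:
        warnings.warn("solver did not converge; increase max_outer or tol",
                      UserWarning)
    beta = _embed(beta_s, kept, scale)
    intercept = float(b - np.dot(beta, center)) if fit_intercept else float(b)
    return HLRModel(beta=beta, intercept=intercept, penalty=penalty,
                    n_outer_iters=n_outer, converged=bool(conv),
                    final_objective=float(obj), center=center, scale=scale,
                    fit_intercept=fit_intercept, n_safeguard=int(n_sg),
                    feature_names=feature_names, loss="gaussian")


def lambda_max(X, y, family: Family = Family.HLR, alpha: float = 1.0, *,
               loss: str = "logistic", fit_intercept: bool = True,
               standardize: bool = True) -> float:
    """Smallest λ at which a cold start keeps every coefficient at zero.

    Derived from the dead-zone condition of the relevant operator at β = 0
    (the ridge part of the hybrid penalty is ignored here, which can only
    overestimate slightly — harmless for a path top).
    """
    family = Family(family)
    X, y = _check_Xy(X, y, binary=(loss == "logistic"))
    Xs, center, scale, kept = _standardize(X, fit_intercept, standardize)
    if loss == "logistic":
        ybar = float(np.mean(y))
        b0 = np.log(ybar / (1.0 - ybar)) if fit_intercept else 0.0
        f = np.clip(expit(np.full(y.shape[0], b0)), PROB_EPS, 1.0 - PROB_EPS)
        W = np.maximum(f * (1.0 - f), W_MIN)
        resid = (y - f)
        omega = Xs.T @ resid          # = sum W x (Z - eta) with Z-eta=(y-f)/W
        v = W @ (Xs * Xs)
    else:
        resid = y - (np.mean(y) if fit_intercept else 0.0)
        omega = Xs.T @ resid
        v = np.sum(Xs * Xs, axis=0)
    a = max(alpha, 1e-3)
    probe = PenaltySpec(family, 1.0, alpha)
    if probe.uses_half:
        # dead zone: |omega|/v <= (3/4) (c*lam*a/v)^(2/3), c=2 logistic, 1 gaussian
        c = 2.0 if loss == "logistic" else 1.0
        lam = (v / (c * a)) * (4.0 * np.abs(omega) / (3.0 * v)) ** 1.5
    else:
        lam = np.abs(omega) / a
    return float(np.max(lam))


def lambda_grid(lmax: float, n_lambda: int = 30,
                min_ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced λ path from ``lmax`` down to ``min_ratio·lmax``."""
    if lmax <= 0:
        raise ValueError("lmax must be positive")
    return np.geomspace(lmax, min_ratio * lmax, n_lambda)


def fit_path(X, y, family: Family, alpha: float, lambdas, *,
             loss: str = "logistic", fit_intercept: bool = True,
             standardize: bool = True, tol: float = 1e-4,
             max_outer: int = 100, max_cycles: int = 100,
             dev_ratio_stop: float = 0.999):
    """Warm-started descending-λ path at fixed α.

    Returns ``(betas, intercepts, info)`` where ``betas`` has one row per λ
    (original feature scale).  The path stops refining once the training
    deviance is essentially saturated (deviance ratio > ``dev_ratio_stop``)
    and replicates the last solution for the remaining λ values.
    """
    family = Family(family)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambdas must be non-increasing")
    X, y = _check_Xy(X, y, binary=(loss == "logistic"))
    Xs, center, scale, kept = _standardize(X, fit_intercept, standardize)
    n, ps = Xs.shape
    beta_s = np.zeros(ps)
    if loss == "logistic":
        ybar = float(np.mean(y))
        b = float(np.log(ybar / (1.0 - ybar))) if fit_intercept else 0.0
        null_dev = _nll_np(np.full(n, b), y)
    else:
        b = float(np.mean(y)) if fit_intercept else 0.0
        null_dev = None
    L = lambdas.shape[0]
    betas = np.zeros((L, kept.shape[0]))
    intercepts = np.zeros(L)
    objs = np.zeros(L)
    conv = np.zeros(L, dtype=bool)
    saturated_at = -1
    for k, lam in enumerate(lambdas):
        pen = PenaltySpec(family, float(lam), alpha)
        if loss == "logistic":
            b, n_outer, cv, obj, n_sg = _kernels.fit_logistic_cd(
                Xs, y, beta_s, b, fit_intercept, _op_code(pen),
                pen.lam1, pen.lam2, tol, max_outer, max_cycles,
                W_MIN, PROB_EPS, True,
            )
        else:
            b, n_outer, cv, obj, n_sg = _kernels.fit_gaussian_cd(
                Xs, y, beta_s, b, fit_intercept, _op_code(pen),
                pen.lam1, pen.lam2, tol, max_outer, max_cycles, True,
            )
        beta = _embed(beta_s, kept, scale)
        betas[k] = beta
        intercepts[k] = (b - np.dot(beta, center)) if fit_intercept else b
        objs[k] = obj
        conv[k] = cv
        if loss == "logistic" and null_dev > 0:
            dev = _nll_np(b + Xs @ beta_s, y)
            if 1.0 - dev / null_dev > dev_ratio_stop:
                saturated_at = k
                for kk in range(k + 1, L):
                    betas[kk] = beta
                    intercepts[kk] = intercepts[k]
                    objs[kk] = obj
                    conv[kk] = cv
                break
    info = {"converged": conv, "objective": objs, "saturated_at": saturated_at,
            "lambdas": lambdas, "alpha": alpha, "family": family}
    return betas, intercepts, info


def predict(model: HLRModel, X, threshold: float = 0.5):
    """Probabilities and 0/1 labels (``prob >= threshold`` maps to 1)."""
    eta = model.linear_predictor(X)
    prob = logistic_prob(eta)
    labels = (prob >= threshold).astype(int)
    return prob, labels


def save_model(model: HLRModel, base: str) -> None:
    """Write ``<base>.coef.tsv`` (feature → coefficient) and a JSON sidecar
    with penalty, standardization and convergence metadata."""
    names = (list(model.feature_names) if model.feature_names is not None
             else [f"x{j+1}" for j in range(model.beta.shape[0])])
    with open(f"{base}.coef.tsv", "w") as fh:
        fh.write("feature\tcoefficient\n")
        fh.write(f"(intercept)\t{float(model.intercept):.17g}\n")
        for name, b in zip(names, model.beta):
            fh.write(f"{name}\t{float(b):.17g}\n")
    meta = {
        "penalty": {"family": model.penalty.family.value,
                    "lam": model.penalty.lam, "alpha": model.penalty.alpha},
        "loss": model.loss,
        "fit_intercept": model.fit_intercept,
        "n_outer_iters": model.n_outer_iters,
        "converged": model.converged,
        "final_objective": model.final_objective,
        "n_safeguard": model.n_safeguard,
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
    }
    with open(f"{base}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(base: str) -> HLRModel:
    """Inverse of `save_model`."""
    names, coefs = [], []
    intercept = 0.0
    with open(f"{base}.coef.tsv") as fh:
        next(fh)
        for line in fh:
            name, val = line.rstrip("\n").split("\t")
            if name == "(intercept)":
                intercept = float(val)
            else:
                names.append(name)
                coefs.append(float(val))
    with open(f"{base}.meta.json") as fh:
        meta = json.load(fh)
    pen = PenaltySpec(Family(meta["penalty"]["family"]),
                      meta["penalty"]["lam"], meta["penalty"]["alpha"])
    return HLRModel(beta=np.array(coefs), intercept=intercept, penalty=pen,
                    n_outer_iters=meta["n_outer_iters"],
                    converged=meta["converged"],
                    final_objective=meta["final_objective"],
                    center=np.array(meta["center"]),
                    scale=np.array(meta["scale"]),
                    fit_intercept=meta["fit_intercept"],
                    n_safeguard=meta["n_safeguard"],
                    feature_names=names, loss=meta["loss"])
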