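"""Synthetic study: correlated sparse logistic scenarios and support-recovery
metrics.

Data are drawn from the latent-logit model

    log(p/(1-p)) = Xβ + σ·ε,   ε ~ N(0, 1),   y = 1 iff p > 1/2

with X i.i.d. standard normal (p = 1000 features by default) and groups of
correlated predictors injected as x_i ← ρ·x_anchor + (1-ρ)·x_i.  Four
scenarios of increasing support size (5, 10, 30, 200 nonzero coefficients)
define the study conditions; the benchmark repeats the full
generate → CV-tune → fit → evaluate pipeline and reports mean feature
selection sensitivity/specificity and test-set classification accuracy.

Label mechanism: σ·ε is the only noise source — the latent logit is
thresholded, y = 1 iff Xβ + σε > 0.  An additional Bernoulli draw
y ~ Bernoulli(p) (``bernoulli_labels=True``) is offered for sensitivity
analysis, but its irreducible error is far larger (the Bayes accuracy of
the Bernoulli variant is below 94% in every scenario-1 condition, which is
incompatible with the near-perfect reference accuracies this study is
calibrated against).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .selection import accuracy, cross_validate
from .solver import predict
from .thresholding import Family

logger = logging.getLogger(__name__)

__all__ = ["ScenarioSpec", "SimDataset", "SelectionMetrics", "scenario_spec",
           "generate_scenario", "selection_metrics", "run_benchmark",
           "METHOD_FAMILIES"]

#: benchmark method name -> penalty family
METHOD_FAMILIES = {
    "lasso": Family.L1,
    "l1": Family.L1,
    "half": Family.HALF,
    "en": Family.EN,
    "hlr": Family.HLR,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Generation parameters of one simulation scenario."""

    id: int
    n_train: int
    n_test: int
    p: int
    sigma: float
    rho: float
    beta_true: np.ndarray
    groups: Tuple[Tuple[int, Tuple[int, int]], ...]  # (anchor, (lo, hi)) 0-based, hi inclusive


@dataclass
class SimDataset:
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    beta_true: np.ndarray
    seed: int


@dataclass
class SelectionMetrics:
    """Support-recovery confusion counts and rates.

    Supports are nonzero indicators of the true and estimated coefficient
    vectors: TP = |β.*β̂|₀, FP = |β̄.*β̂|₀, TN = |β̄.*β̂̄|₀, FN = |β.*β̂̄|₀,
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    test_accuracy: Optional[float] = None


def _beta_scenario(sid: int, p: int = 1000) -> np.ndarray:
    beta = np.zeros(p)
    if sid == 1:
        beta[:5] = 2.0
    elif sid == 2:
        beta[:10] = [2, 2, 2, 2, 2, 1.5, -2, 1.7, 3, -2.5]
    elif sid == 3:
        beta[:10] = [2, 2, 2, 2, 2, 1.5, -2, 1.7, 3, -2.5]
        beta[10:30] = 3.0
    elif sid == 4:
        beta[:30] = 3.0
        beta[30:35] = [-2.5, 2, -1.5, 1.8, -2.5]
        beta[35:75] = 3.0
        beta[75:100] = 2.0
        beta[100:130] = 3.0
        beta[130:200] = 2.0
    else:
        raise ValueError(f"unknown scenario id {sid}")
    return beta


_SCENARIO_LAYOUT = {
    # id: (n_train, n_test, sigma, groups as (anchor, (lo, hi)) 0-based)
    1: (100, 100, 0.3, ((0, (1, 4)),)),
    2: (100, 100, 0.3, ((0, (1, 4)),)),
    3: (200, 200, 0.4, ((0, (1, 4)), (10, (11, 29)))),
    4: (400, 400, 0.4, ((0, (1, 29)), (35, (36, 74)), (100, (101, 129)))),
}


def scenario_spec(sid: int, rho: float, *, n_train: Optional[int] = None,
                  n_test: Optional[int] = None, p: int = 1000,
                  sigma: Optional[float] = None) -> ScenarioSpec:
    """Build one of the four study scenarios, with optional overrides."""
    if sid not in _SCENARIO_LAYOUT:
        raise ValueError(f"unknown scenario id {sid}")
    ntr, nte, sg, groups = _SCENARIO_LAYOUT[sid]
    return ScenarioSpec(
        id=sid,
        n_train=n_train if n_train is not None else ntr,
        n_test=n_test if n_test is not None else nte,
        p=p,
        sigma=sigma if sigma is not None else sg,
        rho=float(rho),
        beta_true=_beta_scenario(sid, p),
        groups=groups,
    )


def _draw_block(rng: np.random.Generator, n: int, spec: ScenarioSpec,
                bernoulli_labels: bool):
    X = rng.standard_normal((n, spec.p))
    for anchor, (lo, hi) in spec.groups:
        X[:, lo:hi + 1] = (spec.rho * X[:, [anchor]]
                           + (1.0 - spec.rho) * X[:, lo:hi + 1])
    eta = X @ spec.beta_true + spec.sigma * rng.standard_normal(n)
    prob = expit(eta)
    if bernoulli_labels:
        y = rng.binomial(1, prob).astype(float)
    else:
        y = (prob > 0.5).astype(float)
    return X, y


def generate_scenario(spec: ScenarioSpec, seed: int, *,
                      bernoulli_labels: bool = False) -> SimDataset:
    """Generate independent train and test blocks; deterministic given seed."""
    ss = np.random.SeedSequence([int(seed), int(spec.id)])
    tr_ss, te_ss = ss.spawn(2)
    X_tr, y_tr = _draw_block(np.random.default_rng(tr_ss), spec.n_train,
                             spec, bernoulli_labels)
    X_te, y_te = _draw_block(np.random.default_rng(te_ss), spec.n_test,
                             spec, bernoulli_labels)
    return SimDataset(X_train=X_tr, y_train=y_tr, X_test=X_te, y_test=y_te,
                      beta_true=spec.beta_true.copy(), seed=int(seed))


def selection_metrics(beta_true, beta_hat, y_test=None,
                      y_pred=None) -> SelectionMetrics:
    """Support-recovery confusion counts plus optional test accuracy."""
    beta_true = np.asarray(beta_true, dtype=float).ravel()
    beta_hat = np.asarray(beta_hat, dtype=float).ravel()
    if beta_true.shape != beta_hat.shape:
        raise ValueError("beta_true and beta_hat must have equal length")
    s_true = beta_true != 0
    s_hat = beta_hat != 0
    tp = int(np.sum(s_true & s_hat))
    fp = int(np.sum(~s_true & s_hat))
    tn = int(np.sum(~s_true & ~s_hat))
    fn = int(np.sum(s_true & ~s_hat))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = None
    if y_test is not None and y_pred is not None:
        acc = accuracy(y_test, y_pred)
    return SelectionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                            specificity=spec, test_accuracy=acc)


def _derive_seed(*parts) -> int:
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2**31))


def run_benchmark(scenarios: Sequence[int] = (1,),
                  rhos: Sequence[float] = (0.3,),
                  methods: Sequence[str] = ("hlr",),
                  n_repeats: int = 50, seed: int = 0, *, k: int = 10,
                  n_lambda: int = 30, alpha_grid=None,
                  metric: str = "accuracy", fit_intercept: bool = False,
                  n_train: Optional[int] = None,
                  n_test: Optional[int] = None, p: Optional[int] = None,
                  progress: bool = False) -> pd.DataFrame:
    """Repeated generate → CV-tune → fit → evaluate benchmark.

    Returns one row per (scenario, ρ, method) with mean feature-selection
    sensitivity/specificity, mean test accuracy (percent, 0.5 cutoff) and
    standard errors over repeats.  Datasets are shared across methods
    within a repeat; per-repeat seeds derive reproducibly from ``seed``.

    The fitted model mirrors the generating one, which has no intercept
    (the latent logit is Xβ + σε); pass ``fit_intercept=True`` to add an
    unpenalized intercept anyway.
    """
    for m in methods:
        if m not in METHOD_FAMILIES:
            raise ValueError(f"unknown method {m!r}; choose from "
                             f"{sorted(METHOD_FAMILIES)}")
    overrides = {}
    if n_train is not None:
        overrides["n_train"] = n_train
    if n_test is not None:
        overrides["n_test"] = n_test
    if p is not None:
        overrides["p"] = p
    rows = []
    for sid in scenarios:
        for rho in rhos:
            spec = scenario_spec(sid, rho, **overrides)
            per_method = {m: [] for m in methods}
            n_failed = {m: 0 for m in methods}
            for r in range(n_repeats):
                ds_seed = _derive_seed(seed, sid, round(rho * 1000), r)
                ds = generate_scenario(spec, ds_seed)
                cv_seed = _derive_seed(seed, sid, round(rho * 1000), r, 1)
                for m in methods:
                    try:
                        cv = cross_validate(
                            ds.X_train, ds.y_train, METHOD_FAMILIES[m],
                            k=k, seed=cv_seed, metric=metric,
                            n_lambda=n_lambda, alpha_grid=alpha_grid,
                            fit_intercept=fit_intercept)
                        prob, pred = predict(cv.model, ds.X_test)
                        sm = selection_metrics(ds.beta_true, cv.model.beta,
                                               ds.y_test, pred)
                        per_method[m].append(
                            (sm.sensitivity, sm.specificity,
                             sm.test_accuracy, cv.model.nnz))
                    except Exception:  # noqa: BLE001 - a failed repeat is recorded
                        logger.exception(
                            "repeat %d failed (scenario %d, rho %.2f, %s)",
                            r, sid, rho, m)
                        n_failed[m] += 1
                if progress:
                    print(f"scenario {sid} rho {rho}: repeat {r + 1}/"
                          f"{n_repeats} done", flush=True)
            for m in methods:
                vals = np.array(per_method[m], dtype=float)
                if vals.size == 0:
                    continue
                nrep = vals.shape[0]
                se = vals.std(axis=0, ddof=1) / np.sqrt(nrep) if nrep > 1 \
                    else np.zeros(4)
                rows.append({
                    "scenario": sid, "rho": rho, "method": m,
                    "n_repeats": nrep, "n_failed": n_failed[m],
                    "sensitivity": vals[:, 0].mean(),
                    "se_sensitivity": se[0],
                    "specificity": vals[:, 1].mean(),
                    "se_specificity": se[1],
                    "accuracy_pct": 100.0 * vals[:, 2].mean(),
                    "se_accuracy_pct": 100.0 * se[2],
                    "mean_nonzero": vals[:, 3].mean(),
                })
    return pd.DataFrame(rows)
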