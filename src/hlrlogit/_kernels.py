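"""Numba-compiled coordinate-descent kernels.

The inner loops of the solver live here: cyclic coordinate descent on the
(possibly IRLS-linearized) penalized least-squares surrogate, with residual
bookkeeping, an active-set strategy and — for the non-convex half-threshold
families — an objective-increase safeguard.

Updates are the exact per-coordinate stationary conditions of the penalized
objective (see `solver` for the objective conventions per family):

* half families, Gaussian loss ||y - Xb||^2:
      b_j <- Half(w_j/(v_j+l2), l1/(v_j+l2))
* half families, logistic loss (negative log-likelihood):
      b_j <- Half(w_j/(v_j+2*l2), 2*l1/(v_j+2*l2))
* soft families (glmnet convention), either loss:
      b_j <- Soft(w_j, l1) / (v_j + l2)

with w_j = sum_i W_i x_ij (r_i + x_ij b_j) the weighted partial-residual
correlation and v_j = sum_i W_i x_ij^2.  Matrices are expected in Fortran
order so column access is contiguous.
"""

import math

import numpy as np
from numba import njit

SOFT_OP = 0
HALF_OP = 1


@njit(cache=False)
def _half_op(u, t):
    """Half-thresholding: largest stationary point of (b-u)^2 + t*|b|^(1/2)."""
    if t <= 0.0:
        return u
    au = abs(u)
    if au <= 0.75 * t ** (2.0 / 3.0):
        return 0.0
    arg = (t / 8.0) * (au / 3.0) ** (-1.5)
    if arg > 1.0:
        arg = 1.0
    elif arg < -1.0:
        arg = -1.0
    phi = math.acos(arg)
    return (2.0 / 3.0) * u * (1.0 + math.cos(2.0 * (math.pi - phi) / 3.0))


@njit(cache=False)
def _soft_op(u, t):
    if u > t:
        return u - t
    if u < -t:
        return u + t
    return 0.0


@njit(cache=False)
def _penalty_value(beta, op, l1, l2):
    """Penalty term matching each family's objective convention."""
    s = 0.0
    if op == HALF_OP:
        for j in range(beta.shape[0]):
            b = beta[j]
            s += l1 * math.sqrt(abs(b)) + l2 * b * b
    else:
        for j in range(beta.shape[0]):
            b = beta[j]
            s += l1 * abs(b) + 0.5 * l2 * b * b
    return s


@njit(cache=False)
def _nll(eta, y):
    """Binomial negative log-likelihood, overflow-safe."""
    s = 0.0
    for i in range(eta.shape[0]):
        e = eta[i]
        if e > 0.0:
            s += e + math.log1p(math.exp(-e)) - y[i] * e
        else:
            s += math.log1p(math.exp(e)) - y[i] * e
    return s


@njit(cache=False)
def _linear_predictor(X, beta, b):
    n = X.shape[0]
    eta = np.full(n, b)
    for j in range(beta.shape[0]):
        bj = beta[j]
        if bj != 0.0:
            for i in range(n):
                eta[i] += X[i, j] * bj
    return eta


@njit(cache=False)
def _sweep(X, W, r, beta, v, op, l1, l2, logistic, active_only):
    """One cycle of coordinate updates; returns max |delta beta_j|.

    ``r`` holds the working residual (Z - eta for logistic, y - eta for
    Gaussian) and is kept in sync as coefficients move.
    """
    n, p = X.shape
    maxd = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        vj = v[j]
        if vj <= 0.0:
            continue
        c = 0.0
        for i in range(n):
            c += W[i] * X[i, j] * r[i]
        w = c + vj * bj
        if op == HALF_OP:
            if logistic:
                den = vj + 2.0 * l2
                new = _half_op(w / den, 2.0 * l1 / den)
            else:
                den = vj + l2
                new = _half_op(w / den, l1 / den)
        else:
            new = _soft_op(w, l1) / (vj + l2)
        d = new - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= d * X[i, j]
            beta[j] = new
            ad = abs(d)
            if ad > maxd:
                maxd = ad
    return maxd


@njit(cache=False)
def _intercept_step(W, r):
    """Unpenalized intercept update on the weighted residual."""
    sw = 0.0
    swr = 0.0
    for i in range(W.shape[0]):
        sw += W[i]
        swr += W[i] * r[i]
    d = swr / sw
    for i in range(r.shape[0]):
        r[i] -= d
    return d


@njit(cache=False)
def _inner_cd(X, W, r, beta, v, op, l1, l2, logistic, fit_intercept, tol, max_cycles):
    """Full-cycle / active-set coordinate descent until max step <= tol."""
    b_shift = 0.0
    cycles = 0
    while cycles < max_cycles:
        maxd = _sweep(X, W, r, beta, v, op, l1, l2, logistic, False)
        if fit_intercept:
            d = _intercept_step(W, r)
            b_shift += d
            if abs(d) > maxd:
                maxd = abs(d)
        cycles += 1
        if maxd <= tol:
            break
        while cycles < max_cycles:
            maxd_a = _sweep(X, W, r, beta, v, op, l1, l2, logistic, True)
            if fit_intercept:
                d = _intercept_step(W, r)
                b_shift += d
                if abs(d) > maxd_a:
                    maxd_a = abs(d)
            cycles += 1
            if maxd_a <= tol:
                break
    return b_shift, cycles


@njit(cache=False)
def fit_logistic_cd(X, y, beta, b0, fit_intercept, op, l1, l2, tol,
                    max_outer, max_cycles, w_min, prob_eps, safeguard):
    """IRLS + coordinate descent for penalized logistic regression.

    Mutates ``beta`` in place; returns (intercept, n_outer, converged,
    objective, n_safeguard_events).
    """
    n, p = X.shape
    b = b0
    W = np.empty(n)
    r = np.empty(n)
    v = np.empty(p)
    beta_prev = np.empty(p)
    prev_obj = np.inf
    n_sg = 0
    converged = False
    n_outer = 0
    obj = np.inf
    for outer in range(max_outer):
        n_outer = outer + 1
        eta = _linear_predictor(X, beta, b)
        for i in range(n):
            e = eta[i]
            if e > 0.0:
                f = 1.0 / (1.0 + math.exp(-e))
            else:
                ex = math.exp(e)
                f = ex / (1.0 + ex)
            if f < prob_eps:
                f = prob_eps
            elif f > 1.0 - prob_eps:
                f = 1.0 - prob_eps
            w = f * (1.0 - f)
            if w < w_min:
                w = w_min
            W[i] = w
            r[i] = (y[i] - f) / w
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += W[i] * X[i, j] * X[i, j]
            v[j] = s
        for j in range(p):
            beta_prev[j] = beta[j]
        b_prev = b

        b_shift, _ = _inner_cd(X, W, r, beta, v, op, l1, l2, True,
                               fit_intercept, tol, max_cycles)
        b += b_shift

        eta = _linear_predictor(X, beta, b)
        obj = _nll(eta, y) + _penalty_value(beta, op, l1, l2)
        if safeguard and op == HALF_OP and obj > prev_obj + 1e-9:
            # Non-convex safeguard: try a single damped (half) step, else
            # revert to the previous iterate and stop.
            n_sg += 1
            for j in range(p):
                beta[j] = 0.5 * (beta[j] + beta_prev[j])
            b = 0.5 * (b + b_prev)
            eta = _linear_predictor(X, beta, b)
            obj2 = _nll(eta, y) + _penalty_value(beta, op, l1, l2)
            if obj2 > prev_obj + 1e-9:
                for j in range(p):
                    beta[j] = beta_prev[j]
                b = b_prev
                obj = prev_obj
                converged = True
                break
            obj = obj2

        maxd = abs(b - b_prev)
        for j in range(p):
            d = abs(beta[j] - beta_prev[j])
            if d > maxd:
                maxd = d
        prev_obj = obj
        if maxd <= tol:
            converged = True
            break
    return b, n_outer, converged, obj, n_sg


@njit(cache=False)
def fit_gaussian_cd(X, y, beta, b0, fit_intercept, op, l1, l2, tol,
                    max_outer, max_cycles, safeguard):
    """Coordinate descent for the penalized squared-error criterion.

    For half families the loss is ||y - eta||^2 (so the objective tracked
    here is r'r + penalty); for soft families it is the glmnet convention
    (1/2)||y - eta||^2.
    """
    n, p = X.shape
    b = b0
    W = np.ones(n)
    v = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        v[j] = s
    r = y - _linear_predictor(X, beta, b)
    beta_prev = np.empty(p)
    prev_obj = np.inf
    n_sg = 0
    converged = False
    n_outer = 0
    obj = np.inf
    for outer in range(max_outer):
        n_outer = outer + 1
        for j in range(p):
            beta_prev[j] = beta[j]
        b_prev = b
        b_shift, _ = _inner_cd(X, W, r, beta, v, op, l1, l2, False,
                               fit_intercept, tol, max_cycles)
        b += b_shift
        rss = 0.0
        for i in range(n):
            rss += r[i] * r[i]
        if op == HALF_OP:
            obj = rss + _penalty_value(beta, op, l1, l2)
        else:
            obj = 0.5 * rss + _penalty_value(beta, op, l1, l2)
        if safeguard and op == HALF_OP and obj > prev_obj + 1e-9:
            n_sg += 1
            for j in range(p):
                beta[j] = 0.5 * (beta[j] + beta_prev[j])
            b = 0.5 * (b + b_prev)
            r = y - _linear_predictor(X, beta, b)
            rss = 0.0
            for i in range(n):
                rss += r[i] * r[i]
            obj2 = rss + _penalty_value(beta, op, l1, l2)
            if obj2 > prev_obj + 1e-9:
                for j in range(p):
                    beta[j] = beta_prev[j]
                b = b_prev
                r = y - _linear_predictor(X, beta, b)
                obj = prev_obj
                converged = True
                break
            obj = obj2
        maxd = abs(b - b_prev)
        for j in range(p):
            d = abs(beta[j] - beta_prev[j])
            if d > maxd:
                maxd = d
        prev_obj = obj
        if maxd <= tol:
            converged = True
            break
    return b, n_outer, converged, obj, n_sg
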