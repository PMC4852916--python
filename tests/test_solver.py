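"""Solver tests: IRLS pieces, oracle equivalences, penalty structure."""

import warnings

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from hlrlogit import (Family, PenaltySpec, fit, fit_gaussian, fit_path,
                      hlr_update, load_model, neg_log_likelihood,
                      penalized_objective, predict, save_model)
from hlrlogit.solver import (HLRModel, coordinate_omega, irls_refresh,
                             lambda_grid, lambda_max, logistic_prob)


def _model(beta, intercept=0.0):
    beta = np.asarray(beta, dtype=float)
    return HLRModel(beta=beta, intercept=intercept,
                    penalty=PenaltySpec(Family.HLR, 0.0, 0.5),
                    n_outer_iters=0, converged=True, final_objective=0.0,
                    center=np.zeros(beta.size), scale=np.ones(beta.size))


class TestLogisticProb:
    def test_values(self):
        assert logistic_prob([0.0]) == pytest.approx([0.5])
        assert logistic_prob([np.log(3)]) == pytest.approx([0.75])
        assert logistic_prob([40.0])[0] == pytest.approx(1.0, abs=1e-9)
        assert logistic_prob([40.0])[0] < 1.0          # clipped
        assert logistic_prob([-40.0])[0] > 0.0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            logistic_prob([np.inf])


class TestNegLogLikelihood:
    def test_null_model_is_n_log2(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((17, 3))
        y = (rng.random(17) < 0.5).astype(float)
        assert neg_log_likelihood(X, y, _model(np.zeros(3))) == \
            pytest.approx(17 * np.log(2))

    def test_perfect_fit_limit(self):
        X = np.array([[1.0]])
        y = np.array([1.0])
        assert neg_log_likelihood(X, y, _model([50.0])) == \
            pytest.approx(0.0, abs=1e-10)

    def test_direct_evaluation_oracle(self):
        X = np.array([[1.0, -0.5], [0.2, 2.0]])
        y = np.array([1.0, 0.0])
        beta = np.array([0.7, -0.3])
        eta = X @ beta
        f = 1 / (1 + np.exp(-eta))
        expected = -np.sum(y * np.log(f) + (1 - y) * np.log(1 - f))
        assert neg_log_likelihood(X, y, _model(beta)) == pytest.approx(expected)


class TestIRLS:
    def test_zero_beta_state(self):
        X = np.eye(4)
        y = np.array([1.0, 0.0, 1.0, 1.0])
        st = irls_refresh(X, y, np.zeros(4))
        assert st.W == pytest.approx(np.full(4, 0.25))
        assert st.Z == pytest.approx(np.where(y == 1, 2.0, -2.0))

    def test_weight_floor_engages(self):
        X = np.array([[1.0]])
        y = np.array([1.0])
        st = irls_refresh(X, y, np.array([50.0]))
        assert st.W[0] == pytest.approx(1e-5)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((11, 4))
        y = (rng.random(11) < 0.5).astype(float)
        beta = rng.standard_normal(4) * 0.5
        st = irls_refresh(X, y, beta)
        eta = X @ beta
        f = 1 / (1 + np.exp(-eta))
        W = np.maximum(f * (1 - f), 1e-5)
        assert st.W == pytest.approx(W)
        assert st.Z == pytest.approx(eta + (y - f) / W)


class TestCoordinateOmega:
    def test_zero_beta_reduces_to_weighted_correlation(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((9, 3))
        y = (rng.random(9) < 0.5).astype(float)
        st = irls_refresh(X, y, np.zeros(3))
        for j in range(3):
            assert coordinate_omega(j, X, st, np.zeros(3)) == \
                pytest.approx(np.sum(st.W * X[:, j] * st.Z))

    def test_matches_literal_double_loop(self):
        X = np.array([[1.0, 0.5], [-0.3, 2.0], [0.8, -1.0]])
        y = np.array([1.0, 0.0, 1.0])
        beta = np.array([0.4, -0.2])
        st = irls_refresh(X, y, beta)
        for j in range(2):
            acc = 0.0
            for i in range(3):
                zcheck = sum(X[i, k] * beta[k] for k in range(2) if k != j)
                acc += st.W[i] * X[i, j] * (st.Z[i] - zcheck)
            assert coordinate_omega(j, X, st, beta) == pytest.approx(acc)


class TestFitLogistic:
    def test_total_shrinkage(self, toy_logistic):
        X, y, _ = toy_logistic
        lmax = lambda_max(X, y, Family.HLR, 0.5)
        m = fit(X, y, PenaltySpec(Family.HLR, 3 * lmax, 0.5))
        assert m.nnz == 0

    def test_lambda_zero_matches_unpenalized_mle(self, toy_logistic):
        """With no penalty the solver agrees with an independent
        second-order optimizer coefficient-wise."""
        X, y, _ = toy_logistic
        m = fit(X, y, PenaltySpec(Family.HLR, 0.0, 0.5), tol=1e-6)
        sk = LogisticRegression(C=np.inf, tol=1e-10, max_iter=2000).fit(X, y)
        assert np.max(np.abs(m.beta - sk.coef_.ravel())) < 1e-4
        assert abs(m.intercept - sk.intercept_[0]) < 1e-4

    def test_ridge_collapse_matches_independent_optimizer(self, toy_logistic):
        """alpha=0 is a ridge-penalized logistic fit: objective
        NLL + lam*||b||^2 equals sklearn's with C = 0.5/lam."""
        X, y, _ = toy_logistic
        lam = 1.7
        m = fit(X, y, PenaltySpec(Family.HLR, lam, 0.0), standardize=False,
                fit_intercept=False, tol=1e-7)
        sk = LogisticRegression(C=0.5 / lam, tol=1e-12, max_iter=5000,
                                fit_intercept=False).fit(X, y)
        assert np.max(np.abs(m.beta - sk.coef_.ravel())) < 1e-3

    def test_hlr_objective_beats_dense_grid(self):
        """Penalized objective at the p=2 solution is no worse than a dense
        grid minimum (grid refined near its optimum)."""
        rng = np.random.default_rng(11)
        n = 40
        X = rng.standard_normal((n, 2))
        X /= np.linalg.norm(X, axis=0)
        eta = 14.0 * X[:, 0] - 10.0 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        pen = PenaltySpec(Family.HLR, 0.5, 0.5)
        m = fit(X, y, pen, standardize=False, fit_intercept=False, tol=1e-8,
                max_outer=300)
        obj = penalized_objective(X, y, m.beta, 0.0, pen, loss="logistic")

        def grid_min(center, half_width, steps):
            b1 = np.linspace(center[0] - half_width, center[0] + half_width, steps)
            b2 = np.linspace(center[1] - half_width, center[1] + half_width, steps)
            B1, B2 = np.meshgrid(b1, b2, indexing="ij")
            etaG = X[:, 0][:, None] * B1.ravel() + X[:, 1][:, None] * B2.ravel()
            nll = np.sum(np.logaddexp(0, etaG) - y[:, None] * etaG, axis=0)
            penv = pen.lam1 * (np.sqrt(np.abs(B1.ravel())) + np.sqrt(np.abs(B2.ravel()))) \
                + pen.lam2 * (B1.ravel() ** 2 + B2.ravel() ** 2)
            k = np.argmin(nll + penv)
            return (B1.ravel()[k], B2.ravel()[k]), (nll + penv)[k]

        center, _ = grid_min((0.0, 0.0), 20.0, 201)
        center, gmin = grid_min(center, 0.3, 301)
        assert obj <= gmin + 1e-3

    def test_single_class_raises(self):
        X = np.eye(4)
        with pytest.raises(ValueError):
            fit(X, np.ones(4), PenaltySpec(Family.HLR, 1.0, 0.5))

    def test_non_finite_raises(self):
        X = np.array([[np.nan, 1.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            fit(X, np.array([0.0, 1.0]), PenaltySpec(Family.HLR, 1.0, 0.5))

    def test_constant_feature_dropped_with_warning(self, toy_logistic):
        X, y, _ = toy_logistic
        Xc = np.column_stack([X, np.full(X.shape[0], 3.7)])
        with pytest.warns(UserWarning, match="constant"):
            m = fit(Xc, y, PenaltySpec(Family.HLR, 0.5, 0.5))
        assert m.beta[-1] == 0.0

    def test_non_convergence_warns(self, toy_logistic):
        X, y, _ = toy_logistic
        with pytest.warns(UserWarning, match="converge"):
            m = fit(X, y, PenaltySpec(Family.HLR, 0.0, 0.5), max_outer=1,
                    max_cycles=1)
        assert not m.converged

    def test_permutation_equivariance(self, toy_logistic):
        X, y, _ = toy_logistic
        pen = PenaltySpec(Family.HLR, 0.8, 0.5)
        m = fit(X, y, pen, tol=1e-8)
        perm = np.array([3, 0, 4, 1, 2])
        mp = fit(X[:, perm], y, pen, tol=1e-8)
        assert np.max(np.abs(mp.beta - m.beta[perm])) < 1e-6


class TestGroupingEffect:
    def test_duplicated_columns_get_equal_coefficients(self):
        """With an exact duplicate pair and alpha < 1 the ridge part forces
        the two coefficients together (relative gap <= 1e-3)."""
        gaps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 80
            Z = rng.standard_normal((n, 5))
            X = np.column_stack([Z[:, 0], Z[:, 0], Z[:, 1:]])
            eta = 2.0 * Z[:, 0] + 1.0 * Z[:, 1]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            m = fit(X, y, PenaltySpec(Family.HLR, 1.0, 0.5), tol=1e-9,
                    max_outer=500)
            b0, b1 = m.beta[0], m.beta[1]
            denom = max(abs(b0), abs(b1))
            gaps.append(0.0 if denom == 0 else abs(b0 - b1) / denom)
        assert max(gaps) <= 1e-3

    def test_pure_half_may_pick_one(self):
        """alpha=1 has no grouping guarantee — just exercise the fit; the
        duplicate gap is allowed to be arbitrarily large."""
        rng = np.random.default_rng(1)
        n = 80
        Z = rng.standard_normal((n, 5))
        X = np.column_stack([Z[:, 0], Z[:, 0], Z[:, 1:]])
        eta = 2.0 * Z[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        m = fit(X, y, PenaltySpec(Family.HALF, 1.0), tol=1e-8)
        assert m.converged


class TestFitGaussian:
    def test_lambda_zero_is_ols(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0]) + 0.1 * rng.standard_normal(50)
        m = fit_gaussian(X, y, PenaltySpec(Family.HLR, 0.0, 0.5), tol=1e-10)
        Xd = np.column_stack([np.ones(50), X])
        coef = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert np.max(np.abs(m.beta - coef[1:])) < 1e-6
        assert abs(m.intercept - coef[0]) < 1e-6

    @pytest.mark.parametrize("family, alpha", [
        (Family.HALF, 1.0), (Family.HLR, 1.0), (Family.HLR, 0.0),
        (Family.L1, 1.0), (Family.EN, 0.5), (Family.L2, 0.0),
    ])
    def test_orthonormal_design_decouples(self, family, alpha):
        """On orthonormal columns the solution is the univariate update
        applied to the OLS coordinates X'y."""
        rng = np.random.default_rng(9)
        A = rng.standard_normal((30, 4))
        Q, _ = np.linalg.qr(A)
        y = rng.standard_normal(30) * 2.0
        lam = 0.4
        pen = PenaltySpec(family, lam, alpha)
        m = fit_gaussian(Q, y, pen, standardize=False, fit_intercept=False,
                         tol=1e-10)
        expected = [hlr_update(w, pen) for w in Q.T @ y]
        assert np.max(np.abs(m.beta - np.array(expected))) < 1e-6

    def test_objective_beats_dense_grid(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((25, 2))
        X /= np.linalg.norm(X, axis=0)
        y = X @ np.array([3.0, -2.0]) + 0.2 * rng.standard_normal(25)
        pen = PenaltySpec(Family.HLR, 0.6, 0.5)
        m = fit_gaussian(X, y, pen, standardize=False, fit_intercept=False,
                         tol=1e-10)
        obj = penalized_objective(X, y, m.beta, 0.0, pen, loss="gaussian")
        b1 = np.linspace(-6, 6, 1201)
        B1, B2 = np.meshgrid(b1, b1, indexing="ij")
        resid = y[:, None] - (np.outer(X[:, 0], B1.ravel())
                              + np.outer(X[:, 1], B2.ravel()))
        rss = np.sum(resid ** 2, axis=0)
        penv = pen.lam1 * (np.sqrt(np.abs(B1.ravel())) + np.sqrt(np.abs(B2.ravel()))) \
            + pen.lam2 * (B1.ravel() ** 2 + B2.ravel() ** 2)
        gmin = np.min(rss + penv)
        assert obj <= gmin + 5e-2      # grid resolution 0.01 per coordinate

    def test_shrunken_gram_equivalence(self):
        """The hybrid Gaussian solution equals the pure-L1/2 solution of the
        ridge-augmented problem, whose Gram matrix is X'X + lam2*I — the
        shrunken-correlation formulation."""
        rng = np.random.default_rng(21)
        for p in (2, 3, 5):
            n = 20
            X = rng.standard_normal((n, p))
            X /= np.linalg.norm(X, axis=0)
            y = X @ rng.standard_normal(p) * 2 + 0.3 * rng.standard_normal(n)
            lam1, lam2 = 0.6, 0.4
            hybrid = fit_gaussian(
                X, y, PenaltySpec.from_lam12(lam1, lam2),
                standardize=False, fit_intercept=False, tol=1e-10)
            X_aug = np.vstack([X, np.sqrt(lam2) * np.eye(p)])
            y_aug = np.concatenate([y, np.zeros(p)])
            half = fit_gaussian(
                X_aug, y_aug, PenaltySpec(Family.HALF, lam1),
                standardize=False, fit_intercept=False, tol=1e-10)
            assert np.allclose((X_aug.T @ X_aug), X.T @ X + lam2 * np.eye(p))
            assert np.max(np.abs(hybrid.beta - half.beta)) < 1e-3


class TestSparsityPath:
    def test_nnz_near_monotone_for_convex_families(self):
        """Support grows as λ decreases along a warm-started path.  Exact
        monotonicity does not hold even for the Lasso (single coefficients
        can leave the active set again), so the assertion allows small,
        transient drops below the running maximum."""
        rng = np.random.default_rng(17)
        n, p = 60, 30
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[:4] = [2, -2, 1.5, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
        for fam, alpha in [(Family.L1, 1.0), (Family.EN, 0.5)]:
            lmax = lambda_max(X, y, fam, alpha)
            grid = lambda_grid(lmax, 25)
            betas, _, _ = fit_path(X, y, fam, alpha, grid)
            nnz = (betas != 0).sum(axis=1)
            assert nnz[0] < nnz[-1]
            assert np.all(np.maximum.accumulate(nnz) - nnz <= 2)

    def test_hlr_nnz_roughly_monotone(self):
        # non-convex path: jumps are possible, so only recorded, not asserted
        rng = np.random.default_rng(17)
        n, p = 60, 30
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[:4] = [2, -2, 1.5, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
        lmax = lambda_max(X, y, Family.HLR, 0.5)
        betas, _, _ = fit_path(X, y, Family.HLR, 0.5, lambda_grid(lmax, 25))
        nnz = (betas != 0).sum(axis=1)
        assert nnz[0] <= nnz[-1]       # sparse top, dense bottom


class TestPredictAndSerialization:
    def test_zero_model_tie_convention(self):
        m = _model(np.zeros(3))
        prob, labels = predict(m, np.zeros((4, 3)))
        assert prob == pytest.approx(np.full(4, 0.5))
        assert np.all(labels == 1)      # prob >= threshold maps to 1

    def test_strong_positive_coefficient(self):
        m = _model([100.0])
        _, labels = predict(m, np.array([[1.0]]))
        assert labels[0] == 1

    def test_roundtrip_threshold_consistency(self, toy_logistic):
        X, y, _ = toy_logistic
        m = fit(X, y, PenaltySpec(Family.HLR, 0.5, 0.5))
        prob, labels = predict(m, X, threshold=0.3)
        assert np.array_equal(labels, (prob >= 0.3).astype(int))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            predict(_model([1.0, 2.0]), np.zeros((3, 5)))

    def test_save_load_roundtrip(self, toy_logistic, tmp_path):
        X, y, _ = toy_logistic
        m = fit(X, y, PenaltySpec(Family.HLR, 0.7, 0.3),
                feature_names=[f"g{j}" for j in range(5)])
        base = str(tmp_path / "model")
        save_model(m, base)
        m2 = load_model(base)
        assert np.array_equal(m2.beta, m.beta)
        assert m2.intercept == m.intercept
        assert m2.penalty == m.penalty
        assert m2.feature_names == [f"g{j}" for j in range(5)]
        p1, l1 = predict(m, X)
        p2, l2 = predict(m2, X)
        assert np.array_equal(l1, l2)


class TestSurrogateDescent:
    def test_convex_family_cycle_never_increases_surrogate(self):
        """One full coordinate cycle on the weighted least-squares surrogate
        does not increase the penalized surrogate for the soft families."""
        from hlrlogit._kernels import SOFT_OP, _penalty_value, _sweep
        rng = np.random.default_rng(23)
        n, p = 30, 8
        X = np.asfortranarray(rng.standard_normal((n, p)))
        W = rng.random(n) * 0.25 + 0.01
        Z = rng.standard_normal(n)
        beta = rng.standard_normal(p) * 0.2
        v = W @ (X * X)
        l1, l2 = 0.3, 0.2

        def surrogate(b, r):
            return 0.5 * np.sum(W * r ** 2) + _penalty_value(b, SOFT_OP, l1, l2)

        r = Z - X @ beta
        before = surrogate(beta, r)
        for _ in range(3):
            _sweep(X, W, r, beta, v, SOFT_OP, l1, l2, True, False)
            after = surrogate(beta, Z - X @ beta)
            assert after <= before + 1e-10
            before = after
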