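import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import igxe
from igxe.stage2 import (sgl_block_update, fit_ige, fit_path, cross_validate,
                         lambda_max, default_lambda_grid, predict)

from conftest import make_tiny_gxe
from _oracles import (block_objective, gxe_objective, solve_block_nm,
                      solve_gxe_fista, soft)


class TestBlockUpdate:
    def test_unpenalized_limit_is_ols(self, rng):
        X = rng.normal(size=(30, 3))
        r = rng.normal(size=30)
        b = sgl_block_update(r, X, 0.0)
        ols = np.linalg.lstsq(X, r, rcond=None)[0]
        np.testing.assert_allclose(b, ols, atol=1e-7)

    def test_full_shrinkage_zeroes_block(self, rng):
        X = rng.normal(size=(30, 3))
        r = rng.normal(size=30)
        lam_big = np.abs(X.T @ r / 30).max() + 1.0
        np.testing.assert_array_equal(sgl_block_update(r, X, lam_big), 0.0)

    def test_matches_generic_convex_oracle(self):
        for seed in range(4):
            g = np.random.default_rng(seed)
            X = g.normal(size=(20, 3))
            r = X @ np.array([1.0, 0.0, -0.5]) + g.normal(size=20) * 0.3
            lam = 0.2
            b = sgl_block_update(r, X, lam)
            _, f_oracle = solve_block_nm(r, X, lam, seed=seed)
            f_ours = block_objective(r, X, lam, b)
            assert f_ours <= f_oracle + 1e-5

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_prox_solves_its_variational_problem(self, seed):
        """The soft-then-group prox minimizes (1/2)||x-v||^2 + t(||x||2+|x|1)."""
        from igxe._solvers import sparse_group_prox
        g = np.random.default_rng(seed)
        v = g.normal(size=3) * 2
        t = float(g.uniform(0.05, 1.5))
        out = np.empty(3)
        sparse_group_prox(v, t, out)

        def f(x):
            return (0.5 * np.sum((x - v) ** 2)
                    + t * (np.linalg.norm(x) + np.abs(x).sum()))

        from scipy.optimize import minimize
        best = min((minimize(f, x0, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12,
                                      "maxiter": 10000})
                    for x0 in (np.zeros(3), v, out)),
                   key=lambda r: r.fun)
        assert f(out) <= best.fun + 1e-7


class TestFitIge:
    def test_zero_penalized_design_gives_ols_alpha(self, rng):
        n, q = 40, 2
        E = rng.normal(size=(n, q))
        y = rng.normal(size=n)
        GV = np.zeros((n, 1))
        X1, X2, i1, i2 = igxe.build_design(GV, np.zeros((n, 2)), E,
                                           center=False)
        design = igxe.DecomposedDesign(GV=GV, RU=GV, G_resid=np.zeros((n, 2)),
                                       R_resid=np.zeros((n, 3)), X1=X1, X2=X2,
                                       x1_index=i1, x2_index=i2)
        fit = fit_ige(design, y, E, lam=0.5, standardize=False)
        ols = np.linalg.lstsq(E, y, rcond=None)[0]
        np.testing.assert_allclose(fit.alpha_hat, ols, atol=1e-10)

    def test_above_lambda_max_gives_null_model(self):
        design, y, E, Z = make_tiny_gxe(seed=3)
        lmax = lambda_max(design, y, E, R_resid=Z, standardize=False)
        fit = fit_ige(design, y, E, R_resid=Z, lam=lmax * 1.01,
                      standardize=False)
        assert not fit.b1_hat.any() and not fit.b2_hat.any()
        assert not fit.gamma_hat.any()
        ols = np.linalg.lstsq(E, y, rcond=None)[0]
        np.testing.assert_allclose(fit.alpha_hat, ols, atol=1e-8)
        # just below, something enters
        fit2 = fit_ige(design, y, E, R_resid=Z, lam=lmax * 0.95,
                       standardize=False)
        assert (fit2.b1_hat.any() or fit2.b2_hat.any()
                or fit2.gamma_hat.any())

    def test_objective_monotone_descent(self):
        design, y, E, Z = make_tiny_gxe(seed=5)
        fit = fit_ige(design, y, E, R_resid=Z, lam=0.1, standardize=False,
                      tol=1e-9, max_iter=300)
        h = fit.objective_history
        assert (np.diff(h) <= 1e-10 * max(1.0, abs(h[0]))).all()

    def test_matches_joint_convex_oracle(self):
        """Alternating solver and monolithic FISTA agree on the penalized
        objective of the same problem (small random instances)."""
        for seed in range(5):
            design, y, E, Z = make_tiny_gxe(seed=seed)
            q = E.shape[1]
            X = np.hstack([design.X1, design.X2])
            lam = 0.3
            fit = fit_ige(design, y, E, R_resid=Z, lam=lam,
                          standardize=False, tol=1e-10, max_iter=3000)
            ao, bo, go = solve_gxe_fista(E, X, Z, y, q + 1, lam)
            f_ours = gxe_objective(E, X, Z, y, q + 1, lam, fit.alpha_hat,
                                   np.concatenate([fit.b1_hat, fit.b2_hat]),
                                   fit.gamma_hat)
            f_oracle = gxe_objective(E, X, Z, y, q + 1, lam, ao, bo, go)
            assert f_ours == pytest.approx(f_oracle, abs=1e-4)

    def test_bilevel_selection_pattern_exists(self):
        """Somewhere on the path one block is fully zero while another keeps
        a strict subset of its slots — the bi-level selection signature."""
        design, y, E, Z = make_tiny_gxe(seed=2, snr=3.0)
        path = fit_path(design, y, E, R_resid=Z,
                        lambda_grid=default_lambda_grid(40),
                        standardize=False, grid_units="auto")
        q = E.shape[1]
        found = False
        for f in path.fits:
            blocks = np.concatenate([f.b1_hat, f.b2_hat]).reshape(-1, q + 1)
            nnz = (np.abs(blocks) > 1e-10).sum(axis=1)
            if (nnz == 0).any() and ((nnz > 0) & (nnz < q + 1)).any():
                found = True
                break
        assert found


class TestPath:
    def test_sparsity_monotone_in_penalty(self):
        design, y, E, Z = make_tiny_gxe(seed=4)
        path = fit_path(design, y, E, R_resid=Z,
                        lambda_grid=default_lambda_grid(30),
                        standardize=False)
        nnz = [int(np.count_nonzero(np.concatenate(
            [f.b1_hat, f.b2_hat, f.gamma_hat]))) for f in path.fits]
        # grid is descending, so counts should (weakly) grow, small solver
        # ties aside
        violations = sum(max(0, nnz[i] - nnz[i + 1] - 2)
                         for i in range(len(nnz) - 1))
        assert violations == 0

    def test_singleton_grid_equals_single_fit(self):
        design, y, E, Z = make_tiny_gxe(seed=6)
        path = fit_path(design, y, E, R_resid=Z, lambda_grid=[0.2],
                        standardize=False, grid_units="absolute")
        single = fit_ige(design, y, E, R_resid=Z, lam=0.2,
                         standardize=False)
        np.testing.assert_allclose(path.fits[0].b1_hat, single.b1_hat,
                                   atol=1e-8)
        np.testing.assert_allclose(path.fits[0].gamma_hat, single.gamma_hat,
                                   atol=1e-8)

    def test_warm_starts_match_cold_fits(self):
        design, y, E, Z = make_tiny_gxe(seed=7)
        grid = np.array([0.5, 0.3, 0.15, 0.05])
        path = fit_path(design, y, E, R_resid=Z, lambda_grid=grid,
                        standardize=False, grid_units="absolute",
                        tol=1e-9, max_iter=2000)
        for f, lam in zip(path.fits, sorted(grid, reverse=True)):
            cold = fit_ige(design, y, E, R_resid=Z, lam=lam,
                           standardize=False, tol=1e-9, max_iter=2000)
            assert f.objective <= cold.objective + 1e-6


class TestCrossValidate:
    def test_leave_one_out_matches_explicit_loop(self):
        design, y, E, Z = make_tiny_gxe(seed=8, n=20)
        grid = np.array([0.4, 0.1, 0.02])
        best, cv = cross_validate(design, y, E, R_resid=Z, lambda_grid=grid,
                                  folds=20, rng=0, standardize=False,
                                  grid_units="absolute")
        # brute-force loop with identical fold assignment
        perm = np.random.default_rng(0).permutation(20)
        errs = np.zeros((20, 3))
        from igxe.stage2 import _subset_design
        for f, i in enumerate(perm):
            tr = np.ones(20, bool)
            tr[i] = False
            p = fit_path(_subset_design(design, tr), y[tr], E[tr],
                         R_resid=Z[tr], lambda_grid=grid,
                         standardize=False, grid_units="absolute")
            X_va = np.hstack([design.X1[~tr], design.X2[~tr]])
            for k, ft in enumerate(p.fits):
                beta = np.concatenate([ft.b1_hat, ft.b2_hat])
                pred = (ft.intercept + E[~tr] @ ft.alpha_hat + X_va @ beta
                        + Z[~tr] @ ft.gamma_hat)
                errs[f, k] = np.mean((y[~tr] - pred) ** 2)
        np.testing.assert_allclose(cv, errs.mean(axis=0), atol=1e-10)

    def test_pure_noise_prefers_heavy_shrinkage(self):
        """With no signal the most-shrunk models win CV on average."""
        grid = default_lambda_grid(20)
        wins = 0
        for seed in range(10):
            g = np.random.default_rng(200 + seed)
            n = 40
            E = g.normal(size=(n, 2))
            y = g.normal(size=n)
            GV = g.normal(size=(n, 2))
            Gr = g.normal(size=(n, 3))
            X1, X2, i1, i2 = igxe.build_design(GV, Gr, E)
            design = igxe.DecomposedDesign(GV=GV, RU=GV, G_resid=Gr,
                                           R_resid=g.normal(size=(n, 3)),
                                           X1=X1, X2=X2, x1_index=i1,
                                           x2_index=i2)
            best, _ = cross_validate(design, y, E, lambda_grid=grid,
                                     folds=5, rng=seed)
            if best >= np.median(grid):
                wins += 1
        assert wins >= 7

    def test_duplicated_noiseless_rows_interpolate(self):
        """With every row duplicated, folds split by copy, and a noiseless
        linear outcome, the near-unpenalized fit interpolates the training
        copy and so predicts its held-out twin exactly."""
        g = np.random.default_rng(9)
        n = 12
        E = g.normal(size=(n, 2))
        GV = g.normal(size=(n, 2))
        Gr = g.normal(size=(n, 2))
        Z = g.normal(size=(n, 2))
        X1, X2, i1, i2 = igxe.build_design(GV, Gr, E, center=False)
        beta = g.normal(size=X1.shape[1])
        y = E @ np.array([1.0, -1.0]) + X1 @ beta
        dup = np.concatenate([np.arange(n), np.arange(n)])
        design = igxe.DecomposedDesign(GV=GV[dup], RU=GV[dup],
                                       G_resid=Gr[dup], R_resid=Z[dup],
                                       X1=X1[dup], X2=X2[dup],
                                       x1_index=i1, x2_index=i2)

        class SplitByCopy:
            """Permutation that puts the first copies in fold 0 and the
            second copies in fold 1."""

            def permutation(self, m):
                perm = np.empty(m, dtype=int)
                perm[0::2] = np.arange(m // 2)
                perm[1::2] = np.arange(m // 2, m)
                return perm

        best, cv = cross_validate(design, y[dup], E[dup],
                                  lambda_grid=np.array([0.3, 1e-4]),
                                  folds=2, rng=SplitByCopy(),
                                  standardize=False,
                                  grid_units="absolute", tol=1e-10,
                                  max_iter=20000)
        assert cv[-1] < 1e-4

    def test_refit_stage1_mode_runs(self, small_dataset):
        ds, _ = small_dataset
        s1 = igxe.fit_stage1(ds.G, ds.R, L=4, rng=7)
        design = igxe.decompose(ds.G, ds.R, ds.E, s1)
        best, cv = cross_validate(None, ds.Y, ds.E,
                                  lambda_grid=default_lambda_grid(8),
                                  folds=3, rng=0, refit_stage1=True,
                                  G=ds.G, R=ds.R, L=4)
        assert np.isfinite(cv).all() and len(cv) == 8


def test_predict_is_exact_on_training_fit():
    design, y, E, Z = make_tiny_gxe(seed=10)
    fit = fit_ige(design, y, E, R_resid=Z, lam=1e-6, standardize=True,
                  tol=1e-10, max_iter=5000)
    pred = predict(fit, design, E, R_resid=Z)
    # near-unpenalized fit on n >> p reproduces y up to the noise floor
    assert np.corrcoef(pred, y)[0, 1] > 0.95
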