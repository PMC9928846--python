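"""Univariate REML: likelihood definition, optimizer, invariances."""

import numpy as np
import pytest

from gremlkit import (GRM, NonIdentifiableError, RemlSettings,
                      fit_greml_univariate, reml_loglikelihood)


def dense_loglik_oracle(y, X, G, sg2, se2):
    """Literal dense-matrix evaluation of the restricted likelihood."""
    n = y.size
    V = sg2 * G + se2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(XtViX)[1] + y @ P @ y)


def rotated_loglik(lam, ys, Xs, sg2, se2):
    """O(n) likelihood via eigen-rotation (validated against the dense
    formula before use as a grid-search engine)."""
    v = sg2 * lam + se2
    w = 1 / v
    C = Xs.T @ (Xs * w[:, None])
    beta = np.linalg.solve(C, Xs.T @ (ys * w))
    q = (ys - Xs @ beta) * w
    return -0.5 * (np.log(v).sum() + np.linalg.slogdet(C)[1] + ys @ q)


def grid_golden_max(lam, ys, Xs, vp, n_grid=60):
    """Dense grid + coordinate golden-section refinement of the logL."""
    grid = np.linspace(vp * 1e-4, vp * 2.0, n_grid)
    best, best_ll = None, -np.inf
    for a in grid:
        for b in grid:
            ll = rotated_loglik(lam, ys, Xs, a, b)
            if ll > best_ll:
                best, best_ll = (a, b), ll
    gr = (np.sqrt(5) - 1) / 2
    theta = list(best)
    for _ in range(4):
        for axis in (0, 1):
            lo = max(theta[axis] - vp * 0.1, vp * 1e-6)
            hi = theta[axis] + vp * 0.1

            def f(t):
                args = list(theta)
                args[axis] = t
                return rotated_loglik(lam, ys, Xs, *args)

            c, d = hi - gr * (hi - lo), lo + gr * (hi - lo)
            for _ in range(40):
                if f(c) > f(d):
                    hi = d
                else:
                    lo = c
                c, d = hi - gr * (hi - lo), lo + gr * (hi - lo)
            theta[axis] = (lo + hi) / 2
    return max(best_ll, rotated_loglik(lam, ys, Xs, *theta))


class TestLoglikelihood:
    def test_identity_grm_is_symmetric_in_components(self):
        # with G = I only the sum sg2 + se2 enters V
        grm = GRM([("f", f"i{j}") for j in range(3)], np.eye(3))
        y = np.array([0.3, -1.2, 0.7])
        a = reml_loglikelihood(y, None, grm, 0.4, 1.1)
        b = reml_loglikelihood(y, None, grm, 1.1, 0.4)
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_dense_oracle_on_fixed_toy(self):
        y = np.array([1.2, -0.4, 0.0, 2.1, -1.3])
        X = np.column_stack([np.ones(5), [0.1, 0.5, -0.2, 1.0, 0.3]])
        A = np.array([
            [1.10, 0.50, 0.25, 0.05, 0.00],
            [0.50, 1.05, 0.25, 0.00, 0.05],
            [0.25, 0.25, 0.95, 0.10, 0.10],
            [0.05, 0.00, 0.10, 1.00, 0.50],
            [0.00, 0.05, 0.10, 0.50, 0.90]])
        grm = GRM([("f", f"i{j}") for j in range(5)], A)
        for sg2, se2 in ((0.5, 0.5), (1.3, 0.2), (0.05, 2.0)):
            assert reml_loglikelihood(y, X, grm, sg2, se2) == pytest.approx(
                dense_loglik_oracle(y, X, A, sg2, se2), abs=1e-10)

    def test_scale_equivariance_of_maximizer(self, sim_small):
        grm = sim_small["grm"]
        y = sim_small["phenotypes"].values[:, 0]
        lam, U = np.linalg.eigh(grm.values)
        lam = np.clip(lam, 0, None)
        Xs = U.T @ np.ones((y.size, 1))
        vp = y.var()

        def grid_argmax(yv, vpv):
            grid = np.linspace(vpv * 0.01, vpv * 1.5, 40)
            lls = [[rotated_loglik(lam, U.T @ yv, Xs, a, b) for b in grid]
                   for a in grid]
            i, j = np.unravel_index(np.argmax(lls), (40, 40))
            return grid[i], grid[j]

        a1, b1 = grid_argmax(y, vp)
        a2, b2 = grid_argmax(2 * y, 4 * vp)
        assert a2 == pytest.approx(4 * a1, rel=1e-9)
        assert b2 == pytest.approx(4 * b1, rel=1e-9)
        assert a1 / (a1 + b1) == pytest.approx(a2 / (a2 + b2), rel=1e-9)


class TestFit:
    def test_identity_grm_not_identifiable(self):
        rng = np.random.default_rng(1)
        grm = GRM([("f", f"i{j}") for j in range(30)], np.eye(30))
        with pytest.raises(NonIdentifiableError):
            fit_greml_univariate(rng.normal(size=30), grm)

    def test_matches_grid_golden_oracle(self, sim_small):
        grm = sim_small["grm"]
        y = sim_small["phenotypes"].values[:, 0]
        fit = fit_greml_univariate(y, grm)
        # validate the rotated oracle engine against the dense formula
        lam, U = np.linalg.eigh(grm.values)
        lam = np.clip(lam, 0, None)
        ys, Xs = U.T @ y, U.T @ np.ones((y.size, 1))
        assert rotated_loglik(lam, ys, Xs, 0.4, 0.6) == pytest.approx(
            reml_loglikelihood(y, None, grm, 0.4, 0.6), abs=1e-5)
        oracle_ll = grid_golden_max(lam, ys, Xs, y.var())
        assert fit.loglik >= oracle_ll - 1e-3
        assert fit.converged

    def test_reordering_invariance(self, sim_small):
        grm = sim_small["grm"]
        y = sim_small["phenotypes"].values[:, 0]
        fit = fit_greml_univariate(y, grm)
        rng = np.random.default_rng(4)
        perm = rng.permutation(grm.n)
        grm_p = grm.subset(perm)
        fit_p = fit_greml_univariate(y[perm], grm_p)
        assert fit_p.sigma_g2 == pytest.approx(fit.sigma_g2, abs=1e-10)
        assert fit_p.sigma_e2 == pytest.approx(fit.sigma_e2, abs=1e-10)
        assert fit_p.h2 == pytest.approx(fit.h2, abs=1e-10)

    def test_em_warmup_is_monotone(self, sim_small):
        from gremlkit.univariate import _Rotated
        grm = sim_small["grm"]
        y = sim_small["phenotypes"].values[:, 0]
        rot = _Rotated(grm.values, y, np.ones((y.size, 1)))
        vp = y.var()
        theta = (vp / 2, vp / 2)
        ll = rot.loglik(*theta)
        for _ in range(8):
            theta = rot.em_step(*theta)
            new_ll = rot.loglik(*theta)
            assert new_ll >= ll - 1e-9
            ll = new_ll

    def test_final_loglik_beats_em_only(self, sim_small):
        grm = sim_small["grm"]
        y = sim_small["phenotypes"].values[:, 0]
        fit = fit_greml_univariate(y, grm)
        from gremlkit.univariate import _Rotated
        rot = _Rotated(grm.values, y, np.ones((y.size, 1)))
        vp = y.var()
        theta = (vp / 2, vp / 2)
        best_em = -np.inf
        for _ in range(50):
            theta = rot.em_step(*theta)
            best_em = max(best_em, rot.loglik(*theta))
        assert fit.loglik >= best_em - 1e-6

    def test_estimates_are_components_of_vp(self, sim_small):
        fit = fit_greml_univariate(sim_small["phenotypes"].values[:, 0],
                                   sim_small["grm"])
        assert fit.sigma_p2 == pytest.approx(fit.sigma_g2 + fit.sigma_e2)
        assert fit.h2 == pytest.approx(fit.sigma_g2 / fit.sigma_p2)
        assert 0 <= fit.h2 <= 1
        evals = np.linalg.eigvalsh(fit.sampling_covariance)
        assert evals.min() >= -1e-10  # PSD sampling covariance

    def test_settings_validation(self):
        with pytest.raises(Exception):
            RemlSettings(loglik_tolerance=-1.0)
        with pytest.raises(Exception):
            RemlSettings(variance_floor_fraction=0.5)
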