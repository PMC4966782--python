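"""Sparse rank-1 machinery: SVD init, soft-threshold update, alternating fit."""

import numpy as np
import pytest

from jammit import (
    extract_signature,
    frobenius_scale,
    jammit_fit,
    residualize,
    sparse_u_update,
    stack,
    svd_rank1,
)
from jammit.selection import lambda_grid

from conftest import make_matrix


def power_iteration_rank1(A, steps=500):
    """Independent oracle for the leading singular triple."""
    rng = np.random.default_rng(0)
    v = rng.standard_normal(A.shape[1])
    for _ in range(steps):
        u = A @ v
        u /= np.linalg.norm(u)
        v = A.T @ u
        v /= np.linalg.norm(v)
    sigma = float(u @ A @ v)
    return u, v, sigma


class TestSvdRank1:
    def test_diagonal_example(self):
        u0, v0, sigma = svd_rank1(np.diag([3.0, 1.0]))
        np.testing.assert_allclose(u0, [1, 0], atol=1e-12)
        np.testing.assert_allclose(v0, [3, 0], atol=1e-12)
        assert sigma == pytest.approx(3.0)

    def test_rank_one_exact(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(5)
        D = np.outer(a, b)
        u0, v0, _ = svd_rank1(D)
        assert np.linalg.norm(D - np.outer(u0, v0)) <= 1e-10 * np.linalg.norm(D)

    def test_matches_power_iteration_oracle(self, rng):
        D = rng.standard_normal((50, 20))
        u0, v0, sigma = svd_rank1(D)
        uo, vo, so = power_iteration_rank1(D)
        assert sigma == pytest.approx(so, abs=1e-8)
        np.testing.assert_allclose(np.abs(u0), np.abs(uo), atol=1e-8)

    def test_sign_convention(self, rng):
        u0, _, _ = svd_rank1(rng.standard_normal((20, 6)))
        assert u0[np.argmax(np.abs(u0))] > 0

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="zero"):
            svd_rank1(np.zeros((3, 3)))


def bruteforce_u(D, v, lam, step=1e-4):
    """Per-coordinate 1-D grid minimization of ||d_i - t v||^2 + lam |t|."""
    out = np.empty(D.shape[0])
    vv = v @ v
    for i, d in enumerate(D):
        z = d @ v
        hi = 1.5 * abs(z) / vv + 1.0
        grid = np.arange(-hi, hi, step)
        vals = vv * grid**2 - 2 * z * grid + lam * np.abs(grid)
        out[i] = grid[np.argmin(vals)]
    return out


class TestSparseUUpdate:
    def test_no_shrinkage_is_least_squares(self, rng):
        D, v = rng.standard_normal((10, 6)), rng.standard_normal(6)
        np.testing.assert_allclose(sparse_u_update(D, v, 0.0), D @ v / (v @ v))

    def test_worked_example(self):
        u = sparse_u_update(np.array([[2.0, 0.0], [0.0, 1.0]]), np.array([1.0, 0.0]), 1.0)
        np.testing.assert_allclose(u, [1.5, 0.0])

    def test_full_shrinkage_threshold(self, rng):
        D, v = rng.standard_normal((10, 6)), rng.standard_normal(6)
        lam = 2.0 * np.max(np.abs(D @ v))
        assert np.all(sparse_u_update(D, v, lam) == 0)

    def test_zero_v_errors(self):
        with pytest.raises(ValueError, match="non-zero"):
            sparse_u_update(np.ones((2, 2)), np.zeros(2), 0.1)

    @pytest.mark.parametrize("lam_frac", [0.0, 0.1, 0.5, 0.9])
    def test_matches_bruteforce_oracle(self, rng, lam_frac):
        D, v = rng.standard_normal((20, 10)), rng.standard_normal(10)
        lam = lam_frac * 2 * np.max(np.abs(D @ v))
        np.testing.assert_allclose(
            sparse_u_update(D, v, lam), bruteforce_u(D, v, lam), atol=1e-3
        )

    def test_support_non_increasing_in_lambda(self, rng):
        D, v = rng.standard_normal((40, 8)), rng.standard_normal(8)
        lams = np.linspace(0, 2 * np.max(np.abs(D @ v)), 15)
        s = [np.count_nonzero(sparse_u_update(D, v, lam)) for lam in lams]
        assert all(a >= b for a, b in zip(s, s[1:]))
        assert s[0] == 40 and s[-1] == 0


class TestJammitFit:
    def test_lambda_zero_matches_svd_error(self, rng):
        D = rng.standard_normal((80, 15))
        fit = jammit_fit(D, 0.0)
        u0, v0, _ = svd_rank1(D)
        err_fit = np.linalg.norm(D - np.outer(fit.u, fit.v))
        err_svd = np.linalg.norm(D - np.outer(u0, v0))
        assert err_fit == pytest.approx(err_svd, rel=1e-8)

    def test_v_equals_Dt_u_contract(self, rng):
        D = rng.standard_normal((60, 12))
        fit = jammit_fit(D, 0.05 * np.max(np.abs(D)))
        np.testing.assert_allclose(fit.v, D.T @ fit.u, rtol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_support_recovery(self, seed):
        rng = np.random.default_rng(seed)
        u_true = np.zeros(100)
        supp = rng.choice(100, 5, replace=False)
        u_true[supp] = rng.uniform(1, 2, 5) * rng.choice([-1, 1], 5)
        v_true = rng.standard_normal(20)
        D = np.outer(u_true, v_true) + 0.01 * rng.standard_normal((100, 20))
        grid = lambda_grid(D, 30)
        fit = jammit_fit(D, grid.lambdas[3])
        assert set(np.nonzero(fit.u)[0]) == set(supp)

    def test_lambda_sup_gives_empty_fit(self, rng):
        D = rng.standard_normal((30, 8))
        grid = lambda_grid(D, 5)
        fit = jammit_fit(D, grid.lam_sup)
        assert fit.empty and fit.s == 0 and not np.any(fit.v)

    @pytest.mark.parametrize("lam_frac", [0.0, 0.2, 0.6])
    def test_objective_trace_non_increasing(self, rng, lam_frac):
        D = rng.standard_normal((50, 10))
        grid = lambda_grid(D, 5)
        fit = jammit_fit(D, lam_frac * grid.lam_sup, debias=False)
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs <= 1e-10)

    def test_debias_preserves_support(self, rng):
        D = rng.standard_normal((50, 10))
        lam = 0.4 * lambda_grid(D, 5).lam_sup
        biased = jammit_fit(D, lam, debias=False)
        refit = jammit_fit(D, lam, debias=True)
        assert np.array_equal(biased.u != 0, refit.u != 0)
        # the refit explains at least as much variance along its support
        assert np.linalg.norm(D - np.outer(refit.u, refit.v)) <= (
            np.linalg.norm(D - np.outer(biased.u / np.linalg.norm(biased.u),
                                        D.T @ (biased.u / np.linalg.norm(biased.u))))
            + 1e-12
        )

    def test_invalid_parameters(self, rng):
        D = rng.standard_normal((5, 4))
        with pytest.raises(ValueError):
            jammit_fit(D, 0.1, tol=0.0)
        with pytest.raises(ValueError):
            jammit_fit(D, 0.1, max_iter=0)


class TestSignature:
    def test_block_parse_example(self, rng):
        a = make_matrix(rng.standard_normal((3, 4)), tag="t1")
        b = make_matrix(rng.standard_normal((2, 4)), tag="t2", prefix="w")
        sm = stack([a, b])
        fit = jammit_fit(sm.values, 0.0)
        fit.u = np.array([1.0, 0, 0, 0, -2.0])
        sig = extract_signature(fit, sm)
        assert sig.per_block_counts == {"t1": 1, "t2": 1}
        assert sig.entries[0][:2] == ("v0", "t1")
        assert sig.entries[1][:2] == ("w1", "t2")

    def test_empty_fit_empty_signature(self, rng):
        a = make_matrix(rng.standard_normal((4, 5)), tag="t1")
        sm = stack([a])
        fit = jammit_fit(sm.values, lambda_grid(sm.values, 5).lam_sup)
        sig = extract_signature(fit, sm)
        assert sig.s == 0 and sig.per_block_counts == {"t1": 0}

    def test_counts_sum_to_s_over_random_fits(self, rng):
        a = make_matrix(rng.standard_normal((30, 8)), tag="t1")
        b = make_matrix(rng.standard_normal((20, 8)), tag="t2", prefix="w")
        sm = frobenius_scale(stack([a, b]))
        grid = lambda_grid(sm.values, 12)
        for lam in grid.lambdas:
            fit = jammit_fit(sm.values, lam)
            sig = extract_signature(fit, sm)
            assert sum(sig.per_block_counts.values()) == fit.s == sig.s

    def test_length_mismatch_errors(self, rng):
        a = make_matrix(rng.standard_normal((4, 5)), tag="t1")
        sm = stack([a])
        fit = jammit_fit(rng.standard_normal((6, 5)), 0.0)
        with pytest.raises(ValueError, match="does not match"):
            extract_signature(fit, sm)


class TestResidualize:
    def test_eckart_young_energy_split(self, rng):
        D = rng.standard_normal((40, 12))
        _, _, sigma = svd_rank1(D)
        resid = residualize(D, jammit_fit(D, 0.0))
        assert np.linalg.norm(resid) ** 2 == pytest.approx(
            np.linalg.norm(D) ** 2 - sigma**2, rel=1e-8
        )

    def test_rank_one_fully_deflated(self, rng):
        D = np.outer(rng.standard_normal(15), rng.standard_normal(6))
        resid = residualize(D, jammit_fit(D, 0.0))
        assert np.linalg.norm(resid) <= 1e-10 * np.linalg.norm(D)

    def test_second_planted_signal_recovered_after_deflation(self):
        rng = np.random.default_rng(3)
        n = 30
        v1, v2 = np.ones(n), np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        u1, u2 = np.zeros(200), np.zeros(200)
        u1[rng.choice(200, 8, replace=False)] = 3.0
        s2 = rng.choice(np.nonzero(u1 == 0)[0], 8, replace=False)
        u2[s2] = 2.0
        D = np.outer(u1, v1) + np.outer(u2, v2) + 0.05 * rng.standard_normal((200, n))
        fit1 = jammit_fit(D, 0.0)
        resid = residualize(D, fit1)
        grid = lambda_grid(resid, 20)
        fit2 = jammit_fit(resid, grid.lambdas[8])
        assert set(np.nonzero(fit2.u)[0]) == set(s2)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="shape"):
            residualize(rng.standard_normal((5, 4)), jammit_fit(rng.standard_normal((6, 4)), 0.0))
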