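import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batvoc import (
    SignalRecord,
    build_design,
    fit_group_lasso,
    lambda_star,
    reconstruct_coefficients,
    segment_table,
)
from batvoc.synthetic import PiecewiseSpec, gen_piecewise_ar


class TestBuildDesign:
    def test_hand_example_n2_p1(self):
        X = build_design(SignalRecord([1.0, 2.0, 3.0]), 1).dense()
        np.testing.assert_array_equal(X, [[0, 0, 0], [1, 1, 0], [2, 2, 2]])

    def test_column_block_zero_above_its_row(self, rng):
        sig = SignalRecord(rng.normal(size=15))
        des = build_design(sig, 2)
        X = des.dense()
        for n in range(15):
            assert np.all(X[:n, n * 2 : (n + 1) * 2] == 0)

    def test_first_block_only_reproduces_constant_prediction(self, rng):
        """X d with a single nonzero first group equals M c (constant AR)."""
        sig = SignalRecord(rng.normal(size=21))
        p = 3
        des = build_design(sig, p)
        c = rng.normal(size=p)
        d = np.zeros(21 * p)
        d[:p] = c
        np.testing.assert_allclose(des.dense() @ d, des.regressors @ c, atol=1e-12)

    def test_order_too_large_raises(self):
        with pytest.raises(ValueError):
            build_design(SignalRecord([1.0, 2.0, 3.0]), 2)


class TestLambdaStar:
    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.normal(size=200)
        l1 = lambda_star(build_design(SignalRecord(x), 2))
        l2 = lambda_star(build_design(SignalRecord(3.0 * x), 2))
        assert l2 == pytest.approx(9.0 * l1, rel=1e-8)

    def test_zero_signal_gives_zero(self):
        with pytest.warns(RuntimeWarning):
            val = lambda_star(build_design(SignalRecord(np.zeros(50)), 1))
        assert val == 0.0

    def test_white_noise_positive_finite(self, rng):
        val = lambda_star(build_design(SignalRecord(rng.normal(size=201)), 2))
        assert np.isfinite(val) and val > 0


class TestGroupLasso:
    def test_degenerates_to_constant_ar_at_lambda_star(self, rng):
        """At lambda >= lambda* the fit is the constant least-squares AR."""
        sig, _ = gen_piecewise_ar(PiecewiseSpec(N=400, boundaries=(200,), seed=2))
        res = fit_group_lasso(sig, 2, lambda_frac=1.0)
        assert res.K == 0
        des = build_design(sig, 2)
        d0c, *_ = np.linalg.lstsq(des.regressors, des.y, rcond=None)
        dev = np.abs(res.coeff_trajectory - d0c)
        assert np.max(dev) < 1e-6 * max(np.max(np.abs(d0c)), 1.0)

    def test_objective_trace_non_increasing(self):
        sig, _ = gen_piecewise_ar(PiecewiseSpec(N=400, boundaries=(200,), seed=3))
        res = fit_group_lasso(sig, 2, lambda_frac=0.1)
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs <= 1e-9 * np.abs(res.objective_trace[:-1]))

    def test_penalized_objective_matches_bookkeeping(self):
        """First objective term equals 0.5 * || y - X d ||^2 recomputed."""
        sig, _ = gen_piecewise_ar(PiecewiseSpec(N=300, boundaries=(150,), seed=4))
        res = fit_group_lasso(sig, 2, lambda_frac=0.1)
        des = build_design(sig, 2)
        pred = des.dense() @ res.diff_sequence.ravel()
        data_term = 0.5 * np.sum((des.y - pred) ** 2)
        pen = res.lambda_used * np.sum(np.linalg.norm(res.diff_sequence[1:], axis=1))
        assert res.objective_trace[-1] == pytest.approx(data_term + pen, rel=1e-8)

    def test_sparsity_monotone_in_lambda(self):
        sig, _ = gen_piecewise_ar(PiecewiseSpec(N=500, boundaries=(250,), seed=5))
        k_small = fit_group_lasso(sig, 2, lambda_frac=0.05).K
        k_large = fit_group_lasso(sig, 2, lambda_frac=0.20).K
        assert k_large <= k_small

    def test_matches_proximal_gradient_oracle(self, rng):
        """BCD objective agrees with an independent FISTA solve."""
        sig, _ = gen_piecewise_ar(PiecewiseSpec(N=200, boundaries=(100,), seed=6))
        res = fit_group_lasso(sig, 2, lambda_frac=0.15, tol=1e-10, max_iter=500)
        des = build_design(sig, 2)
        oracle = _fista_group_lasso(des.dense(), des.y, res.lambda_used, 2, 40_000)
        assert res.objective_trace[-1] <= oracle * (1 + 1e-4)

    def test_nonconvergence_warns_in_result(self):
        sig, _ = gen_piecewise_ar(PiecewiseSpec(N=400, boundaries=(200,), seed=7))
        res = fit_group_lasso(sig, 2, lambda_frac=0.05, max_iter=1, tol=1e-15)
        assert not res.converged
        assert any("tol" in w for w in res.warnings)


def _fista_group_lasso(X, y, lam, p, iters):
    """Accelerated proximal-gradient minimizer of the same objective."""
    n_pts = y.size
    L = np.linalg.norm(X, 2) ** 2
    XtX, Xty = X.T @ X, X.T @ y

    def prox(v):
        V = v.reshape(n_pts, p).copy()
        nrm = np.linalg.norm(V[1:], axis=1)
        V[1:] *= np.maximum(0, 1 - lam / L / np.maximum(nrm, 1e-300))[:, None]
        return V.ravel()

    v = np.zeros(n_pts * p)
    w, tk = v.copy(), 1.0
    for _ in range(iters):
        v_new = prox(w - (XtX @ w - Xty) / L)
        tk_new = (1 + np.sqrt(1 + 4 * tk * tk)) / 2
        w = v_new + (tk - 1) / tk_new * (v_new - v)
        v, tk = v_new, tk_new
    V = v.reshape(n_pts, p)
    return 0.5 * np.sum((y - X @ v) ** 2) + lam * np.sum(
        np.linalg.norm(V[1:], axis=1)
    )


class TestReconstruction:
    def test_single_group_constant_trajectory(self):
        D = np.zeros((10, 2))
        D[0] = [1.0, -0.5]
        traj = reconstruct_coefficients(D)
        np.testing.assert_array_equal(traj, np.tile([1.0, -0.5], (10, 1)))

    def test_two_groups_step_trajectory(self):
        D = np.zeros((10, 1))
        D[0], D[4] = 1.0, 0.5
        traj = reconstruct_coefficients(D).ravel()
        np.testing.assert_array_equal(traj, [1, 1, 1, 1, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_running_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        D = rng.normal(size=(51, 3))
        traj = reconstruct_coefficients(D)
        acc = np.zeros(3)
        for n in range(51):
            acc = acc + D[n]
            np.testing.assert_array_almost_equal(traj[n], acc, decimal=12)


class TestSegmentTable:
    def test_no_change_points_single_segment(self):
        sig, _ = gen_piecewise_ar(PiecewiseSpec(N=300, boundaries=(150,), seed=8))
        res = fit_group_lasso(sig, 2, lambda_frac=1.0)
        table = segment_table(res)
        assert table == [(0, 300, pytest.approx(res.segment_coeffs[0]))] or (
            table[0][0] == 0 and table[0][1] == 300
        )

    def test_segments_partition_range_and_match_trajectory(self):
        sig, _ = gen_piecewise_ar(PiecewiseSpec(seed=9))
        res = fit_group_lasso(sig, 2, lambda_frac=0.15)
        table = segment_table(res)
        assert table[0][0] == 0 and table[-1][1] == 1000
        for (s, e, c), (s2, _, _) in zip(table, table[1:]):
            assert e + 1 == s2
        for s, e, c in table:
            np.testing.assert_allclose(res.coeff_trajectory[s], c, atol=1e-12)
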