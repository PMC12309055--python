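import numpy as np
import pytest

from batvoc import SignalRecord, fit_basis_tvar, make_basis
from batvoc.basis import assemble_normal_equations, cross_correlation
from batvoc.synthetic import SmoothSpec, gen_smooth_tvar

FAMILIES = ("legendre", "chebyshev", "dct")


class TestMakeBasis:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_row_zero_is_ones(self, family):
        b = make_basis(family, 4, 50)
        np.testing.assert_array_equal(b.values[0], np.ones(50))

    def test_chebyshev_endpoint_alternates(self):
        b = make_basis("chebyshev", 5, 30)
        # at n=1 the mapped argument is -1, so f_j(1) = (-1)^j
        np.testing.assert_allclose(b.values[:, 0], [(-1.0) ** j for j in range(6)],
                                   atol=1e-12)

    def test_legendre_p2_midpoint(self):
        N = 101  # odd N puts a sample exactly at t = 0
        b = make_basis("legendre", 2, N)
        mid = (N + 1) // 2  # n = 51 maps to t = 0
        assert b.values[2, mid - 1] == pytest.approx(-0.5, abs=1e-12)

    @pytest.mark.parametrize("family", ("legendre", "chebyshev"))
    def test_matches_numpy_orthogonal_polynomials(self, family):
        N, q = 64, 6
        b = make_basis(family, q, N)
        t = 2 * (np.arange(1, N + 1) - 1) / (N - 1) - 1
        mod = {"legendre": np.polynomial.legendre.legval,
               "chebyshev": np.polynomial.chebyshev.chebval}[family]
        for j in range(q + 1):
            coeffs = np.zeros(j + 1)
            coeffs[j] = 1.0
            np.testing.assert_allclose(b.values[j], mod(t, coeffs), atol=1e-10)

    def test_rows_linearly_independent(self):
        for family in FAMILIES:
            b = make_basis(family, 6, 40)
            assert np.linalg.matrix_rank(b.values) == 7

    def test_unknown_family_raises(self):
        with pytest.raises(ValueError, match="family"):
            make_basis("fourier", 2, 20)


class TestCrossCorrelation:
    def test_symmetry(self, rng):
        sig = SignalRecord(rng.normal(size=40))
        phi = cross_correlation(sig, make_basis("dct", 2, 39), 3)
        np.testing.assert_allclose(phi, np.transpose(phi, (1, 0, 3, 2)), atol=1e-10)

    def test_energy_reduction_at_q0(self, rng):
        x = rng.normal(size=30)
        p = 2
        phi = cross_correlation(SignalRecord(x), make_basis("dct", 0, 29), p)
        for k in range(p + 1):
            expect = sum(x[n - k] ** 2 for n in range(p + 1, 30))
            assert phi[0, 0, k, k] == pytest.approx(expect)

    def test_matches_brute_force_quadruple_loop(self, rng):
        x = rng.normal(size=13)
        p, q = 2, 1
        basis = make_basis("legendre", q, 12)
        phi = cross_correlation(SignalRecord(x), basis, p)
        F = basis.values
        for l in range(q + 1):
            for j in range(q + 1):
                for k in range(p + 1):
                    for i in range(p + 1):
                        expect = sum(
                            F[l, n - 1] * F[j, n - 1] * x[n - k] * x[n - i]
                            for n in range(p + 1, 13)
                        )
                        assert phi[l, j, k, i] == pytest.approx(expect, abs=1e-10)


class TestNormalEquations:
    def test_R_symmetric_and_psd(self, rng):
        sig = SignalRecord(rng.normal(size=100))
        phi = cross_correlation(sig, make_basis("chebyshev", 2, 99), 3)
        R, r = assemble_normal_equations(phi)
        np.testing.assert_array_equal(R, R.T)
        eigs = np.linalg.eigvalsh(R)
        assert eigs.min() >= -1e-8 * np.trace(R)

    def test_p1_q0_reduces_to_lag1_covariance_equation(self, rng):
        x = rng.normal(size=50)
        phi = cross_correlation(SignalRecord(x), make_basis("dct", 0, 49), 1)
        R, r = assemble_normal_equations(phi)
        ns = np.arange(2, 50)
        assert R[0, 0] == pytest.approx(np.sum(x[ns - 1] ** 2))
        assert r[0] == pytest.approx(np.sum(x[ns] * x[ns - 1]))


class TestFitBasisTvar:
    @pytest.mark.parametrize("p", (2, 4, 6))
    def test_q0_equals_covariance_least_squares(self, rng, p):
        x = rng.normal(size=1000)
        fit = fit_basis_tvar(SignalRecord(x), p, "dct", 0)
        N = x.size - 1
        ns = np.arange(p + 1, N + 1)
        A = np.column_stack([x[ns - i] for i in range(1, p + 1)])
        c_ls, *_ = np.linalg.lstsq(A, x[ns], rcond=None)
        np.testing.assert_allclose(fit.base_coeffs.ravel(), c_ls, atol=1e-8)

    def test_families_coincide_at_q0(self, rng):
        x = rng.normal(size=300)
        fits = [fit_basis_tvar(SignalRecord(x), 3, fam, 0).base_coeffs
                for fam in FAMILIES]
        np.testing.assert_allclose(fits[0], fits[1], atol=1e-10)
        np.testing.assert_allclose(fits[0], fits[2], atol=1e-10)

    def test_unknown_count_is_p_times_q_plus_1(self, rng):
        fit = fit_basis_tvar(SignalRecord(rng.normal(size=500)), 3, "dct", 4)
        assert fit.base_coeffs.size == 3 * 5

    def test_gradient_zero_at_solution(self):
        """The modeling-error gradient w.r.t. every c_kl vanishes."""
        sig, _ = gen_smooth_tvar(SmoothSpec(N=2000, seed=3))
        p, q = 2, 2
        fit = fit_basis_tvar(sig, p, "dct", q)
        x = sig.samples
        N = x.size - 1
        ns = np.arange(p + 1, N + 1)
        F = fit.basis.values[:, ns - 1]
        pred = np.zeros(ns.size)
        for i in range(1, p + 1):
            for j in range(q + 1):
                pred += fit.base_coeffs[i - 1, j] * F[j] * x[ns - i]
        eps = x[ns] - pred
        for k in range(1, p + 1):
            for l in range(q + 1):
                grad = -2 * np.sum(eps * F[l] * x[ns - k])
                assert abs(grad) < 1e-6 * max(fit.modeling_error, 1.0)

    def test_modeling_error_non_increasing_in_q(self, rng):
        sig, _ = gen_smooth_tvar(SmoothSpec(N=1500, seed=4))
        xis = [fit_basis_tvar(sig, 2, "legendre", q).modeling_error
               for q in range(9)]
        assert all(b <= a * (1 + 1e-10) for a, b in zip(xis, xis[1:]))

    def test_recovers_base_coefficients_in_span(self):
        spec = SmoothSpec(N=4000, seed=5)
        sig, truth = gen_smooth_tvar(spec)
        fit = fit_basis_tvar(sig, spec.p, spec.family, spec.q)
        rmse = np.sqrt(np.mean((fit.base_coeffs - spec.base_coeffs) ** 2))
        assert rmse < 0.05

    def test_too_many_unknowns_raises(self, rng):
        with pytest.raises(ValueError, match="longer signal"):
            fit_basis_tvar(SignalRecord(rng.normal(size=30)), 6, "dct", 8)
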