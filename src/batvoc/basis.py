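"""Continuous TV-AR estimation by basis-function expansion.

Each time-varying coefficient is written as a fixed linear combination of
basis functions of the sample index,

    c_i(n) = sum_{j=0..q} c_ij f_j(n),

turning the time-varying estimation problem into a time-invariant least
squares problem in the p*(q+1) base coefficients c_ij.  Minimizing the
summed squared one-step prediction error leads to block normal equations
R c = r built from the cross-correlations

    phi_{lj}(k, i) = sum_{n=p+1..N} f_l(n) f_j(n) x(n-k) x(n-i).

Three families are supported: Legendre polynomials, Chebyshev polynomials
(both on the interval mapped from samples 1..N to [-1, 1]) and the discrete
cosine basis.  f_0(n) = 1 in every family, so q = 0 reduces exactly to the
ordinary covariance-method AR fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import SignalRecord, TVARModel, residuals

__all__ = [
    "BasisSet",
    "BasisFitResult",
    "make_basis",
    "cross_correlation",
    "assemble_normal_equations",
    "fit_basis_tvar",
    "BASIS_FAMILIES",
]

BASIS_FAMILIES = ("legendre", "chebyshev", "dct")


@dataclass
class BasisSet:
    """Sampled basis functions f_j(n), j = 0..q, on samples n = 1..N.

    ``values`` has shape (q+1, N); column n-1 holds [f_0(n), ..., f_q(n)].
    """

    family: str
    dimension_q: int
    N: int
    values: np.ndarray

    def trajectory(self, base_coeffs: np.ndarray) -> np.ndarray:
        """Expand base coefficients (p, q+1) into a (N+1, p) trajectory.

        The basis is defined on samples 1..N; the coefficient at n = 0 is
        taken equal to its value at n = 1 (edge extension, synthesis only).
        """
        base_coeffs = np.atleast_2d(base_coeffs)
        traj_1N = base_coeffs @ self.values  # (p, N)
        return np.vstack((traj_1N[:, 0], traj_1N.T))


@dataclass
class BasisFitResult:
    order_p: int
    basis: BasisSet
    base_coeffs: np.ndarray  # (p, q+1)
    coeff_trajectory: np.ndarray  # (N+1, p)
    modeling_error: float
    condition: float
    ridge_jitter: float = 0.0

    def to_model(self, sample_rate_hz: float, noise_variance: float) -> TVARModel:
        return TVARModel(
            order_p=self.order_p,
            coeff_trajectory=self.coeff_trajectory,
            noise_variance=noise_variance,
            sample_rate_hz=sample_rate_hz,
        )


def make_basis(family: str, q: int, N: int) -> BasisSet:
    """Sample a basis family at n = 1..N.

    legendre : three-term recurrence on t(n) = 2(n-1)/(N-1) - 1
    chebyshev: f_j(n) = cos(j * arccos t(n))
    dct      : f_j(n) = cos(pi j (2n+1) / (2N))  (unit scaling)
    """
    if q < 0:
        raise ValueError("dimension q must be >= 0")
    if N < q + 2:
        raise ValueError(f"need N >= q+2 samples (got N={N}, q={q})")
    n = np.arange(1, N + 1, dtype=float)
    F = np.empty((q + 1, N))
    F[0] = 1.0
    if family == "legendre":
        t = 2.0 * (n - 1) / (N - 1) - 1.0
        if q >= 1:
            F[1] = t
        for j in range(2, q + 1):
            F[j] = ((2 * j - 1) * t * F[j - 1] - (j - 1) * F[j - 2]) / j
    elif family == "chebyshev":
        t = 2.0 * (n - 1) / (N - 1) - 1.0
        theta = np.arccos(np.clip(t, -1.0, 1.0))
        for j in range(1, q + 1):
            F[j] = np.cos(j * theta)
    elif family == "dct":
        for j in range(1, q + 1):
            F[j] = np.cos(np.pi * j * (2 * n + 1) / (2 * N))
    else:
        raise ValueError(f"unknown basis family {family!r}; choose from {BASIS_FAMILIES}")
    return BasisSet(family=family, dimension_q=q, N=N, values=F)


def _lag_matrix(x: np.ndarray, p: int, ns: np.ndarray) -> np.ndarray:
    """Rows x(n-k) for k = 0..p at the summation indices ns."""
    return np.stack([x[ns - k] for k in range(p + 1)])


def cross_correlation(signal: SignalRecord, basis: BasisSet, p: int) -> np.ndarray:
    """Cross-correlation tensor phi[l, j, k, i], l,j in 0..q, k,i in 0..p."""
    x = signal.samples
    N = x.size - 1
    if basis.N != N:
        raise ValueError(f"basis sampled at N={basis.N} but signal has N={N}")
    if N <= p + 1:
        raise ValueError("signal too short for the requested order")
    ns = np.arange(p + 1, N + 1)
    F = basis.values[:, ns - 1]  # f_l(n) at n = p+1..N (values column n-1)
    L = _lag_matrix(x, p, ns)
    q1, p1 = F.shape[0], L.shape[0]
    G = (F[:, None, :] * L[None, :, :]).reshape(q1 * p1, ns.size)
    phi = (G @ G.T).reshape(q1, p1, q1, p1)
    # phi[l, k, j, i] -> phi[l, j, k, i]
    return np.transpose(phi, (0, 2, 1, 3))


def assemble_normal_equations(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Block normal equations R c = r from the cross-correlation tensor.

    Block (k, i) of R (k, i = 1..p) holds phi[l, j, k, i]; block k of r holds
    phi[l, 0, k, 0].  Unknown ordering matches: c = [c_1; ...; c_p] with
    c_i = [c_i0, ..., c_iq].
    """
    q1 = phi.shape[0]
    p = phi.shape[2] - 1
    # R[(k-1)*q1 + l, (i-1)*q1 + j] = phi[l, j, k, i]
    R = np.transpose(phi[:, :, 1:, 1:], (2, 0, 3, 1)).reshape(p * q1, p * q1)
    r = phi[:, 0, 1:, 0].T.reshape(p * q1)
    return R, r


def fit_basis_tvar(
    signal: SignalRecord,
    p: int,
    family: str = "dct",
    q: int = 0,
    cond_limit: float = 1e12,
) -> BasisFitResult:
    """Fit a TV-AR model whose coefficients lie in the span of a basis.

    Solves the symmetric normal equations for the p*(q+1) base coefficients;
    if the condition estimate exceeds ``cond_limit`` a small ridge jitter
    (1e-10 * trace(R)/dim) is added and reported in the result.

    Raises
    ------
    ValueError
        If p*(q+1) unknowns exceed the available prediction equations, or the
        system remains numerically singular after jitter (use a smaller q or
        a longer signal).
    """
    x = signal.samples
    N = x.size - 1
    if p * (q + 1) >= N - p:
        raise ValueError(
            f"p(q+1) = {p * (q + 1)} unknowns need a longer signal (N-p = {N - p})"
        )
    basis = make_basis(family, q, N)
    phi = cross_correlation(signal, basis, p)
    R, r = assemble_normal_equations(phi)
    cond = float(np.linalg.cond(R))
    jitter = 0.0
    if not np.isfinite(cond) or cond > cond_limit:
        jitter = 1e-10 * np.trace(R) / R.shape[0]
        R = R + jitter * np.eye(R.shape[0])
        cond = float(np.linalg.cond(R))
        if not np.isfinite(cond) or cond > 1 / np.finfo(float).eps:
            raise ValueError(
                "normal equations numerically singular; try a smaller basis "
                "dimension q or a longer signal"
            )
    c = scipy.linalg.solve(R, r, assume_a="sym")
    base_coeffs = c.reshape(p, q + 1)
    traj = basis.trajectory(base_coeffs)
    model = TVARModel(order_p=p, coeff_trajectory=traj,
                      sample_rate_hz=signal.sample_rate_hz)
    _, xi = residuals(model, signal)
    return BasisFitResult(
        order_p=p,
        basis=basis,
        base_coeffs=base_coeffs,
        coeff_trajectory=traj,
        modeling_error=xi,
        condition=cond,
        ridge_jitter=jitter,
    )
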