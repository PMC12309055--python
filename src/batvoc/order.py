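"""Model-order and basis-dimension selection.

Order scan
    For each candidate order the chosen fitter is run and its modeling error
    xi_p (summed squared one-step residuals) converted into four classical
    criteria -- MMSE, FPE, AIC and MDL -- plus the decline rate of modeling
    error

        v_xi(p) = (xi_p - xi_{p-1})^2 / xi_p^2.

    Because on real calls the criterion curves rarely show a clean interior
    minimum, the selected order is the smallest one whose decline rate drops
    below a threshold v_th.

Dimension selection
    The same decline-rate rule applied across basis dimensions j = 0..q_max
    for a fixed order: take the interior minimizer of xi_p(j) if one exists,
    otherwise the first j whose decline rate falls below v_th.

TV-OPS
    Time-varying optimal parameter search: a redundancy check on the lags.
    The candidate pool stacks the vectors f_j(n) x(n-i); a maximal linearly
    independent subset is kept (rank-revealing QR), least-squares base
    coefficients are computed on it, and each lag m receives a nonnegative
    energy weight C_m built from its basis-expanded time-varying coefficient.
    Lags whose relative weight is below a tolerance are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .basis import BasisSet, fit_basis_tvar
from .core import SignalRecord
from .piecewise import fit_group_lasso

__all__ = [
    "OrderScanReport",
    "DimensionScanReport",
    "TvopsReport",
    "order_scan",
    "select_dimension",
    "tvops",
    "DEFAULT_ORDER_GRID",
    "MAX_ORDER",
]

DEFAULT_ORDER_GRID = (4, 6, 8, 10, 12)
MAX_ORDER = 18


@dataclass
class OrderScanReport:
    orders: list[int]
    xi: dict[int, float]
    mmse: dict[int, float]
    fpe: dict[int, float]
    aic: dict[int, float]
    mdl: dict[int, float]
    decline_rate: dict[int, float]
    selected_order: int
    threshold: float
    failed_orders: list[int] = field(default_factory=list)


@dataclass
class DimensionScanReport:
    dimensions: list[int]
    xi: dict[int, float]
    decline_rate: dict[int, float]
    selected_q: int
    threshold: float


@dataclass
class TvopsReport:
    p: int
    q: int
    weights: np.ndarray  # C_m for m = 1..p
    retained_lags: list[int]
    discarded_lags: list[int]
    zero_tolerance: float
    pool_rank: int
    retained_columns: list[tuple[int, int]]  # (lag i, basis j) kept in step 1


def _criteria(xi: float, N: int, p: int) -> tuple[float, float, float, float]:
    sigma2 = xi / (N - p)
    mmse = sigma2
    fpe = sigma2 * (N + p) / (N - p)
    aic = N * math.log(sigma2) + 2 * p
    mdl = N * math.log(sigma2) + p * math.log(N)
    return mmse, fpe, aic, mdl


def decline_rate(xi_curr: float, xi_prev: float) -> float:
    """(xi_p - xi_{p-1})^2 / xi_p^2 -- nonnegative by construction."""
    if xi_curr == 0.0:
        return 0.0 if xi_prev == xi_curr else math.inf
    return (xi_curr - xi_prev) ** 2 / xi_curr**2


def order_scan(
    signal: SignalRecord,
    orders: Sequence[int] = DEFAULT_ORDER_GRID,
    v_th: float = 0.01,
    fitter: str | Callable[[SignalRecord, int], float] = "basis",
    **fit_kwargs,
) -> OrderScanReport:
    """Scan candidate model orders and score each fit.

    ``fitter`` is "basis" (basis-expansion fit; pass family/q via kwargs),
    "piecewise" (Group-Lasso fit; pass lambda_frac etc.), or a callable
    ``(signal, p) -> xi``.  Orders above ``MAX_ORDER`` are rejected.  An
    order whose fit raises is recorded in ``failed_orders`` and skipped.
    """
    orders = list(orders)
    if any(o1 >= o2 for o1, o2 in zip(orders, orders[1:])):
        raise ValueError("orders must be strictly ascending")
    if orders and orders[-1] > MAX_ORDER:
        raise ValueError(f"maximum model order is capped at {MAX_ORDER}")
    if fitter == "basis":
        def fit_fn(sig, p):
            return fit_basis_tvar(sig, p, **fit_kwargs).modeling_error
    elif fitter == "piecewise":
        def fit_fn(sig, p):
            from .core import TVARModel, residuals

            res = fit_group_lasso(sig, p, **fit_kwargs)
            model = TVARModel(order_p=p, coeff_trajectory=res.coeff_trajectory)
            return residuals(model, sig)[1]
    elif callable(fitter):
        fit_fn = fitter
    else:
        raise ValueError(f"unknown fitter {fitter!r}")

    N = len(signal) - 1
    xi, mmse, fpe, aic, mdl, v = {}, {}, {}, {}, {}, {}
    failed = []
    prev_xi = None
    for p in orders:
        try:
            xi_p = fit_fn(signal, p)
        except Exception:
            failed.append(p)
            continue
        xi[p] = xi_p
        mmse[p], fpe[p], aic[p], mdl[p] = _criteria(xi_p, N, p)
        if prev_xi is not None:
            v[p] = decline_rate(xi_p, prev_xi)
        prev_xi = xi_p
    fitted = [p for p in orders if p in xi]
    if not fitted:
        raise RuntimeError("no candidate order could be fitted")
    selected = next((p for p in fitted if p in v and v[p] <= v_th), fitted[-1])
    if all(rate == 0.0 for rate in v.values()) and v:
        selected = fitted[0]
    return OrderScanReport(
        orders=fitted, xi=xi, mmse=mmse, fpe=fpe, aic=aic, mdl=mdl,
        decline_rate=v, selected_order=selected, threshold=v_th,
        failed_orders=failed,
    )


def select_dimension(
    signal: SignalRecord,
    p: int,
    family: str = "dct",
    q_max: int = 20,
    v_th: float = 0.01,
) -> DimensionScanReport:
    """Choose the basis dimension for a fixed order.

    Computes the modeling-error curve xi_p(j) for j = 0..q_max and its
    decline rate; returns the interior minimizer of xi_p(j) if one exists,
    otherwise the first j whose decline rate is at or below v_th (falling
    back to q_max if the rate never drops that far).
    """
    if q_max < 1:
        raise ValueError("q_max must be >= 1")
    xi: dict[int, float] = {}
    v: dict[int, float] = {}
    for j in range(q_max + 1):
        xi[j] = fit_basis_tvar(signal, p, family=family, q=j).modeling_error
        if j >= 1:
            v[j] = decline_rate(xi[j], xi[j - 1])
    j_min = min(xi, key=xi.get)
    if j_min < q_max:
        selected = j_min
    else:
        selected = next((j for j in range(1, q_max + 1) if v[j] <= v_th), q_max)
    return DimensionScanReport(
        dimensions=list(range(q_max + 1)), xi=xi, decline_rate=v,
        selected_q=selected, threshold=v_th,
    )


def tvops(
    signal: SignalRecord,
    p: int,
    basis: BasisSet,
    zero_tol: float = 1e-3,
) -> TvopsReport:
    """Prune redundant lags by time-varying optimal parameter search.

    Candidate columns are f_j(n) x(n-i) for i = 1..p, j = 0..q over n = 1..N
    (zero pre-signal history).  Weights are

        C_m = (1/N) sum_n sum_{k=0..q} a_m(n)^2 [f_k(n) x(n-m)]^2

    with a_m(n) the basis-expanded time-varying coefficient of lag m from the
    least-squares solution on the retained independent columns.  Lags with
    C_m <= zero_tol * max_m C_m are discarded.
    """
    x = signal.samples
    N = x.size - 1
    q = basis.dimension_q
    if basis.N != N:
        raise ValueError(f"basis sampled at N={basis.N} but signal has N={N}")
    ns = np.arange(1, N + 1)
    padded = np.concatenate((np.zeros(p), x))
    F = basis.values  # (q+1, N) at n = 1..N
    # pool columns ordered x_10, .., x_1q, x_20, ..., x_pq
    cols = []
    index_map: list[tuple[int, int]] = []
    for i in range(1, p + 1):
        lag = padded[p + ns - i]  # x(n-i), zero-padded
        for j in range(q + 1):
            cols.append(F[j] * lag)
            index_map.append((i, j))
    W_h = np.column_stack(cols)
    target = x[1:]

    # step 1: maximal linearly independent subset via rank-revealing QR
    _, Rqr, piv = scipy.linalg.qr(W_h, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rqr))
    if diag.size == 0 or diag[0] <= 0:
        raise ValueError("degenerate signal: candidate pool has rank 0")
    rank = int(np.sum(diag > max(W_h.shape) * np.finfo(float).eps * diag[0]))
    if rank < 1:
        raise ValueError("degenerate signal: candidate pool has rank 0")
    kept = sorted(piv[:rank])
    W = W_h[:, kept]
    retained_cols = [index_map[c] for c in kept]

    # step 2: least-squares base coefficients on the retained columns
    theta, *_ = np.linalg.lstsq(W, target, rcond=None)
    full_theta = np.zeros(W_h.shape[1])
    full_theta[kept] = theta
    coeff = full_theta.reshape(p, q + 1)  # row m-1: basis coefficients of lag m

    # step 3: per-lag energy weights
    A = coeff @ F  # a_m(n), shape (p, N)
    C = np.empty(p)
    for m in range(1, p + 1):
        w2 = (F * padded[p + ns - m]) ** 2  # w_{m,k}(n)^2, shape (q+1, N)
        C[m - 1] = float(np.sum(A[m - 1] ** 2 * np.sum(w2, axis=0))) / N

    # step 4: discard near-zero weights
    cmax = C.max()
    if cmax == 0:
        raise ValueError("degenerate signal: all lag weights are zero")
    retained = [m + 1 for m in range(p) if C[m] > zero_tol * cmax]
    discarded = [m + 1 for m in range(p) if C[m] <= zero_tol * cmax]
    return TvopsReport(
        p=p, q=q, weights=C, retained_lags=retained, discarded_lags=discarded,
        zero_tolerance=zero_tol, pool_rank=rank, retained_columns=retained_cols,
    )
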