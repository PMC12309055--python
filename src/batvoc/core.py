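"""Time-varying all-pole (TV-AR) representation of a vocal system.

A vocal tract acts as a cascade of resonators (formants); driven by wideband
noise from the lungs it shapes a flat excitation spectrum into a structured
call.  The discrete-time model is an autoregression whose coefficients depend
on the sample index::

    x(n) = sum_{i=1..p} c_i(n) x(n-i) + v(n),   v(n) ~ N(0, sigma_v^2)

Instantaneous resonance frequencies and bandwidths are read off the roots of
the characteristic polynomial z^p - sum_i c_i(n) z^{p-i} at each n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalRecord",
    "TVARModel",
    "PoleSet",
    "DivergenceError",
    "simulate",
    "residuals",
    "poles_at",
]


class DivergenceError(RuntimeError):
    """Raised when synthesis produces a non-finite sample."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(
            f"synthesis diverged: first non-finite output sample at index {index}"
        )


@dataclass
class SignalRecord:
    """A sampled single-channel acoustic signal.

    Parameters
    ----------
    samples : array-like of float
        Amplitude values, arbitrary units.
    sample_rate_hz : float
        Sampling rate in Hz.
    id : str
        Free-text label carried through fits and reports.
    """

    samples: np.ndarray
    sample_rate_hz: float = 1.0
    id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class TVARModel:
    """A time-varying AR model: order, per-sample coefficients, noise power.

    ``coeff_trajectory`` has shape ``(N+1, p)``; row ``n`` holds
    ``[c_1(n), ..., c_p(n)]``.
    """

    order_p: int
    coeff_trajectory: np.ndarray
    noise_variance: float = 1.0
    sample_rate_hz: float = 1.0

    def __post_init__(self):
        self.coeff_trajectory = np.atleast_2d(
            np.asarray(self.coeff_trajectory, dtype=float)
        )
        if not np.all(np.isfinite(self.coeff_trajectory)):
            raise ValueError("coefficient trajectory contains non-finite entries")
        if self.coeff_trajectory.shape[1] != self.order_p:
            raise ValueError(
                f"order_p={self.order_p} does not match trajectory width "
                f"{self.coeff_trajectory.shape[1]}"
            )
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.coeff_trajectory.shape[0]


@dataclass
class PoleSet:
    """Instantaneous poles of the model at one sample index."""

    time_index: int
    poles: np.ndarray = field(default_factory=lambda: np.empty(0, complex))
    max_radius: float = 0.0


def simulate(
    model: TVARModel,
    n_samples: int | None = None,
    seed: int = 0,
    burn_in: int = 0,
    stabilize: bool = False,
    initial: np.ndarray | None = None,
) -> SignalRecord:
    """Drive the time-varying all-pole system with Gaussian white noise.

    The recursion uses zero pre-signal history (x(n) = 0 for n < 0) unless
    ``initial`` supplies the p pre-signal samples [x(-p), ..., x(-1)].  The
    first ``burn_in`` samples are computed against the start of the
    coefficient trajectory and discarded.  Output is bit-reproducible for a
    fixed ``seed``.

    Parameters
    ----------
    model : TVARModel
    n_samples : int, optional
        Output length; defaults to the trajectory length minus ``burn_in``.
    seed : int
        Seed for the white-noise draw.
    burn_in : int
        Warm-up samples computed then discarded (default 0).
    stabilize : bool
        If True, instantaneous poles with radius > 1 - 1e-3 are reflected to
        radius 1 - 1e-3 before each step, guarding against transiently
        unstable fitted trajectories.

    Raises
    ------
    DivergenceError
        If the output becomes non-finite (index reported is in output
        coordinates, after burn-in removal).
    """
    p = model.order_p
    traj = model.coeff_trajectory
    if n_samples is None:
        n_samples = traj.shape[0] - burn_in
    total = n_samples + burn_in
    if total > traj.shape[0]:
        raise ValueError(
            f"n_samples + burn_in = {total} exceeds trajectory length {traj.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(model.noise_variance), size=total)
    x = np.zeros(total + p)  # leading p entries hold the pre-signal history
    if initial is not None:
        initial = np.asarray(initial, float)
        if initial.size != p:
            raise ValueError(f"initial history must have p={p} samples")
        x[:p] = initial
    for n in range(total):
        c = traj[n]
        if stabilize:
            c = _stabilized_coeffs(c)
        # x[n + p - i] is x(n - i) with the zero-history offset
        acc = float(np.dot(c, x[n + p - 1 :: -1][:p]))
        val = acc + noise[n]
        if not np.isfinite(val):
            raise DivergenceError(max(n - burn_in, 0))
        x[n + p] = val
    return SignalRecord(
        x[p + burn_in :], sample_rate_hz=model.sample_rate_hz, id="simulated"
    )


def _stabilized_coeffs(c: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Reflect instantaneous poles with |z| > 1-eps back to radius 1-eps."""
    roots = np.roots(np.concatenate(([1.0], -c)))
    r = np.abs(roots)
    if not np.any(r > 1 - eps):
        return c
    roots = np.where(r > 1 - eps, roots * (1 - eps) / np.where(r == 0, 1, r), roots)
    poly = np.real(np.poly(roots))
    return -poly[1:]


def residuals(model: TVARModel, signal: SignalRecord) -> tuple[np.ndarray, float]:
    """One-step prediction residuals and the modeling error.

    Returns ``(eps, xi)`` where ``eps(n) = x(n) - sum_i c_i(n) x(n-i)`` for
    n = p+1 .. N and ``xi = sum eps^2`` (the modeling error used throughout
    order and dimension selection).
    """
    x = signal.samples
    traj = model.coeff_trajectory
    p = model.order_p
    if x.size != traj.shape[0]:
        raise ValueError(
            f"signal length {x.size} does not match trajectory length {traj.shape[0]}"
        )
    N = x.size - 1
    ns = np.arange(p + 1, N + 1)
    lagged = np.column_stack([x[ns - i] for i in range(1, p + 1)])
    eps = x[ns] - np.einsum("ij,ij->i", traj[ns], lagged)
    return eps, float(np.dot(eps, eps))


def poles_at(model: TVARModel, n: int) -> PoleSet:
    """Roots of the instantaneous characteristic polynomial at sample ``n``.

    The polynomial is ``z^p - sum_{i=1..p} c_i(n) z^{p-i}`` (the sign
    convention of the recursion x(n) = +sum c_i x(n-i) + v(n)).
    """
    if not 0 <= n < model.n_samples:
        raise IndexError(f"sample index {n} outside trajectory [0, {model.n_samples - 1}]")
    c = model.coeff_trajectory[n]
    roots = np.roots(np.concatenate(([1.0], -c)))
    return PoleSet(
        time_index=n,
        poles=roots,
        max_radius=float(np.max(np.abs(roots))) if roots.size else 0.0,
    )
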