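"""Synthetic TV-AR signal generators with known ground truth.

Recorded echolocation calls come with no ground-truth vocal-system
parameters, so every estimator in this package is exercised on synthetic
signals whose generating model is known exactly:

* piecewise-constant AR signals with abrupt coefficient jumps at chosen
  sample indices (the piecewise fitter's generative assumption);
* TV-AR signals whose coefficient trajectories lie exactly in the span of a
  chosen basis family (the basis fitter's generative assumption);
* CF-FM chirp surrogates -- a resonator whose pole angle holds a constant
  frequency and then sweeps downward, qualitatively mimicking the
  constant-frequency/frequency-modulated calls of hipposiderid bats.

Segments and resonators are parameterized by pole radius and angle, which
guarantees stability by construction; raw coefficient vectors are accepted
but checked.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import make_basis
from .core import SignalRecord, TVARModel, simulate

__all__ = [
    "PiecewiseSpec",
    "SmoothSpec",
    "ChirpSpec",
    "gen_piecewise_ar",
    "gen_smooth_tvar",
    "gen_cf_fm_chirp",
    "resonator_coeffs",
]


def resonator_coeffs(radius, angle) -> tuple[np.ndarray, np.ndarray]:
    """AR(2) coefficients (c1, c2) of a conjugate pole pair r e^{+-j w}.

    c1 = 2 r cos w, c2 = -r^2, so that z^2 - c1 z - c2 has roots r e^{+-jw}.
    """
    radius = np.asarray(radius, float)
    angle = np.asarray(angle, float)
    return 2.0 * radius * np.cos(angle), -(radius**2)


def _check_stable_trajectory(traj: np.ndarray, margin: float = 0.0) -> float:
    """Largest instantaneous pole radius over the trajectory."""
    p = traj.shape[1]
    uniq = np.unique(traj, axis=0)
    worst = 0.0
    for row in uniq:
        roots = np.roots(np.concatenate(([1.0], -row)))
        if roots.size:
            worst = max(worst, float(np.max(np.abs(roots))))
    if worst >= 1.0 - margin:
        raise ValueError(
            f"unstable trajectory: max instantaneous pole radius {worst:.4f} "
            f">= {1.0 - margin:.4f}"
        )
    return worst


@dataclass
class PiecewiseSpec:
    """Piecewise-constant AR signal: jumps at ``boundaries``.

    ``segments`` holds one (radius, angle) pair per segment for p = 2, or a
    list of (radius, angle) pairs per segment for cascaded resonators
    (p = 2 * pairs), or raw coefficient vectors via ``raw_coeffs``.
    """

    N: int = 1000
    boundaries: tuple[int, ...] = (500,)
    segments: tuple = ((0.95, 0.5 * np.pi), (0.95, 0.25 * np.pi))
    raw_coeffs: np.ndarray | None = None
    noise_sigma: float = 1.0
    seed: int = 0
    sample_rate_hz: float = 1.0


@dataclass
class SmoothSpec:
    """TV-AR signal whose trajectory lies exactly in a basis span."""

    N: int = 8000
    p: int = 2
    family: str = "dct"
    q: int = 2
    # rows: lag i = 1..p; columns: basis index j = 0..q.  The default keeps
    # c_2 = -0.81 fixed so the resonator radius stays at 0.9 while the pole
    # angle wanders with the basis -- stable for every family.
    base_coeffs: np.ndarray = field(
        default_factory=lambda: np.array([[0.9, 0.4, 0.15], [-0.81, 0.0, 0.0]])
    )
    noise_sigma: float = 1.0
    seed: int = 0
    stability_margin: float = 0.02
    sample_rate_hz: float = 1.0


@dataclass
class ChirpSpec:
    """CF-FM call surrogate from a slowly swept resonator pole trajectory."""

    sample_rate_hz: float = 192_000.0
    cf_freq_hz: float = 60_000.0
    cf_duration_s: float = 0.015
    fm_start_hz: float = 60_000.0
    fm_end_hz: float = 45_000.0
    fm_duration_s: float = 0.005
    pole_radius: float = 0.98
    noise_sigma: float = 1.0
    seed: int = 0


def _segment_coeff_matrix(spec: PiecewiseSpec) -> np.ndarray:
    if spec.raw_coeffs is not None:
        return np.atleast_2d(np.asarray(spec.raw_coeffs, float))
    rows = []
    for seg in spec.segments:
        pairs = seg if isinstance(seg[0], (tuple, list, np.ndarray)) else [seg]
        poly = np.array([1.0])
        for radius, angle in pairs:
            c1, c2 = resonator_coeffs(radius, angle)
            poly = np.convolve(poly, [1.0, -c1, -c2])
        rows.append(-poly[1:])
    return np.asarray(rows)


def gen_piecewise_ar(spec: PiecewiseSpec) -> tuple[SignalRecord, TVARModel]:
    """Simulate a piecewise-constant AR signal; return it with ground truth."""
    bounds = list(spec.boundaries)
    if any(b1 >= b2 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("segment boundaries must be strictly increasing")
    if bounds and (bounds[0] < 1 or bounds[-1] > spec.N):
        raise ValueError(f"boundaries must lie in [1, N={spec.N}]")
    seg_coeffs = _segment_coeff_matrix(spec)
    if seg_coeffs.shape[0] != len(bounds) + 1:
        raise ValueError(
            f"{len(bounds)} boundaries require {len(bounds) + 1} segments, "
            f"got {seg_coeffs.shape[0]}"
        )
    p = seg_coeffs.shape[1]
    traj = np.empty((spec.N + 1, p))
    starts = [0] + bounds
    ends = bounds + [spec.N + 1]
    for coeffs, s, e in zip(seg_coeffs, starts, ends):
        traj[s:e] = coeffs
    _check_stable_trajectory(traj)
    model = TVARModel(
        order_p=p,
        coeff_trajectory=traj,
        noise_variance=spec.noise_sigma**2,
        sample_rate_hz=spec.sample_rate_hz,
    )
    sig = simulate(model, seed=spec.seed)
    sig.id = f"piecewise-ar-p{p}-seed{spec.seed}"
    return sig, model


def gen_smooth_tvar(spec: SmoothSpec) -> tuple[SignalRecord, TVARModel]:
    """Simulate a TV-AR signal whose trajectory is an exact basis expansion."""
    base = np.atleast_2d(np.asarray(spec.base_coeffs, float))
    if base.shape != (spec.p, spec.q + 1):
        raise ValueError(
            f"base_coeffs must have shape (p, q+1) = ({spec.p}, {spec.q + 1})"
        )
    basis = make_basis(spec.family, spec.q, spec.N)
    traj = basis.trajectory(base)
    _check_stable_trajectory(traj, margin=spec.stability_margin)
    model = TVARModel(
        order_p=spec.p,
        coeff_trajectory=traj,
        noise_variance=spec.noise_sigma**2,
        sample_rate_hz=spec.sample_rate_hz,
    )
    sig = simulate(model, seed=spec.seed)
    sig.id = f"smooth-tvar-{spec.family}-q{spec.q}-seed{spec.seed}"
    return sig, model


def gen_cf_fm_chirp(spec: ChirpSpec) -> tuple[SignalRecord, TVARModel]:
    """Simulate a CF-FM-like call from a swept resonator pole trajectory.

    The instantaneous resonance holds ``cf_freq_hz`` for the CF part, then
    sweeps linearly from ``fm_start_hz`` to ``fm_end_hz``.
    """
    fs = spec.sample_rate_hz
    nyq = fs / 2
    for f in (spec.cf_freq_hz, spec.fm_start_hz, spec.fm_end_hz):
        if not 0 < f < nyq:
            raise ValueError(f"frequency {f} Hz outside (0, Nyquist={nyq})")
    if not 0 < spec.pole_radius < 1:
        raise ValueError("pole radius must lie in (0, 1)")
    n_cf = int(round(spec.cf_duration_s * fs))
    n_fm = int(round(spec.fm_duration_s * fs))
    freq = np.concatenate(
        (np.full(n_cf, spec.cf_freq_hz), np.linspace(spec.fm_start_hz, spec.fm_end_hz, n_fm))
    )
    omega = 2 * np.pi * freq / fs
    c1, c2 = resonator_coeffs(spec.pole_radius, omega)
    traj = np.column_stack((c1, np.full(c1.size, float(c2))))
    model = TVARModel(
        order_p=2,
        coeff_trajectory=traj,
        noise_variance=spec.noise_sigma**2,
        sample_rate_hz=fs,
    )
    sig = simulate(model, seed=spec.seed)
    sig.id = f"cf-fm-chirp-seed{spec.seed}"
    return sig, model
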