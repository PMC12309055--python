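# Methods

## Model

A call `x(n)`, `n = 0..N`, is modeled as the output of a time-varying
all-pole system driven by Gaussian white noise:

    x(n) = Σ_{i=1..p} c_i(n) x(n−i) + v(n),    v(n) ~ N(0, σ_v²).

The instantaneous poles — roots of `z^p − Σ_i c_i(n) z^{p−i}` — play the
role of formants: a conjugate pair at radius `r` and angle `ω` is a
resonance at frequency `ω·fs/2π` with bandwidth shrinking as `r → 1`. A
cascade of `p/2` such second-order sections is the classical source-filter
picture of a vocal tract. Two sign conventions for the all-pole denominator
circulate (`1 + Σ c_i z^{−i}` vs the recursion above with `+Σ c_i x(n−i)`);
this package uses one convention throughout — the recursion as written —
so the denominator polynomial carries negated coefficients.

Assumptions worth keeping in mind: the excitation is stationary white
noise (no glottal pulse train, no harmonics), the system is linear, and all
vocal organs are lumped into a single filter. Pre-signal history is zero
(`x(n) = 0` for `n < 0`) in both simulation and every design matrix; an
optional `initial` argument to `simulate` overrides it, which is what makes
the noiseless "self-model" reproduce a reference exactly.

## Piecewise-constant estimator

Hypothesis: the articulators hold quasi-steady postures and jump between
them. With `d_0 = c_0` and `d_n = c_n − c_{n−1}`, the prediction of the
whole signal is `X d` with the cumulative lower-block-triangular design
(row `n` holds the regressor `h_n = [x(n−1)..x(n−p)]` repeated in column
blocks `0..n`). Change points are the nonzero groups of

    min_d  ½‖y − X d‖² + λ Σ_{n≥1} ‖d_n‖₂ .

The penalty is the *unsquared* group ℓ2 norm. (The squared form sometimes
written for this problem is ridge-like and produces no group sparsity at
all; the unsquared form is the one consistent with a finite `λ*` and with
"large `λ` ⇒ fewer change points".)

`λ* = max_{n≥1} ‖X_nᵀ(X_0 d_{0,c} − y)‖₂`, with `d_{0,c}` the constant-AR
least-squares fit, is the smallest penalty at which the all-constant
solution satisfies the optimality conditions; `lambda_frac` expresses `λ`
as a fraction of it, working range 0.05–0.20, default 0.15.

Solver: cyclic block coordinate descent. The baseline block `d_0` is
unpenalized (exact least-squares step); each penalized block is minimized
exactly — zero if `‖X_nᵀr‖ ≤ λ`, otherwise via the scalar secular equation
in `t = ‖d_n‖` solved by bracketing on the eigendecomposition of
`A_n = X_nᵀX_n` (all `A_n` are reverse cumulative sums of `h_m h_mᵀ`, so
the dense `X` is never materialized). Full sweeps over all blocks alternate
with cheap refinement sweeps over the currently nonzero blocks; convergence
is declared only after a full sweep (an implicit KKT check over every
block) improves the objective by less than `tol` (default 1e−6 relative,
`max_iter` 200 full sweeps; exhaustion is recorded as a warning in the
result, not raised). Exact block minimization makes the objective trace
non-increasing, which the tests assert on every run. On 200-point problems
the solution matches an independent FISTA solve of the same objective to
1e−4 relative in objective value.

Known behavior, not a bug: at the exact minimizer the ℓ2 shrinkage tends to
split one true jump across a dominant difference group plus small satellite
groups nearby (verified against the independent FISTA solver). The dominant
group localizes the jump well; the raw count of nonzero groups
overestimates the number of physical change points. `K` is counted with a
relative zero tolerance of 1e−8, i.e. essentially exactly.

## Basis-expansion estimator

Hypothesis: the articulators move continuously. Each coefficient is
constrained to a `q+1`-dimensional subspace, `c_i(n) = Σ_j c_ij f_j(n)`,
with three basis families sampled on `n = 1..N`:

* Legendre, by the three-term recurrence on `t(n) = 2(n−1)/(N−1) − 1`;
* Chebyshev, `f_j(n) = cos(j arccos t(n))`;
* discrete cosine, `f_j(n) = cos(πj(2n+1)/2N)`, unit scaling.

`f_0 ≡ 1` in every family, so `q = 0` reduces all of them to the ordinary
covariance-method AR fit (asserted to 1e−8 against a direct least-squares
oracle). Minimizing the modeling error
`ξ = Σ_{n=p+1..N} (x(n) − Σ_i c_i(n) x(n−i))²` over the base coefficients
gives the symmetric normal equations `R c = r` with entries built from

    φ_lj(k, i) = Σ_{n=p+1..N} f_l(n) f_j(n) x(n−k) x(n−i),

assembled as Gram blocks (the cross-correlation tensor is computed as one
`G Gᵀ` matrix product). The system is solved with a symmetric solver,
never explicit inversion; the condition number is always reported, and if
it exceeds 1e12 a ridge jitter of `1e−10·tr(R)/dim` is added (and recorded)
before solving — high-`q` bases on short signals are ill-conditioned. The
trajectory at `n = 0` (outside the basis domain) copies the `n = 1` value;
it only matters for synthesis.

## Order, dimension, and redundancy selection

For a scanned order grid (default {4, 6, 8, 10, 12}, hard cap 18) the four
classical criteria are computed from `ξ_p` with `σ̂² = ξ_p/(N−p)`:
`MMSE = σ̂²`, `FPE = σ̂²(N+p)/(N−p)`, `AIC = N ln σ̂² + 2p`,
`MDL = N ln σ̂² + p ln N`. These are the standard textbook forms; on real
calls their curves rarely bottom out, so the selected order is the smallest
whose decline rate `v_ξ(p) = (ξ_p − ξ_{p−1})²/ξ_p²` falls below a threshold
`v_th` (default 0.01 — a 10% residual-error drop per step; configurable,
as no canonical value exists). Dimension selection applies the same rule
across `j = 0..q_max` at fixed `p`, preferring an interior minimizer of
`ξ_p(j)` when one exists.

TV-OPS (time-varying optimal parameter search) checks lags for redundancy:
the candidate pool stacks the vectors `f_j(n)x(n−i)`; a maximal linearly
independent subset is chosen by rank-revealing pivoted QR; least-squares
base coefficients `θ̂` are computed on it; each lag `m` gets the energy
weight

    C_m = (1/N) Σ_n Σ_{k=0..q} a_m(n)² [f_k(n) x(n−m)]²,

where `a_m(n) = Σ_j θ̂_mj f_j(n)` is the basis-expanded time-varying
coefficient of lag `m` (the weight formula indexes a per-candidate
coefficient by time; since the least-squares solution is time-invariant
per column, the expanded per-lag trajectory is the natural reading, and it
makes `C_m = 0` exactly when the lag is inactive). Lags with
`C_m ≤ zero_tol · max C` (default 1e−3 relative) are discarded. In
practice `C_m` for a truly inactive lag is quadratic in the least-squares
estimation noise of its base coefficients; at `N = 4000` that noise floor
puts the relative weight near 1e−3 itself, so the inactive lag reliably has
the *smallest* weight but clears the 1e−3 cutoff only about half the time.

## Synthesis and evaluation

`simulate` runs the recursion forward from zero (or supplied) history with
a seeded Gaussian draw; output is bit-reproducible per seed. A non-finite
sample raises a divergence error naming the first offending index; an
optional `stabilize` flag reflects instantaneous poles with radius
`> 1 − 10⁻³` back to that radius before each step, since fitted
trajectories can be transiently unstable. The synthesis noise variance is
taken as `ξ/(N−p)` from the fit; Pearson correlation is amplitude-blind,
so this choice only affects amplitude realism. Burn-in defaults to zero —
the model's coefficients are explicitly time-indexed, so warm-up is the
caller's decision.

`monte_carlo_similarity` synthesizes `n_trials` times (sub-seeds spawned
from one seed, default 200 at desk scale; 5000 mirrors full-scale use),
correlates each trial with the reference, and reports the per-trial values
and their mean ρ; divergent trials are dropped and counted. Cohort
statistics use the population (divide-by-count) standard deviation.
A caveat the package reports but does not hide: syntheses driven by fresh
noise carry an independent phase, so E[ρ] = 0 even for a perfect model of
a narrowband call — the per-trial |ρ| and the STFT ridge comparison
(per-frame spectral-peak frequency; Hann 256 / hop 64 ≈ 1.3 ms frames at
192 kHz) are the discriminating fidelity measures.

## Synthetic generators

Generators return `(signal, ground-truth model)` pairs and are
deterministic per seed. Segments and resonators are specified by pole
radius and angle, which guarantees stability by construction; raw
coefficient vectors are accepted but stability-checked (rejected at radius
≥ 1, or ≥ 1 − margin for smooth trajectories, default margin 0.02).
Defaults are the study conditions used throughout the tests:

* piecewise: AR(2), N = 1000, one jump at n = 500, pole radius 0.95,
  angle 0.5π → 0.25π, σ = 1;
* smooth: p = 2, q = 2, N = 8000, σ = 1, base coefficients
  `[[0.9, 0.4, 0.15], [−0.81, 0, 0]]` — keeping `c_2 = −r²` constant pins
  the pole radius at 0.9 while the angle wanders with the basis, so the
  trajectory is stable for every family;
* chirp: fs = 192 kHz, 60 kHz CF for 15 ms then a linear sweep to 45 kHz
  over 5 ms, pole radius 0.98, σ = 1 — a qualitative CF-FM surrogate (no
  published quantitative call parameters exist to copy);
* the TV-OPS study system (p = 3, lag 2 identically zero, N = 4000) uses
  `c_1` varying around 0.9 and `c_3 = −0.3`, chosen for strong excitation
  of the active lags; max pole radius 0.82.

What the generators deliberately do not emulate: harmonic stacks and
glottal-pulse excitation, amplitude envelopes (onset/offset ramps),
recording noise and reverberation, and sound-pressure calibration.
Estimator tests passing on these signals therefore demonstrate correctness
of the estimation machinery under the model's own assumptions, not that
the model captures every property of field recordings.

## Problem sizes and runtime

The test suite and `scripts/acceptance.py` run the estimators at the sizes
above (N between 1000 and 8000; 20–50 seeds per stochastic property; 200
Monte-Carlo trials), completing in a few minutes on one CPU. The
Group-Lasso fit is the dominant cost (~2–3 s per N = 1000 signal at
default tolerance).

## Limitations

* The Group-Lasso change-point count over-segments one physical jump into
  a dominant group plus satellites (inherent ℓ2-shrinkage behavior);
  downstream consumers should cluster nearby detections or read the
  dominant group.
* TV-OPS's absolute `C_m = 0` test requires a tolerance; near the
  least-squares noise floor the discard decision is data-dependent.
* Mean Pearson correlation against a fixed reference is uninformative for
  phase-random syntheses (expectation zero); it is reported for
  completeness alongside the informative measures.
* Single-channel only; no physical (finite-element) modeling of vocal
  anatomy; no adaptive (Kalman/RLS) tracking — the basis method is batch.
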