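# Methods

## Model

The hyper-spherical diffusion model (HSDM) represents a
continuous-response decision as an n-dimensional Wiener accumulation
process `dX = μ dt + σ dW`, `X(0) = 0`, absorbed the first time
`‖X(t)‖ ≥ b(t)`.  The response is the angle of the hitting point on the
boundary sphere, the response time is the hitting time plus a
non-decision latency `t0`.  Parameters and units:

| parameter | meaning | units | support used in studies |
|---|---|---|---|
| `n` | dimension of the evidence space | – | 2–4 |
| `μ` | drift vector (stimulus quality per axis) | evidence/s | U[−6,6] per axis (constant-b study), U[−3,3] (collapse study) |
| `σ` | diffusion coefficient | evidence/√s | fixed 1 (identification convention) |
| `b` or `b0, λ` | threshold radius / initial radius and collapse slope | evidence, evidence/s | b ~ U[0.5,6]; b0 ~ U[2,5], λ ~ U[0.1,2] |
| `t0` | non-decision time | s | U[0.1,1] |

`σ` is not separately identifiable from (μ, b); all solvers assume
σ = 1 and general σ is removed exactly at the API boundary by the
rescaling X → X/σ, μ → μ/σ, b → b/σ.  The precision index
κ = b‖μ‖/σ² summarises a constant-threshold model's response
consistency.

Assumptions inherited from the model family: isotropic diffusion
(scalar σ), unbiased start at the origin, spherical (not elliptic)
boundary, drift constant within and across trials.

## First-passage density

The squared radius `Y = ‖X‖²` of the zero-drift process is a
squared-Bessel process `dY = n dt + 2√Y dW`.  Its first-passage density
through `S(t) = b(t)²` solves a second-kind Volterra equation whose
kernel Ψ combines the free squared-Bessel transition density (a
noncentral-χ²-type kernel; a Gamma(n/2, 2Δ) density from the origin)
with the boundary drift term `𝒦(t) = (n − 1 − dS/dt)/2`.  The kernel
vanishes on the boundary as the time gap closes, which removes the
singularity of the naive first-kind formulation and makes the rectangle
left-point scheme stable and first-order convergent (verified: log–log
error slope ≈ 1.0–1.3 against the analytic series).

Numerical choices:

* **Origin start.**  The first-step kernel uses the exact y→0 limit of
  the modified Bessel function (no ε-offset start).
* **Overflow control.**  `exp(−(S+y)/2Δ)·I_ν(√(Sy)/Δ)` is evaluated as
  `exp(−(√S−√y)²/2Δ)·ive(ν, z)` with the exponentially scaled Bessel
  function; the naive product overflows for small Δ.
* **Fast Bessel orders.**  The order pairs occurring for n ∈ {2,3,4}
  ((0,1), (½,3∕2), (1,2)) use `i0e`/`i1e`, spherical-Bessel closed forms
  and the three-term recurrence, each with a short power series where
  the closed form loses digits; other dimensions fall back to generic
  `ive`.  Relative accuracy ≤ 1e−13 on the dominant order.
* **Solver structure.**  For constant thresholds the kernel depends on
  (t, τ) only through the gap, so the K×K kernel table collapses to K
  lag values (Toeplitz fast path); time-dependent thresholds compute the
  strict lower triangle in one vectorized pass.  Both are O(K²) total
  and produce identical results to the scalar recursion.
* **Grid horizon.**  For fitting, `T_max = max(RT) + 5Δt` (decision
  times never exceed raw RTs).  Standalone constant-threshold runs stop
  where the series CDF reaches 0.999.  Collapsing grids are truncated at
  `min(0.98·t_singular, t_singular − 2Δt)` — the kernel is undefined at
  b = 0 — and the tiny tail mass is absorbed by the likelihood floor.
* **Grid step defaults.**  Δt = 0.02 s for fitting collapsing models,
  0.05 s acceptable for constant ones; non-decision time needs
  Δt ≤ 0.1 s (its estimate is driven by the leading edge of the
  density, which coarse grids blur — the coarse-grid study below shows
  the resulting upward bias in b and t0).
* **Off-grid times** are linearly interpolated; T ≤ 0 maps to density 0
  and times beyond the horizon to the floor.
* **Negative excursions.**  Discretization can produce tiny negative
  density values (> −1e−4 at Δt ≤ 0.02); they are not clamped in the
  grid, and the likelihood floor guards the log.

The constant-threshold Bessel series (500 terms by default) is kept as
an independent oracle.  Its short-time truncation artifacts — slowly
decaying sign-alternating terms, oscillating and negative values for
T ≲ 0.1 at b = 5 — are returned unclamped so they remain detectable;
the likelihood never evaluates through the series.

## Likelihood

The joint density of (RT, angles) multiplies the zero-drift density by
the Girsanov factor `exp(μ·X(T) − ‖μ‖²T/2)`, with `X(T)` on the sphere
of radius `b(T)` — the boundary at the stopping time, which is the only
modification required for collapsing thresholds.  The density is defined
with respect to (time × uniform surface measure); the constant
`1/A_{n−1}` makes it normalize (checked to 1e−2 by double quadrature for
n = 2) and is irrelevant to maximum likelihood.  Expressed per angle
coordinates it would gain the Jacobian `∏ sin^{n−1−k}(φ_k)`; this
package reports per-surface-measure densities throughout.  A likelihood
floor of 1e−10 before the log keeps the objective finite for
out-of-support trials (T ≤ 0, past-collapse times) and
discretization-induced negative density values.

Angle convention: φ₁…φ_{n−2} ∈ [0, π], φ_{n−1} ∈ [0, 2π); files store
radians and seconds.

## Simulator

Euler–Maruyama with step `dt_sim` (default 1 ms), crossing checked at
step ends, exiting states projected radially onto the boundary for the
reported angle, and surviving trials at a collapse singular time
absorbed there (the boundary has radius zero).  Trials still running at
`max_time` (default 30 s) are censored: excluded, counted and logged.

The discrete crossing check makes simulated passage times systematically
late by ≈ 0.583·√dt_sim in boundary units (measured: mean-FPT bias
0.020 at dt = 1 ms for b = 1, n = 2, true mean 0.5 s), shrinking as
√dt.  Tests validating solved densities against simulation therefore
use 1e−4–3e−4 s steps so the oracle's own bias sits well below the
tolerances being checked.  What the simulator does *not* emulate about
real data: across-trial parameter variability, contaminant/guess trials,
and any non-Wiener accumulation dynamics — passing recovery tests bound
estimation error under the model, not model misfit to empirical data.

## Fitting and recovery studies

Maximum likelihood uses scipy differential evolution over a bounded box
(bounds default to the generating prior supports, making recovery
comparable across sets), `popsize = 15`, latin-hypercube initialisation,
immediate updating, relative tolerance 0.01, an evaluation budget of
60,000 (generation cap derived from it), and a final L-BFGS-B polish;
the optimizer seed makes fits bit-reproducible.  One zero-drift grid is
solved per objective evaluation and shared across trials; grids are
additionally cached on the threshold parameters (drift enters only the
Girsanov factor, t0 only through T = RT − t0), which in particular
accelerates the coordinate-wise polish — results are identical with and
without the cache.

The recovery harness draws parameter sets from the uniform priors above,
simulates a fixed number of trials per set, refits each set, and scores
RMSE, Pearson ρ and R² = 1 − SSE/SST per parameter.  All randomness
derives from one master seed (per-set simulation and optimizer seeds by
fixed offsets), so reports are reproducible regardless of execution
order.  Individual fit failures are logged and excluded.

Study-scale defaults: 40 parameter sets per study (a desk-scale analogue
of full 300-set figure-level replications, which the same entry point
reproduces by raising `n_sets`).  Measured desk-scale behaviour on one
CPU: the 250-trial constant-threshold study runs in ≈ 1 min, the
500-trial collapse study in ≈ 5 min.

## Known limitations

* Constant and linear thresholds only are first-class; custom `b(t)` is
  accepted by the solver but outside the tested scope.
* No across-trial drift variability, elliptic (anisotropic) thresholds,
  biased starting points, or non-identity diffusion covariance.
* The collapse-slope λ is the hardest parameter: its recovery degrades
  with dimension and needs ≥ 500 trials for stable estimates.
* Non-decision time is the most trial-hungry parameter.  At 250 trials
  per set it recovers as well as the rest; at 50 trials, sets with slow
  dynamics (large b, small ‖μ‖) have flat leading edges and the b/t0
  tradeoff dominates, leaving t0 recovery slightly below that of every
  other parameter (the 50-trial acceptance test pins this: t0 is its
  only failing assertion).  Collect more trials, or tighten the prior
  on t0, when non-decision time is the quantity of interest.
* Time-dependent-threshold likelihoods near the singular time rely on
  the 0.98·t_singular truncation plus floor; models whose data
  concentrate in that last 2% of the collapse window are estimated less
  accurately.
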