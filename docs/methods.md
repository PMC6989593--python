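# Methods

## Model and conventions

The network is the continuum ring `τ ∂u/∂t = −u + w ∗ g(u) + I` with the
normalized circular convolution `(1/2π)∫ w(θ−φ) g(u(φ)) dφ`, kernel
`w(θ) = a + b cosθ + c cos2θ` (optionally `+ α dw/dθ`) and gain `g` either
Heaviside or logistic with slope `k` and threshold `u₀`. Discretization
samples `n` units at `θⱼ = 2πj/n` (0-based, half-open — any other phase
convention differs by a rotation the model is invariant to) and replaces the
integral by the Riemann sum `(1/n) Σₖ w(θⱼ−θₖ) g(uₖ)`, i.e. the scaled
circulant `(1/n)W`. On trigonometric polynomials this quadrature is exact.

Units: time in multiples of τ (τ = 1 throughout; eigenvalues are in 1/τ),
activity in the dimensionless units of `u`; `b` and `c` are dimensionless
synaptic weights. The step gain returns 1/2 exactly at threshold — a
measure-zero choice in the continuum but one that must be fixed for
reproducible discrete runs.

All closed-form analysis sets `a = I = 0`: a constant input is absorbed into
`a`, and `a` only translates every equilibrium vertically.

## Equilibrium catalog

With the step gain, the kernel's two harmonics close the self-consistency
equation `u = w ∗ H(u)` on degree-2 trig polynomials
`u = b₁cosθ + b₂sinθ + c₁cos2θ + c₂sin2θ`. The positive set of such a
polynomial is at most two arcs, so the right-hand side integrates in closed
form over the arcs. Two computational elements exploit this:

* **Algebraic zeros.** Substituting `z = e^{iθ}` converts the profile into a
  degree-4 polynomial whose unit-circle roots are the zeros of `u`
  (`numpy.roots`; roots closer than 1e-8 rad merged).
* **Exact self-consistency map.** `heaviside_map` integrates the kernel
  analytically over the positive arcs. An equilibrium certified by this map
  carries no quadrature error at all, in contrast to the grid residual
  (below).

Families and existence conditions (θ₀ is the free rotation phase):

| family | profile | exists iff |
| --- | --- | --- |
| flat | u = 0 | always |
| single_peak | (b/π)cos(θ−θ₀) | b > 0 |
| double_peak | (c/π)cos2(θ−θ₀) | c > 0 |
| mixed_± | B cos ± C cos2, B = (b/π)√((c+b)/2c), C = √(c²−b²)/2π | 0 < b < c ≤ 2b |
| asym_± | B cos ± (b/2π) sin2, B = (b/π)√((2c−b)/2c) | 0 < b < 2c |
| two_domain_0/π | numeric, two positive arcs | c/2 < b < 2c |

The two-domain pair is *not* transcribed from printed closed forms (those
are typographically ambiguous as printed in the literature); it is solved from its
defining root system — the arc endpoints (α, β) must be zeros of the mapped
profile, and always satisfy cosα·cosβ = −1/2 — then certified by the exact
residual (< 1e-9 demanded). Two findings from this solver are worth
recording because they correct the traditionally quoted conditions:

1. **Existence window.** Dense 40×40 multi-start scans of the root system
   find no two-arc solution anywhere with `b ≤ c/2`; solutions appear for
   `b/c` just above 1/2 and vanish above `b/c = 2`. The correct region is
   `c/2 < b < 2c` — the often-quoted "0 < b < 2c, b/c ≠ 1/2" treats the
   boundary of an empty region as an isolated exclusion.
2. **Double-peak masquerade.** The double-peaked state's zeros (odd
   multiples of π/4) also satisfy cosα·cosβ = −1/2, so the solver must
   reject roots with vanishing first harmonic or it returns the wrong
   family.

At the boundary `c = 2b` the mixed family's zero crossing becomes tangent
(`|u′| → 0`); the catalog flags this and the stability delta-sums refuse the
degenerate case rather than dividing by a vanishing slope.

### The numeric oracle

`generic_fixed_points` is a from-scratch census used to check that the
catalog is complete: rotation invariance is quotiented out (representative
with b₂ = 0), the four self-consistency conditions are solved by
Levenberg–Marquardt least squares from a deterministic two-scale
amplitude/phase start lattice (4 amplitude fractions² × 2 scales × 4 phases
= 128 starts) plus `n_starts` seeded random starts, the mirror image of each
root is registered (the even kernel makes the map reflection-equivariant),
and rotation classes are deduplicated on the invariant triple
(first amplitude, second amplitude, relative phase 2θ₂−2θ₁) at 1e-4. Both
amplitude scales matter: the asymmetric family has *both* harmonics on the
scale of `b`, so starts drawn on the scale of `c` alone miss it when
`b ≪ c`. Across 15 random (b, c) points spanning every region of the phase
plane the oracle recovers every closed-form family that exists and nothing
else.

## Residuals: grid vs exact

The grid residual `max|u − (1/n)W H(u)|` inherits an O(1/n) error from the
Riemann sum over the jump set of `H` (measured: ~6e-3 at n = 512 down to
~7e-4 at n = 4096 for the single-peaked state, prefactor depending on how
the zeros align with the lattice). It is reported alongside the `n` used and
is useful for convergence studies; *certification* uses the exact arc
integration, which is independent of `n`. Code that quotes a residual
threshold of 1e-6 or tighter always means the exact method.

## Dynamics

Explicit Euler with fixed `dt` (default 0.1, `dt < τ` enforced), seeded
initial conditions, convergence when `max|du/dt| < 1e-9`. Fixed-step Euler
keeps runs bit-reproducible; no adaptive stepping.

Two discretization artifacts of the *step* gain deserve explicit warning
because they shape what simulations can and cannot show:

* **Pinning.** The drive changes only when some cell crosses zero, so any
  perturbation smaller than roughly `|u′|·π/(2n)` at the profile's zeros
  (≈ 2e-3 at n = 1000 for the reference parameters) flips no cell and the
  state relaxes back onto a frozen-sign fixed point. Consequences: (i) the
  unstable asymmetric state *locks* under 1e-3 noise even though its
  analytic λ_max = +0.78 — demonstrating the escape requires noise above
  the threshold (0.01 is used; the trajectory then leaves at the analytic
  rate and lands on the single-peaked attractor); (ii) converged bump states
  sit within O(1/n) of the continuum family, not on it — e.g. at n = 500
  the double-peaked state's zeros fall exactly mid-cell and the locked state
  carries ~2.6e-2 of first-harmonic contamination, which is why the
  double-peak convergence check runs at n = 1000.
* **Chatter.** In the inhibitory quadrant (b, c < 0) cells hover at the
  threshold and flip every step, so the state reaches an O(dt) neighborhood
  of the flat attractor rather than a strict fixed point.

Neither artifact exists for the logistic gain, which is why the simulated
phase diagrams use it.

An exact structural fact of the discretization worth knowing: the kernel
feeds only Fourier modes 0, ±1, ±2, so every other harmonic of the state
obeys `u_m(t) = u_m(0)(1 − dt/τ)^{t/dt}` exactly — pure leak, matching the
continuum `e^{−t/τ}` to O(dt). The tests use the 5th harmonic as a probe.

## Lyapunov energy

For even kernels and invertible gains,

    E = ∫ dθ ∫₀^{g(u)} (g⁻¹(V) − I) dV − (1/4π) ∬ w(θ−φ) g(u(φ)) g(u(θ)) dφ dθ

is non-increasing along trajectories and stationary exactly at equilibria.
For the logistic gain the inner integral is the closed form
`u₀x + (1/k)(x ln x + (1−x)ln(1−x))` at `x = g(u)` — a scaled binary
entropy — so no numerical inversion is performed. Both terms are discretized
with the same uniform-grid sums as the dynamics; measured worst per-step
increase along Euler trajectories at k = 2, dt = 0.1 is ~1e-15, far inside
the 1e-9 tolerance asserted. The step gain has no finite energy
(g⁻¹ undefined); callers wanting a near-Heaviside energy use a steep
logistic (k ≥ 1e3).

The certified asymptotic bound `|u| ≤ max|w|·max|g| + |I|` is evaluated on a
2e4-point grid and verified dynamically for random kernels in [−5, 5]².

## Linear stability: three routes and a correction

Linearization gives `τ ε̇ = (−I + (1/n) W G) ε`. In Fourier space the mode
equation is `τ ε̇_m = −ε_m + w_m Σ_p Ĝ_{m−p} ε_p`, with `w_{±1} = b/2`,
`w_{±2} = c/2`, zero otherwise, and `Ĝ_m = (1/2π)∫ g′(u(θ)) e^{imθ} dθ`.
For the step gain `g′` is a Dirac comb on the zeros of `u`, so
`Ĝ_m = (1/2π) Σᵢ e^{imθᵢ}/|u′(θᵢ)|` (zeros located by an 8192-point sign
scan plus bisection to 1e-12 — deliberately independent of the algebraic
root path, so the two cross-validate). For the logistic gain `Ĝ_m` is a
periodic trapezoid sum; the steep-gain limit k = 1e4 needs ~1.3e5 quadrature
points to resolve the near-delta peaks and then matches the delta sums to
1e-7. All moments are taken in the canonical frame (first-harmonic phase
rotated to zero) because they are phase-dependent.

Three spectral routes:

* **Two-mode quadratic** (`jacobian_spectrum`): roots of
  `(λ+1)² − (b g22/2 + c g33/2)(λ+1) + (bc/4)(g22 g33 − g23²)` with
  `(g22, g33, g23) = (Ĝ₂, Ĝ₄, Ĝ₃)`, plus an (n−2)-fold bulk −1. This is
  the classical closed-form catalog for this model: single peak
  {−3/2, −1 + c/2b}, double peak {−1, −3/2}, and for the mixed family the
  rational function of `k = c/b` that the package cross-checks at sampled
  ratios. The package reproduces all of these printed values exactly.
* **Four-mode reduction** (`four_mode_spectrum`): eigenvalues of the exact
  4×4 coupled block `M[m,p] = w_m Ĝ_{m−p}` on modes (+1, −1, +2, −2),
  plus the bulk. Because rows with `w_m = 0` decouple, this is the *entire*
  non-bulk spectrum of the linearization — no approximation.
* **Numeric Jacobian** (`numeric_jacobian_spectrum`): brute
  eigendecomposition of `−I + (1/n) W diag(g′(u))` for finite-slope gains.

The two-mode quadratic omits the diagonal (Ĝ₀) and odd (Ĝ₁, Ĝ₃-as-coupling)
terms of the exact block, and the difference is not cosmetic. Verified
against steep-logistic numeric Jacobians (n up to 1600, k up to 400) and
against direct simulation:

* the true single-peak spectrum is {0, −1 + c/b} (plus bulk) — the zero is
  the rotational neutral mode every continuous-attractor bump must have,
  absent from the two-mode result — so the single bump destabilizes by
  splitting at `c > b`, not `c > 2b`; at (b, c) = (1, 1.5) simulations
  confirm the bump abandons the single-peak state and lands on the mixed
  state;
* the true double-peak spectrum is {0, −1 + b/2c (twice)}: stable only for
  `b < 2c`, not unconditionally;
* at the asymmetric state the exact four-mode λ_max is +0.78 (unstable, as
  simulation shows), while the two-mode formula evaluates to −1 with exact
  delta-sum inputs — it cannot even reproduce the instability it is
  traditionally cited for.

The package therefore keeps both: the two-mode route as the quoted-catalog
reference, and the four-mode route for every real stability verdict
(phase diagrams, dynamics consistency, the escape experiment). `stable` on
four-mode spectra means "no eigenvalue above 1e-7", i.e. stability modulo
the neutral rotation.

The flat state is handled separately: logistic gives modes
`−1 + (k/4)(b/2)` and `−1 + (k/4)(c/2)` (each doubly degenerate), hence
stability iff `b < 8/k` and `c < 8/k`, with the boundary crossing exact in
floating point at `b = 8/k`; the step gain has infinite slope at threshold,
so the verdict is categorical (stable iff b < 0 and c < 0) with ±inf
sentinel roots.

## Phase diagrams

*Analytic* (step gain): existence flags from the table above; stability from
the four-mode route per family; two-domain solver failures are annotated,
never silently dropped.

*Numerical* (logistic): per (b, c) cell the network (default n = 50 cells,
dt = 0.02, up to 4e4 steps, convergence 1e-5) is integrated from cos θ,
cos 2θ and `n_random` seeded uniform(−0.5, 0.5) starts; finals are
classified by harmonic amplitudes A_m = 2|u_m| (flat below
1e-3 × the asymptotic bound; otherwise the larger of A₁/A₂ wins; the label
is "bistable" when both peaked outcomes occur). Two protocol details:

* the deterministic starts get seeded gaussian jitter (σ = 0.01): an exact
  cos 2θ start lies on the symmetry-invariant manifold of the double-peaked
  state and would report an unstable saddle as an attractor;
* unconverged cells are labeled "other" unless every run is already flat.

At k = 64 the simulated one-peak/two-peak/bistable regions agree with the
step-gain attractor catalog on 77/80 non-boundary cells of a 10×10 grid over
[0.5, 5]²; the three disagreements sit just past the `b = 2c` line where the
finite-k correction to the double-peak stability boundary is still visible.
The flat region equals the `{b < 8/k, c < 8/k}` square to within one grid
cell for k ∈ {2, 4, 8}.

## Shifting

Adding `α dw/dθ` to the kernel makes a stable equilibrium `U` travel
rigidly: substituting `u(θ,t) = U(θ − vt)` into the dynamics gives
`−τv U′ = α U′`, so `v = −α/τ` exactly — the bump moves toward decreasing θ
for positive α under this sign convention. The experiment tracks the
complex argument of the dominant harmonic (sub-grid resolution), unwraps it,
and fits the velocity on the final 80% of the run; measured −0.19992 at
α = 0.2 with profile amplitudes holding within a few percent, and linear in
α within a few percent over α ∈ {0.05, 0.1, 0.2}. Shift runs on unstable
equilibria are annotated with a warning rather than refused.

## Problem sizes and tolerances used by the test suite

Certification grid n = 2048 (exact residuals are n-independent); dynamics
checks n = 500 (n = 1000 where mid-cell zeros would contaminate, see
pinning); escape experiment n = 1000, dt = 0.1, ≤ 1e5 steps, noise 0.01;
Lyapunov descent 20 seeds × 1000 steps at n = 100; simulated phase scans
20×20 (k = 2 flat-boundary), ~8×8 (k = 4, 8) and 10×10 (k = 64); oracle runs
200 random starts at the reference points and 60 per point across 30 random
points. These sizes were chosen so the full suite completes in a few minutes
while every tolerance asserted retains at least an order-of-magnitude margin
over the measured numerical error, except where a tolerance is exact by
construction (closed forms, equivariances).

## Known limitations

* The closed-form catalog and stability analysis cover the two-harmonic
  kernel only; the convolution and Fourier utilities accept general
  profiles, but kernels with higher harmonics get no catalog.
* Spectra for shifted kernels (α ≠ 0) are not computed analytically — the
  circulant loses symmetry and its spectrum becomes complex; the shift case
  is exercised dynamically instead.
* The step-gain discretization artifacts above mean step-gain simulations
  near marginal states must be interpreted with the pinning threshold in
  mind; the logistic gain is the reliable route there.
* Time-varying kernels and spatially structured inputs are out of scope.
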