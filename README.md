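# hdring

Equilibria, linear stability and phase diagrams of the **head-direction ring
attractor network** — the classic continuum model in which a population of
neurons arranged on a circle of preferred directions sustains localized
activity bumps that encode the animal's heading.

## The model

The membrane state `u(θ, t)` of the unit preferring direction `θ ∈ [0, 2π)`
evolves as

    τ ∂u/∂t = −u + (w ∗ g(u))(θ) + I,
    (w ∗ r)(θ) = (1/2π) ∫₀^{2π} w(θ − φ) r(φ) dφ,

with a two-harmonic recurrent kernel `w(θ) = a + b cos θ + c cos 2θ` and a
monotone gain `g` — either the Heaviside step `H(u)` or the logistic
`1/(1 + e^{−k(u−u₀)})`. `b` controls cooperative drive between neighboring
directions, `c` between directions 180° apart; `c > 0` is what makes
*double-bump* activity patterns possible, a configuration of interest because
a two-bump ring rotating at half speed is electrophysiologically
indistinguishable from the classic single bump at the single-cell level.

For the step gain, zero mean drive (`a = I = 0`) every equilibrium is a
degree-2 trigonometric polynomial, and the package constructs the complete
catalog in closed form: the flat state, single-peaked `(b/π)cos(θ−θ₀)`
(exists iff `b > 0`), double-peaked `(c/π)cos 2(θ−θ₀)` (iff `c > 0`), a mixed
pair (iff `0 < b < c ≤ 2b`), an asymmetric mirror pair (iff `0 < b < 2c`) and
a two-positive-arc pair solved from its root system (iff `c/2 < b < 2c`).
Every solution is certified by the self-consistency residual
`max|u − w ∗ H(u)|`, computed either on the discretization grid or exactly by
analytic integration over the arcs where `u > 0`.

Stability comes from linearizing around an equilibrium:
`τ ∂ε/∂t = (−I + (1/n) W G) ε`, with `W` the circulant weight matrix
(eigenvalues `b/2`, `c/2` on Fourier modes ±1, ±2, zero elsewhere) and `G`
the diagonal of gain slopes. Three routes are implemented and cross-checked:
the classical two-mode characteristic quadratic built from the delta-sum
coefficients `(g22, g33, g23)`; the exact four-mode reduction using the full
harmonic moments `G₀..G₄` of `g′(u)` (this is the route that reproduces the
finite-n Jacobian, including the rotational zero mode every bump state must
have — see `docs/methods.md` for why the two routes disagree); and the brute
numeric eigendecomposition. A Lyapunov energy functional, a certified
asymptotic bound on `|u|`, phase-diagram scans over the `(b, c)` plane, and
the derivative-kernel shifting mechanism (`w + α dw/dθ` makes a bump travel
at angular velocity `−α/τ`) round out the toolkit.

## Worked example

The full equilibrium census at the reference parameters `b = 3, c = 2`
(single- and double-bump attractors coexist):

```
$ hdring equilibria --b 3 --c 2 --out out/eq
  flat           residual_exact=0
  single_peak    residual_exact=2.73e-16
  double_peak    residual_exact=2.72e-16
  two_domain_0   residual_exact=1.67e-15
  two_domain_pi  residual_exact=1.47e-15
  asym_plus      residual_exact=5.48e-16
  asym_minus     residual_exact=5.3e-17
```

Seven rotation classes, each an exact fixed point of the Heaviside
self-consistency map (residuals at machine precision). Stability of the
single bump:

```
$ hdring stability --b 3 --c 2 --family single_peak --out out/st
  single_peak    two-mode special=[-1.5 -0.j -0.6667+0.j] four-mode lam_max=0.0000 stable=True
```

The two-mode quadratic returns the textbook eigenvalue pair
`{−3/2, −1 + c/2b} = {−1.5, −0.667}`; the exact four-mode spectrum has
largest eigenvalue 0 — the neutral rotation mode of a continuous attractor —
with all genuine modes negative, so the bump is stable (it would lose
stability to bump-splitting only for `c > b`). Making the bump move:

```
$ hdring shift --b 3 --c 2 --family single_peak --shift-alpha 0.2 --T 30 --n 500 --dt 0.01 --out out/sh
  fitted velocity = -0.199920 rad/tau (alpha=0.2)
```

With the derivative term `α dw/dθ` at `α = 0.2` the bump translates rigidly
at `−α/τ` to three decimal places.

## Layout

| module | contents |
| --- | --- |
| `hdring.ring_model` | kernel/gain/grid types, circular convolution, Fourier utilities |
| `hdring.dynamics`   | explicit-Euler integration, Lyapunov energy, boundedness |
| `hdring.equilibria` | closed-form catalog, two-domain root solver, multi-start oracle |
| `hdring.stability`  | delta-sum g-coefficients, two-mode / four-mode / numeric spectra |
| `hdring.phase_scan` | analytic and simulated (b, c) phase diagrams, bump shifting |
| `hdring.cli_io`     | `hdring` command-line interface, configs, initial states |

`docs/methods.md` documents the numerical choices, the discretization
artifacts of the step gain (jump quadrature, pinning), and two places where
the package's exact computations correct the traditionally quoted formulas.
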