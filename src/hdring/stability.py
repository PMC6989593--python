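"""Linear stability of ring-network equilibria.

Perturbing an equilibrium ``u`` and linearizing gives
``tau de/dt = (-I + (1/n) W G) e`` with ``G = diag(g'(u(theta_j)))``.
Because the two-harmonic kernel's circulant has eigenvalues b/2 (modes +/-1),
c/2 (modes +/-2) and 0 otherwise, the spectrum is -1 (in units of 1/tau)
for every mode the kernel does not feed, plus the eigenvalues of a small
coupled block on the fed modes.  The couplings are the harmonic moments of
the gain derivative along the equilibrium,

    G_m = (1/2pi) int g'(u(theta)) exp(i m theta) dtheta,

evaluated as Dirac delta sums over the zeros of ``u`` for the step gain and
by quadrature for the logistic gain.

Two analytic reductions are provided:

* :func:`jacobian_spectrum` — the classical two-mode quadratic
  ``(L+1)^2 - (b g22/2 + c g33/2)(L+1) + (bc/4)(g22 g33 - g23^2)`` built
  from (g22, g33, g23) = (G_2, G_4, G_3).  This is the closed-form catalog
  traditionally quoted for this model (single peak {-3/2, -1 + c/2b}, double
  peak {-1, -3/2}, and the rational mixed-family forms), and the package
  reproduces those printed values exactly.  Note, however, that it omits
  the diagonal (G_0) and odd (G_1) couplings of g'.
* :func:`four_mode_spectrum` — the exact reduction on modes (+1, -1, +2, -2)
  with the full G_0..G_4 coupling matrix.  This is the spectrum that agrees
  with the finite-n Jacobian (:func:`numeric_jacobian_spectrum`) and with
  the observed dynamics: it exhibits the rotational zero mode every
  non-flat equilibrium must have, gives the single-peak mode -1 + c/b, the
  doubly degenerate double-peak mode -1 + b/2c, and a positive lambda_max
  for the asymmetric states.  Use it whenever a true stability verdict is
  needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .equilibria import EquilibriumSolution, rotate, trig_deriv, trig_eval
from .ring_model import (
    GainFunction,
    WeightProfile,
    evaluate_gain,
    evaluate_weight,
    gain_derivative,
)

__all__ = [
    "GCoeffs",
    "Spectrum",
    "ModeSpectrum",
    "weight_mode_eigenvalues",
    "canonicalize",
    "gain_mode_coefficients",
    "g_coefficients",
    "jacobian_spectrum",
    "four_mode_spectrum",
    "flat_stability",
    "numeric_jacobian_spectrum",
    "spectrum_to_json",
]

#: eigenvalues are reported in units of 1/tau (tau = 1 normalization)
NEUTRAL_TOL = 1e-7


@dataclass(frozen=True)
class GCoeffs:
    """Harmonic couplings (g22, g33, g23) = (G_2, G_4, G_3) of g'(u)."""

    g22: complex
    g33: complex
    g23: complex

    @property
    def g32(self) -> complex:
        return self.g23


@dataclass
class Spectrum:
    """Spectrum in the two-mode reduction: bulk -1 plus two special roots."""

    bulk: float
    special: tuple[complex, complex]
    lambda_max: float
    stable: bool
    family: str = ""
    b: float = 0.0
    c: float = 0.0


@dataclass
class ModeSpectrum:
    """Exact four-mode spectrum: bulk -1 plus eigenvalues of the coupled block.

    ``lambda_max`` includes the rotational neutral mode (so it is >= 0 for
    every non-flat equilibrium up to round-off); ``stable`` means no
    eigenvalue exceeds the neutral tolerance, i.e. stability modulo rotation.
    """

    bulk: float
    eigenvalues: np.ndarray
    lambda_max: float
    stable: bool
    family: str = ""
    b: float = 0.0
    c: float = 0.0


# ---------------------------------------------------------------------------
# circulant weight eigenvalues

def weight_mode_eigenvalues(w: WeightProfile, modes) -> np.ndarray:
    """Continuum eigenvalues ``lambda_j = (1/2pi) int w(phi) cos(j phi) dphi``.

    For the two-harmonic kernel: a at j=0, b/2 at j=1, c/2 at j=2, zero
    above.  Agrees with the direct eigen-decomposition of the n x n scaled
    circulant (1/n) W to 1e-10 at n = 500 (the uniform grid integrates
    trigonometric polynomials exactly).
    """
    if w.alpha != 0.0:
        raise ValueError(
            "mode eigenvalues assume an even kernel; the shifted kernel has "
            "a complex circulant spectrum which is not implemented"
        )
    modes = np.atleast_1d(np.asarray(modes, dtype=int))
    vals = np.zeros(len(modes))
    vals[modes == 0] = w.a
    vals[np.abs(modes) == 1] = w.b / 2.0
    vals[np.abs(modes) == 2] = w.c / 2.0
    return vals


# ---------------------------------------------------------------------------
# gain-derivative harmonics

def canonicalize(sol: EquilibriumSolution) -> EquilibriumSolution:
    """Rotate so the first harmonic peaks at theta = 0 (b2 = 0, b1 >= 0).

    The harmonic moments of g' are phase dependent; the closed-form values
    quoted for each family assume this frame.  If the first harmonic
    vanishes (double peak) the second harmonic is aligned instead.
    """
    a0, b1, b2, c1, c2 = sol.coeffs
    # beta = B exp(-i theta0), so rotating by angle(beta) = -theta0 brings
    # the peak to zero (rotate(s) maps the profile to u(theta - s))
    if np.hypot(b1, b2) > 1e-10:
        shift = np.angle(b1 - 1j * b2)
    elif np.hypot(c1, c2) > 1e-10:
        shift = np.angle(c1 - 1j * c2) / 2.0
    else:
        return sol
    return rotate(sol, shift) if shift != 0.0 else sol


def _step_zeros_bisect(coeffs, n_scan: int = 8192, tol: float = 1e-12) -> np.ndarray:
    """Zeros of the equilibrium profile by sign-change scan plus bisection.

    Deliberately independent of the algebraic root path used by the
    equilibrium solver, so the two can cross-validate each other.
    """
    th = np.linspace(0.0, 2.0 * np.pi, n_scan, endpoint=False)
    u = trig_eval(coeffs, th)
    zeros = []
    for i in range(n_scan):
        j = (i + 1) % n_scan
        a, bb = th[i], th[i] + 2.0 * np.pi / n_scan
        ua, ub = u[i], u[j]
        if ua == 0.0:
            zeros.append(a)
            continue
        if ua * ub < 0.0:
            lo, hi = a, bb
            flo = ua
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                fm = trig_eval(coeffs, mid)
                if fm == 0.0:
                    lo = hi = mid
                    break
                if flo * fm < 0.0:
                    hi = mid
                else:
                    lo, flo = mid, fm
            zeros.append(0.5 * (lo + hi))
    merged: list[float] = []
    for z in sorted(zeros):
        if not merged or z - merged[-1] > 1e-6:
            merged.append(z)
    if len(merged) > 1 and 2.0 * np.pi - merged[-1] + merged[0] <= 1e-6:
        merged.pop()
    return np.asarray(merged)


def gain_mode_coefficients(
    sol: EquilibriumSolution,
    gain: GainFunction,
    mmax: int = 4,
    n_quad: int = 8192,
    canonical: bool = True,
) -> np.ndarray:
    """Harmonic moments G_0..G_mmax of g'(u(theta)) along the equilibrium.

    Step gain: g' is a Dirac comb on the zero set of u, so
    ``G_m = (1/2pi) sum_i exp(i m theta_i) / |u'(theta_i)|``.  Logistic
    gain: periodic trapezoid quadrature on ``n_quad`` points (spectrally
    accurate for smooth profiles).
    """
    if canonical:
        sol = canonicalize(sol)
    if gain.kind == "step":
        if max(abs(x) for x in sol.coeffs) < 1e-12:
            raise ValueError(
                "flat equilibrium: g' has no zero set; use flat_stability"
            )
        z = _step_zeros_bisect(sol.coeffs)
        if len(z) == 0:
            raise ValueError("profile has no zero crossings; use flat_stability")
        du = trig_deriv(sol.coeffs, z)
        if np.min(np.abs(du)) <= 1e-8:
            raise ValueError(
                "degenerate equilibrium: |u'| <= 1e-8 at a zero crossing, "
                "the delta sum is singular"
            )
        m = np.arange(mmax + 1)
        return (np.exp(1j * np.outer(m, z)) / np.abs(du)).sum(axis=1) / (2.0 * np.pi)
    # logistic: plain Riemann sum on the periodic grid == trapezoid rule
    if n_quad < 4096:
        raise ValueError("use n_quad >= 4096 for logistic quadrature")
    th = 2.0 * np.pi * np.arange(n_quad) / n_quad
    gp = gain_derivative(gain, trig_eval(sol.coeffs, th))
    m = np.arange(mmax + 1)
    return (np.exp(1j * np.outer(m, th)) * gp).sum(axis=1) / n_quad


def g_coefficients(
    sol: EquilibriumSolution, gain: GainFunction, n_quad: int = 8192
) -> GCoeffs:
    """Couplings (g22, g33, g23) = (G_2, G_4, G_3) in the canonical frame."""
    G = gain_mode_coefficients(sol, gain, mmax=4, n_quad=n_quad)
    return GCoeffs(g22=complex(G[2]), g33=complex(G[4]), g23=complex(G[3]))


# ---------------------------------------------------------------------------
# spectra

def jacobian_spectrum(b: float, c: float, g: GCoeffs, n: int = 500) -> Spectrum:
    """Two-mode characteristic quadratic built from (g22, g33, g23).

    Roots of ``(L+1)^2 - (b g22/2 + c g33/2)(L+1) + (bc/4)(g22 g33 - g23^2)``
    plus the (n-2)-fold bulk eigenvalue -1.  Solved in complex arithmetic;
    stability is decided on real parts.  This reduction reproduces the
    classical printed eigenvalue catalog; see the module docstring for its
    known blind spots and :func:`four_mode_spectrum` for the exact reduction.
    """
    if n < 4:
        raise ValueError("n >= 4 required")
    S = b * g.g22 / 2.0 + c * g.g33 / 2.0
    P = (b * c / 4.0) * (g.g22 * g.g33 - g.g23 * g.g32)
    mu = np.roots([1.0, -S, P])
    special = (complex(mu[0] - 1.0), complex(mu[1] - 1.0))
    lam = max(-1.0, special[0].real, special[1].real)
    return Spectrum(
        bulk=-1.0, special=special, lambda_max=lam, stable=bool(lam < 0.0),
        b=b, c=c,
    )


def four_mode_spectrum(
    sol: EquilibriumSolution, gain: GainFunction, n_quad: int = 8192
) -> ModeSpectrum:
    """Exact spectrum of the linearization restricted to modes (+-1, +-2).

    The coupled block is ``M[m, p] = w_m G_{m-p}`` for m, p in
    (1, -1, 2, -2) with w_{+-1} = b/2 and w_{+-2} = c/2; the remaining
    n - 4 modes contribute the bulk eigenvalue -1.  Every non-flat
    equilibrium has a rotational neutral eigenvalue ~0 in this block.
    """
    G = gain_mode_coefficients(sol, gain, mmax=4, n_quad=n_quad)
    Gm = {m: G[m] for m in range(5)}
    for m in range(1, 5):
        Gm[-m] = np.conj(G[m])
    modes = (1, -1, 2, -2)
    wm = {1: sol.b / 2.0, -1: sol.b / 2.0, 2: sol.c / 2.0, -2: sol.c / 2.0}
    M = np.array([[wm[m] * Gm[m - p] for p in modes] for m in modes])
    lam = np.linalg.eigvals(M) - 1.0
    lam_max = float(np.max(lam.real))
    return ModeSpectrum(
        bulk=-1.0,
        eigenvalues=lam,
        lambda_max=lam_max,
        stable=bool(lam_max < NEUTRAL_TOL),
        family=sol.family,
        b=sol.b,
        c=sol.c,
    )


def flat_stability(b: float, c: float, gain: GainFunction) -> Spectrum:
    """Stability of the uniform state u = 0.

    Logistic (threshold 0): the perturbation modes +-1 and +-2 have
    eigenvalues -1 + g'(0) b/2 and -1 + g'(0) c/2 with g'(0) = k/4, so the
    flat state is stable iff b < 8/k and c < 8/k.  Step gain: g'(0) is a
    delta spike (infinite slope), so any excitatory harmonic destabilizes
    the flat state — stable iff b < 0 and c < 0, encoded with -inf/+inf
    sentinel roots.
    """
    if gain.kind == "logistic":
        if gain.u0 != 0.0:
            raise ValueError("flat-state analysis assumes threshold u0 = 0")
        gp0 = gain.k / 4.0
        special = (-1.0 + gp0 * b / 2.0, -1.0 + gp0 * c / 2.0)
        lam = max(-1.0, *special)
        return Spectrum(
            bulk=-1.0,
            special=(complex(special[0]), complex(special[1])),
            lambda_max=lam,
            stable=bool(lam < 0.0),
            family="flat",
            b=b,
            c=c,
        )
    # step gain: categorical verdict from the sign conditions
    s_b = -math.inf if b < 0 else math.inf if b > 0 else 0.0
    s_c = -math.inf if c < 0 else math.inf if c > 0 else 0.0
    stable = b < 0 and c < 0
    return Spectrum(
        bulk=-1.0,
        special=(complex(s_b), complex(s_c)),
        lambda_max=-1.0 if stable else math.inf,
        stable=stable,
        family="flat",
        b=b,
        c=c,
    )


def numeric_jacobian_spectrum(
    sol: EquilibriumSolution, gain: GainFunction, n: int = 256
) -> np.ndarray:
    """All eigenvalues of the finite-n Jacobian ``-I + (1/n) W diag(g'(u))``.

    Finite-slope (logistic) gains only; the independent oracle for the
    analytic reductions in the steep-gain limit.
    """
    if gain.kind != "logistic":
        raise ValueError("numeric Jacobian needs a finite-slope gain")
    if n < 64:
        raise ValueError("n >= 64 required")
    th = 2.0 * np.pi * np.arange(n) / n
    w = WeightProfile(0.0, sol.b, sol.c)
    W = evaluate_weight(w, th[:, None] - th[None, :])
    gp = gain_derivative(gain, sol.u_values(th))
    J = -np.eye(n) + (W / n) * gp[None, :]
    return np.linalg.eigvals(J)


def spectrum_to_json(sp: Spectrum | ModeSpectrum) -> dict:
    if isinstance(sp, Spectrum):
        re = [s.real for s in sp.special]
        im = [s.imag for s in sp.special]
    else:
        re = list(sp.eigenvalues.real)
        im = list(sp.eigenvalues.imag)
    return {
        "family": sp.family,
        "b": sp.b,
        "c": sp.c,
        "bulk": sp.bulk,
        "special_re": re,
        "special_im": im,
        "lambda_max": sp.lambda_max,
        "stable": sp.stable,
    }
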