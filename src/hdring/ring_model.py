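"""Core types and spectral utilities for the ring attractor network.

The network is a continuum of rate units on the circle with membrane state
``u(theta, t)`` evolving under leak plus recurrent drive,

    tau du/dt = -u + (w * g(u))(theta) + I,

where ``*`` is the normalized circular convolution ``(1/2pi) int w(theta-phi)
g(u(phi)) dphi``.  The synaptic kernel used throughout the closed-form
analysis is the two-harmonic profile ``w(theta) = a + b cos(theta) +
c cos(2 theta)``, optionally augmented by ``alpha * dw/dtheta`` to make
attractor bumps travel (the derivative shift rule).  The gain ``g`` is either
the Heaviside step or a logistic sigmoid with slope ``k`` and threshold
``u0``; both map into [0, 1].

Discretization samples ``n`` units at ``theta_j = 2 pi j / n`` and replaces
the convolution integral by the Riemann sum ``(1/n) sum_k w(theta_j -
theta_k) g(u_k)``, i.e. multiplication by the scaled circulant weight matrix
``(1/n) W``.  For trigonometric polynomials this quadrature is exact, which
is why the spectral (FFT) and direct circulant paths agree to machine
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WeightProfile",
    "GainFunction",
    "RingGrid",
    "StateProfile",
    "ExternalInput",
    "evaluate_weight",
    "evaluate_gain",
    "gain_derivative",
    "ring_convolution",
    "harmonics",
    "reconstruct",
    "save_state",
    "load_state",
    "model_to_json",
    "model_from_json",
]


@dataclass(frozen=True)
class WeightProfile:
    """Two-harmonic synaptic kernel ``a + b cos(theta) + c cos(2 theta)``.

    ``alpha`` adds ``alpha * dw/dtheta`` (an odd component) which breaks the
    evenness of the kernel and makes stable bumps translate at angular
    velocity ``-alpha/tau``.  With ``alpha = 0`` the kernel is even and the
    network admits a Lyapunov function.
    """

    a: float
    b: float
    c: float
    alpha: float = 0.0

    def __call__(self, theta):
        return evaluate_weight(self, theta)

    @property
    def is_even(self) -> bool:
        return self.alpha == 0.0


@dataclass(frozen=True)
class GainFunction:
    """Monotone gain ``g(u)`` mapping membrane state to rate in [0, 1].

    ``kind="step"`` is the Heaviside function with the symmetric convention
    ``g(u0) = 1/2`` at threshold; ``kind="logistic"`` is
    ``1 / (1 + exp(-k (u - u0)))``.  The step gain is the ``k -> inf`` limit
    of the logistic.
    """

    kind: str
    k: float | None = None
    u0: float = 0.0

    def __post_init__(self):
        if self.kind not in ("step", "logistic"):
            raise ValueError(f"unknown gain kind {self.kind!r}")
        if self.kind == "logistic":
            if self.k is None or self.k <= 0:
                raise ValueError("logistic gain requires slope k > 0")

    def __call__(self, u):
        return evaluate_gain(self, u)

    def derivative(self, u):
        return gain_derivative(self, u)


@dataclass(frozen=True)
class RingGrid:
    """Uniform periodic grid of ``n`` units, ``theta_j = 2 pi j / n``."""

    n: int

    def __post_init__(self):
        if self.n < 8:
            raise ValueError("ring grid needs at least 8 cells")

    @property
    def theta(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n) / self.n

    @property
    def spacing(self) -> float:
        return 2.0 * np.pi / self.n


@dataclass
class StateProfile:
    """Sampled activity ``u(theta_j)`` at time ``t`` (units of tau)."""

    grid: RingGrid
    u: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (self.grid.n,):
            raise ValueError("state length must match grid size")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("state contains non-finite values")


@dataclass(frozen=True)
class ExternalInput:
    """Constant external drive I, uniform in direction and time."""

    value: float = 0.0


def evaluate_weight(profile: WeightProfile, theta) -> np.ndarray:
    """Evaluate the kernel, including the ``alpha`` shift term, at ``theta``."""
    th = np.asarray(theta, dtype=float)
    w = profile.a + profile.b * np.cos(th) + profile.c * np.cos(2.0 * th)
    if profile.alpha != 0.0:
        w = w + profile.alpha * (
            -profile.b * np.sin(th) - 2.0 * profile.c * np.sin(2.0 * th)
        )
    return w


def evaluate_gain(gain: GainFunction, u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if gain.kind == "step":
        return np.where(u > gain.u0, 1.0, np.where(u < gain.u0, 0.0, 0.5))
    # logistic; clip the exponent so saturated tails do not overflow
    z = np.clip(gain.k * (u - gain.u0), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(-z))


def gain_derivative(gain: GainFunction, u) -> np.ndarray:
    """Slope ``g'(u) = k g (1 - g)`` of the logistic gain.

    The step gain's derivative is a Dirac comb on the zero set of ``u`` and
    has no pointwise value; its harmonic moments are handled analytically by
    :func:`hdring.stability.g_coefficients`.
    """
    if gain.kind == "step":
        raise ValueError(
            "step gain has a delta-function derivative; use the analytic "
            "delta-sum path in hdring.stability"
        )
    g = evaluate_gain(gain, u)
    return gain.k * g * (1.0 - g)


def ring_convolution(
    profile: WeightProfile, rates, grid: RingGrid, method: str = "fft"
) -> np.ndarray:
    """Normalized circular convolution ``(1/n) sum_k w(theta_j - theta_k) r_k``.

    This is the Riemann sum of ``(1/2pi) int w(theta - phi) r(phi) dphi`` on
    the uniform grid and equals multiplication by the scaled circulant matrix
    ``(1/n) W``.  ``method="fft"`` multiplies in the Fourier domain;
    ``method="direct"`` builds the circulant row and multiplies explicitly
    (reference path, identical to 1e-12).
    """
    r = np.asarray(rates, dtype=float)
    if r.shape != (grid.n,):
        raise ValueError("rates length must match grid size")
    wv = evaluate_weight(profile, grid.theta)
    if method == "fft":
        return np.real(np.fft.ifft(np.fft.fft(wv) * np.fft.fft(r))) / grid.n
    if method == "direct":
        th = grid.theta
        W = evaluate_weight(profile, th[:, None] - th[None, :])
        return W @ r / grid.n
    raise ValueError(f"unknown convolution method {method!r}")


def harmonics(state: StateProfile, order: int) -> np.ndarray:
    """Complex Fourier coefficients ``u_m`` for ``|m| <= order``.

    Normalization follows the series ``u(theta) = sum_m u_m exp(i m theta)``,
    i.e. ``u_m = DFT(u)_m / n`` (the internal DFT is numpy's unnormalized
    forward transform).  Index ``order + m`` of the returned array holds
    ``u_m``, so a trig polynomial of degree <= order is reconstructed exactly
    by :func:`reconstruct`.
    """
    n = state.grid.n
    if order >= n / 2:
        raise ValueError("order must be < n/2 to avoid aliasing")
    F = np.fft.fft(state.u) / n
    m = np.arange(-order, order + 1)
    return F[np.mod(m, n)]


def reconstruct(coeffs: np.ndarray, theta) -> np.ndarray:
    """Evaluate ``sum_m u_m exp(i m theta)`` for coefficients from harmonics()."""
    coeffs = np.asarray(coeffs)
    order = (len(coeffs) - 1) // 2
    th = np.asarray(theta, dtype=float)
    m = np.arange(-order, order + 1)
    return np.real(np.exp(1j * np.outer(th, m)) @ coeffs)


# ---------------------------------------------------------------------------
# serialization

def save_state(state: StateProfile, path) -> None:
    """Write a state profile as CSV with columns (index, theta_rad, u)."""
    df = pd.DataFrame(
        {
            "index": np.arange(state.grid.n),
            "theta_rad": state.grid.theta,
            "u": state.u,
        }
    )
    df.to_csv(path, index=False, float_format="%.15g")


def load_state(path, t: float = 0.0) -> StateProfile:
    df = pd.read_csv(path)
    return StateProfile(grid=RingGrid(len(df)), u=df["u"].to_numpy(), t=t)


def model_to_json(profile: WeightProfile, gain: GainFunction) -> str:
    return json.dumps(
        {
            "a": profile.a,
            "b": profile.b,
            "c": profile.c,
            "alpha": profile.alpha,
            "gain_kind": gain.kind,
            "k": gain.k,
            "u0": gain.u0,
        }
    )


def model_from_json(s: str) -> tuple[WeightProfile, GainFunction]:
    d = json.loads(s)
    known = {"a", "b", "c", "alpha", "gain_kind", "k", "u0"}
    extra = set(d) - known
    if extra:
        raise ValueError(f"unknown model keys: {sorted(extra)}")
    profile = WeightProfile(
        a=float(d["a"]), b=float(d["b"]), c=float(d["c"]),
        alpha=float(d.get("alpha", 0.0)),
    )
    gain = GainFunction(
        kind=d["gain_kind"],
        k=None if d.get("k") is None else float(d["k"]),
        u0=float(d.get("u0", 0.0)),
    )
    return profile, gain
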