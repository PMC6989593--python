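import numpy as np
import pytest

from hdring import (
    GainFunction,
    RingGrid,
    StateProfile,
    WeightProfile,
    harmonics,
)


@pytest.fixture
def step_gain():
    return GainFunction("step")


@pytest.fixture
def w32():
    """Reference kernel b=3, c=2 (single- and double-peak bistable regime)."""
    return WeightProfile(0.0, 3.0, 2.0)


@pytest.fixture
def w115():
    """Kernel b=1, c=1.5 (mixed-family regime)."""
    return WeightProfile(0.0, 1.0, 1.5)


def fitted_family_distance(state: StateProfile, family: str, b: float, c: float):
    """Sup-distance from a state to the rotation family of a closed form.

    The family phase is free, so it is fitted from the dominant harmonic
    before comparison.
    """
    from hdring import construct_family, rotate

    h = harmonics(state, 2)
    sol0 = construct_family(family, b, c)
    if sol0.first_amplitude >= sol0.second_amplitude:
        shift = -np.angle(h[3]) - (-np.angle(sol0.coeffs[1] - 1j * sol0.coeffs[2]))
    else:
        shift = (-np.angle(h[4]) - (-np.angle(sol0.coeffs[3] - 1j * sol0.coeffs[4]))) / 2.0
    best = np.inf
    # the second harmonic leaves a pi ambiguity in the fitted rotation
    for extra in (0.0, np.pi):
        sol = rotate(sol0, shift + extra)
        d = np.max(np.abs(state.u - sol.u_values(state.grid.theta)))
        best = min(best, float(d))
    return best
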