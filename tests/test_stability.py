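"""Circulant eigenvalues, g-coefficients and the three spectral routes."""

import numpy as np
import pytest
from scipy.optimize import root as scipy_root

from hdring import (
    EquilibriumSolution,
    GainFunction,
    RingGrid,
    WeightProfile,
    construct_family,
    evaluate_gain,
    evaluate_weight,
    flat_stability,
    four_mode_spectrum,
    g_coefficients,
    gain_mode_coefficients,
    harmonics,
    jacobian_spectrum,
    numeric_jacobian_spectrum,
    weight_mode_eigenvalues,
)
from hdring.ring_model import StateProfile


def _logistic_equilibrium(b, c, k, n, start="cos"):
    """Solve u = w * g(u) on an n-grid and return it as a trig polynomial."""
    grid = RingGrid(n)
    w = WeightProfile(0, b, c)
    gain = GainFunction("logistic", k=k)
    kern = np.fft.fft(evaluate_weight(w, grid.theta))

    def f(u):
        return u - np.real(np.fft.ifft(kern * np.fft.fft(evaluate_gain(gain, u)))) / n

    u0 = np.cos(grid.theta) if start == "cos" else np.cos(2 * grid.theta)
    res = scipy_root(f, u0, method="krylov", options={"fatol": 1e-13})
    assert np.max(np.abs(f(res.x))) < 1e-11
    h = harmonics(StateProfile(grid=grid, u=res.x), 2)
    coeffs = (h[2].real, 2 * h[3].real, -2 * h[3].imag, 2 * h[4].real, -2 * h[4].imag)
    return EquilibriumSolution(coeffs, "numeric", b, c), gain


class TestWeightModes:
    def test_two_harmonic_kernel_modes(self):
        lam = weight_mode_eigenvalues(WeightProfile(0, 3, 2), [0, 1, 2, 3])
        np.testing.assert_allclose(lam, [0.0, 1.5, 1.0, 0.0], atol=1e-15)

    def test_zero_and_constant_kernels(self):
        assert np.all(weight_mode_eigenvalues(WeightProfile(0, 0, 0), [0, 1, 2]) == 0)
        lam = weight_mode_eigenvalues(WeightProfile(2, 0, 0), [0, 1, 5])
        np.testing.assert_allclose(lam, [2.0, 0.0, 0.0])

    def test_matches_direct_circulant_eigendecomposition(self):
        # independent oracle: eigen-decompose the n x n scaled circulant
        n = 500
        th = 2 * np.pi * np.arange(n) / n
        w = WeightProfile(0, 3, 2)
        W = evaluate_weight(w, th[:, None] - th[None, :])
        ev = np.sort(np.linalg.eigvalsh(W / n))[::-1]
        # spectrum: {1.5 x2, 1.0 x2, 0 x(n-4)}
        np.testing.assert_allclose(ev[:2], 1.5, atol=1e-10)
        np.testing.assert_allclose(ev[2:4], 1.0, atol=1e-10)
        np.testing.assert_allclose(ev[4:], 0.0, atol=1e-10)

    def test_shifted_kernel_rejected(self):
        with pytest.raises(ValueError, match="even"):
            weight_mode_eigenvalues(WeightProfile(0, 3, 2, alpha=0.1), [0])


class TestGCoefficients:
    def test_single_peak_delta_sums(self, step_gain):
        # zeros at pi/2, 3pi/2 with |u'| = b/pi give (-1/b, 1/b, 0)
        g = g_coefficients(construct_family("single_peak", 3, 2), step_gain)
        assert g.g22 == pytest.approx(-1 / 3, abs=1e-12)
        assert g.g33 == pytest.approx(1 / 3, abs=1e-12)
        assert abs(g.g23) < 1e-12

    def test_double_peak_delta_sums(self, step_gain):
        g = g_coefficients(construct_family("double_peak", 3, 2), step_gain)
        assert abs(g.g22) < 1e-12
        assert g.g33 == pytest.approx(-0.5, abs=1e-12)
        assert abs(g.g23) < 1e-12

    def test_mixed_family_rational_forms(self, step_gain):
        # printed closed forms for g22 and g33 at (b, c) = (1, 1.5)
        b, c = 1.0, 1.5
        g = g_coefficients(construct_family("mixed_plus", b, c), step_gain)
        den = 2 * c**2 + b * c - b**2
        assert g.g22.real == pytest.approx(-2 * b / den, abs=1e-8)
        assert g.g33.real == pytest.approx((4 * b**2 - 2 * c**2) / (den * c), abs=1e-8)
        assert abs(g.g22.imag) < 1e-10 and abs(g.g33.imag) < 1e-10

    def test_canonical_frame_reality(self, step_gain):
        # even-symmetric families have real harmonic moments after the
        # first-harmonic phase is rotated to zero
        for fam in ["single_peak", "double_peak", "two_domain_0", "two_domain_pi"]:
            sol = construct_family(fam, 3, 2, theta0=1.234)
            G = gain_mode_coefficients(sol, step_gain)
            assert np.max(np.abs(G.imag)) < 1e-9, fam

    def test_delta_sum_is_steep_logistic_limit(self, step_gain):
        for fam in ["single_peak", "double_peak"]:
            sol = construct_family(fam, 3, 2)
            Gd = gain_mode_coefficients(sol, step_gain)
            Gl = gain_mode_coefficients(
                sol, GainFunction("logistic", k=1e4), n_quad=131072
            )
            assert np.max(np.abs(Gl - Gd)) / np.max(np.abs(Gd)) < 0.01

    def test_flat_profile_rejected(self, step_gain):
        with pytest.raises(ValueError, match="flat"):
            g_coefficients(construct_family("flat", 3, 2), step_gain)

    def test_degenerate_zero_crossing_rejected(self, step_gain):
        # c = 2b: the mixed profile is tangent at its zero, |u'| -> 0
        sol = construct_family("mixed_plus", 1, 2.0)
        with pytest.raises(ValueError, match="degenerate"):
            g_coefficients(sol, step_gain)


class TestTwoModeSpectrum:
    def test_single_peak_printed_roots(self, step_gain):
        g = g_coefficients(construct_family("single_peak", 3, 2), step_gain)
        sp = jacobian_spectrum(3, 2, g)
        got = sorted(s.real for s in sp.special)
        assert got[0] == pytest.approx(-1.5, abs=1e-10)
        assert got[1] == pytest.approx(-1 + 2 / 6, abs=1e-10)  # -1 + c/2b
        assert sp.bulk == -1.0

    def test_double_peak_printed_roots(self, step_gain):
        g = g_coefficients(construct_family("double_peak", 3, 2), step_gain)
        sp = jacobian_spectrum(3, 2, g)
        got = sorted(s.real for s in sp.special)
        assert got == pytest.approx([-1.5, -1.0], abs=1e-10)

    @pytest.mark.parametrize("k", [1.2, 1.5, 1.8])
    def test_mixed_family_matches_rational_eigenvalue_formula(self, step_gain, k):
        # cross-check the quadratic route against the printed closed form
        # in the ratio variable k = c/b
        b, c = 1.0, k
        g = g_coefficients(construct_family("mixed_plus", b, c), step_gain)
        sp = jacobian_spectrum(b, c, g)
        num = -1 + 2 * k + k**2 - 2 * k**3
        disc = 1 - 4 * k + 4 * k**2 + 2 * k**3 - 7 * k**4 + 4 * k**5 + 4 * k**6
        den = 2 * (1 - 3 * k + 4 * k**3)
        expect = sorted([-1 + (num + np.sqrt(disc)) / den, -1 + (num - np.sqrt(disc)) / den])
        got = sorted(s.real for s in sp.special)
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_symmetric_families_have_real_discriminant(self, step_gain):
        for fam, (b, c) in [
            ("single_peak", (3, 2)), ("double_peak", (3, 2)),
            ("mixed_plus", (1, 1.5)), ("two_domain_0", (3, 2)),
        ]:
            g = g_coefficients(construct_family(fam, b, c), step_gain)
            disc = (b * g.g22 - c * g.g33) ** 2 + 4 * b * c * g.g23**2
            assert disc.real >= -1e-12 and abs(disc.imag) < 1e-10
            sp = jacobian_spectrum(b, c, g)
            assert max(abs(s.imag) for s in sp.special) < 1e-9


class TestFourModeSpectrum:
    def test_single_peak_rotation_mode_and_splitting_mode(self, step_gain):
        ms = four_mode_spectrum(construct_family("single_peak", 3, 2), step_gain)
        ev = np.sort(ms.eigenvalues.real)
        np.testing.assert_allclose(ev, [-1, -1, -1 + 2 / 3, 0], atol=1e-10)
        assert ms.stable  # neutral rotation mode does not count as unstable

    def test_double_peak_doubly_degenerate_mode(self, step_gain):
        ms = four_mode_spectrum(construct_family("double_peak", 3, 2), step_gain)
        ev = np.sort(ms.eigenvalues.real)
        np.testing.assert_allclose(ev, [-1, -0.25, -0.25, 0], atol=1e-10)

    def test_asymmetric_state_is_unstable(self, step_gain):
        ms = four_mode_spectrum(construct_family("asym_plus", 3, 2), step_gain)
        assert ms.lambda_max > 0.5
        assert not ms.stable

    def test_single_peak_unstable_when_second_harmonic_dominates(self, step_gain):
        # c > b: the bump splits; the printed two-mode catalog misses this
        ms = four_mode_spectrum(construct_family("single_peak", 1, 1.5), step_gain)
        assert ms.lambda_max == pytest.approx(0.5, abs=1e-10)
        assert not ms.stable

    @pytest.mark.parametrize("k", [2.0, 8.0, 32.0])
    def test_agrees_with_numeric_jacobian(self, k):
        # the four coupled modes against the full finite-n eigenproblem
        n = 256
        sol, gain = _logistic_equilibrium(3, 2, k, n)
        ms = four_mode_spectrum(sol, gain, n_quad=8192)
        ev = numeric_jacobian_spectrum(sol, gain, n=n)
        nonbulk = ev[np.abs(ev + 1) > 1e-4]
        assert len(nonbulk) == 4
        got = np.sort(nonbulk.real)
        expect = np.sort(ms.eigenvalues.real)
        np.testing.assert_allclose(got, expect, atol=1e-6)
        assert np.max(np.abs(ev.imag)) < 1e-8


class TestFlatStability:
    def test_logistic_special_roots(self):
        g2 = GainFunction("logistic", k=2)
        sp = flat_stability(3.5, 3.5, g2)
        np.testing.assert_allclose([s.real for s in sp.special], [-0.125, -0.125])
        assert sp.stable
        sp = flat_stability(4.5, 3.5, g2)
        np.testing.assert_allclose(sorted(s.real for s in sp.special), [-0.125, 0.125])
        assert not sp.stable

    def test_boundary_crossing_exact_at_8_over_k(self):
        for k in [2.0, 4.0, 8.0]:
            sp = flat_stability(8.0 / k, 0.0, GainFunction("logistic", k=k))
            assert sp.special[0].real == 0.0  # exactly marginal

    def test_step_gain_categorical(self):
        g = GainFunction("step")
        assert flat_stability(-1, -2, g).stable
        assert not flat_stability(3, 2, g).stable
        assert not flat_stability(-1, 2, g).stable
        assert np.isinf(flat_stability(3, 2, g).special[0].real)


class TestNumericJacobian:
    def test_zero_kernel_gives_pure_leak(self):
        sol = EquilibriumSolution((0, 0, 0, 0, 0), "flat", 0.0, 0.0)
        ev = numeric_jacobian_spectrum(sol, GainFunction("logistic", k=2), n=64)
        np.testing.assert_allclose(ev.real, -1.0, atol=1e-12)

    def test_flat_state_mode_degeneracies(self):
        # modes +-1 and +-2 each give a pair at -1 + (k/4)(b or c)/2
        sol = EquilibriumSolution((0, 0, 0, 0, 0), "flat", 3.5, 3.5)
        ev = numeric_jacobian_spectrum(sol, GainFunction("logistic", k=2), n=200)
        ev = np.sort(ev.real)[::-1]
        np.testing.assert_allclose(ev[:4], -0.125, atol=1e-8)
        np.testing.assert_allclose(ev[4:], -1.0, atol=1e-8)

    def test_step_gain_rejected(self):
        sol = construct_family("single_peak", 3, 2)
        with pytest.raises(ValueError):
            numeric_jacobian_spectrum(sol, GainFunction("step"), n=64)
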