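"""Forward-model behaviour: closed-form limits, scaling, monotonicity."""

import math

import numpy as np
import pytest

from poremech.errors import ConfigError
from poremech.fvk import (MembraneSpec, ModelKind, force, force_approx,
                          force_exact, get_profile, q_factor,
                          solve_point_load)


class TestMembraneSpec:
    @pytest.mark.parametrize("bad", [
        dict(E=0.0), dict(E=-1.0), dict(sigma=-1e-3), dict(h=0.0),
        dict(R=-1e-9), dict(nu=0.0), dict(nu=0.5),
    ])
    def test_invariant_violations_raise(self, bad):
        good = dict(E=1e8, sigma=1e-3, h=6.7e-9, R=600e-9, nu=0.485)
        with pytest.raises(ValueError):
            MembraneSpec(**{**good, **bad})

    def test_e2d_is_product(self):
        spec = MembraneSpec(E=513e6, sigma=0.0, h=6.7e-9, R=600e-9)
        assert spec.e2d == pytest.approx(513e6 * 6.7e-9)


class TestApproxModel:
    def test_zero_indentation_gives_zero_force(self, pmc_spec):
        assert force_approx(0.0, pmc_spec) == 0.0

    def test_negative_indentation_rejected(self, pmc_spec):
        with pytest.raises(ValueError):
            force_approx(-1e-9, pmc_spec)

    def test_tension_only_limit_is_pi_sigma_delta(self):
        # with a vanishing modulus the linear term is all that remains
        spec = MembraneSpec(E=1e-12, sigma=5.2e-3, h=6.7e-9, R=600e-9,
                            nu=0.485)
        delta = 10e-9
        expected = math.pi * 5.2e-3 * 1e-8
        assert force_approx(delta, spec) == pytest.approx(expected, rel=1e-9)

    def test_zero_tension_cubic_term(self):
        # independent evaluation of E2D * q^3 * delta^3 / R^2
        E, h, nu, R, delta = 513e6, 6.7e-9, 0.485, 600e-9, 18e-9
        spec = MembraneSpec(E=E, sigma=0.0, h=h, R=R, nu=nu)
        q = 1.0 / (1.049 - 0.146 * nu - 0.158 * nu * nu)
        expected = (E * h) * q**3 * delta**3 / R**2
        assert force_approx(delta, spec) == pytest.approx(expected, rel=1e-12)


class TestExactModel:
    def test_zero_indentation_gives_zero_force(self, profile, pmc_spec):
        assert force_exact(0.0, pmc_spec) == 0.0

    def test_zero_tension_loglog_slope_is_three(self, profile):
        spec = MembraneSpec(E=513e6, sigma=0.0, h=6.7e-9, R=600e-9)
        d = np.geomspace(0.01, 0.1, 30) * spec.R
        F = force_exact(d, spec)
        slope = np.polyfit(np.log(d), np.log(F), 1)[0]
        assert slope == pytest.approx(3.0, abs=0.01)

    def test_zero_tension_coefficient_near_conventional_cubic(self, profile):
        # Schwerin-type constant within 10% of the q^3 prefactor
        spec = MembraneSpec(E=100e6, sigma=0.0, h=6.7e-9, R=500e-9)
        d = 0.05 * spec.R
        C = force_exact(d, spec) * spec.R**2 / (spec.e2d * d**3)
        assert C == pytest.approx(q_factor(spec.nu) ** 3, rel=0.10)

    def test_small_indentation_slope_linear_in_sigma(self, profile):
        # doubling the pre-stress doubles the initial stiffness
        base = dict(E=100e6, h=6.7e-9, R=600e-9, nu=0.485)
        d = 1e-10
        slopes = []
        for sigma in (2e-3, 4e-3):
            spec = MembraneSpec(sigma=sigma, **base)
            slopes.append(force_exact(d, spec) / d)
        assert slopes[1] / slopes[0] == pytest.approx(2.0, rel=0.05)

    def test_dimensionless_collapse(self, profile):
        # F/(E2D R) depends only on (delta/R, sigma/E2D, nu)
        a = MembraneSpec(E=513e6, sigma=5.2e-3, h=6.7e-9, R=600e-9)
        scale = 3.0
        b = MembraneSpec(E=513e6 * scale, sigma=5.2e-3 * scale * (400 / 600),
                         h=6.7e-9 * (400 / 600), R=400e-9)
        assert b.sigma / b.e2d == pytest.approx(a.sigma / a.e2d)
        d_over_R = 0.03
        fa = force_exact(d_over_R * a.R, a) / (a.e2d * a.R)
        fb = force_exact(d_over_R * b.R, b) / (b.e2d * b.R)
        assert fa == pytest.approx(fb, rel=1e-9)

    def test_profile_matches_direct_bvp_solve(self, profile):
        # interpolated law vs a fresh BVP solve at off-grid points
        for f, s in [(3e-4, 1e-2), (2e-4, 1.6e-3), (5e-2, 2.5e-1)]:
            d, _ = solve_point_load(f, s, 0.485)
            f_interp = profile.scaled_force(d, s)
            assert f_interp == pytest.approx(f, rel=1e-3)

    def test_vectorized_equals_scalar_loop(self, profile, pmc_spec):
        d = np.linspace(0, 30e-9, 100)
        vec = force_exact(d, pmc_spec)
        loop = np.array([force_exact(float(x), pmc_spec) for x in d])
        np.testing.assert_allclose(vec, loop, rtol=1e-12)


class TestMonotonicity:
    @pytest.mark.parametrize("kind", [ModelKind.APPROX, ModelKind.EXACT])
    def test_strictly_increasing_in_delta(self, profile, kind, pmc_spec,
                                          pmc_minus_spec):
        d = np.linspace(1e-10, 0.15 * 600e-9, 200)
        for spec in (pmc_spec, pmc_minus_spec):
            F = force(np.linspace(1e-10, 0.15 * spec.R, 200), spec, kind)
            assert np.all(np.diff(F) > 0)

    @pytest.mark.parametrize("kind", [ModelKind.APPROX, ModelKind.EXACT])
    def test_increasing_in_E_and_sigma(self, profile, kind):
        delta, h, R = 20e-9, 6.7e-9, 600e-9
        for sigma in (1e-3, 5e-3):
            F = [force(delta, MembraneSpec(E=E, sigma=sigma, h=h, R=R), kind)
                 for E in np.geomspace(10e6, 1000e6, 8)]
            assert np.all(np.diff(F) > 0)
        for E in (50e6, 500e6):
            F = [force(delta, MembraneSpec(E=E, sigma=s, h=h, R=R), kind)
                 for s in np.geomspace(5e-4, 2e-2, 8)]
            assert np.all(np.diff(F) > 0)


class TestDispatch:
    def test_kinds_delegate(self, profile, pmc_spec):
        d = np.linspace(0, 20e-9, 7)
        np.testing.assert_array_equal(
            force(d, pmc_spec, "approx_superposition"),
            force_approx(d, pmc_spec))
        np.testing.assert_array_equal(
            force(d, pmc_spec, "exact_fvk"), force_exact(d, pmc_spec))

    def test_unknown_kind_is_config_error(self, pmc_spec):
        with pytest.raises(ConfigError):
            force(1e-9, pmc_spec, "hertzian")

    def test_regime_crossover_inside_measured_range(self, pmc_spec):
        # cubic/linear terms of the superposition cross at
        # delta* = R sqrt(pi sigma / (E2D q^3)); for these parameters the
        # crossover sits in the experimentally probed window
        q3 = q_factor(pmc_spec.nu) ** 3
        d_star = pmc_spec.R * math.sqrt(
            math.pi * pmc_spec.sigma / (pmc_spec.e2d * q3))
        assert 0.01 < d_star / pmc_spec.R < 0.2
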