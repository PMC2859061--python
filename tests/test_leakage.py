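"""Eigenfunction-series solution of Robin-boundary sphere leakage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipokin import (
    DomainError,
    MLVSpec,
    ValidationError,
    concentration,
    fraction_remaining,
    solve_eigenvalues,
    series_coefficients,
    time_to_fraction,
)
from lipokin.leakage import build_series, mean_theta, theta_profile
from lipokin.oracles import fd_fraction_remaining


class TestBiot:
    def test_definition(self, unit_biot_spec):
        assert unit_biot_spec.biot == pytest.approx(1.0)

    def test_hand_computed(self):
        # independently: 2.5e-7 * 2e-6 / 5e-13 = 1.0
        assert MLVSpec(2e-6, 5e-13, 2.5e-7).biot == pytest.approx(1.0, abs=1e-15)

    def test_vanishing_surface_coeff_limit(self):
        assert MLVSpec(1e-6, 1e-12, 1e-20).biot == pytest.approx(1e-14)

    @pytest.mark.parametrize("field", ["radius", "diffusivity", "surface_coeff", "initial_conc"])
    def test_nonpositive_field_rejected_by_name(self, field):
        kwargs = dict(radius=1e-6, diffusivity=1e-12, surface_coeff=1e-6, initial_conc=1.0)
        kwargs[field] = -1.0
        with pytest.raises(ValidationError, match=field):
            MLVSpec(**kwargs)


class TestEigenvalues:
    def test_unit_biot_closed_form(self):
        # At Bi = 1 the eigencondition reduces to cos(lam) = 0.
        lam = solve_eigenvalues(1.0, 3)
        assert lam == pytest.approx([math.pi / 2, 3 * math.pi / 2, 5 * math.pi / 2], abs=1e-10)

    def test_absorbing_surface_limit(self):
        lam = solve_eigenvalues(1e12, 3)
        assert lam == pytest.approx([math.pi, 2 * math.pi, 3 * math.pi], abs=1e-9)

    def test_small_biot_leading_order(self):
        bi = 0.01
        (lam1,) = solve_eigenvalues(bi, 1)
        # bisection oracle on the eigencondition over (0, pi)
        lo, hi = 1e-14, math.pi - 1e-14
        g = lambda x: x * math.cos(x) + (bi - 1) * math.sin(x)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(lo) * g(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert lam1 == pytest.approx(0.5 * (lo + hi), abs=1e-13)
        assert lam1 == pytest.approx(math.sqrt(3 * bi), rel=2e-3)

    @given(log_bi=st.floats(-3, 3), n=st.integers(1, 40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_interlacing_and_residual(self, log_bi, n):
        bi = 10.0**log_bi
        lam = solve_eigenvalues(bi, n)
        assert np.all(np.diff(lam) > 0)
        k = np.arange(n)
        assert np.all(lam > k * math.pi)
        assert np.all(lam < (k + 1) * math.pi)
        resid = np.abs(lam * np.cos(lam) + (bi - 1) * np.sin(lam))
        assert np.all(resid / np.maximum(np.maximum(1.0, abs(bi - 1)), lam) < 1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            solve_eigenvalues(-1.0, 3)
        with pytest.raises(ValidationError):
            solve_eigenvalues(1.0, 0)


class TestSeriesCoefficients:
    def test_reconstruction_error_decreases_with_order(self):
        bi = 3.7
        eta = np.linspace(0, 1, 200)
        errs = []
        for n in (5, 20, 80):
            sol = build_series(bi, n)
            theta0 = theta_profile(sol, eta, 2e-6)  # just above the IC clamp
            errs.append(np.sqrt(np.mean((theta0 - 1.0) ** 2)))
        assert errs[0] > errs[1] > errs[2]

    def test_first_coefficient_is_projection(self):
        # quadrature oracle: composite Simpson, 1e4 panels
        from lipokin.oracles import project_initial_condition

        lam = solve_eigenvalues(1.0, 1)
        a = series_coefficients(lam, 1.0)
        a_quad = project_initial_condition(1.0, lam, n_panels=10_000)
        assert a[0] == pytest.approx(a_quad[0], abs=1e-10)

    def test_dirichlet_limit_coefficients(self):
        lam = solve_eigenvalues(1e12, 50)
        a = series_coefficients(lam, 1e12)
        n = np.arange(1, 51)
        dirichlet = 2 * (-1.0) ** (n + 1) / (n * math.pi)
        assert np.max(np.abs(a - dirichlet)) < 1e-6

    def test_mismatched_eigenvalues_rejected(self):
        lam = solve_eigenvalues(1.0, 5)
        with pytest.raises(ValidationError):
            series_coefficients(lam, 50.0)


class TestConcentration:
    def test_initial_condition(self, unit_biot_spec):
        r = np.linspace(0, 0.9e-6, 50)  # away from the surface
        c = concentration(unit_biot_spec, r, 0.0, n_terms=200)
        assert np.max(np.abs(c - 1.0)) < 1e-3

    def test_fully_decayed(self, unit_biot_spec):
        # All modes decay at least as fast as the slowest, lambda_1^2;
        # at Bi = 1 (lambda_1 = pi/2) six diffusion times suffice for 1e-6.
        t6 = 6.0 * unit_biot_spec.diffusion_time
        r = np.linspace(0, 1e-6, 20)
        assert np.max(concentration(unit_biot_spec, r, t6)) < 1e-6
        lam1 = math.pi / 2
        for tau in (3.0, 4.0, 5.0):
            c = np.max(concentration(unit_biot_spec, r, tau * unit_biot_spec.diffusion_time))
            assert c < 1.3 * math.exp(-lam1**2 * tau)

    def test_center_value_finite_and_matches_nearby(self, unit_biot_spec):
        t = 0.1 * unit_biot_spec.diffusion_time
        c0 = concentration(unit_biot_spec, 0.0, t)
        c_eps = concentration(unit_biot_spec, 1e-12, t)
        assert math.isfinite(c0)
        assert c0 == pytest.approx(c_eps, rel=1e-9)

    def test_interior_value_vs_fd_oracle(self, unit_biot_spec):
        from lipokin.oracles import fd_sphere_diffusion

        tau = 0.1
        sol = fd_sphere_diffusion(unit_biot_spec, n_nodes=2000, taus=np.array([tau]))
        i = np.argmin(np.abs(sol.eta - 0.5))
        t = tau * unit_biot_spec.diffusion_time
        c = concentration(unit_biot_spec, 0.5 * unit_biot_spec.radius, t)
        assert c == pytest.approx(sol.theta[0, i], rel=1e-4)

    def test_domain_errors(self, unit_biot_spec):
        with pytest.raises(DomainError):
            concentration(unit_biot_spec, 2e-6, 1.0)
        with pytest.raises(DomainError):
            concentration(unit_biot_spec, 0.5e-6, -1.0)


class TestFractionRemaining:
    def test_starts_at_one(self, unit_biot_spec):
        assert fraction_remaining(unit_biot_spec, 0.0) == pytest.approx(1.0, abs=1e-3)

    def test_dirichlet_limit_closed_form(self):
        spec = MLVSpec(1e-6, 1e-12, 1.0)  # Bi = 1e6
        tau = 0.1
        got = fraction_remaining(spec, tau * spec.diffusion_time)
        want = (6 / math.pi**2) * sum(
            math.exp(-(n**2) * math.pi**2 * tau) / n**2 for n in range(1, 10_001)
        )
        assert got == pytest.approx(want, abs=1e-5)

    def test_lumped_capacity_limit(self):
        spec = MLVSpec(1e-6, 1e-12, 1e-9)  # Bi = 1e-3
        for tau in (0.01, 0.1, 1.0, 10.0, 100.0):
            got = fraction_remaining(spec, tau * spec.diffusion_time, n_terms=100)
            assert got == pytest.approx(math.exp(-3e-3 * tau), rel=1e-3)

    def test_strictly_decreasing_in_time(self, unit_biot_spec):
        t = np.linspace(0, 2, 50) * unit_biot_spec.diffusion_time
        f = fraction_remaining(unit_biot_spec, t)
        assert np.all(np.diff(f) < 0)

    def test_larger_biot_leaks_no_slower(self):
        taus = np.array([0.01, 0.1, 0.5])
        prev = None
        for bi in (0.1, 1.0, 10.0, 100.0):
            cur = mean_theta(build_series(bi, 200), taus)
            if prev is not None:
                assert np.all(cur <= prev + 1e-12)
            prev = cur

    def test_mass_accounting_against_surface_flux(self, unit_biot_spec):
        # Leaked amount equals the time-integrated surface flux:
        # 1 - mean(tau) = 3 Bi int_0^tau theta(1, s) ds (dimensionless).
        from lipokin.oracles import fd_sphere_diffusion

        taus = np.linspace(0, 0.5, 1000)
        sol = fd_sphere_diffusion(unit_biot_spec, n_nodes=1000, taus=taus, dtau=1e-4)
        surface = sol.theta[:, -1]
        leaked_flux = 3.0 * unit_biot_spec.biot * np.concatenate(
            ([0.0], np.cumsum(0.5 * (surface[1:] + surface[:-1]) * np.diff(taus)))
        )
        leaked_series = 1.0 - mean_theta(build_series(unit_biot_spec.biot, 200), taus)
        assert np.max(np.abs(leaked_flux - leaked_series)) < 0.01


class TestSeriesVsOracle:
    def test_three_seeded_specs(self, tau_grid):
        from lipokin.fixtures import random_mlv_specs

        for spec in random_mlv_specs(7, 3):
            fd = fd_fraction_remaining(spec, tau_grid, n_nodes=1500)
            ser = mean_theta(build_series(spec.biot, 200), tau_grid)
            assert np.max(np.abs(fd - ser)) < 1e-3


class TestTimeToFraction:
    def test_inverse_of_fraction_remaining(self, unit_biot_spec):
        t_star = time_to_fraction(unit_biot_spec, 0.3)
        assert fraction_remaining(unit_biot_spec, t_star) == pytest.approx(0.3, abs=1e-6)

    def test_near_one_gives_near_zero_time(self, unit_biot_spec):
        assert time_to_fraction(unit_biot_spec, 0.999) < 0.01 * unit_biot_spec.diffusion_time

    def test_lumped_limit_half_time(self):
        spec = MLVSpec(1e-6, 1e-12, 1e-9)  # Bi = 1e-3
        want = spec.radius**2 * math.log(2) / (3 * 1e-3 * spec.diffusivity)
        assert time_to_fraction(spec, 0.5) == pytest.approx(want, rel=1e-3)

    def test_monotone_in_target(self, unit_biot_spec):
        ts = [time_to_fraction(unit_biot_spec, f) for f in (0.8, 0.5, 0.2)]
        assert ts[0] < ts[1] < ts[2]

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.5])
    def test_target_outside_unit_interval_rejected(self, unit_biot_spec, bad):
        with pytest.raises(DomainError):
            time_to_fraction(unit_biot_spec, bad)
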