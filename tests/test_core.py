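"""Closed-form physics: dispersion constants, drag, decay solutions, PDE."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bundlerheo import (
    DriveProtocol,
    RodModel,
    decay_constants,
    drag_coefficient,
    effective_stiffness,
    end_driven_solution,
    hydrodynamic_length,
    middle_driven_solution,
    solve_pde,
)
from bundlerheo.core import complex_amplitude_profile

positive = st.floats(min_value=1e-30, max_value=1e30, allow_nan=False, allow_infinity=False)


class TestDecayConstants:
    def test_matches_first_quadrant_root_of_quartic(self):
        # independent oracle: closed-form root exp(i*pi/8) of k^4 = i
        k = cmath.exp(1j * math.pi / 8)
        dc = decay_constants()
        assert dc.c_tilde == pytest.approx(k.real, abs=1e-12)
        assert dc.s_tilde == pytest.approx(k.imag, abs=1e-12)
        assert dc.c_tilde == pytest.approx(0.9238795325112867, abs=1e-9)
        assert dc.s_tilde == pytest.approx(0.3826834323650898, abs=1e-9)

    def test_unit_modulus_and_ordering(self):
        dc = decay_constants()
        assert dc.c_tilde**2 + dc.s_tilde**2 == pytest.approx(1.0, abs=1e-12)
        assert dc.c_tilde > dc.s_tilde > 0

    def test_rounds_to_published_two_decimal_values(self):
        dc = decay_constants()
        assert round(dc.c_tilde, 2) == 0.92
        assert round(dc.s_tilde, 2) == 0.38


class TestDragCoefficient:
    def test_linear_in_viscosity(self):
        z1 = drag_coefficient(1e-3, 20e-6, 20e-9)
        z2 = drag_coefficient(2e-3, 20e-6, 20e-9)
        assert z2 == pytest.approx(2 * z1, rel=1e-12)

    def test_increases_with_diameter(self):
        assert drag_coefficient(1e-3, 20e-6, 40e-9) > drag_coefficient(1e-3, 20e-6, 20e-9)

    def test_slender_body_value(self):
        # direct evaluation of the perpendicular slender-body formula
        eta, L, d = 1e-3, 20e-6, 20e-9
        expected = 4 * math.pi * eta / (math.log(L / d) + 0.84)
        assert drag_coefficient(eta, L, d) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "eta,L,d",
        [(-1e-3, 20e-6, 20e-9), (1e-3, 20e-9, 20e-6), (1e-3, 20e-6, -1e-9), (0.0, 1e-6, 1e-9)],
    )
    def test_rejects_bad_inputs(self, eta, L, d):
        with pytest.raises(ValueError):
            drag_coefficient(eta, L, d)


class TestHydrodynamicLength:
    def test_identity_case(self):
        assert hydrodynamic_length(1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_quarter_power_in_frequency(self):
        l1 = hydrodynamic_length(2e-24, 0.1, 1.0)
        assert hydrodynamic_length(2e-24, 0.1, 16.0) == pytest.approx(l1 / 2, rel=1e-12)

    @given(kappa=st.floats(1e-27, 1e-20), zeta=st.floats(1e-4, 10.0), omega=st.floats(1e-3, 1e3))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance_of_frequency_doubling(self, kappa, zeta, omega):
        ratio = hydrodynamic_length(kappa, zeta, 2 * omega) / hydrodynamic_length(kappa, zeta, omega)
        assert ratio == pytest.approx(2 ** (-0.25), rel=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hydrodynamic_length(-1e-24, 0.1, 1.0)


class TestEffectiveStiffness:
    def test_identity_case(self):
        assert effective_stiffness(1.0, 1.0) == pytest.approx(1.0)

    def test_fourth_power_in_decay_length(self):
        assert effective_stiffness(2.0, 1.0) == pytest.approx(16.0)

    @given(kappa_over_zeta=st.floats(1e-24, 1e-18), omega=st.floats(1e-3, 1e3))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_with_hydrodynamic_length(self, kappa_over_zeta, omega):
        l_om = (kappa_over_zeta / omega) ** 0.25
        assert effective_stiffness(l_om, omega) == pytest.approx(
            kappa_over_zeta, rel=1e-12
        )

    def test_returns_absolute_stiffness_with_drag(self):
        keff, kappa = effective_stiffness(2e-6, 3.0, zeta=0.09)
        assert kappa == pytest.approx(0.09 * keff, rel=1e-12)


class TestDrivenSolutions:
    def test_end_driven_boundary_condition(self):
        t = np.linspace(0, 3.0, 17)
        omega = 2.1
        y = end_driven_solution(0.0, t, 1e-6, omega)
        assert np.allclose(y, 1e-6 * np.cos(omega * t), rtol=1e-12)

    def test_decay_far_from_drive(self):
        y = end_driven_solution(40.0, 0.3, 1e-6, 1.0)
        assert abs(y) < 1e-12

    def test_end_driven_value_term_by_term(self):
        # independent evaluation of the two-wave expression at eta=1, t=0
        k = cmath.exp(1j * math.pi / 8)
        c, s = k.real, k.imag
        expected = 0.5 * (math.exp(-s) * math.cos(c) + math.exp(-c) * math.cos(s))
        assert end_driven_solution(1.0, 0.0, 1.0, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_envelope_below_5_percent_at_eta_8(self):
        eta = 8.0
        t = np.linspace(0, 2 * np.pi, 400)
        y = end_driven_solution(eta, t, 1.0, 1.0)
        assert np.max(np.abs(y)) < 0.05

    def test_middle_driven_boundary_and_decay(self):
        omega = 1.7
        t = np.linspace(0, 5, 31)
        y = middle_driven_solution(0.0, t, 2e-6, omega)
        assert np.allclose(y, 2e-6 * np.cos(omega * t), rtol=1e-10, atol=1e-18)
        assert abs(middle_driven_solution(40.0, 0.1, 2e-6, omega)) < 1e-12

    def test_middle_driven_value_at_origin_time_zero(self):
        assert middle_driven_solution(0.0, 0.0, 1.0, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_complex_profile_consistent_with_real_solution(self):
        eta = np.linspace(0, 6, 25)
        omega, t = 0.9, 0.37
        z = complex_amplitude_profile(eta)
        reconstructed = np.real(z * np.exp(-1j * omega * t))
        assert np.allclose(reconstructed, end_driven_solution(eta, t, 1.0, omega), rtol=1e-10, atol=1e-14)

    def test_analytic_solution_satisfies_pde_under_refinement(self):
        # residual of zeta*y_t + kappa*y_xxxx on the closed form -> 0 as dx, dt -> 0
        residuals = []
        for n in (64, 128):
            eta = np.linspace(0.5, 6.0, 8 * n)
            t = np.linspace(0.1, 0.1 + 2 * np.pi, 4 * n)
            deta, dt = eta[1] - eta[0], t[1] - t[0]
            y = end_driven_solution(eta[None, :], t[:, None], 1.0, 1.0)
            y_t = (y[2:, 2:-2] - y[:-2, 2:-2]) / (2 * dt)
            y_4x = (
                y[1:-1, 4:] - 4 * y[1:-1, 3:-1] + 6 * y[1:-1, 2:-2]
                - 4 * y[1:-1, 1:-3] + y[1:-1, :-4]
            ) / deta**4
            residuals.append(np.sqrt(np.mean((y_t + y_4x) ** 2)))
        assert residuals[1] < residuals[0] / 3  # ~second-order convergence


@pytest.fixture(scope="module")
def setup(rod):
    drive = DriveProtocol(amplitude=1e-6, frequency_hz=0.5, n_periods=3)
    l_om = hydrodynamic_length(rod.kappa, rod.zeta, drive.omega)
    return rod, drive, l_om


class TestSolvePde:
    def test_matches_end_driven_solution(self, setup):
        rod, drive, l_om = setup
        kymo = solve_pde(rod, drive, length=8 * l_om)
        keep = kymo.times >= drive.period
        ref = end_driven_solution(
            kymo.x_positions[None, :] / l_om,
            (kymo.times[keep] - drive.period / 4)[:, None],
            drive.amplitude,
            drive.omega,
        )
        err = np.sqrt(np.mean((kymo.y[keep] - ref) ** 2)) / drive.amplitude
        assert err < 0.01

    def test_zero_drive_gives_zero_field(self, setup):
        rod, drive, l_om = setup
        kymo = solve_pde(rod, drive, length=8 * l_om, drive_fn=lambda t: np.zeros_like(np.asarray(t, float)))
        assert np.max(np.abs(kymo.y)) == 0.0

    def test_spatial_refinement_reduces_error(self, setup):
        # compare against a much finer reference solution of the same scheme
        rod, drive, l_om = setup
        L = 8 * l_om
        errs = []
        ref = solve_pde(rod, drive, nx=641, length=L, steps_per_period=400)
        for nx in (81, 161):
            sol = solve_pde(rod, drive, nx=nx, length=L, steps_per_period=400)
            step = (ref.y.shape[1] - 1) // (nx - 1)
            errs.append(np.sqrt(np.mean((sol.y - ref.y[:, ::step]) ** 2)))
        assert errs[1] < errs[0] / 2.5  # consistent with a second-order scheme

    def test_reports_unresolved_grid(self, setup):
        rod, drive, l_om = setup
        with pytest.raises(ValueError, match="dx"):
            solve_pde(rod, drive, nx=12, length=8 * l_om)
        with pytest.raises(ValueError, match="steps per period"):
            solve_pde(rod, drive, length=8 * l_om, steps_per_period=10)


class TestDomainTypes:
    def test_rod_invariants(self):
        rod = RodModel(kappa=5e-24, contour_length=20e-6, diameter=60e-9, medium_viscosity=0.05)
        kb_t = 1.380649e-23 * rod.temperature
        assert rod.persistence_length * kb_t == pytest.approx(rod.kappa, rel=1e-12)
        with pytest.raises(ValueError):
            RodModel(kappa=-1e-24, contour_length=20e-6, diameter=60e-9, medium_viscosity=0.05)
        with pytest.raises(ValueError, match="L/d"):
            RodModel(kappa=1e-24, contour_length=20e-9, diameter=60e-9, medium_viscosity=0.05)

    def test_drive_protocol_omega_and_validation(self):
        d = DriveProtocol(amplitude=1e-6, frequency_hz=0.5)
        assert d.omega == pytest.approx(2 * math.pi * 0.5, rel=1e-15)
        with pytest.raises(ValueError):
            DriveProtocol(amplitude=1e-6, frequency_hz=0.5, n_periods=2)
        with pytest.raises(ValueError):
            DriveProtocol(amplitude=0.0, frequency_hz=0.5)
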