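"""Sweep aggregation, power-law fits, regime classification, stability."""

import dataclasses
import math

import numpy as np
import pytest

from bundlerheo import (
    DrivePoint,
    Kymograph,
    ModelKind,
    build_sweep,
    classify_regime,
    default_rod,
    drift_test,
    fit_power_law,
    stability_check,
)
from bundlerheo.core import end_driven_solution
from bundlerheo.oscillation import HydrodynamicFit


def make_fit(frequency_hz: float, l_omega: float, sd: float = 1e-9) -> HydrodynamicFit:
    omega = 2 * math.pi * frequency_hz
    return HydrodynamicFit(
        l_omega=l_omega, y0_fit=1e-6, x0=0.0, phase0=0.0, omega=omega,
        drive_point=DrivePoint.END, mode="complex", residual_norm=0.0,
        rms_residual=0.0, l_omega_sd=sd, covariance=None, n_points=50,
        span_decay_lengths=4.0,
    )


def synthetic_sweep(l_exponent: float, n: int = 8, l_ref: float = 3e-6,
                    noise: float = 0.0, seed: int = 0):
    freqs = np.geomspace(0.04, 2.5, n)
    rng = np.random.default_rng(seed)
    fits = []
    for f in freqs:
        l_om = l_ref * (f / 0.3) ** l_exponent
        if noise > 0:
            l_om *= 1.0 + noise * rng.normal()
        fits.append(make_fit(f, l_om))
    return build_sweep(fits)


class TestFitPowerLaw:
    def test_exact_quarter_power(self):
        x = np.geomspace(0.1, 10, 12)
        fit = fit_power_law(x, x ** (-0.25))
        assert fit.exponent == pytest.approx(-0.25, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_data_gives_zero_exponent(self):
        x = np.geomspace(1, 100, 10)
        fit = fit_power_law(x, np.full(10, 3.3))
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_noisy_square_law(self):
        rng = np.random.default_rng(123)
        x = np.geomspace(0.5, 50, 20)
        y = x**2 * (1 + 0.01 * rng.normal(size=20))
        fit = fit_power_law(x, y)
        assert fit.exponent == pytest.approx(2.0, abs=0.05)

    def test_rejects_nonpositive_and_short_data(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0, -3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0], [1.0, 2.0])


class TestBuildSweep:
    def test_wlc_scaling_gives_constant_stiffness(self):
        sweep = synthetic_sweep(-0.25)
        keff = sweep.table["kappa_eff"].to_numpy()
        assert keff.max() / keff.min() == pytest.approx(1.0, rel=1e-9)

    def test_constant_decay_length_gives_linear_stiffness(self):
        sweep = synthetic_sweep(0.0)
        fit = fit_power_law(sweep.table["omega"], sweep.table["kappa_eff"])
        assert fit.exponent == pytest.approx(1.0, abs=1e-12)

    def test_absolute_stiffness_added_when_rod_known(self):
        rod = default_rod()
        freqs = [0.1, 0.5, 2.0]
        fits = [make_fit(f, 3e-6 * (f / 0.3) ** -0.25) for f in freqs]
        sweep = build_sweep(fits, rod=rod)
        np.testing.assert_allclose(
            sweep.table["kappa"], rod.zeta * sweep.table["kappa_eff"], rtol=1e-12
        )

    def test_duplicate_frequencies_collapsed_with_warning(self):
        fits = [make_fit(f, 3e-6) for f in (0.1, 0.1, 0.5, 2.0)]
        with pytest.warns(UserWarning, match="duplicate"):
            sweep = build_sweep(fits)
        assert len(sweep.table) == 3

    def test_stiffness_identity_enforced(self):
        sweep = synthetic_sweep(-0.25)
        bad = sweep.table.copy()
        bad.loc[0, "kappa_eff"] *= 1.001
        with pytest.raises(ValueError, match="kappa_eff"):
            type(sweep)(table=bad)


class TestClassifyRegime:
    def test_quarter_power_classified_wormlike_chain(self):
        scaling = classify_regime(synthetic_sweep(-0.25))
        assert scaling.model_kind is ModelKind.WLC_CONSTANT
        assert scaling.exponent == -0.25

    def test_shear_coupled_bundle_signature(self):
        # l_omega ~ omega^-1/2 makes kappa_eff ~ l_omega^2
        scaling = classify_regime(synthetic_sweep(-0.5))
        assert scaling.model_kind is ModelKind.WLB_SHEAR_COUPLED
        assert scaling.mode_stiffness_exponent == -2.0

    def test_other_scaling_is_free_power_law(self):
        scaling = classify_regime(synthetic_sweep(-0.8))
        assert scaling.model_kind is ModelKind.FREE_POWER_LAW

    def test_two_frequencies_indeterminate(self):
        fits = [make_fit(0.1, 4e-6), make_fit(1.0, 2e-6), make_fit(1.0, 2e-6)]
        with pytest.warns(UserWarning, match="duplicate"):
            sweep = build_sweep(fits)
        assert classify_regime(sweep).model_kind is ModelKind.INDETERMINATE

    def test_narrow_span_flagged_low_power(self):
        freqs = [0.2, 0.3, 0.4, 0.5]
        fits = [make_fit(f, 3e-6 * (f / 0.3) ** -0.25) for f in freqs]
        sweep = build_sweep(fits)
        with pytest.warns(UserWarning, match="low-power"):
            scaling = classify_regime(sweep)
        assert scaling.details.get("low_power")

    def test_classification_invariant_under_unit_rescaling(self):
        sweep = synthetic_sweep(-0.5, noise=0.02, seed=9)
        rescaled = dataclasses.replace(sweep)
        tab = rescaled.table.copy()
        tab["l_omega"] *= 1e6  # metres -> micrometres
        tab["kappa_eff"] = tab["l_omega"] ** 4 * tab["omega"]
        rescaled = type(sweep)(table=tab)
        a = classify_regime(sweep)
        b = classify_regime(rescaled)
        assert a.model_kind is b.model_kind
        assert a.details["fits"]["kappa_vs_l_omega"].exponent == pytest.approx(
            b.details["fits"]["kappa_vs_l_omega"].exponent, rel=1e-9
        )

    @pytest.mark.parametrize("l_exponent", [-0.25, -0.35, -0.5])
    def test_exponent_identity_kappa_vs_omega(self, l_exponent):
        # kappa_eff = l_omega^4 * omega makes the OLS exponents satisfy
        # b_kappa = 4*b_l + 1 exactly, also on noisy sweeps
        sweep = synthetic_sweep(l_exponent, noise=0.05, seed=21)
        b_l = fit_power_law(sweep.table["omega"], sweep.table["l_omega"]).exponent
        b_k = fit_power_law(sweep.table["omega"], sweep.table["kappa_eff"]).exponent
        assert b_k == pytest.approx(4 * b_l + 1, abs=1e-10)


class TestStability:
    def test_drift_test_flags_trend_and_passes_stable_series(self):
        t = np.linspace(0, 600, 30)
        rng = np.random.default_rng(4)
        stable = 3e-6 + 1e-8 * rng.normal(size=30)
        drifting = 3e-6 + 2e-9 * t + 1e-8 * rng.normal(size=30)
        a = drift_test(t, stable)
        b = drift_test(t, drifting)
        assert abs(a["slope"]) < 2 * a["slope_stderr"]
        assert b["slope"] > 3 * b["slope_stderr"]
        assert b["p_value"] < 1e-6

    def test_stability_check_on_steady_recording(self):
        # 600 s at fixed drive: windowed l_omega shows no divergence
        rod = default_rod()
        f = 0.1
        omega = 2 * math.pi * f
        from bundlerheo import hydrodynamic_length

        l_om = hydrodynamic_length(rod.kappa, rod.zeta, omega)
        t = np.arange(0, 600.0, 0.5)
        x = np.linspace(0.2e-6, 18e-6, 60)
        y = end_driven_solution(x[None, :] / l_om, t[:, None], 1e-6, omega)
        y += np.random.default_rng(8).normal(0, 5e-9, size=y.shape)
        kymo = Kymograph(y=y, x_positions=x, times=t)
        result = stability_check(kymo, f, window_periods=4, step_periods=4)
        drift = result["drift"]
        rel_drift_per_100s = abs(drift["slope"]) * 100 / l_om
        assert rel_drift_per_100s < 0.02
        assert len(result["windows"]) >= 10
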