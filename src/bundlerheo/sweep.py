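"""Frequency-sweep aggregation, power-law fits, and regime classification.

A wormlike chain has one frequency-independent bending stiffness, so its
hydrodynamic length scales as l_omega ~ omega^(-1/4) and the effective
stiffness kappa_eff = l_omega^4 * omega is flat across the sweep.
Crosslink-coupled (wormlike-bundle) behaviour shows up instead as a
stiffness growing with the probed length scale, kappa_eff ~ l_omega^2
(equivalently kappa_eff ~ omega^(-1/2)), the signature of mode stiffness
scaling as kappa_n ~ q_n^(-2).  This module fits those exponents from a
set of per-frequency fits and classifies the regime with an explicit,
configurable tolerance rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelKind, RodModel, ScalingModel
from .oscillation import HydrodynamicFit, bandpass, fit_hydrodynamic_length


@dataclass
class PowerLawFit:
    """Ordinary least squares of log10(y) on log10(x)."""

    exponent: float
    prefactor: float
    stderr: float
    r_squared: float
    variables: str = ""
    n: int = 0

    def predict(self, x):
        return self.prefactor * np.asarray(x, dtype=float) ** self.exponent


def fit_power_law(xs, ys, variables: str = "") -> PowerLawFit:
    """Fit y = a * x^b by linear regression in log-log space."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be 1-D arrays of equal length")
    if xs.size < 3:
        raise ValueError(f"need at least 3 points for a power-law fit, got {xs.size}")
    if (xs <= 0).any() or (ys <= 0).any():
        raise ValueError("power-law fit requires strictly positive data")
    res = stats.linregress(np.log10(xs), np.log10(ys))
    return PowerLawFit(
        exponent=float(res.slope),
        prefactor=float(10.0**res.intercept),
        stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        r_squared=float(res.rvalue**2),
        variables=variables,
        n=int(xs.size),
    )


@dataclass
class SweepResult:
    """Per-frequency rheology records for one bundle.

    ``table`` columns: frequency_hz, omega, l_omega, l_omega_sd,
    kappa_eff (= l_omega^4 * omega, m^4/s) and, when the drag coefficient
    is known, kappa (J·m).
    """

    table: pd.DataFrame
    bundle_label: str = ""
    zeta: Optional[float] = None

    def __post_init__(self) -> None:
        required = {"frequency_hz", "omega", "l_omega", "kappa_eff"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sweep table missing columns {sorted(missing)}")
        check = self.table["l_omega"] ** 4 * self.table["omega"]
        if not np.allclose(check, self.table["kappa_eff"], rtol=1e-12, atol=0.0):
            raise ValueError("kappa_eff must equal l_omega^4 * omega exactly")

    @property
    def frequencies(self) -> np.ndarray:
        return self.table["frequency_hz"].to_numpy()

    def decade_span(self) -> float:
        f = self.frequencies
        return float(np.log10(f.max() / f.min()))


def build_sweep(
    fits: Sequence[HydrodynamicFit],
    rod: Optional[RodModel] = None,
    bundle_label: str = "",
) -> SweepResult:
    """Aggregate per-frequency fits into a rheological spectrum.

    ``kappa_eff`` is recomputed from each fitted decay length; the
    absolute stiffness ``kappa = zeta * kappa_eff`` is added when the rod
    geometry and medium viscosity (hence the drag coefficient) are known.
    Duplicate frequencies are averaged with a warning.
    """
    if len(fits) < 3:
        raise ValueError(f"need at least 3 frequencies in a sweep, got {len(fits)}")
    rows = []
    for fit in fits:
        rows.append(
            {
                "frequency_hz": fit.frequency_hz,
                "omega": fit.omega,
                "l_omega": fit.l_omega,
                "l_omega_sd": fit.l_omega_sd,
                "n_points": fit.n_points,
                "rms_residual": fit.rms_residual,
                "identifiable": fit.identifiable,
            }
        )
    df = pd.DataFrame(rows)
    if df["frequency_hz"].duplicated().any():
        dupes = df.loc[df["frequency_hz"].duplicated(), "frequency_hz"].unique()
        warnings.warn(
            f"duplicate frequencies {list(dupes)} collapsed by averaging",
            stacklevel=2,
        )
        df = df.groupby("frequency_hz", as_index=False).mean(numeric_only=True)
    df = df.sort_values("frequency_hz", ignore_index=True)
    df["kappa_eff"] = df["l_omega"] ** 4 * df["omega"]
    zeta = rod.zeta if rod is not None else None
    if zeta is not None:
        df["kappa"] = zeta * df["kappa_eff"]
    return SweepResult(table=df, bundle_label=bundle_label, zeta=zeta)


def classify_regime(
    sweep: SweepResult,
    exponent_tolerance: float = 0.05,
    min_frequencies: int = 4,
    min_decades: float = 1.0,
) -> ScalingModel:
    """Classify a sweep as wormlike-chain, shear-coupled bundle, or free.

    Fits the l_omega-vs-omega exponent; within
    ``exponent_tolerance + 2 * fit stderr`` of -1/4 the sweep is
    ``WLC_constant``.  Otherwise the kappa_eff-vs-omega and
    kappa_eff-vs-l_omega exponents are reported; a kappa-vs-l_omega
    exponent within tolerance of +2 earns the ``WLB_shear_coupled`` label.
    Sweeps with fewer than 3 frequencies are ``indeterminate``; smaller
    sweeps than ``min_frequencies`` frequencies or ``min_decades`` decades
    get a low-power warning flag in ``details`` rather than a silent
    default.
    """
    df = sweep.table
    n = len(df)
    details: dict = {"n_frequencies": n, "decade_span": None}
    if n >= 2:
        details["decade_span"] = sweep.decade_span()
    if n < 3:
        return ScalingModel(
            model_kind=ModelKind.INDETERMINATE,
            details={**details, "reason": "fewer than 3 frequencies"},
        )
    low_power = n < min_frequencies or details["decade_span"] < min_decades
    if low_power:
        warnings.warn(
            f"sweep has {n} frequencies over {details['decade_span']:.2f} "
            "decades; classification is low-powered",
            stacklevel=2,
        )
        details["low_power"] = True

    omega = df["omega"].to_numpy()
    l_fit = fit_power_law(omega, df["l_omega"].to_numpy(), "l_omega_vs_omega")
    k_om = fit_power_law(omega, df["kappa_eff"].to_numpy(), "kappa_vs_omega")
    k_l = fit_power_law(df["l_omega"].to_numpy(), df["kappa_eff"].to_numpy(), "kappa_vs_l_omega")
    details["fits"] = {
        "l_omega_vs_omega": l_fit,
        "kappa_vs_omega": k_om,
        "kappa_vs_l_omega": k_l,
    }

    tol_l = exponent_tolerance + 2.0 * l_fit.stderr
    if abs(l_fit.exponent + 0.25) <= tol_l:
        return ScalingModel(model_kind=ModelKind.WLC_CONSTANT, details=details)

    tol_k = 4.0 * exponent_tolerance + 2.0 * k_l.stderr
    if abs(k_l.exponent - 2.0) <= tol_k:
        return ScalingModel(
            model_kind=ModelKind.WLB_SHEAR_COUPLED,
            exponent=l_fit.exponent,
            mode_stiffness_exponent=-2.0,
            details=details,
        )
    return ScalingModel(
        model_kind=ModelKind.FREE_POWER_LAW,
        exponent=l_fit.exponent,
        details=details,
    )


def drift_test(times, values) -> dict:
    """Linear drift of a quantity over time: slope, its standard error,
    and the two-sided p-value of slope = 0.

    Used for the long-recording stability check: a bundle driven at fixed
    frequency should show no tendency of its hydrodynamic length to
    diverge over hundreds of seconds.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 time points for a drift test")
    res = stats.linregress(times, values)
    return {
        "slope": float(res.slope),
        "slope_stderr": float(res.stderr),
        "p_value": float(res.pvalue),
        "intercept": float(res.intercept),
        "n": int(times.size),
    }


def stability_check(
    kymo,
    drive_hz: float,
    window_periods: int = 3,
    step_periods: int = 2,
    **fit_kwargs,
) -> dict:
    """Sliding-window hydrodynamic length over one long recording.

    Splits the kymograph into overlapping windows of ``window_periods``
    drive periods, fits l_omega in each, and runs :func:`drift_test` on
    the series.  Returns the per-window table and the drift statistics.
    """
    period = 1.0 / drive_hz
    t0, t1 = kymo.times[0], kymo.times[-1]
    starts = np.arange(t0, t1 - window_periods * period + 1e-9, step_periods * period)
    rows = []
    for start in starts:
        sel = (kymo.times >= start - 1e-9) & (
            kymo.times < start + window_periods * period - 1e-9
        )
        if sel.sum() < 8:
            continue
        sub = type(kymo)(
            y=kymo.y[sel],
            x_positions=kymo.x_positions,
            times=kymo.times[sel],
            quality=kymo.quality[sel],
            excluded_columns=kymo.excluded_columns,
        )
        try:
            prof = bandpass(sub, drive_hz, exclude_periods=0)
            fit = fit_hydrodynamic_length(prof, **fit_kwargs)
        except (ValueError, RuntimeError):
            continue
        rows.append({"t_center": start + window_periods * period / 2, "l_omega": fit.l_omega})
    if len(rows) < 3:
        raise ValueError(
            f"only {len(rows)} usable windows; recording too short for a "
            "stability check"
        )
    table = pd.DataFrame(rows)
    drift = drift_test(table["t_center"], table["l_omega"])
    return {"windows": table, "drift": drift}
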