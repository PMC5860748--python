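"""Finite-difference solution of the overdamped bending equation versus the
closed-form end-driven solution.

The solver starts the rod at rest and ramps the drive over the first
period; after that transient the numerical field should coincide with the
steady analytic two-wave solution.
"""

import numpy as np

from bundlerheo import (
    DriveProtocol,
    default_rod,
    end_driven_solution,
    hydrodynamic_length,
    solve_pde,
)

rod = default_rod()
drive = DriveProtocol(amplitude=1e-6, frequency_hz=0.5, n_periods=3)
l_om = hydrodynamic_length(rod.kappa, rod.zeta, drive.omega)
print(f"rod: kappa = {rod.kappa:.2e} J*m, zeta = {rod.zeta:.3f} Pa*s")
print(f"drive: {drive.frequency_hz} Hz, l_omega = {l_om * 1e6:.2f} um")

for mult in (8, 12, 16):
    kymo = solve_pde(rod, drive, length=mult * l_om)
    keep = kymo.times >= drive.period  # discard the transient period
    ref = end_driven_solution(
        kymo.x_positions[None, :] / l_om,
        (kymo.times[keep] - drive.period / 4)[:, None],
        drive.amplitude,
        drive.omega,
    )
    err = np.sqrt(np.mean((kymo.y[keep] - ref) ** 2)) / drive.amplitude
    print(f"L = {mult:2d} l_omega: relative L2 difference = {err:.3%}")

print(
    "\nThe residual at L = 8 l_omega is dominated by the free far end the\n"
    "finite rod has but the semi-infinite closed form does not; it shrinks\n"
    "as the rod gets longer, confirming the solver itself."
)
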