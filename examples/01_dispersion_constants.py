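"""Decay constants and closed-form solutions of the driven bending equation.

A transversely driven elastic rod in a viscous fluid obeys
zeta*y_t = -kappa*y_xxxx.  Rescaling x by the hydrodynamic length
l_omega = (kappa/(zeta*omega))**(1/4) and inserting a travelling wave
gives the dispersion relation k^4 = i; the first-quadrant root fixes the
universal spatial constants of the driven solution.
"""

import numpy as np

from bundlerheo import decay_constants, end_driven_solution, hydrodynamic_length

dc = decay_constants()
print(f"first-quadrant root of k^4 = i : C = {dc.c_tilde:.6f}, S = {dc.s_tilde:.6f}")
print(f"rounded as conventionally quoted: C ~= {dc.c_tilde:.2f}, S ~= {dc.s_tilde:.2f}")
print(f"unit modulus check C^2 + S^2   : {dc.c_tilde**2 + dc.s_tilde**2:.12f}")

# A concrete bundle: kappa = 5.5e-24 J*m, zeta = 0.094 Pa*s, driven at 0.7 Hz
kappa, zeta, omega = 5.5e-24, 0.094, 2 * np.pi * 0.7
l_om = hydrodynamic_length(kappa, zeta, omega)
print(f"\nhydrodynamic length at 0.7 Hz  : {l_om * 1e6:.2f} um")
print("  (the oscillation amplitude decays over this distance)")

eta = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
envelope = [np.max(np.abs(end_driven_solution(e, np.linspace(0, 2 * np.pi, 400), 1.0, 1.0)))
            for e in eta]
print("\nenvelope of the end-driven solution (units of the drive amplitude):")
for e, a in zip(eta, envelope):
    print(f"  eta = x/l_omega = {e:3.0f} : {a:.4f}")
print("by eta = 8 the oscillation has decayed below 5% of the drive.")
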