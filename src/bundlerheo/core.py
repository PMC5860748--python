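"""Closed-form and numerical solutions of the overdamped driven bending
equation.

A weakly bending rod in a viscous medium at low Reynolds number obeys

    zeta * (y_t - u) = -kappa * y_xxxx,

the balance of transverse drag against the wormlike-chain bending force.
Driving one point sinusoidally at angular frequency omega launches bending
waves whose amplitude decays over the hydrodynamic length

    l_omega = (kappa / (omega * zeta))**(1/4),

the single length scale of the problem.  Nondimensionalising x by l_omega
and substituting a travelling wave exp(i k eta - i omega t) yields the
dispersion relation k**4 = i; its first-quadrant root k = C + iS fixes the
universal decay constants of the driven solutions.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Callable, Optional, Union

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .models import DecayConstants, DrivePoint, DriveProtocol, Kymograph, RodModel

ArrayLike = Union[float, np.ndarray]


@lru_cache(maxsize=1)
def decay_constants() -> DecayConstants:
    """Decay constants of the driven-rod solution.

    Solves the dimensionless dispersion relation k^4 = i with a polynomial
    root finder and returns the root with positive real and imaginary
    parts.  Its real part C is the spatial oscillation constant of the
    outgoing excitation wave (and the decay constant of the wave reflected
    by the medium); its imaginary part S is the decay constant of the
    excitation wave.  Numerically C ≈ 0.924, S ≈ 0.383.
    """
    roots = np.roots([1.0, 0.0, 0.0, 0.0, -1.0j])
    (k,) = [z for z in roots if z.real > 0 and z.imag > 0]
    return DecayConstants(c_tilde=float(k.real), s_tilde=float(k.imag))


def drag_coefficient(viscosity: float, contour_length: float, diameter: float) -> float:
    """Transverse slender-body drag per unit length of a rod, Pa·s.

    Uses the standard low-Reynolds-number result for a slender cylinder
    moving perpendicular to its axis,

        zeta_perp = 4 * pi * eta / (ln(L/d) + 0.84),

    which depends on geometry only through the aspect ratio L/d.
    """
    if not viscosity > 0:
        raise ValueError(f"viscosity must be > 0, got {viscosity}")
    if not diameter > 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    if not contour_length > diameter:
        raise ValueError(
            f"slender-body drag needs L > d, got L={contour_length}, d={diameter}"
        )
    return 4.0 * math.pi * viscosity / (math.log(contour_length / diameter) + 0.84)


def hydrodynamic_length(kappa: float, zeta: float, omega: float) -> float:
    """l_omega = (kappa / (zeta * omega))**(1/4), m.

    The length over which the driven oscillation amplitude decays; equals
    (kB*T*lp / (omega*zeta))**(1/4) when kappa = kB*T*lp.
    """
    if not (kappa > 0 and zeta > 0 and omega > 0):
        raise ValueError(
            f"kappa, zeta, omega must all be > 0, got {kappa}, {zeta}, {omega}"
        )
    return (kappa / (zeta * omega)) ** 0.25


def effective_stiffness(
    l_omega: float, omega: float, zeta: Optional[float] = None
) -> Union[float, tuple]:
    """Effective bending rigidity kappa_eff = l_omega**4 * omega.

    This is the drag-normalised stiffness kappa/zeta (units m^4/s) read off
    from a measured decay length at a given drive frequency.  When the drag
    coefficient is supplied the absolute stiffness kappa = zeta * kappa_eff
    (J·m) is returned alongside.
    """
    if not (l_omega > 0 and omega > 0):
        raise ValueError(f"l_omega and omega must be > 0, got {l_omega}, {omega}")
    kappa_eff = l_omega**4 * omega
    if zeta is None:
        return kappa_eff
    return kappa_eff, zeta * kappa_eff


def end_driven_solution(eta: ArrayLike, t: ArrayLike, y0: float, omega: float) -> np.ndarray:
    """Steady-state deflection of a rod driven sinusoidally at one end.

    y(eta, t) = y0/2 * [ exp(-S eta) cos(C eta - omega t)
                       + exp(-C eta) cos(S eta + omega t) ],

    with eta = x / l_omega.  The first term is the outgoing excitation
    wave, the second its reflection by the medium.  The driven end obeys
    y(0, t) = y0 cos(omega t) with zero curvature (torque-free drive).
    """
    dc = decay_constants()
    eta = np.asarray(eta, dtype=float)
    phase = omega * np.asarray(t, dtype=float)
    c, s = dc.c_tilde, dc.s_tilde
    return 0.5 * y0 * (
        np.exp(-s * eta) * np.cos(c * eta - phase)
        + np.exp(-c * eta) * np.cos(s * eta + phase)
    )


def middle_driven_solution(eta: ArrayLike, t: ArrayLike, y0: float, omega: float) -> np.ndarray:
    """Steady-state deflection on one side of a rod driven at its middle.

    y(eta, t) = y0/2 * { exp(-S eta) [cos(C eta - omega t) + sin(C eta - omega t)]
                       + exp(-C eta) [cos(S eta + omega t) + sin(S eta + omega t)] }.

    Both sides of the contour carry this same profile (mirror symmetry,
    zero slope at the drive point); eta >= 0 is distance from the drive in
    units of l_omega.
    """
    dc = decay_constants()
    eta = np.asarray(eta, dtype=float)
    phase = omega * np.asarray(t, dtype=float)
    c, s = dc.c_tilde, dc.s_tilde
    a = c * eta - phase
    b = s * eta + phase
    return 0.5 * y0 * (
        np.exp(-s * eta) * (np.cos(a) + np.sin(a))
        + np.exp(-c * eta) * (np.cos(b) + np.sin(b))
    )


def complex_amplitude_profile(eta: ArrayLike, drive_point: DrivePoint = DrivePoint.END) -> np.ndarray:
    """Complex oscillation amplitude Z(eta) of the driven solution, per unit y0.

    Defined by y(eta, t) = Re[ Z(eta) * exp(-i omega t) ], so |Z| is the
    local amplitude and arg(Z) the local phase relative to the drive.  For
    the end-driven rod

        Z = 1/2 [ exp((iC - S) eta) + exp((-iS - C) eta) ],

    and for the middle-driven rod the two terms carry factors (1 -/+ i)/2.
    """
    dc = decay_constants()
    eta = np.asarray(eta, dtype=float)
    c, s = dc.c_tilde, dc.s_tilde
    out_wave = np.exp((1j * c - s) * eta)
    refl_wave = np.exp((-1j * s - c) * eta)
    if DrivePoint(drive_point) is DrivePoint.END:
        return 0.5 * (out_wave + refl_wave)
    return 0.5 * ((1 - 1j) * out_wave + (1 + 1j) * refl_wave)


def _fourth_derivative_matrix(n: int, dx: float, drive_point: DrivePoint) -> tuple:
    """Second-order stencil for y_xxxx on nodes 0..n-1 with node 0 Dirichlet.

    Ghost nodes implement zero curvature (end drive) or zero slope (middle
    drive, mirror symmetry) at the driven node and a force/torque-free far
    end (y_xx = y_xxx = 0).  Returns (A, b0) where A acts on the interior
    unknowns y_1..y_{n-1} and b0 is the column of coefficients multiplying
    the prescribed y_0.
    """
    coeffs = np.array([1.0, -4.0, 6.0, -4.0, 1.0])
    full = np.zeros((n - 1, n + 3))  # columns: ghost(-1), 0..n-1, ghost(n), ghost(n+1)

    def col(j):  # grid index -> column index
        return j + 1

    for row, i in enumerate(range(1, n)):
        for c_, j in zip(coeffs, range(i - 2, i + 3)):
            full[row, col(j)] += c_

    # driven-end ghost y_{-1}
    if DrivePoint(drive_point) is DrivePoint.END:
        # zero curvature: y_{-1} = 2 y_0 - y_1
        full[:, col(0)] += 2.0 * full[:, col(-1)]
        full[:, col(1)] += -1.0 * full[:, col(-1)]
    else:
        # zero slope (mirror symmetry): y_{-1} = y_1
        full[:, col(1)] += full[:, col(-1)]
    full[:, col(-1)] = 0.0

    # free far end: y_xx = 0  ->  y_n = 2 y_{n-1} - y_{n-2}
    #               y_xxx = 0 ->  y_{n+1} = 2 y_n - 2 y_{n-2} + y_{n-3}
    #                                     = 4 y_{n-1} - 4 y_{n-2} + y_{n-3}
    full[:, col(n - 1)] += 2.0 * full[:, col(n)]
    full[:, col(n - 2)] += -1.0 * full[:, col(n)]
    full[:, col(n)] = 0.0
    full[:, col(n - 1)] += 4.0 * full[:, col(n + 1)]
    full[:, col(n - 2)] += -4.0 * full[:, col(n + 1)]
    full[:, col(n - 3)] += 1.0 * full[:, col(n + 1)]
    full[:, col(n + 1)] = 0.0

    interior = full[:, col(1) : col(n - 1) + 1] / dx**4
    b0 = full[:, col(0)] / dx**4
    return scipy.sparse.csc_matrix(interior), b0


def solve_pde(
    rod: RodModel,
    drive: DriveProtocol,
    nx: Optional[int] = None,
    steps_per_period: int = 200,
    n_transient_periods: int = 1,
    length: Optional[float] = None,
    soft_start: bool = True,
    drive_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> Kymograph:
    """Finite-difference solution of zeta*(y_t - u) = -kappa*y_xxxx.

    The rod starts at rest; node 0 follows the prescribed drive
    displacement (default y0*sin(omega t), optionally ramped over the
    first period to suppress the start-up transient), the driven node is
    torque-free (end drive) or a mirror plane (middle drive, one side of
    the contour is solved), and the far end is force- and torque-free.
    Crank-Nicolson time stepping with a second-order spatial stencil; the
    scheme is unconditionally stable, so only resolution preconditions are
    enforced: at least 10 nodes per hydrodynamic length and 20 steps per
    period.

    Returns the full space-time field as a ground-truth :class:`Kymograph`
    (times from 0 to (n_transient_periods + n_periods)*T).  Callers
    comparing against the steady analytic solutions should discard the
    transient periods.
    """
    omega = drive.omega
    l_om = hydrodynamic_length(rod.kappa, rod.zeta, omega)
    L = length if length is not None else rod.contour_length
    if nx is None:
        nx = max(int(np.ceil(15 * L / l_om)) + 1, 41)
    dx = L / (nx - 1)
    dt = drive.period / steps_per_period
    if dx > l_om / 10:
        raise ValueError(
            f"grid too coarse: dx={dx:.3e} m exceeds l_omega/10={l_om / 10:.3e} m"
        )
    if steps_per_period < 20:
        raise ValueError(
            f"time step too coarse: dt={dt:.3e} s gives {steps_per_period} "
            "steps per period, need >= 20"
        )

    n_total = n_transient_periods + drive.n_periods
    n_steps = n_total * steps_per_period
    times = dt * np.arange(n_steps + 1)

    if drive_fn is None:

        def drive_fn(t):
            g = drive.amplitude * np.sin(omega * np.asarray(t, dtype=float))
            if soft_start:
                ramp = np.minimum(np.asarray(t, dtype=float) / drive.period, 1.0)
                g = g * (0.5 - 0.5 * np.cos(np.pi * ramp))
            return g

    d4, b0 = _fourth_derivative_matrix(nx, dx, drive.drive_point)
    diff = rod.kappa / rod.zeta  # m^4/s
    a_op = -diff * d4  # du/dt = A u + (-diff*b0) * y_0(t) + u_flow term
    ident = scipy.sparse.identity(nx - 1, format="csc")
    lhs = scipy.sparse.linalg.splu((ident - 0.5 * dt * a_op).tocsc())
    rhs_op = ident + 0.5 * dt * a_op
    forcing = -diff * b0

    g = np.asarray(drive_fn(times), dtype=float)
    u_flow = rod.background_velocity

    y = np.zeros((n_steps + 1, nx))
    y[0, 0] = g[0]
    state = np.zeros(nx - 1)
    for n in range(n_steps):
        rhs = rhs_op @ state + 0.5 * dt * (forcing * (g[n] + g[n + 1])) + dt * u_flow
        state = lhs.solve(rhs)
        y[n + 1, 1:] = state
        y[n + 1, 0] = g[n + 1]

    x = dx * np.arange(nx)
    return Kymograph(y=y, x_positions=x, times=times)
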