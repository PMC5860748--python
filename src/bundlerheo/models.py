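"""Domain types shared across the pipeline.

All physical quantities are SI unless a name says otherwise (``*_px`` are
pixel units, ``*_hz`` are cycles per second). Angular frequency ``omega``
(rad/s) is used in every formula; acquisition metadata stores Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional

import numpy as np
from scipy.constants import k as BOLTZMANN  # J/K


class ImagingError(ValueError):
    """Raised when a requested rendering or preprocessing is unphysical
    (field of view too small for the decay length, crop band excluding the
    contour, ...)."""


class DrivePoint(str, Enum):
    """Where along the contour the bead imposes the oscillation."""

    END = "end"
    MIDDLE = "middle"


class ModelKind(str, Enum):
    """Scaling regimes distinguishable from a frequency sweep.

    ``WLC_CONSTANT``: single frequency-independent bending stiffness, the
    wormlike-chain prediction (decay length scales as omega^(-1/4)).
    ``WLB_SHEAR_COUPLED``: stiffness grows with the probed length scale as
    kappa_eff ~ l_omega^2, the wormlike-bundle shear-dominated regime in
    which mode stiffness scales with wave vector as kappa_n ~ q_n^(-2).
    ``FREE_POWER_LAW``: frequency-dependent but not matching the bundle
    shear signature. ``INDETERMINATE``: sweep too small to classify.
    """

    WLC_CONSTANT = "WLC_constant"
    WLB_SHEAR_COUPLED = "WLB_shear_coupled"
    FREE_POWER_LAW = "free_power_law"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class RodModel:
    """A filament bundle idealised as a homogeneous elastic rod in a viscous
    medium at low Reynolds number.

    Parameters
    ----------
    kappa:
        Bending stiffness (flexural rigidity), J·m.
    contour_length:
        Rod length L, m.
    diameter:
        Rod diameter d, m.  Bundles are sub-resolution optically; the
        diameter enters only through the drag coefficient (and rendering
        brightness), never as a resolvable width.
    medium_viscosity:
        Dynamic viscosity of the surrounding medium, Pa·s.
    temperature:
        Absolute temperature, K (used only to convert stiffness to a
        persistence length).
    background_velocity:
        Uniform background flow u, m/s.  Zero in a quiescent sample where
        the trap moves the bead rather than the fluid.
    """

    kappa: float
    contour_length: float
    diameter: float
    medium_viscosity: float
    temperature: float = 298.15
    background_velocity: float = 0.0

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if not self.contour_length > 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if not self.diameter > 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if not self.contour_length / self.diameter > 1:
            raise ValueError(
                "slender-rod model requires L/d > 1, got "
                f"L={self.contour_length}, d={self.diameter}"
            )
        if not self.medium_viscosity > 0:
            raise ValueError(f"medium_viscosity must be > 0, got {self.medium_viscosity}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def persistence_length(self) -> float:
        """lp = kappa / (kB T), m."""
        return self.kappa / (BOLTZMANN * self.temperature)

    @property
    def zeta(self) -> float:
        """Transverse slender-body drag per unit length, Pa·s."""
        from .core import drag_coefficient

        return drag_coefficient(self.medium_viscosity, self.contour_length, self.diameter)

    @classmethod
    def from_persistence_length(
        cls, persistence_length: float, temperature: float = 298.15, **kwargs
    ) -> "RodModel":
        kappa = persistence_length * BOLTZMANN * temperature
        return cls(kappa=kappa, temperature=temperature, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["persistence_length"] = self.persistence_length
        d["zeta"] = self.zeta
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RodModel":
        keys = (
            "kappa",
            "contour_length",
            "diameter",
            "medium_viscosity",
            "temperature",
            "background_velocity",
        )
        return cls(**{k: d[k] for k in keys if k in d})


@dataclass(frozen=True)
class DriveProtocol:
    """Sinusoidal excitation imposed by the optically trapped bead.

    ``amplitude`` (y0, m) and ``frequency_hz`` define the drive; the bead
    displacement is y0·cos(omega·t).  ``frame_interval`` and ``exposure``
    (s) describe the camera timing of the recording; ``n_periods`` is the
    number of drive periods recorded.
    """

    amplitude: float
    frequency_hz: float
    drive_point: DrivePoint = DrivePoint.END
    n_periods: int = 7
    frame_interval: float = 0.05
    exposure: float = 0.05

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if not self.frequency_hz > 0:
            raise ValueError(f"frequency_hz must be > 0, got {self.frequency_hz}")
        if self.n_periods < 3:
            raise ValueError(f"need n_periods >= 3, got {self.n_periods}")
        if not 0 < self.frame_interval:
            raise ValueError("frame_interval must be > 0")
        if not 0 < self.exposure <= self.frame_interval:
            raise ValueError(
                f"exposure must be in (0, frame_interval={self.frame_interval}], "
                f"got {self.exposure}"
            )
        object.__setattr__(self, "drive_point", DrivePoint(self.drive_point))

    @property
    def omega(self) -> float:
        """Angular frequency, rad/s."""
        return 2.0 * math.pi * self.frequency_hz

    @property
    def period(self) -> float:
        return 1.0 / self.frequency_hz

    def displacement(self, t) -> np.ndarray:
        """Bead displacement y0·cos(omega t) at time(s) ``t``."""
        return self.amplitude * np.cos(self.omega * np.asarray(t, dtype=float))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drive_point"] = self.drive_point.value
        d["omega"] = self.omega
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DriveProtocol":
        keys = ("amplitude", "frequency_hz", "drive_point", "n_periods", "frame_interval", "exposure")
        return cls(**{k: d[k] for k in keys if k in d})

    @classmethod
    def for_camera(
        cls,
        amplitude: float,
        frequency_hz: float,
        drive_point: DrivePoint = DrivePoint.END,
        n_periods: int = 7,
        min_exposure: float = 0.05,
        max_frames_per_period: int = 32,
    ) -> "DriveProtocol":
        """Acquisition timing a CCD with a fixed minimum exposure would use.

        Fast drives are limited by the minimum exposure (50 ms spans a fifth
        of a period already at 4 Hz); slow drives are sub-sampled to at most
        ``max_frames_per_period`` frames per period so recordings stay short
        against photobleaching.  The frame interval always divides the
        period exactly, which keeps Fourier projection windows commensurate.
        """
        period = 1.0 / frequency_hz
        fpp = int(np.clip(round(period / min_exposure), 8, max_frames_per_period))
        interval = period / fpp
        return cls(
            amplitude=amplitude,
            frequency_hz=frequency_hz,
            drive_point=drive_point,
            n_periods=n_periods,
            frame_interval=interval,
            exposure=min(min_exposure, interval),
        )


@dataclass(frozen=True)
class DecayConstants:
    """Real and imaginary parts of the first-quadrant root of k^4 = i.

    ``c_tilde`` is the spatial oscillation constant of the outgoing
    excitation wave (and decay constant of the reflected wave);
    ``s_tilde`` is the decay constant of the excitation wave.  The root
    lies on the unit circle, so c² + s² = 1.
    """

    c_tilde: float
    s_tilde: float

    def __post_init__(self) -> None:
        if abs(self.c_tilde**2 + self.s_tilde**2 - 1.0) > 1e-12:
            raise ValueError("decay constants must satisfy c² + s² = 1")
        if not self.c_tilde > self.s_tilde > 0:
            raise ValueError("expected first-quadrant root with c > s > 0")

    @property
    def k(self) -> complex:
        """The complex wave number c + i·s."""
        return complex(self.c_tilde, self.s_tilde)


@dataclass
class ScalingModel:
    """Outcome of classifying a frequency sweep into a stiffness regime."""

    model_kind: ModelKind
    exponent: float = float("nan")  # fitted l_omega-vs-omega exponent
    mode_stiffness_exponent: Optional[float] = None  # kappa_n vs q_n
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.model_kind = ModelKind(self.model_kind)
        if self.model_kind is ModelKind.WLC_CONSTANT:
            # the wormlike chain has, by definition, the -1/4 decay-length law
            self.exponent = -0.25


@dataclass
class Kymograph:
    """Transverse deflection y(x, t) of the tracked contour.

    ``y`` is a (time, position) matrix in metres (absolute position along
    the deflection axis; the oscillation analysis removes the DC offset).
    Failed or excluded samples are NaN.  ``quality`` holds a per-sample fit
    diagnostic (residual RMS relative to peak height; NaN where invalid).
    ``excluded_columns`` marks columns deliberately masked, e.g. the bead
    vicinity.
    """

    y: np.ndarray
    x_positions: np.ndarray
    times: np.ndarray
    quality: Optional[np.ndarray] = None
    excluded_columns: Optional[np.ndarray] = None
    bad_frames: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x_positions = np.asarray(self.x_positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        nt, nx = self.y.shape
        if self.x_positions.shape != (nx,) or self.times.shape != (nt,):
            raise ValueError(
                f"inconsistent kymograph dimensions: y {self.y.shape}, "
                f"x {self.x_positions.shape}, t {self.times.shape}"
            )
        if self.quality is None:
            self.quality = np.full_like(self.y, np.nan)
        if self.excluded_columns is None:
            self.excluded_columns = np.zeros(nx, dtype=bool)
        else:
            self.excluded_columns = np.asarray(self.excluded_columns, dtype=bool)
            # excluded columns must carry no deflection values
            self.y[:, self.excluded_columns] = np.nan
        if self.bad_frames is None:
            self.bad_frames = np.zeros(nt, dtype=bool)

    @property
    def n_times(self) -> int:
        return self.y.shape[0]

    @property
    def n_positions(self) -> int:
        return self.y.shape[1]

    def valid_fraction(self) -> float:
        keep = ~self.excluded_columns
        if not keep.any():
            return 0.0
        return float(np.mean(np.isfinite(self.y[:, keep])))
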