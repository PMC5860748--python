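"""Rendering of synthetic fluorescence image stacks of a driven bundle.

Emulates CCD fluorescence recordings of a TRITC-labelled bundle with a
bead attached at the drive point: the analytic contour is integrated over
the camera exposure (motion blur), convolved transversely with a Gaussian
line profile, the bead drawn as a bright disk, the signal bleached
exponentially, and Poisson shot noise plus Gaussian read noise applied.
Every stack carries its ground-truth kymograph, so trackers can be scored
against what is actually in the image (the exposure-averaged contour).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from . import io as _io
from .core import end_driven_solution, hydrodynamic_length, middle_driven_solution
from .models import DrivePoint, DriveProtocol, ImagingError, Kymograph, RodModel


@dataclass(frozen=True)
class ImagingConfig:
    """Camera and optics parameters of the synthetic microscope.

    Defaults correspond to a typical 100x fluorescence setup: 100 nm
    pixels, a 150 nm point-spread sigma, a peak signal of 200 photons per
    pixel over a background of 20 counts, 3 counts read noise, and a 2 um
    bead.  The bundle itself is sub-resolution: its diameter never appears
    as a resolvable width, only as line brightness and drag.
    """

    pixel_size: float = 100e-9  # m per pixel
    psf_sigma: float = 150e-9  # m, transverse Gaussian width of the line
    shape: tuple = (128, 256)  # (rows, columns) = (y, x) pixels
    photons_per_pixel_peak: float = 200.0
    background_level: float = 20.0
    bleach_rate: float = 0.005  # 1/s, applied to signal only
    bead_radius: float = 1e-6  # m
    bead_brightness: float = 20.0  # multiple of the peak signal (saturating blob)
    read_noise_sd: float = 3.0  # counts
    shot_noise: bool = True
    exposure_subsamples: int = 8  # contour samples per exposure window
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.psf_sigma < self.pixel_size / 2:
            raise ValueError(
                f"psf_sigma must be >= pixel_size/2 = {self.pixel_size / 2:.3g} m "
                "(narrower lines are not sampled adequately)"
            )
        if self.bleach_rate < 0 or self.read_noise_sd < 0 or self.bead_radius < 0:
            raise ValueError("bleach_rate, read_noise_sd, bead_radius must be >= 0")
        if self.exposure_subsamples < 1:
            raise ValueError("exposure_subsamples must be >= 1")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingConfig":
        keys = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in d.items() if k in keys})


@dataclass
class FrameStack:
    """An image time series with calibration metadata and optional truth.

    ``frames`` is (time, y, x) in camera counts.  ``x_origin``/``y_origin``
    give the physical position (m) of the centre of pixel (0, 0), so that
    column i sits at ``x_origin + (i + 0.5) * pixel_size`` — this keeps
    coordinates consistent through cropping.  ``truth`` is the
    exposure-averaged analytic contour actually rendered into each frame.
    """

    frames: np.ndarray
    config: ImagingConfig
    drive: DriveProtocol
    rod: Optional[RodModel] = None
    truth: Optional[Kymograph] = None
    x_drive: float = 0.0  # m, drive (bead) position along x
    y_center: float = 0.0  # m, undisturbed contour position
    x_origin: float = 0.0
    y_origin: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (time, y, x), got {self.frames.shape}")
        if np.issubdtype(self.frames.dtype, np.floating) and (self.frames < 0).any():
            raise ValueError("frame intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Exposure start time of each frame, s."""
        return self.drive.frame_interval * np.arange(self.n_frames)

    @property
    def mid_times(self) -> np.ndarray:
        """Mid-exposure time of each frame, s."""
        return self.frame_times + 0.5 * self.drive.exposure

    @property
    def x_positions(self) -> np.ndarray:
        """Physical x of each column centre, m."""
        px = self.config.pixel_size
        return self.x_origin + px * (np.arange(self.frames.shape[2]) + 0.5)

    @property
    def y_positions(self) -> np.ndarray:
        px = self.config.pixel_size
        return self.y_origin + px * (np.arange(self.frames.shape[1]) + 0.5)


def _contour_deflection(
    x: np.ndarray, t: np.ndarray, rod: RodModel, drive: DriveProtocol, x_drive: float
) -> tuple:
    """Analytic deflection (m) on the rendering grid and the on-rod mask.

    ``x`` is (nx,), ``t`` broadcastable; returns deflection with shape
    t.shape + (nx,), NaN off the rod.
    """
    l_om = hydrodynamic_length(rod.kappa, rod.zeta, drive.omega)
    if drive.drive_point is DrivePoint.END:
        eta = (x - x_drive) / l_om
        on_rod = (eta >= 0) & (eta * l_om <= rod.contour_length)
        sol = end_driven_solution
    else:
        eta = np.abs(x - x_drive) / l_om
        on_rod = eta * l_om <= rod.contour_length / 2
        sol = middle_driven_solution
    t = np.asarray(t, dtype=float)
    defl = sol(eta[None, :], t.reshape(t.shape + (1,)), drive.amplitude, drive.omega)
    defl = np.where(on_rod[None, :], defl, np.nan)
    return defl, on_rod


def render_stack(
    rod: RodModel,
    drive: DriveProtocol,
    config: Optional[ImagingConfig] = None,
    x_drive: Optional[float] = None,
) -> FrameStack:
    """Render a seeded, truth-annotated stack of the driven bundle.

    The contour follows the steady-state analytic solution (recordings
    start after transients have died out, as in the experiment).  Raises
    :class:`ImagingError` when the field of view does not cover at least
    six hydrodynamic lengths beyond the drive point, since the decay could
    then not be measured.
    """
    config = config or ImagingConfig()
    ny, nx = config.shape
    px = config.pixel_size
    if x_drive is None:
        x_drive = 12 * px
    l_om = hydrodynamic_length(rod.kappa, rod.zeta, drive.omega)
    fov_beyond_drive = nx * px - x_drive if drive.drive_point is DrivePoint.END else (
        min(x_drive, nx * px - x_drive)
    )
    if fov_beyond_drive < 6 * l_om:
        raise ImagingError(
            f"field of view covers {fov_beyond_drive:.3g} m beyond the drive "
            f"point but the hydrodynamic length is l_omega={l_om:.3g} m; "
            "need >= 6 l_omega to resolve the decay"
        )

    n_frames = int(np.floor(drive.n_periods * drive.period / drive.frame_interval + 1e-9))
    x = px * (np.arange(nx) + 0.5)
    yrows = px * (np.arange(ny) + 0.5)
    y_center = yrows[ny // 2]

    nsub = config.exposure_subsamples
    t0 = drive.frame_interval * np.arange(n_frames)
    tsub = t0[:, None] + (np.arange(nsub)[None, :] + 0.5) * (drive.exposure / nsub)

    defl, on_rod = _contour_deflection(x, tsub.ravel(), rod, drive, x_drive)
    defl = defl.reshape(n_frames, nsub, nx)
    contour_y = y_center + defl  # (T, nsub, nx), NaN off rod

    sigma = config.psf_sigma
    peak = config.photons_per_pixel_peak
    bleach = np.exp(-config.bleach_rate * tsub)  # (T, nsub)

    bead_y = y_center + drive.displacement(tsub)  # (T, nsub)
    bead_x = x_drive
    rb2 = config.bead_radius**2
    bead_level = config.bead_brightness * peak

    frames = np.empty((n_frames, ny, nx), dtype=float)
    dy = yrows[:, None]  # (ny, 1)
    for i in range(n_frames):
        acc = np.zeros((ny, nx))
        for j in range(nsub):
            yc = contour_y[i, j]
            line = np.exp(-((dy - yc[None, :]) ** 2) / (2 * sigma**2))
            line = np.where(on_rod[None, :], line, 0.0)
            sub = peak * bleach[i, j] * line
            if config.bead_radius > 0:
                mask = (x[None, :] - bead_x) ** 2 + (dy - bead_y[i, j]) ** 2 <= rb2
                sub = np.where(mask, bead_level * bleach[i, j], sub)
            acc += sub
        frames[i] = config.background_level + acc / nsub

    rng = np.random.default_rng(config.rng_seed)
    if config.shot_noise:
        frames = rng.poisson(frames).astype(float)
    if config.read_noise_sd > 0:
        frames = frames + rng.normal(0.0, config.read_noise_sd, size=frames.shape)
    frames = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns off the rod are fine
        truth_y = y_center + np.nanmean(defl, axis=1)  # exposure-averaged contour
        truth = Kymograph(
            y=truth_y,
            x_positions=x,
            times=t0 + 0.5 * drive.exposure,
            excluded_columns=~on_rod,
        )

    return FrameStack(
        frames=frames,
        config=config,
        drive=drive,
        rod=rod,
        truth=truth,
        x_drive=bead_x,
        y_center=y_center,
    )


def write_stack(stack: FrameStack, path) -> Path:
    """Write a stack as multi-page 16-bit TIFF + JSON sidecar (+ truth CSV).

    ``path`` may end in ``.tif``/``.tiff`` or be a bare base name.  The
    sidecar ``<base>.json`` holds all calibration metadata; the optional
    ``<base>.truth.csv`` holds the ground-truth kymograph.  The round trip
    through :func:`read_stack` is lossless.
    """
    base = Path(path)
    if base.suffix.lower() in (".tif", ".tiff"):
        base = base.with_suffix("")
    tif_path = base.with_suffix(".tif")
    frames = stack.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(tif_path, frames, photometric="minisblack")

    meta = {
        "format": "bundlerheo-stack",
        "version": 1,
        "n_frames": int(stack.n_frames),
        "config": stack.config.to_dict(),
        "drive": stack.drive.to_dict(),
        "rod": stack.rod.to_dict() if stack.rod is not None else None,
        "x_drive": stack.x_drive,
        "y_center": stack.y_center,
        "x_origin": stack.x_origin,
        "y_origin": stack.y_origin,
        "has_truth": stack.truth is not None,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    if stack.truth is not None:
        _io.write_kymograph_csv(stack.truth, base.with_suffix(".truth.csv"))
    return tif_path


def read_stack(path) -> FrameStack:
    """Read a stack written by :func:`write_stack`."""
    base = Path(path)
    if base.suffix.lower() in (".tif", ".tiff"):
        base = base.with_suffix("")
    tif_path = base.with_suffix(".tif")
    json_path = base.with_suffix(".json")
    if not tif_path.exists():
        raise FileNotFoundError(f"missing image file {tif_path}")
    if not json_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {json_path}")
    try:
        meta = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise IOError(f"malformed metadata sidecar {json_path}: {exc}") from exc
    try:
        frames = tifffile.imread(tif_path)
    except Exception as exc:
        raise IOError(f"unreadable TIFF {tif_path}: {exc}") from exc
    frames = np.atleast_3d(frames)
    if frames.ndim != 3:
        frames = frames.reshape((1,) + frames.shape[-2:])
    expected = meta.get("n_frames")
    if expected is not None and frames.shape[0] != expected:
        raise IOError(
            f"truncated stack {tif_path}: expected {expected} frames, "
            f"read {frames.shape[0]} (failure at frame {frames.shape[0]})"
        )
    truth = None
    truth_path = base.with_suffix(".truth.csv")
    if meta.get("has_truth") and truth_path.exists():
        truth = _io.read_kymograph_csv(truth_path)
    rod = RodModel.from_dict(meta["rod"]) if meta.get("rod") else None
    return FrameStack(
        frames=frames,
        config=ImagingConfig.from_dict(meta["config"]),
        drive=DriveProtocol.from_dict(meta["drive"]),
        rod=rod,
        truth=truth,
        x_drive=meta["x_drive"],
        y_center=meta["y_center"],
        x_origin=meta.get("x_origin", 0.0),
        y_origin=meta.get("y_origin", 0.0),
    )
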