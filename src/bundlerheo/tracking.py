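"""Contour tracking: recover y(x, t) from image stacks.

The pipeline mirrors how driven-filament recordings are evaluated by hand:
rotate the deflection direction onto the image y-axis and crop to the band
of anticipated amplitudes, smooth mildly along x while emphasising
horizontal lines in y, then per column fit a parabola around the intensity
maximum and take its vertex as the subpixel contour position.  Columns in
the bead vicinity are excluded; ambiguous multi-peak columns are resolved
by temporal continuity (search near the previous frame's position).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
from scipy import ndimage

from .imaging import FrameStack
from .models import ImagingError, Kymograph

# Least-squares parabola design for a window of half-width h is fixed, so
# the pseudoinverse can be precomputed once per window size.
_PINV_CACHE: dict = {}


def _parabola_pinv(window: int) -> tuple:
    if window not in _PINV_CACHE:
        offs = np.arange(window) - window // 2
        design = np.vander(offs, 3, increasing=True).astype(float)  # 1, o, o^2
        _PINV_CACHE[window] = (offs, np.linalg.pinv(design), design)
    return _PINV_CACHE[window]


def _column_centroids(
    frame: np.ndarray,
    min_signal_frac: float = 0.2,
    column_mask: Optional[np.ndarray] = None,
) -> tuple:
    """Background-subtracted intensity centroid per column.

    Returns (column_indices, centroid_rows) for columns carrying contour
    signal; ``column_mask`` pre-excludes columns (e.g. the bead vicinity,
    whose brightness would otherwise dominate the signal threshold).
    """
    img = np.asarray(frame, dtype=float)
    bg = np.median(img)
    sig = np.clip(img - bg, 0.0, None)
    if column_mask is not None:
        sig = sig * column_mask[None, :]
    colsum = sig.sum(axis=0)
    good = colsum > min_signal_frac * np.median(colsum[colsum > 0]) if (colsum > 0).any() else colsum > 0
    if good.sum() < 2:
        raise ImagingError("no contour signal found in frame")
    rows = np.arange(img.shape[0])
    centroid = (sig[:, good] * rows[:, None]).sum(axis=0) / colsum[good]
    return np.flatnonzero(good), centroid


def estimate_rotation(
    frame: np.ndarray,
    min_signal_frac: float = 0.2,
    column_mask: Optional[np.ndarray] = None,
) -> float:
    """Contour tilt (rad) of a single frame from a linear fit to the
    column-wise intensity centroid, background-subtracted.

    Positive angles mean the contour rises with x (mathematically positive
    rotation in pixel coordinates with y as row index).
    """
    cols, centroid = _column_centroids(frame, min_signal_frac, column_mask)
    slope = np.polyfit(cols, centroid, 1)[0]
    return float(np.arctan(slope))


def preprocess(
    stack: FrameStack,
    rotation_angle: Optional[float] = None,
    crop_halfwidth: Optional[float] = None,
) -> FrameStack:
    """Rotate the deflection axis onto y and crop to the amplitude band.

    ``rotation_angle`` (rad) is the contour tilt to remove; when None it is
    estimated from the first frame (assumed closest to undisturbed or, for
    a driven recording, representative enough for small tilts).
    ``crop_halfwidth`` (m) keeps a band of rows around the contour's mean
    position; it must exceed the largest anticipated amplitude, and a band
    that would cut off the contour raises :class:`ImagingError`.
    Rotation uses bilinear interpolation about the image centre.
    """
    frames = stack.frames.astype(float)
    col_ok = (
        np.abs(stack.x_positions - stack.x_drive) > 2.0 * stack.config.bead_radius
    )
    if rotation_angle is None:
        rotation_angle = estimate_rotation(frames[0], column_mask=col_ok)
    if abs(rotation_angle) > 1e-12:
        deg = np.degrees(rotation_angle)
        rotated = np.empty_like(frames)
        for i, fr in enumerate(frames):
            # rotate by -angle so the contour becomes horizontal
            rotated[i] = ndimage.rotate(
                fr, deg, reshape=False, order=1, mode="nearest"
            )
        frames = np.clip(rotated, 0.0, None)

    y_origin = stack.y_origin
    if crop_halfwidth is not None:
        px = stack.config.pixel_size
        half_px = int(np.ceil(crop_halfwidth / px))
        _, centroid = _column_centroids(frames[0], column_mask=col_ok)
        center_row = int(round(np.median(centroid)))
        r0 = max(center_row - half_px, 0)
        r1 = min(center_row + half_px + 1, frames.shape[1])
        if np.any(centroid < r0 + 1) or np.any(centroid > r1 - 2):
            raise ImagingError(
                f"crop band rows [{r0}, {r1}) excludes part of the contour "
                f"(centroid range {centroid.min():.1f}..{centroid.max():.1f} px); "
                "increase crop_halfwidth"
            )
        frames = frames[:, r0:r1, :]
        y_origin = stack.y_origin + r0 * px

    return dataclasses.replace(stack, frames=frames, y_origin=y_origin)


def smooth_and_enhance(
    stack: FrameStack,
    sigma_x_px: float = 1.0,
    sigma_y_px: float = 1.0,
    enhance_weight: float = 1.0,
) -> FrameStack:
    """Gaussian smoothing along x plus a horizontal-line-enhancing filter.

    The enhancement subtracts the y second derivative of a Gaussian-blurred
    copy (scaled by sigma_y^2), which boosts ridges running along x while
    suppressing slowly varying background; intensities are clamped at zero.
    """
    frames = stack.frames.astype(float)
    ny, nx = frames.shape[1:]
    if sigma_x_px * 4 > nx or sigma_y_px * 4 > ny:
        raise ValueError(
            f"smoothing kernel (sigma_x={sigma_x_px}, sigma_y={sigma_y_px} px) "
            f"too wide for {ny}x{nx} frames"
        )
    out = ndimage.gaussian_filter1d(frames, sigma_x_px, axis=2, mode="nearest")
    if enhance_weight > 0 and sigma_y_px > 0:
        ridge = -ndimage.gaussian_filter1d(out, sigma_y_px, axis=1, order=2, mode="nearest")
        out = out + enhance_weight * sigma_y_px**2 * ridge
    out = np.clip(out, 0.0, None)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite intensities after filtering")
    return dataclasses.replace(stack, frames=out)


def _fit_columns(
    frames_t: np.ndarray,
    peak_idx: np.ndarray,
    window: int,
    baseline: Optional[np.ndarray] = None,
    log_profile: bool = True,
) -> tuple:
    """Vectorised parabola vertex fit around per-column peak indices.

    ``frames_t`` is (ny, nx); returns (vertex_row, quality, curvature_ok).
    With ``log_profile`` the parabola is fitted to the logarithm of the
    baseline-subtracted intensities, which is exact for a Gaussian line
    profile and removes the pull-toward-integer bias a plain quadratic
    shows on sharp peaks; quality is still reported on the intensity scale.
    """
    ny, nx = frames_t.shape
    offs, pinv, design = _parabola_pinv(window)
    half = window // 2
    centers = np.clip(peak_idx, half, ny - 1 - half)
    rows = centers[None, :] + offs[:, None]  # (window, nx)
    vals = frames_t[rows, np.arange(nx)[None, :]]  # (window, nx)
    if baseline is not None:
        vals = vals - baseline[None, :]
    peak_height = vals.max(axis=0) - vals.min(axis=0)
    if log_profile:
        floor = np.maximum(0.01 * vals.max(axis=0), 1e-12)
        fit_vals = np.log(np.maximum(vals, floor[None, :]))
    else:
        fit_vals = vals
    coef = pinv @ fit_vals  # (3, nx): c0 + c1*o + c2*o^2
    c0, c1, c2 = coef
    with np.errstate(divide="ignore", invalid="ignore"):
        off = -c1 / (2.0 * c2)
    ok = (c2 < 0) & np.isfinite(off) & (np.abs(off) <= half + 0.5)
    vertex = centers + off
    pred = design @ coef
    resid = (np.exp(pred) if log_profile else pred) - vals
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        quality = np.sqrt(np.mean(resid**2, axis=0)) / np.where(
            peak_height > 0, peak_height, np.nan
        )
    return vertex, quality, ok


def fit_deflection(
    column_profile: np.ndarray,
    window: int = 5,
    min_peak_height: float = 5.0,
    min_peak_snr: float = 4.0,
    log_profile: bool = True,
) -> tuple:
    """Subpixel contour position in one intensity column.

    Fits a parabola over ``window`` pixels around the discrete argmax
    (by default to the log of the background-subtracted profile, exact for
    a Gaussian line) and returns ``(vertex_row_px, quality)``; ``quality``
    is the fit residual RMS relative to the peak height.  A column without
    a detectable peak (below ``min_peak_height`` counts and
    ``min_peak_snr`` robust noise units above the median) returns
    ``(nan, nan)`` rather than fabricating a position.
    """
    prof = np.asarray(column_profile, dtype=float)
    if prof.ndim != 1:
        raise ValueError("column_profile must be 1-D")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > prof.size:
        raise ValueError(f"window {window} exceeds column height {prof.size}")
    bg = np.median(prof)
    noise = 1.4826 * np.median(np.abs(prof - bg))
    peak_idx = int(np.argmax(prof))
    if prof[peak_idx] - bg < max(min_peak_height, min_peak_snr * noise):
        return float("nan"), float("nan")
    vertex, quality, ok = _fit_columns(
        prof[:, None], np.array([peak_idx]), window,
        baseline=np.array([bg]), log_profile=log_profile,
    )
    if not ok[0]:
        return float("nan"), float("nan")
    return float(vertex[0]), float(quality[0])


def track(
    stack: FrameStack,
    window: int = 5,
    search_halfwidth_px: int = 10,
    bead_exclusion_radii: float = 2.0,
    min_peak_height: float = 5.0,
    min_peak_snr: float = 4.0,
    max_failed_fraction: float = 0.5,
    log_profile: bool = True,
) -> Kymograph:
    """Track the contour through a (preprocessed) stack.

    Per frame and column the intensity peak is located — globally in the
    first frame, within ``search_halfwidth_px`` of the previous frame's
    position afterwards (temporal continuity resolves multi-peak columns)
    — and refined to subpixel precision by the parabola fit.  Columns
    within ``bead_exclusion_radii`` bead radii of the drive point are
    excluded; frames whose failed-column fraction exceeds
    ``max_failed_fraction`` are flagged in ``bad_frames``.
    """
    frames = stack.frames.astype(float)
    nt, ny, nx = frames.shape
    px = stack.config.pixel_size

    x = stack.x_positions
    excluded = np.abs(x - stack.x_drive) <= bead_exclusion_radii * stack.config.bead_radius

    y_px = np.full((nt, nx), np.nan)
    quality = np.full((nt, nx), np.nan)
    prev = None

    cols = np.arange(nx)
    for i in range(nt):
        fr = frames[i]
        bg = np.median(fr, axis=0)
        noise = 1.4826 * np.median(np.abs(fr - bg[None, :]), axis=0)
        if prev is None:
            peak_idx = np.argmax(fr, axis=0)
        else:
            centers = np.where(np.isfinite(prev), prev, ny / 2).astype(int)
            lo = np.clip(centers - search_halfwidth_px, 0, ny - 1)
            hi = np.clip(centers + search_halfwidth_px + 1, 1, ny)
            span = int((hi - lo).max())
            rows = np.minimum(lo[None, :] + np.arange(span)[:, None], hi[None, :] - 1)
            windowed = fr[rows, cols[None, :]]
            peak_idx = rows[np.argmax(windowed, axis=0), cols]
        height = fr[peak_idx, cols] - bg
        detected = height >= np.maximum(min_peak_height, min_peak_snr * noise)
        vertex, qual, ok = _fit_columns(
            fr, peak_idx, window, baseline=bg, log_profile=log_profile
        )
        valid = detected & ok & ~excluded
        y_px[i, valid] = vertex[valid]
        quality[i, valid] = qual[valid]
        prev_candidate = np.where(valid, vertex, prev if prev is not None else np.nan)
        prev = prev_candidate

    tracked_any = np.isfinite(y_px).any(axis=0)
    considered = ~excluded & tracked_any
    with np.errstate(invalid="ignore"):
        failed_frac = 1.0 - np.mean(np.isfinite(y_px[:, considered]), axis=1)
    bad_frames = failed_frac > max_failed_fraction
    if bad_frames.any():
        warnings.warn(
            f"{int(bad_frames.sum())} of {nt} frames had more than "
            f"{max_failed_fraction:.0%} failed columns",
            stacklevel=2,
        )

    y_m = stack.y_origin + (y_px + 0.5) * px
    return Kymograph(
        y=y_m,
        x_positions=x,
        times=stack.mid_times,
        quality=quality,
        excluded_columns=excluded,
        bad_frames=bad_frames,
    )
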