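"""Particle detection and subpixel PSF fitting on ratiometric frames.

Candidate particles are highlighted with a Laplacian-of-Gaussian (LoG)
filter, sign-normalised so that the dark dips of particles give positive
peaks; strict local maxima above a threshold become candidates, and each
candidate's 13 x 13 px surrounding is fitted with the model PSF (a
symmetric 2-D Gaussian of fixed width) to extract the subpixel position
and the contrast dip magnitude.

The detection threshold may be stated in mass units: a mass in kDa is
converted via the calibration line to a contrast, and then to the
filtered-image response a noise-free PSF of that contrast would produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .massmap import CalibrationModel
from .video import RatiometricVideo

__all__ = [
    "Detection",
    "log_filter",
    "unit_log_response",
    "mass_threshold_to_filter_units",
    "candidate_pixels",
    "fit_psf",
    "detect_frame",
    "detect_video",
]

DEFAULT_PSF_SIGMA_PX = 1.4
DEFAULT_ROI_HALF = 5  # 11 x 11 px region of interest
DEFAULT_THRESHOLD_KDA = 53.0


@dataclass
class Detection:
    """One fitted particle in one frame."""

    frame: int
    x: float
    y: float
    contrast: float  # dip magnitude, > 0
    fit_residual: float  # r.m.s. of the PSF fit over the ROI
    candidate_peak: float  # LoG response at the candidate pixel


def log_filter(frame: np.ndarray, sigma_px: float = DEFAULT_PSF_SIGMA_PX) -> np.ndarray:
    """Laplacian-of-Gaussian response with particle dips as positive peaks.

    ``scipy.ndimage.gaussian_laplace`` yields a positive response at the
    centre of a negative-amplitude blob, so no extra sign flip is needed;
    the filter is linear, so the peak response scales with contrast.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    return ndimage.gaussian_laplace(np.asarray(frame, dtype=float), sigma_px)


def _psf_patch(contrast: float, sigma_px: float, half: int) -> np.ndarray:
    rr = np.arange(-half, half + 1)[:, None]
    cc = np.arange(-half, half + 1)[None, :]
    return -contrast * np.exp(-(rr**2 + cc**2) / (2.0 * sigma_px**2))


def unit_log_response(sigma_px: float = DEFAULT_PSF_SIGMA_PX) -> float:
    """Peak LoG response of a noise-free unit-contrast model PSF."""
    half = int(np.ceil(8 * sigma_px)) + 1
    patch = _psf_patch(1.0, sigma_px, half)
    return float(log_filter(patch, sigma_px).max())


def mass_threshold_to_filter_units(
    mass_kda: float,
    calibration: CalibrationModel,
    sigma_px: float = DEFAULT_PSF_SIGMA_PX,
) -> float:
    """Filtered-image threshold equivalent to a mass cut-off.

    The calibration line converts the mass to a contrast; the threshold
    is the LoG peak a noise-free PSF of that contrast would produce.
    """
    if calibration is None:
        raise ValueError("a calibration model is required for a mass threshold")
    contrast = float(calibration.mass_to_contrast(mass_kda))
    return contrast * unit_log_response(sigma_px)


def candidate_pixels(
    filtered: np.ndarray,
    threshold: float,
    min_separation_px: float | None = None,
    sigma_px: float = DEFAULT_PSF_SIGMA_PX,
) -> list[tuple[int, int]]:
    """Strict local maxima of the filtered image above a threshold.

    Maxima closer than ``min_separation_px`` (default 2 sigma) are merged
    keeping the stronger; ties break deterministically by (row, col).
    """
    if min_separation_px is None:
        min_separation_px = 2.0 * sigma_px
    local_max = filtered == ndimage.maximum_filter(filtered, size=3, mode="nearest")
    # border pixels lack a full 3x3 neighbourhood (and edge filtering
    # inflates their variance); they cannot seed candidates
    local_max[0, :] = local_max[-1, :] = False
    local_max[:, 0] = local_max[:, -1] = False
    rows, cols = np.nonzero(local_max & (filtered > threshold))
    if rows.size == 0:
        return []
    vals = filtered[rows, cols]
    order = np.lexsort((cols, rows, -vals))  # strongest first, then (row, col)
    accepted: list[tuple[int, int]] = []
    for k in order:
        r, c = int(rows[k]), int(cols[k])
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_separation_px**2
               for ar, ac in accepted):
            accepted.append((r, c))
    accepted.sort()
    return accepted


def fit_psf(
    frame: np.ndarray,
    candidate: tuple[int, int],
    frame_index: int = 0,
    sigma_px: float = DEFAULT_PSF_SIGMA_PX,
    roi_half: int = DEFAULT_ROI_HALF,
    fit_offset: bool = True,
    candidate_peak: float = np.nan,
    min_edge_px: int = 2,
) -> Detection | None:
    """Least-squares fit of the model PSF around a candidate pixel.

    Fits amplitude, subpixel (x, y) and optionally a local offset of a
    negative 2-D Gaussian of fixed width.  The ROI is cropped at the
    frame border so that particles near the edge (down to
    ``min_edge_px`` from it) remain fittable; this keeps the usable
    detection area large, which matters for fast particles in a narrow
    field of view.  Returns ``None`` for candidates closer than
    ``min_edge_px`` to the border, non-converged fits, or fits with an
    amplitude of the wrong sign.
    """
    r0, c0 = candidate
    h, w = frame.shape
    if not (min_edge_px <= r0 < h - min_edge_px
            and min_edge_px <= c0 < w - min_edge_px):
        return None
    r_lo, r_hi = max(0, r0 - roi_half), min(h, r0 + roi_half + 1)
    c_lo, c_hi = max(0, c0 - roi_half), min(w, c0 + roi_half + 1)
    roi = np.asarray(frame[r_lo:r_hi, c_lo:c_hi], dtype=float)
    rr = (np.arange(r_lo, r_hi) - r0)[:, None]
    cc = (np.arange(c_lo, c_hi) - c0)[None, :]

    med = float(np.median(roi))
    a0 = max(med - float(roi.min()), 1e-8)

    def residuals(p):
        if fit_offset:
            a, x, y, off = p
        else:
            a, x, y = p
            off = 0.0
        model = off - a * np.exp(-((cc - x) ** 2 + (rr - y) ** 2)
                                 / (2.0 * sigma_px**2))
        return (model - roi).ravel()

    p0 = [a0, 0.0, 0.0, med] if fit_offset else [a0, 0.0, 0.0]
    try:
        res = optimize.least_squares(residuals, p0, method="lm", max_nfev=200)
    except Exception:
        return None
    if not res.success and res.status <= 0:
        return None
    a, x, y = res.x[0], res.x[1], res.x[2]
    if a <= 0:
        return None
    if abs(x) > roi_half or abs(y) > roi_half:
        return None
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return Detection(frame=frame_index, x=float(c0 + x), y=float(r0 + y),
                     contrast=float(a), fit_residual=rms,
                     candidate_peak=float(candidate_peak))


def detect_frame(
    frame: np.ndarray,
    frame_index: int = 0,
    threshold: float | None = None,
    threshold_kda: float | None = DEFAULT_THRESHOLD_KDA,
    calibration: CalibrationModel | None = None,
    sigma_px: float = DEFAULT_PSF_SIGMA_PX,
    roi_half: int = DEFAULT_ROI_HALF,
) -> list[Detection]:
    """LoG filter, thresholding and PSF fitting of a single frame."""
    if threshold is None:
        threshold = mass_threshold_to_filter_units(threshold_kda, calibration,
                                                   sigma_px)
    filtered = log_filter(frame, sigma_px)
    out = []
    for r, c in candidate_pixels(filtered, threshold, sigma_px=sigma_px):
        det = fit_psf(frame, (r, c), frame_index=frame_index, sigma_px=sigma_px,
                      roi_half=roi_half, candidate_peak=filtered[r, c])
        if det is not None:
            out.append(det)
    return out


def detect_video(
    video: RatiometricVideo,
    threshold: float | None = None,
    threshold_kda: float | None = DEFAULT_THRESHOLD_KDA,
    calibration: CalibrationModel | None = None,
    sigma_px: float = DEFAULT_PSF_SIGMA_PX,
    roi_half: int = DEFAULT_ROI_HALF,
) -> pd.DataFrame:
    """Detections for every frame of a ratiometric video.

    Frame indices in the output refer to the *raw* video (offset by the
    median half-window), so downstream tables align with acquisition
    time.  Columns: frame, x, y, contrast, residual, candidate_peak.
    """
    if threshold is None:
        threshold = mass_threshold_to_filter_units(threshold_kda, calibration,
                                                   sigma_px)
    rows = []
    for i in range(video.n_frames):
        for det in detect_frame(video.frames[i], frame_index=i + video.frame_offset,
                                threshold=threshold, sigma_px=sigma_px,
                                roi_half=roi_half):
            rows.append((det.frame, det.x, det.y, det.contrast,
                         det.fit_residual, det.candidate_peak))
    return pd.DataFrame(rows, columns=["frame", "x", "y", "contrast",
                                       "residual", "candidate_peak"])
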