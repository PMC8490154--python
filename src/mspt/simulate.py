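"""Synthetic iSCAT video generation with known ground truth.

Brownian trajectories are generated on an area four times the field of
view (both axes extended twofold) with periodic boundaries, so the number
of particles in the simulation area is conserved.  Per-axis per-frame
displacements are Gaussian with standard deviation sqrt(2 D dt) (the
2-D Brownian propagator, consistent with the 4 D dt scale of the
jump-distance model used downstream).  In-FOV positions are rendered as
negative-going 2-D Gaussian point spread functions of a set ratiometric
contrast, and the contrast stack is merged with a background video of
linear camera counts via

    counts_out = (contrast + 1) * counts_background

so that dividing by the background and subtracting one recovers the
ratiometric frames exactly.

The FOV occupies ``[0, W) x [0, H)`` in pixel coordinates; the extended
simulation area is ``[-W/2, 3W/2) x [-H/2, 3H/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .video import CameraVideo, RatiometricVideo

__all__ = [
    "SimulationConfig",
    "GroundTruthTrack",
    "gen_trajectories",
    "render_ratiometric_video",
    "synthesize_camera_video",
    "gen_background",
    "gen_landing_events",
    "gen_mass_trace",
    "tracks_to_table",
]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic video run.

    Defaults mirror a fourfold pixel-binned (84.4 nm), fivefold
    frame-averaged (200 Hz, i.e. 5 ms frame time) acquisition with a
    128 x 35 px field of view (31.9 um^2).
    """

    fov_px: tuple = (128, 35)  # (width, height)
    pixel_size_nm: float = 84.4
    frame_time_s: float = 0.005
    n_frames: int = 1000
    n_particles: int | None = None
    particle_density_um2: float | None = None  # per um^2 of the *extended* area
    psf_sigma_px: float = 1.4
    photon_level: float = 1.3e6
    seed: int | None = None

    def __post_init__(self) -> None:
        w, h = self.fov_px
        if w <= 0 or h <= 0:
            raise ValueError("fov_px must be positive")
        for name in ("pixel_size_nm", "frame_time_s", "psf_sigma_px", "photon_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be a positive integer")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def fov_area_um2(self) -> float:
        w, h = self.fov_px
        return w * h * self.pixel_size_um**2

    @property
    def extended_area_um2(self) -> float:
        return 4.0 * self.fov_area_um2

    def resolve_n_particles(self) -> int:
        if self.n_particles is not None:
            return int(self.n_particles)
        if self.particle_density_um2 is not None:
            return max(1, round(self.particle_density_um2 * self.extended_area_um2))
        raise ValueError("set n_particles or particle_density_um2")


@dataclass
class GroundTruthTrack:
    """One simulated particle: positions in extended-area pixel coordinates."""

    particle_id: int
    frames: np.ndarray  # frame indices
    x_px: np.ndarray
    y_px: np.ndarray
    contrast: float  # dip magnitude, > 0
    d_true_um2s: float

    def __post_init__(self) -> None:
        if self.contrast <= 0:
            raise ValueError("contrast must be a positive dip magnitude")


def gen_trajectories(
    config: SimulationConfig,
    d_um2s: float | Sequence[float],
    seed: int | None = None,
    contrast: float | Sequence[float] = 3.5e-3,
) -> list[GroundTruthTrack]:
    """Simulate Brownian tracks on the 4x extended area with periodic wrap.

    ``d_um2s`` and ``contrast`` may be scalars (shared) or per-particle
    sequences.  Per-axis per-frame steps are drawn from N(0, 2 D dt) with
    D converted to pixel units.
    """
    n = config.resolve_n_particles()
    d_arr = np.broadcast_to(np.asarray(d_um2s, dtype=float), (n,)).copy()
    c_arr = np.broadcast_to(np.asarray(contrast, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(d_arr)) or np.any(d_arr < 0):
        raise ValueError("diffusion coefficients must be finite and >= 0")
    if np.any(c_arr <= 0):
        raise ValueError("contrast must be > 0")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    w, h = config.fov_px
    # extended area: both axes doubled, FOV centered
    x_lo, x_hi = -w / 2.0, 3.0 * w / 2.0
    y_lo, y_hi = -h / 2.0, 3.0 * h / 2.0

    step_sd_px = np.sqrt(2.0 * d_arr * config.frame_time_s) / config.pixel_size_um

    x0 = rng.uniform(x_lo, x_hi, size=n)
    y0 = rng.uniform(y_lo, y_hi, size=n)
    steps_x = rng.standard_normal((config.n_frames - 1, n)) * step_sd_px
    steps_y = rng.standard_normal((config.n_frames - 1, n)) * step_sd_px
    x = np.vstack([x0, x0 + np.cumsum(steps_x, axis=0)])
    y = np.vstack([y0, y0 + np.cumsum(steps_y, axis=0)])
    # periodic wrap onto the extended area
    x = (x - x_lo) % (x_hi - x_lo) + x_lo
    y = (y - y_lo) % (y_hi - y_lo) + y_lo

    frames = np.arange(config.n_frames)
    return [
        GroundTruthTrack(i, frames.copy(), x[:, i].copy(), y[:, i].copy(),
                         float(c_arr[i]), float(d_arr[i]))
        for i in range(n)
    ]


def _add_psf(frame: np.ndarray, x: float, y: float, amplitude: float,
             sigma: float) -> None:
    """Add a negative Gaussian dip of the given dip magnitude in place."""
    h, w = frame.shape
    half = int(np.ceil(6 * sigma))
    c0, r0 = int(round(x)), int(round(y))
    r_lo, r_hi = max(0, r0 - half), min(h, r0 + half + 1)
    c_lo, c_hi = max(0, c0 - half), min(w, c0 + half + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr = np.arange(r_lo, r_hi)[:, None] - y
    cc = np.arange(c_lo, c_hi)[None, :] - x
    frame[r_lo:r_hi, c_lo:c_hi] -= amplitude * np.exp(
        -(rr**2 + cc**2) / (2.0 * sigma**2)
    )


def render_ratiometric_video(
    tracks: Sequence[GroundTruthTrack], config: SimulationConfig
) -> RatiometricVideo:
    """Render tracks as negative Gaussian PSFs on an otherwise zero stack.

    Only coordinates whose PSF overlaps the FOV contribute; overlapping
    PSFs add linearly.
    """
    w, h = config.fov_px
    if 6 * config.psf_sigma_px > min(w, h):
        raise ValueError("PSF support wider than the field of view")
    stack = np.zeros((config.n_frames, h, w), dtype=float)
    margin = 6 * config.psf_sigma_px
    for tr in tracks:
        if len(tr.frames) != config.n_frames:
            raise ValueError("tracks must be defined for every frame")
        visible = (
            (tr.x_px > -margin) & (tr.x_px < w + margin)
            & (tr.y_px > -margin) & (tr.y_px < h + margin)
        )
        for f in np.nonzero(visible)[0]:
            _add_psf(stack[f], tr.x_px[f], tr.y_px[f], tr.contrast,
                     config.psf_sigma_px)
    return RatiometricVideo(
        stack, half_window=0, frame_offset=0,
        pixel_size_nm=config.pixel_size_nm, frame_time_s=config.frame_time_s,
    )


def synthesize_camera_video(
    ratiometric: RatiometricVideo, background: CameraVideo
) -> CameraVideo:
    """Merge a contrast stack with a background: (contrast + 1) * counts."""
    if ratiometric.frames.shape != background.frames.shape:
        raise ValueError(
            f"shape mismatch: ratiometric {ratiometric.frames.shape} vs "
            f"background {background.frames.shape}"
        )
    counts = (ratiometric.frames + 1.0) * background.frames
    return CameraVideo(counts, pixel_size_nm=background.pixel_size_nm,
                       frame_time_s=background.frame_time_s)


def gen_background(
    config: SimulationConfig,
    seed: int | None = None,
    fixed_pattern: np.ndarray | None = None,
    noise_free: bool = False,
) -> CameraVideo:
    """Synthetic empty-bilayer background: i.i.d. Poisson counts.

    Mean counts per pixel are ``photon_level``, optionally modulated by a
    static multiplicative ``fixed_pattern`` (emulating residual sample
    roughness).  Relative shot noise per pixel is ~1/sqrt(photon_level).
    With ``noise_free=True`` the stack is the (constant) mean itself.
    """
    if config.photon_level <= 0:
        raise ValueError("photon_level must be > 0")
    w, h = config.fov_px
    mean = np.full((h, w), float(config.photon_level))
    if fixed_pattern is not None:
        fixed_pattern = np.asarray(fixed_pattern, dtype=float)
        if fixed_pattern.shape != (h, w):
            raise ValueError("fixed_pattern shape must match the FOV")
        if np.any(fixed_pattern <= 0):
            raise ValueError("fixed_pattern must be strictly positive")
        mean = mean * fixed_pattern
    if noise_free:
        frames = np.broadcast_to(mean, (config.n_frames, h, w)).copy()
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        frames = rng.poisson(mean, size=(config.n_frames, h, w)).astype(float)
    return CameraVideo(frames, pixel_size_nm=config.pixel_size_nm,
                       frame_time_s=config.frame_time_s)


def gen_landing_events(
    config: SimulationConfig,
    n_events: int,
    min_separation_px: float = 12.0,
    min_separation_frames: int = 26,
    contrast: float = 3.5e-3,
    seed: int | None = None,
    edge_margin_px: float = 7.0,
    max_tries: int = 10000,
) -> list[GroundTruthTrack]:
    """Immobile landing events at random frames and positions.

    Each event appears at a random frame and stays put until the end of
    the video.  A candidate is redrawn if it is both closer than
    ``min_separation_px`` spatially AND closer than
    ``min_separation_frames`` temporally to an already accepted event
    (events well separated in either coordinate may coexist).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    w, h = config.fov_px
    placed: list[tuple[float, float, int]] = []
    for _ in range(n_events):
        for attempt in range(max_tries):
            x = rng.uniform(edge_margin_px, w - edge_margin_px)
            y = rng.uniform(edge_margin_px, h - edge_margin_px)
            f = int(rng.integers(0, config.n_frames))
            ok = all(
                np.hypot(x - px, y - py) >= min_separation_px
                or abs(f - pf) >= min_separation_frames
                for px, py, pf in placed
            )
            if ok:
                placed.append((x, y, f))
                break
        else:
            raise RuntimeError(
                f"could not place event {len(placed)} within {max_tries} tries; "
                "constraints may be unsatisfiable for this FOV"
            )
    tracks = []
    for i, (x, y, f) in enumerate(placed):
        frames = np.arange(config.n_frames)
        xs = np.where(frames >= f, x, 1e9)  # far outside FOV before landing
        ys = np.where(frames >= f, y, 1e9)
        tr = GroundTruthTrack(i, frames, xs.astype(float), ys.astype(float),
                              float(contrast), 0.0)
        tr.landing_frame = f  # type: ignore[attr-defined]
        tracks.append(tr)
    return tracks


def gen_mass_trace(
    plateau_masses_kda: Sequence[float],
    plateau_lengths: Sequence[int],
    noise_sd_kda: float,
    seed: int | None = None,
) -> np.ndarray:
    """Piecewise-constant mass time series with i.i.d. Gaussian frame noise.

    The default downstream noise scale of interest is ~28 kDa s.d. per
    frame (single-frame mass uncertainty in the calibrated regime).
    """
    masses = np.asarray(plateau_masses_kda, dtype=float)
    lengths = np.asarray(plateau_lengths, dtype=int)
    if masses.shape != lengths.shape or masses.ndim != 1:
        raise ValueError("plateau_masses and plateau_lengths must be equal-length 1-D")
    if np.any(lengths < 1):
        raise ValueError("plateau lengths must be >= 1")
    if noise_sd_kda < 0:
        raise ValueError("noise_sd must be non-negative")
    trace = np.repeat(masses, lengths).astype(float)
    if noise_sd_kda > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd_kda, size=trace.size)
    return trace


def tracks_to_table(tracks: Sequence[GroundTruthTrack]):
    """Ground-truth tracks as a tidy DataFrame (one row per frame)."""
    import pandas as pd

    rows = []
    for tr in tracks:
        rows.append(pd.DataFrame({
            "particle_id": tr.particle_id,
            "frame": tr.frames,
            "x_px": tr.x_px,
            "y_px": tr.y_px,
            "contrast": tr.contrast,
            "D_true": tr.d_true_um2s,
        }))
    return pd.concat(rows, ignore_index=True)
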