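"""End-to-end analysis: camera video -> trajectories -> masses and diffusion.

Chains the ratiometric background removal, PSF detection, trajectory
linking/filtering and per-trajectory summaries into one call, carrying a
single serialisable parameter set so every output can be reproduced from
its config.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import background as bg
from . import detect as det
from . import diffusion as diff
from . import track as trk
from .massmap import CalibrationModel
from .video import CameraVideo, RatiometricVideo

__all__ = ["RunConfig", "PipelineResult", "analyze_video", "fit_trajectory_diffusion"]


@dataclass
class RunConfig:
    """All analysis parameters of a pipeline run (fully serialisable)."""

    half_window: int | None = None  # None -> recommend from expected_d
    expected_d_um2s: float = 1.0
    psf_sigma_px: float = det.DEFAULT_PSF_SIGMA_PX
    threshold_kda: float = det.DEFAULT_THRESHOLD_KDA
    search_range_px: float | None = None  # None -> 4x rms frame jump
    memory_frames: int = trk.DEFAULT_MEMORY_FRAMES
    min_length: int = trk.DEFAULT_MIN_LENGTH
    max_lag: int = diff.MAX_LAG
    fov_area_um2: float | None = None  # None -> from video geometry
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


@dataclass
class PipelineResult:
    ratiometric: RatiometricVideo
    detections: pd.DataFrame
    linked: pd.DataFrame
    summary: pd.DataFrame
    config: RunConfig
    counts: dict = field(default_factory=dict)  # in/out bookkeeping per stage


def analyze_video(
    video: CameraVideo,
    calibration: CalibrationModel,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Full MSPT chain on one camera video.

    Background removal uses the configured median half-window (or the
    displacement-based recommendation for ``expected_d_um2s``); detection
    thresholds at ``threshold_kda`` via the calibration line; linking and
    the minimum-length filter produce the trajectory table, which is
    summarised with median contrast/mass, density and censoring flags.
    """
    cfg = config or RunConfig()
    n = cfg.half_window or bg.recommend_half_window(
        cfg.expected_d_um2s, cfg.psf_sigma_px, video.pixel_size_nm,
        video.frame_time_s)
    ratio = bg.ratiometric_video(video, n)
    detections = det.detect_video(
        ratio, threshold_kda=cfg.threshold_kda, calibration=calibration,
        sigma_px=cfg.psf_sigma_px)
    search_range = cfg.search_range_px
    if search_range is None:
        # 4x the rms single-frame 2-D jump keeps the displacement tail
        # (the jump-distance fit needs it) without promiscuous linking
        rms_jump_px = np.sqrt(4.0 * cfg.expected_d_um2s * video.frame_time_s) \
            / video.pixel_size_um
        search_range = max(trk.DEFAULT_SEARCH_RANGE_PX, 4.0 * rms_jump_px)
    linked = trk.link(detections, search_range, cfg.memory_frames)
    filtered, removed_frac = trk.filter_min_length(linked, cfg.min_length)
    fov_area = cfg.fov_area_um2
    if fov_area is None:
        _, h, w = video.frames.shape
        fov_area = h * w * video.pixel_size_um**2
    first = n
    last = video.n_frames - 1 - n
    summary = trk.summarize_trajectories(
        filtered, calibration=calibration, fov_area_um2=fov_area,
        first_frame=first, last_frame=last)
    counts = {
        "localizations": int(len(detections)),
        "linked_trajectories": int(linked["particle"].nunique()) if len(linked) else 0,
        "trajectories_after_length_filter": int(summary.shape[0]),
        "length_filter_removed_fraction": float(removed_frac),
    }
    return PipelineResult(ratio, detections, filtered, summary, cfg, counts)


def fit_trajectory_diffusion(
    linked: pd.DataFrame,
    pixel_size_um: float,
    frame_time_s: float,
    max_lag: int = diff.MAX_LAG,
) -> pd.DataFrame:
    """Jump-distance diffusion fit for every trajectory in a linked table."""
    rows = []
    for pid, g in linked.sort_values("frame").groupby("particle"):
        if len(g) <= 1:
            continue
        fit = diff.fit_jump_distance(
            g["x"].to_numpy(), g["y"].to_numpy(), pixel_size_um, frame_time_s,
            max_lag=max_lag, frames=g["frame"].to_numpy())
        rows.append({
            "particle": pid, "model": fit.model, "D1": fit.d1_um2s,
            "a1": fit.a1, "D2": fit.d2_um2s, "a2": fit.a2,
            "sigma": fit.sigma_offset_um2, "D_eff": fit.d_eff_um2s,
            "reduced_chi2_one": fit.reduced_chi2_one,
            "reduced_chi2_two": fit.reduced_chi2_two,
            "excluded": fit.excluded, "excluded_reason": fit.excluded_reason,
        })
    return pd.DataFrame(rows)
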