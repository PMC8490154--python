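"""Core video containers.

A camera video is a 3-D stack of linear camera counts (frame, row, col)
with the physical metadata needed to convert pixels and frames into
micrometres and seconds.  A ratiometric video is the background-corrected
"mobile features" stack: dimensionless contrast values that fluctuate
around zero wherever no particle is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CameraVideo:
    """Raw (or synthetic) iSCAT video in linear camera counts.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Linear camera counts, non-negative.
    pixel_size_nm : float
        Effective pixel size in nanometres (after any binning).
    frame_time_s : float
        Effective frame time in seconds (after any averaging).
    """

    frames: np.ndarray
    pixel_size_nm: float = 84.4
    frame_time_s: float = 0.005

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (frame, row, col) stack")
        if self.pixel_size_nm <= 0 or self.frame_time_s <= 0:
            raise ValueError("pixel_size_nm and frame_time_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0


@dataclass
class RatiometricVideo:
    """Background-corrected contrast stack.

    ``frames[i]`` corresponds to raw frame ``i + frame_offset`` of the
    video it was computed from; ``half_window`` is the median half-size n
    used for the background estimate (the valid range of the raw video is
    [n, N-1-n]).
    """

    frames: np.ndarray
    half_window: int = 0
    frame_offset: int = 0
    pixel_size_nm: float = 84.4
    frame_time_s: float = 0.005

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (frame, row, col) stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0
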