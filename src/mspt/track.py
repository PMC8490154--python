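"""Trajectory linking and per-trajectory summaries.

Detections are linked frame to frame by globally optimal nearest-neighbour
assignment (minimum total squared displacement, solved with the Hungarian
algorithm); links beyond the search range are forbidden, and a particle
may be missed for up to ``memory`` frames and still be re-linked.

Each surviving trajectory is summarised with its median contrast (mass
via the calibration line) and annotated with the apparent particle
density on the membrane: the median number of concurrently detected
trajectories during its lifetime divided by the FOV area (31.9 um^2 for
the default configuration).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .massmap import CalibrationModel

__all__ = [
    "link",
    "filter_min_length",
    "annotate_density",
    "density_bin",
    "summarize_trajectories",
    "flag_censored",
]

DEFAULT_SEARCH_RANGE_PX = 5.0
DEFAULT_MEMORY_FRAMES = 1
DEFAULT_MIN_LENGTH = 5
DEFAULT_FOV_AREA_UM2 = 31.9


def link(
    detections: pd.DataFrame,
    search_range_px: float = DEFAULT_SEARCH_RANGE_PX,
    memory_frames: int = DEFAULT_MEMORY_FRAMES,
) -> pd.DataFrame:
    """Assign a ``particle`` id to every detection.

    Frame-to-frame matching minimises total squared displacement subject
    to a hard search-range cut; unmatched detections seed new particles.
    A lost particle stays eligible for re-linking for ``memory_frames``
    missed frames (same search range).
    """
    if search_range_px <= 0:
        raise ValueError("search_range_px must be positive")
    df = detections.sort_values(["frame", "y", "x"], kind="mergesort").reset_index(drop=True)
    n = len(df)
    particle = np.full(n, -1, dtype=int)
    if n == 0:
        out = df.copy()
        out["particle"] = particle
        return out

    frames = df["frame"].to_numpy()
    xs = df["x"].to_numpy()
    ys = df["y"].to_numpy()
    next_id = 0
    # active particles: id -> (x, y, last_frame)
    active: dict[int, tuple[float, float, int]] = {}
    big = 1e12

    for f in np.unique(frames):
        idx = np.nonzero(frames == f)[0]
        # drop particles lost longer than memory
        active = {pid: s for pid, s in active.items()
                  if f - s[2] <= memory_frames + 1}
        pids = sorted(active)
        if pids and idx.size:
            ax = np.array([active[p][0] for p in pids])
            ay = np.array([active[p][1] for p in pids])
            cost = ((xs[idx][:, None] - ax[None, :]) ** 2
                    + (ys[idx][:, None] - ay[None, :]) ** 2)
            cost = np.where(cost <= search_range_px**2, cost, big)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < big:
                    particle[idx[r]] = pids[c]
        for k in idx:
            if particle[k] < 0:
                particle[k] = next_id
                next_id += 1
            active[particle[k]] = (xs[k], ys[k], int(f))

    out = df.copy()
    out["particle"] = particle
    return out


def filter_min_length(
    linked: pd.DataFrame, min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[pd.DataFrame, float]:
    """Drop trajectories shorter than ``min_length`` frames (inclusive keep).

    Returns the filtered table and the fraction of trajectories removed.
    """
    if linked.empty:
        return linked.copy(), 0.0
    sizes = linked.groupby("particle")["frame"].size()
    keep = sizes.index[sizes >= min_length]
    removed_frac = 1.0 - len(keep) / len(sizes)
    return linked[linked["particle"].isin(keep)].copy(), float(removed_frac)


def _concurrent_counts(linked: pd.DataFrame) -> pd.Series:
    """Number of distinct trajectories detected in each frame."""
    return linked.groupby("frame")["particle"].nunique()


def annotate_density(
    linked: pd.DataFrame, fov_area_um2: float = DEFAULT_FOV_AREA_UM2
) -> pd.DataFrame:
    """Per-trajectory apparent density: median concurrent count / FOV area.

    Adds columns ``median_count`` and ``density_um2`` to the trajectory
    summary produced by :func:`summarize_trajectories`; here it returns
    a per-particle frame-median over the count of concurrently detected
    trajectories.
    """
    if fov_area_um2 <= 0:
        raise ValueError("fov_area_um2 must be positive")
    counts = _concurrent_counts(linked)
    per_frame = linked["frame"].map(counts)
    med = per_frame.groupby(linked["particle"]).median()
    out = pd.DataFrame({
        "particle": med.index,
        "median_count": med.to_numpy(),
        "density_um2": med.to_numpy() / fov_area_um2,
    }).reset_index(drop=True)
    return out


def density_bin(
    summary: pd.DataFrame, center_count: float, half_width: float = 2.0
) -> pd.DataFrame:
    """Trajectories whose median concurrent count is center +/- half_width.

    Bins are inclusive and may overlap across sliding centres, so pooling
    e.g. centre 4 with half-width 2 selects counts 2..6.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    lo, hi = center_count - half_width, center_count + half_width
    sel = (summary["median_count"] >= lo) & (summary["median_count"] <= hi)
    return summary[sel].copy()


def flag_censored(linked: pd.DataFrame, first_frame: int, last_frame: int) -> pd.Series:
    """True for trajectories touching the first or last valid frame.

    A trajectory that starts on the first (or ends on the last) frame of
    the valid ratiometric range may have been cut off by the recording,
    so its final plateau cannot be read as a genuine membrane release.
    """
    g = linked.groupby("particle")["frame"]
    return (g.min() == first_frame) | (g.max() == last_frame)


def summarize_trajectories(
    linked: pd.DataFrame,
    calibration: CalibrationModel | None = None,
    fov_area_um2: float = DEFAULT_FOV_AREA_UM2,
    first_frame: int | None = None,
    last_frame: int | None = None,
) -> pd.DataFrame:
    """Per-trajectory summary: length, median contrast/mass, density, censoring."""
    if linked.empty:
        return pd.DataFrame(columns=["particle", "length", "median_contrast",
                                     "mass_kda", "median_count", "density_um2",
                                     "censored"])
    g = linked.groupby("particle")
    summary = pd.DataFrame({
        "particle": np.array(sorted(g.groups)),
        "length": g["frame"].size().to_numpy(),
        "median_contrast": g["contrast"].median().to_numpy(),
    })
    if calibration is not None:
        summary["mass_kda"] = calibration.contrast_to_mass(
            summary["median_contrast"].to_numpy())
    dens = annotate_density(linked, fov_area_um2)
    summary = summary.merge(dens, on="particle")
    if first_frame is None:
        first_frame = int(linked["frame"].min())
    if last_frame is None:
        last_frame = int(linked["frame"].max())
    cens = flag_censored(linked, first_frame, last_frame)
    summary["censored"] = summary["particle"].map(cens).fillna(False).astype(bool)
    return summary
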