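"""Contrast-to-mass calibration and mass-distribution analysis.

iSCAT contrast scales linearly with molecular mass, so a set of standard
proteins with known masses defines an affine calibration line

    contrast = slope * mass + intercept

fitted by ordinary least squares (a forced-through-origin variant is
available).  Peak contrasts of the standards are located on 1-D kernel
density estimates; their standard errors come from bootstrap resampling
of the underlying contrast values (default 10,000 resamples).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .kde import DensityEstimate1D, isj_bandwidth, kde1d, kde2d  # noqa: F401

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "find_peaks",
    "bootstrap_peak_se",
    "kde1d",
    "kde2d",
]

PEAK_PROMINENCE_FRAC = 0.05  # of the density maximum; suppresses bandwidth ripple


@dataclass
class CalibrationModel:
    """Affine contrast-mass calibration line."""

    slope: float  # contrast per kDa
    intercept: float = 0.0  # contrast
    se_slope: float = float("nan")
    se_intercept: float = float("nan")
    standards: list = field(default_factory=list)  # (peak_contrast, mass_kDa)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def contrast_to_mass(self, contrast):
        """Invert the line: mass in kDa from a contrast dip magnitude."""
        return (np.asarray(contrast, dtype=float) - self.intercept) / self.slope

    def mass_to_contrast(self, mass_kda):
        return self.slope * np.asarray(mass_kda, dtype=float) + self.intercept

    def to_json(self, path) -> None:
        payload = {
            "slope": self.slope, "intercept": self.intercept,
            "se_slope": self.se_slope, "se_intercept": self.se_intercept,
            "standards": [list(map(float, s)) for s in self.standards],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{**payload,
                      "standards": [tuple(s) for s in payload["standards"]]})


def fit_calibration(standards, through_origin: bool = False) -> CalibrationModel:
    """OLS line through (mass_kDa, peak_contrast) standard points.

    ``standards`` is a sequence of ``(peak_contrast, nominal_mass_kDa)``
    pairs; at least two distinct masses are required.
    """
    standards = [(float(c), float(m)) for c, m in standards]
    contrast = np.array([c for c, _ in standards])
    mass = np.array([m for _, m in standards])
    if np.unique(mass).size < 2:
        raise ValueError("need at least 2 standards with distinct masses")
    if through_origin:
        slope = float(np.sum(contrast * mass) / np.sum(mass**2))
        resid = contrast - slope * mass
        dof = max(mass.size - 1, 1)
        se_slope = float(np.sqrt(np.sum(resid**2) / dof / np.sum(mass**2)))
        return CalibrationModel(slope, 0.0, se_slope, 0.0, standards)
    res = stats.linregress(mass, contrast)
    return CalibrationModel(float(res.slope), float(res.intercept),
                            float(res.stderr), float(res.intercept_stderr),
                            standards)


def find_peaks(
    density: DensityEstimate1D,
    prominence_frac: float = PEAK_PROMINENCE_FRAC,
    select: str = "all",
) -> np.ndarray:
    """Locations of density maxima above a relative prominence floor.

    ``select`` implements the standard-protein conventions: ``"all"``
    (sorted by location), ``"highest"`` (only the largest-location peak,
    used when a standard shows two peaks and the higher-contrast one is
    the calibrant) or ``"drop_lowest"`` (discard the smallest-location
    peak, e.g. free streptavidin in streptavidin-conjugate standards).
    """
    y = density.density
    idx, _ = signal.find_peaks(y, prominence=prominence_frac * y.max())
    if idx.size == 0 and y.size:
        # plateau-free unimodal densities always have an interior argmax
        amax = int(np.argmax(y))
        if 0 < amax < y.size - 1:
            idx = np.array([amax])
    locs = np.sort(density.grid[idx])
    if select == "all":
        return locs
    if select == "highest":
        return locs[-1:]
    if select == "drop_lowest":
        return locs[1:]
    raise ValueError(f"unknown select mode {select!r}")


def bootstrap_peak_se(
    values,
    n_boot: int = 10000,
    seed: int | None = None,
    prominence_frac: float = PEAK_PROMINENCE_FRAC,
    unstable_frac: float = 0.2,
):
    """Standard error of KDE peak locations by bootstrap resampling.

    Resamples the values with replacement, recomputes the KDE (bandwidth
    included) and its peaks, and matches each resampled peak to the
    nearest original peak.  Returns ``(peak_locations, se, unstable)``
    where ``unstable[j]`` flags peaks missing in more than
    ``unstable_frac`` of the resamples.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    base = kde1d(x)
    peaks = find_peaks(base, prominence_frac)
    if peaks.size == 0:
        raise ValueError("no peaks found in the original density")
    rng = np.random.default_rng(seed)
    hits: list[list[float]] = [[] for _ in peaks]
    for _ in range(n_boot):
        sample = rng.choice(x, size=x.size, replace=True)
        try:
            est = kde1d(sample)
        except ValueError:  # pragma: no cover - degenerate resample
            continue
        locs = find_peaks(est, prominence_frac)
        if locs.size == 0:
            continue
        # match each original peak to its nearest resampled peak, one-to-one
        for j, p in enumerate(peaks):
            k = int(np.argmin(np.abs(locs - p)))
            # only accept if this original peak is also the nearest to locs[k]
            if int(np.argmin(np.abs(peaks - locs[k]))) == j:
                hits[j].append(locs[k])
    se = np.array([np.std(h) if len(h) > 1 else np.nan for h in hits])
    unstable = np.array([len(h) < (1.0 - unstable_frac) * n_boot for h in hits])
    return peaks, se, unstable
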