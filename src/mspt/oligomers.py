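"""Oligomer deconvolution of density-binned mass distributions.

Observed mass KDEs of a mixed population are fitted with a non-negative
linear combination of monomer-to-hexamer component distributions.  The
components are not analytic: they are measured by running the full
simulate -> background -> detect -> track -> mass pipeline on synthetic
videos containing a single oligomer species at a matched particle
density, so that density-dependent artefacts (PSF overlap inflating
apparent masses) are built into the component shapes.  Component
distributions are smoothed with a 2.5-kDa moving average before fitting,
and the component contributions are constrained to sum to one in the
least-squares sense (an appended penalty equation, weight 10x the data
scale).  Uncertainties come from random three-way splits of the
trajectory masses, fitted per split, repeated ten times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kde import kde1d
from .massmap import CalibrationModel
from .pipeline import RunConfig, analyze_video
from .simulate import (SimulationConfig, gen_background, gen_trajectories,
                       render_ratiometric_video, synthesize_camera_video)

__all__ = [
    "ComponentLibrary",
    "build_component_library",
    "component_distribution",
    "deconvolve",
    "abundance_uncertainty",
]

SMOOTHING_WINDOW_KDA = 2.5
UNITY_WEIGHT_FACTOR = 10.0
DEFAULT_N_SPLITS = 3
DEFAULT_N_REPEATS = 10


def moving_average_kda(values: np.ndarray, grid: np.ndarray,
                       window_kda: float = SMOOTHING_WINDOW_KDA) -> np.ndarray:
    """Boxcar smoothing with a window expressed in kDa on a regular grid."""
    step = grid[1] - grid[0]
    w = max(int(round(window_kda / step)), 1)
    kernel = np.ones(w) / w
    return np.convolve(values, kernel, mode="same")


@dataclass
class ComponentLibrary:
    """Single-species mass distributions per oligomer order and density."""

    grid_kda: np.ndarray
    components: dict  # order -> {density -> distribution on grid}
    monomer_mass_kda: float
    smoothing_window_kda: float = SMOOTHING_WINDOW_KDA

    @property
    def orders(self) -> list[int]:
        return sorted(self.components)

    def densities(self, order: int) -> list[float]:
        return sorted(self.components[order])

    def nearest_density(self, density: float) -> float:
        ds = np.array(self.densities(self.orders[0]))
        return float(ds[np.argmin(np.abs(ds - density))])

    def matrix(self, density: float) -> np.ndarray:
        """Design matrix (grid x orders) at the nearest library density."""
        d = self.nearest_density(density)
        return np.column_stack([self.components[o][d] for o in self.orders])


def component_distribution(
    masses_kda: np.ndarray,
    grid_kda: np.ndarray,
    window_kda: float = SMOOTHING_WINDOW_KDA,
) -> np.ndarray:
    """Normalised, smoothed mass distribution of one species on a grid."""
    est = kde1d(masses_kda, grid=grid_kda)
    smoothed = moving_average_kda(est.density, grid_kda, window_kda)
    area = np.trapezoid(smoothed, grid_kda)
    if area <= 0:
        raise ValueError("degenerate component distribution")
    return smoothed / area


def build_component_library(
    monomer_mass_kda: float,
    calibration: CalibrationModel,
    densities_um2,
    orders=range(1, 7),
    sim_config: SimulationConfig | None = None,
    run_config: RunConfig | None = None,
    grid_kda: np.ndarray | None = None,
    seed: int = 0,
) -> ComponentLibrary:
    """Measure component shapes from single-species simulated videos.

    For every (order, density): simulate identical-mass particles whose
    contrast is the calibration image of order x monomer mass, run the
    full analysis pipeline, and KDE the per-trajectory median masses.
    Densities are per um^2 of the extended simulation area, i.e. the
    nominal membrane coverage.
    """
    base = sim_config or SimulationConfig()
    if run_config is None:
        # the default 53-kDa mass threshold would reject monomers outright;
        # component shapes need every order measurable, so the library build
        # detects down to 30 kDa (still ~3.5 sigma of the LoG noise floor at
        # the default photon level)
        run_config = RunConfig(threshold_kda=30.0)
    if grid_kda is None:
        top = (max(orders) + 2) * monomer_mass_kda
        grid_kda = np.linspace(-monomer_mass_kda, top, 1024)
    components: dict[int, dict[float, np.ndarray]] = {}
    rng = np.random.default_rng(seed)
    for order in orders:
        mass = order * monomer_mass_kda
        contrast = float(calibration.mass_to_contrast(mass))
        per_density = {}
        for density in densities_um2:
            # faint species (monomers near the noise floor) yield few
            # trajectories; extend the video until the KDE is estimable
            masses = None
            for scale in (1, 2, 4):
                cfg = SimulationConfig(
                    fov_px=base.fov_px, pixel_size_nm=base.pixel_size_nm,
                    frame_time_s=base.frame_time_s,
                    n_frames=base.n_frames * scale,
                    particle_density_um2=density,
                    psf_sigma_px=base.psf_sigma_px,
                    photon_level=base.photon_level,
                    seed=int(rng.integers(1 << 31)))
                try:
                    masses = _single_species_masses(cfg, contrast,
                                                    calibration, run_config)
                    break
                except RuntimeError:
                    continue
            if masses is None:
                raise RuntimeError(
                    f"component (order={order}, density={density}) yielded "
                    "too few trajectories even at 4x video length")
            per_density[float(density)] = component_distribution(
                masses, grid_kda)
        components[int(order)] = per_density
    return ComponentLibrary(grid_kda, components, monomer_mass_kda)


def _single_species_masses(cfg: SimulationConfig, contrast: float,
                           calibration: CalibrationModel,
                           run_config: RunConfig | None) -> np.ndarray:
    tracks = gen_trajectories(cfg, d_um2s=1.0, contrast=contrast)
    ratio = render_ratiometric_video(tracks, cfg)
    backg = gen_background(cfg, seed=(cfg.seed or 0) + 1)
    video = synthesize_camera_video(ratio, backg)
    res = analyze_video(video, calibration, run_config)
    masses = res.summary["mass_kda"].to_numpy()
    if masses.size < 30:
        raise RuntimeError("component simulation yielded too few trajectories")
    return masses


def deconvolve(
    density_on_grid: np.ndarray,
    library: ComponentLibrary,
    density_um2: float,
    unity_weight_factor: float = UNITY_WEIGHT_FACTOR,
):
    """Non-negative least-squares mixture fit with a soft sum-to-one row.

    Returns ``(abundances, residual_norm)``; abundances are normalised to
    sum to exactly one after the soft-constrained fit.  An ill-conditioned
    design (strongly collinear components) triggers a warning carrying
    the condition number.
    """
    from scipy.optimize import nnls

    y = np.asarray(density_on_grid, dtype=float)
    A = library.matrix(density_um2)
    if y.shape[0] != A.shape[0]:
        raise ValueError("density must be evaluated on the library grid")
    cond = np.linalg.cond(A)
    if cond > 1e8:
        import warnings

        warnings.warn(f"component design is ill-conditioned (cond={cond:.3g})",
                      stacklevel=2)
    w = unity_weight_factor * max(np.max(np.abs(A)), 1e-30)
    A_aug = np.vstack([A, w * np.ones((1, A.shape[1]))])
    y_aug = np.concatenate([y, [w]])
    coef, rnorm = nnls(A_aug, y_aug)
    total = coef.sum()
    if total <= 0:
        raise ValueError("deconvolution returned an all-zero mixture")
    return coef / total, float(rnorm)


def abundance_uncertainty(
    trajectory_masses_kda: np.ndarray,
    library: ComponentLibrary,
    density_um2: float,
    n_splits: int = DEFAULT_N_SPLITS,
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int | None = None,
    min_per_split: int = 10,
) -> np.ndarray:
    """Average per-split standard deviation of the fitted abundances.

    The trajectory masses are randomly split into ``n_splits`` samples,
    each split is fitted individually, and the standard deviation of the
    per-split abundances is averaged over ``n_repeats`` repetitions.
    """
    masses = np.asarray(trajectory_masses_kda, dtype=float)
    masses = masses[np.isfinite(masses)]
    if masses.size < n_splits * min_per_split:
        raise ValueError(
            f"need at least {n_splits * min_per_split} trajectories for "
            f"{n_splits}-way split uncertainty")
    rng = np.random.default_rng(seed)
    n_orders = len(library.orders)
    sds = np.empty((n_repeats, n_orders))
    for r in range(n_repeats):
        perm = rng.permutation(masses.size)
        parts = np.array_split(perm, n_splits)
        ab = np.empty((n_splits, n_orders))
        for s, part in enumerate(parts):
            dens = component_distribution(masses[part], library.grid_kda,
                                          library.smoothing_window_kda)
            ab[s], _ = deconvolve(dens, library, density_um2)
        sds[r] = ab.std(axis=0, ddof=1)
    return sds.mean(axis=0)
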