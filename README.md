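# mspt — mass-sensitive particle tracking for iSCAT microscopy

Interferometric scattering (iSCAT) microscopy detects single unlabelled
biomolecules through the interference of scattered and reflected light:
a particle appears as a dark spot whose ratiometric contrast,
`c = signal/background − 1`, scales linearly with molecular mass.
Conventional mass photometry exploits this for molecules *landing* on
glass. `mspt` implements the extension to molecules *diffusing* on
supported lipid bilayers — mass-sensitive particle tracking — where the
landing-assay background strategy fails because moving particles smear
into dark fronts with bright tails.

The package is for biophysicists who want to measure, from raw iSCAT
video of a membrane: the mass of each diffusing complex, its diffusion
coefficient, its membrane residence time, and the subunit
attachment/detachment events along its path. It provides:

- **Background removal**: sliding pixel-wise temporal median, frame by
  frame — `frame_i / median(frame_{i−n}:frame_{i+n}) − 1` — leaving
  moving PSFs undistorted on a shot-noise-limited background.
- **Detection and mass**: Laplacian-of-Gaussian candidates with a
  mass-denominated threshold, subpixel PSF fits, affine contrast↔mass
  calibration from standards, KDE mass distributions (Improved
  Sheather–Jones bandwidth) with bootstrap peak errors, and 2-D
  mass–log₁₀D maps.
- **Tracking and diffusion**: globally optimal nearest-neighbour
  linking, jump-distance CDF fits `P(r², Δt) = 1 − Σ aᵢ exp(−r²/(4DᵢΔt+σ))`
  over lags Δ1–Δ4 with one/two-component selection by reduced χ², an MSD
  fallback, and Evans–Sackmann inversion of D into a membrane inclusion
  radius.
- **Step kinetics**: consensus Kalafut–Visscher change-point detection
  (subsets of l = 1000 frames, all circular shifts, consensus fraction
  f = 0.25), plateau classification into attachment / detachment /
  release, and mode-anchored mean dwell times with bootstrap errors.
- **Oligomer deconvolution**: density-binned mass distributions fitted
  by non-negative mixtures of monomer–hexamer components that are
  measured by running single-species simulations through the full
  pipeline.
- **A simulator** generating iSCAT videos with known ground truth
  (Brownian tracks on a 4× extended area with periodic boundaries,
  Gaussian PSF rendering, Poisson backgrounds, landing events, mass
  traces) — every stage above is validated against it.

## Worked example

Simulate a 66-kDa species diffusing at 1 µm² s⁻¹ on a 128×35-px field
of view (84.4 nm pixels, 5 ms frames) and analyse it blind:

```python
import numpy as np
from mspt.massmap import fit_calibration
from mspt.pipeline import RunConfig, analyze_video, fit_trajectory_diffusion
from mspt.simulate import (SimulationConfig, gen_background, gen_trajectories,
                           render_ratiometric_video, synthesize_camera_video)

cal = fit_calibration([(1.9e-3, 33.0), (3.5e-3, 66.0)])
print(f"calibration: contrast = {cal.slope:.3e} * mass + {cal.intercept:.1e}")

cfg = SimulationConfig(n_frames=1000, particle_density_um2=0.1, seed=8)
tracks = gen_trajectories(cfg, d_um2s=1.0, contrast=3.5e-3)
video = synthesize_camera_video(render_ratiometric_video(tracks, cfg),
                                gen_background(cfg, seed=9))

result = analyze_video(video, cal, RunConfig(expected_d_um2s=1.0))
dtab = fit_trajectory_diffusion(result.linked, video.pixel_size_um,
                                video.frame_time_s)
good = dtab[~dtab["excluded"]]
print(f"localizations: {result.counts['localizations']}, "
      f"trajectories kept: {len(result.summary)}")
print(f"median mass: {result.summary['mass_kda'].median():.1f} kDa (truth 66)")
print(f"median D: {np.median(good['D_eff']):.2f} um^2/s (truth 1.0)")
```

prints

```
calibration: contrast = 4.848e-05 * mass + 3.0e-04
localizations: 2558, trajectories kept: 105
median mass: 64.4 kDa (truth 66)
median D: 0.88 um^2/s (truth 1.0)
```

The calibration line passes through the two standards (slope
4.85·10⁻⁵ per kDa). Of the 2558 single-frame localizations, 105
trajectories survive linking and the 5-frame minimum length; their
median mass (64.4 kDa) and median diffusion coefficient (0.88 µm² s⁻¹)
recover the ground truth to within the few-percent systematics of the
median background method (see `docs/methods.md`).

Inverting the Evans–Sackmann membrane hydrodynamic model turns diffusion
coefficients into inclusion sizes:

```python
from mspt.diffusion import invert_inclusion_size
invert_inclusion_size(0.85)   # -> 5.0 nm
invert_inclusion_size(0.34)   # -> 9.0 nm
```

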