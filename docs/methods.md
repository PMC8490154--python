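# Methods

`mspt` implements mass-sensitive particle tracking (MSPT): detection,
tracking and mass quantification of unlabelled biomolecules diffusing on
supported lipid bilayers (SLBs), imaged by interferometric scattering
(iSCAT) microscopy. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## Ratiometric background removal

An iSCAT frame is dominated by the static scattering background; a
single biomolecule adds a dark point-spread function (PSF) whose dip
magnitude ("contrast") is proportional to molecular mass. For each
frame *i* the background estimate is the pixel-wise temporal median over
frames *i−n* … *i+n*, and the mobile-features frame is

    contrast_i = frame_i / median(frame_{i−n} : frame_{i+n}) − 1.

Static structure cancels exactly; a particle that moves far enough
during the median period survives as an undistorted negative dip on a
shot-noise-limited background. Output frames exist only where the full
window fits (`N − 2n` frames, offset by `n`). The implementation is
bit-identical to a naive per-pixel sorted median (odd windows, middle
order statistic), which the tests assert.

**Choosing the half-window n.** `recommend_half_window` returns the
smallest *n* with `sqrt(4 D n Δt) ≥ k σ_psf`, i.e.
`n = ceil((k σ_psf)² / (4 D Δt))`, capped at 150. The default `k = 8`
is an empirical calibration on simulated videos: a diffusing particle
leaves a shallow, wide halo in the median along its path, and for
`k = 3` (the particle merely clears one PSF width) the halo depresses
recovered contrast by ≈13%. With `k = 8` the residual contrast bias is
2–3% and the diffusion bias from halo-induced position pulling stays
small. Immobile particles cannot be separated by a temporal median at
all; `D = 0` is rejected explicitly.

## Detection and PSF fitting

Frames are filtered with a Laplacian-of-Gaussian (σ = PSF width);
particle dips give positive peaks. Strict interior local maxima above a
threshold become candidates; peaks closer than 2σ merge, the stronger
wins. A threshold stated in mass units is converted through the
calibration line to a contrast, then to the LoG peak response a
noise-free PSF of that contrast would produce (default cut-off 53 kDa).

Each candidate's surrounding region is fitted by least squares with the
model PSF — a symmetric 2-D Gaussian of fixed σ (default 1.4 px) with
free amplitude, subpixel centre and a local additive offset. The
simulator renders the identical model, so simulator→fitter round trips
are exact by construction; the tests exploit this. Two non-obvious
choices:

- **ROI 11×11 px (roi_half = 5), cropped at frame borders.** A larger
  ROI lets the median-halo gradient pull fitted positions toward the
  locally averaged path, which deflates frame-to-frame displacements
  (D biased −10% and worse). Cropping at borders keeps particles down
  to 2 px from the edge fittable, which widens the usable field of view;
  without it, trajectories are censored the moment particles approach
  the edge, and the conditioning of surviving tracks on small
  displacements biases D low — the dominant error for fast particles in
  the 35-px-tall field of view.
- **Offset term.** The fitted local offset absorbs the (near-uniform
  within the small ROI) halo level; fitting without it transfers halo
  depth into amplitude.

## Trajectory linking

Frame-to-frame assignment minimises total squared displacement
(Hungarian algorithm) with a hard search-range cut; unmatched detections
seed new trajectories, and a lost particle may re-link for up to
`memory = 1` missed frame. The pipeline's default search range is
`max(5 px, 4 × sqrt(4 D Δt) / pixel)` using the expected diffusion
coefficient — a fixed 5 px truncates the displacement tail of fast
particles and visibly biases the jump-distance fit. Trajectories
shorter than 5 frames are discarded (inclusive boundary: 5 frames
survive).

Each trajectory is annotated with its apparent particle density: the
median, over its lifetime, of the number of concurrently detected
trajectories, divided by the FOV area (31.9 µm² for 128×35 px at
84.4 nm). Density bins are inclusive and overlap (centre ± 2
trajectories). Trajectories touching the first or last valid frame are
flagged censored; their final plateau is not a membrane release.

## Diffusion coefficients

Squared displacements at lags of 1–4 frames (overlapping pairs, paired
by true frame difference so that memory gaps never masquerade as short
lags) form empirical CDFs that are fitted globally with

    P1c(r², Δt) = 1 − exp(−r² / (4 D Δt + σ)),
    P2c(r², Δt) = 1 − Σ_i a_i exp(−r² / (4 D_i Δt + σ)),  Σ a_i = 1,

with the offset σ unconstrained and shared across lags (it absorbs
localisation error and motion blur). Both models are fitted; the
two-component model is selected only if it improves the reduced χ² by at
least 5% (guarding against overfitting), and then reports
`D_eff = a₁D₁ + a₂D₂`. Diffusion coefficients are bounded below at
10⁻⁴ µm² s⁻¹; fits on the bound are flagged and excluded. An MSD
fallback regresses the first 3 (trajectories under 10 frames) or 4
time-averaged MSD points on `4 D Δt·lag + offset` and carries a relative
residual as a ballistic-motion diagnostic.

**Membrane inclusion size.** The Evans–Sackmann model for a cylinder of
radius *a* in a membrane of surface viscosity η_m·h over a support with
friction b_s,

    D = k_B T / (4π η_m h) · [ε²/4 + ε K₁(ε)/K₀(ε)]⁻¹,  ε = a √(b_s/(η_m h)),

is evaluated with exponentially scaled Bessel functions (stable for
large ε) and inverted by bracketed root finding (D is monotone in a).
The default parameters, η_m·h = 3.676·10⁻¹¹ Pa·s·m and
b_s = 3.128·10⁷ Pa·s·m⁻¹ at 296 K, were fixed once by solving the two
anchor points (D = 0.85 µm²/s ↔ a = 5 nm, D = 0.34 µm²/s ↔ a = 9 nm)
for a DOPC-like bilayer on glass; both are overridable with literature
values.

## Mass analysis

**Calibration.** Contrast is affine in mass: `c = slope·m + intercept`,
ordinary least squares over standards (a through-origin variant exists).
The intercept is retained because the data do not force the line through
zero and the inverse map must be affine-safe.

**KDE.** 1-D densities use a Gaussian kernel with the Improved
Sheather–Jones plug-in bandwidth (Botev fixed point on a DCT of the
binned data; Silverman fallback if the fixed point cannot be
bracketed), evaluated by linear-binned convolution on a 2¹⁰-point grid
padded 3 bandwidths beyond the data. Peaks are density maxima above a
5% relative-prominence floor (suppressing bandwidth ripple), with
selectors for the standard-protein conventions (keep the
highest-contrast peak; drop the lowest, e.g. free streptavidin). Peak
standard errors come from bootstrap resampling (default 10,000) with
bandwidth recomputed per resample and peaks matched one-to-one by
nearest location; peaks missing in over 20% of resamples are flagged
unstable. 2-D mass–diffusion maps use a product Gaussian kernel with
per-axis ISJ bandwidths on a 2⁸×2⁸ grid, the diffusion axis in base-10
log space; marginals are sums of the joint along each axis.

## Time-resolved mass steps

Per-frame masses along a trajectory form a noisy piecewise-constant
series. Change points are found by the Kalafut–Visscher scheme: greedy
insertion of the split that most reduces the residual sum of squares,
accepted while it lowers the Bayesian information criterion of a
piecewise-constant Gaussian model with pooled variance. This package
counts 2k+2 free parameters for k change points (each step contributes a
location *and* a mean), i.e. a 2 ln N penalty per step; with the
textbook k+2 count the false-positive rate on pure noise of length 200
is ~33%, with 2k+2 it is ~2%. After insertion converges, a
deterministic refinement pass re-localises each change point to the
optimal split between its neighbours and removes any whose removal
lowers the criterion — greedy insertion cannot revise earlier choices,
and without this pass displaced first insertions survive as spurious
steps.

Because raw KV is sensitive to series length and to points near series
boundaries, traces are concatenated (sorted by id), cut into subsets of
length l = 1000, and analysed at every one of the l circular shifts of
the cut positions. Subsets are *not* pre-split at trajectory joints:
the joints appear to KV as ordinary mass jumps and are discarded
afterwards (accepted positions within ±1 frame of a joint are dropped) —
keeping the full subset length is what gives the BIC penalty its
intended strength. A change point is accepted where the fraction of
iterations reporting it within ±1 frame reaches f = 0.25.

Plateaus between accepted steps are classified by the sign of the
following mass change (attachment/detachment); the last plateau is the
membrane release unless the trajectory is censored. The initial binding
mass is not a step. Dwell-time averages use the mode-anchored mean
`t̄ = Σ N_i t_i / Σ N_i − t_mode` with dwells under 5 frames excluded and
bootstrap (10,000 resamples of the plateau list) standard errors.
Species windows for dwell statistics default to 66 ± 17 kDa (dimer) and
132 ± 17 kDa (tetramer), inclusive edges.

At the reference conditions (66-kDa steps, 28-kDa frame noise,
plateaus of 60–100 frames) the consensus procedure recovers ≳95% of
steps within ±2 frames with ≲5% spurious. Note an irreducible limit:
the maximum-likelihood change-point location at this step-to-noise ratio
falls more than 2 frames from the truth ~3% of the time, which bounds
any detector's apparent spurious rate under a ±2-frame matching rule.

## Oligomer deconvolution

Mass distributions of density-binned trajectory populations are fitted
with a non-negative linear combination of monomer–hexamer component
distributions. Components are *measured*, not assumed: for each order
and particle density, a single-species video is simulated and pushed
through the full pipeline, and the per-trajectory median masses are
KDE'd onto a common grid, smoothed with a 2.5-kDa moving average and
normalised. This bakes density-dependent artefacts (PSF overlap
inflating apparent masses) into the component shapes. The library build
detects down to 30 kDa (the standard 53-kDa cut would reject monomers
outright) and extends the video up to 4× if a faint species yields too
few trajectories. The sum-to-one constraint is enforced in the
least-squares sense — an appended penalty row with weight 10× the data
scale — and the result is renormalised to sum to exactly one.
Uncertainties: the trajectory masses are split randomly into 3 samples,
each fitted separately; the per-split standard deviation is averaged
over 10 repetitions.

## The simulator and what the tests show

`mspt.simulate` is the validation engine. Brownian tracks start
uniformly on an area four times the field of view (both axes doubled,
FOV centred) with periodic boundaries, so particle number is conserved;
per-axis per-frame steps are Gaussian with s.d. `sqrt(2 D Δt)` — the
2-D Brownian propagator consistent with the `4 D Δt` scale of the
jump-distance model. In-FOV coordinates are rendered as negative
Gaussian PSFs (σ = 1.4 px); overlaps add. The contrast stack merges
with a background via `(contrast + 1) × counts`, whose algebraic inverse
is exact.

Backgrounds are i.i.d. Poisson counts (optionally with a static
multiplicative fixed pattern emulating sample roughness) at a default
`photon_level` of 1.3·10⁶ counts/pixel — the full-well budget of a
4×4-binned, 5-frame-averaged CMOS acquisition. This level places the
53-kDa threshold at ≈5.7σ of the LoG noise floor, a 66-kDa dimer at ≈7σ
and a 33-kDa monomer at ≈3.8σ, reproducing the regime in which dimers
are detected far more reliably than monomers. Mass-trace fixtures for
the step module impose 28-kDa per-frame noise directly.

What the synthetic tests do *not* show: real iSCAT backgrounds have
spatially correlated residuals, drift and vibration that i.i.d. Poisson
noise lacks; the vendor PSF is not a symmetric Gaussian; real particles
blur during the 5-ms exposure. Biases measured here (2–3% contrast
deficit from the median halo, D deficits up to ~10% at 3 µm² s⁻¹ from
in-view censoring) are therefore lower bounds on real-data systematics,
and the loss of localisations to linking and length filtering depends
strongly on how far the species sits above the detection threshold
(~7% for a 7σ species, 25–55% near the threshold).

## Default problem sizes

End-to-end validation uses 2000-frame 128×35-px videos at 0.1 µm⁻²
(≈13 particles on the extended area), the component library 600-frame
videos per order, and the step benchmark 60 three-plateau traces —
sizes at which the recovered medians are stable to a few percent while
a full validation run completes in minutes on one core.
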