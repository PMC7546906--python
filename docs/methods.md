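# Methods

This note documents the models, parameter choices and numerical
conventions behind `cortexflow`, and what the synthetic-data tests do and
do not demonstrate about real cortical movies.

## Synthetic cortical movies

The generator emulates spinning-disk cortical acquisitions of punctate
actomyosin reporters: Gaussian spots (σ = 1.3 px, diffraction-limited at
the 34.1/192 ≈ 0.178 μm pixel size) at a density of 1.5 particles/μm²,
one frame every 5 s, Poisson shot noise on a mean of ~150 photons per
spot peak plus Gaussian read noise (SD 2). Real acquisitions are
maximum-intensity projections of 7 × 0.5 μm cortical z-stacks; the
simulator renders the projected plane directly, so the projection stage
of the pipeline is an identity.

Particles are advected by a prescribed velocity field with forward-Euler
steps of one frame interval on a **toroidal domain**: positions wrap, and
spot rendering wraps with them. This makes a uniform-flow movie exactly
translation-equivariant (frame t+1 is frame t rolled by the programmed
shift), which is what lets an independent phase-correlation oracle verify
advection to < 0.05 px and gives the PIV engine a ground truth free of
boundary artifacts. The cost is that flow entering one edge re-enters at
the other — acceptable because all analyses run on an interior ROI.

Molecular turnover is whole-particle exchange, matching a
binding/unbinding interpretation of the dissociation rate: each particle
survives a frame with probability exp(−k_off Δt), and a Poisson number of
replacements (mean = target count × removal probability) appears at
uniform positions, keeping density stationary (verified to 5% by
integrated-intensity particle counting). Intensity fading per particle is
deliberately not modeled.

Four flow programs cover the phenotypes the analyses must distinguish:
`uniform` (zero spatial gradient; advection/unit tests), `control_like`
(anterior-directed flow ramping logistically across the equator at 17 μm
with a 4 μm length scale, peak 4.5 μm/min in the posterior half, linear
temporal ramp over 40 s — reproducing flow that is fastest posteriorly
and compresses at the equator), `flat_erratic` (a seeded bank of
short-wavelength sinusoids, peak 1 μm/min, no coherent direction —
the motor-compromised phenotype), and `bidirectional` (tanh profile with
both halves flowing toward the equator, as during constriction).

The FRAP generator renders a uniform "embryo" patch (central 80% of the
frame) whose bleach ROI drops by a programmed depth (default 60%) at the
bleach frame and recovers as floor + A(1 − e^(−t ln2/τ½)), on top of a
slow whole-field acquisition-bleaching decay (τ = 500 s) that exercises
the correction stage. The filament-band generator stamps line segments
whose orientations are drawn from a von Mises distribution on doubled
angles around the programmed angle (dispersion 0 → perfectly parallel).

**What passing tests show** is that the analysis chain recovers known
flows, half-times and orientations from data with realistic sampling,
photon statistics and turnover. **What they do not show** is robustness
to features the simulator omits: embryo curvature and shape, uneven
illumination, z-drift, cytoplasmic background structure, flow fields
with shear or D–V structure, and non-exponential (diffusion-coupled)
FRAP recovery.

## PIV engine

The two-pass protocol is fixed by the measurement standard this package
replicates: 64 px then 32 px interrogation windows, 50% overlap, second
pass offset by the rounded first-pass displacement bilinearly
interpolated to the finer grid. The internals, unspecified in that
standard, are the de-facto PIV defaults:

- **Correlation**: FFT circular cross-correlation of mean-subtracted
  windows, normalized by N σ_a σ_b so a perfect match peaks at 1.
  Zero-variance windows are flagged invalid. The map is divided by the
  triangular overlap weighting (floored at 0.5) to remove the σ²/N
  displacement bias of windowed correlation; without this, fractional
  shifts carry a systematic ≈ −0.05 px error.
- **Sub-pixel localization**: three-point Gaussian fit per axis around
  the integer peak (first in row-major order on ties), falling back to a
  parabolic fit when a neighbor is non-positive; border peaks are
  invalid.
- **Validation**: normalized median test on 3×3 neighborhoods
  (threshold 2.0, regularization ε = 0.1 px); outliers are replaced by
  the neighborhood median and flagged; vectors with fewer than 3 valid
  neighbors are flagged but left unreplaced.
- **Geometry**: windows are laid out entirely inside the ROI (clipped,
  never padded); anchors are window centers. Reported positions follow
  the 1-based pixel convention position_μm(k) = k × pixel size, which
  reproduces the 19.2/19.4/34.1 μm sub-region bounds of the standard
  192-px ROI.
- **Units**: V[μm/min] = V[px/frame] × pixel size × 60 / frame interval.

Measured accuracy on seeded movies: ≤ 0.02 px mean error for uniform
shifts of 0.5–5 px/frame noiseless, ≤ 0.01 px at default noise (both well
inside the 0.1/0.3 px acceptance bounds). No temporal smoothing is
applied before region averaging.

## Flow statistics

- **Compression sign**: rate = −∂Vx/∂x so converging flow is positive;
  velocities are converted to μm/s inside the derivative so rates are in
  s⁻¹. Central differences at interior positions, one-sided at the ends;
  on the uniform PIV grid the trapezoid integral of the rate telescopes
  exactly to Vx(start) − Vx(end). No spatial smoothing is applied before
  differentiation — the dense grid plus D–V averaging suppresses noise.
- **Time bins**: 10-s bins from 25 to 95 s after anaphase onset; the
  equatorial band is 15–25 μm. The profile window default is 50 s.
- **Cosine curve**: pair distances are binned at the post-refinement grid
  spacing (16 px × pixel size ≈ 2.8 μm); the zero-distance bin contains
  only self-pairs and is excluded; zero vectors are excluded (cosine
  undefined) and tallied rather than mapped to 0.
- **Pooling**: with several embryos, vectors are averaged within an
  embryo first and embryos contribute equally; the SEM is across embryos.
  Time points with no vectors in a region give missing values, not
  zeros.
- **Kymograph**: 150 × 5 px strip averaged across its short axis, one
  column per frame.

## FRAP

The easyFRAP conventions: background subtraction, simple-ratio
acquisition-bleaching correction (each trace multiplied by
⟨roi2⟩_pre / roi2(t)), double normalization (pre-bleach mean exactly 1),
then nonlinear least squares of N(t) = N₀ + A(1 − e^(−t/τ)) with the
bleach frame excluded (partially exposed) and t = 0 at the first
post-bleach frame — a time-origin choice that leaves τ unchanged for a
single exponential. Initialization comes from a log-linearized slope
estimate; amplitude is bounded non-negative; a flat curve is reported as
unidentifiable rather than fitted. τ½ = τ ln 2 and k_off = ln 2 / τ½,
the standard half-life relation with the natural logarithm. Note that
applying this relation to a 4.9 s half-time gives k_off ≈ 0.14 s⁻¹; a
published per-study average may differ (e.g. if rates are averaged per
embryo before summarizing), so the package reports the literal Eq.-style
extrapolation and leaves cohort averaging to the caller. The mobile
fraction (plateau − floor)/(1 − floor) is reported as a diagnostic; its
floor is read at the first post-bleach frame, a few percent above the
instantaneous bleach depth at fast τ.

## Orientation

Gradients use separable 5-tap derivative-of-Gaussian kernels (σ = 1 px),
chosen over 3×3 Sobel for noise robustness; each interior ROI pixel
(2-px border excluded) votes for its structure orientation — gradient
direction + 90°, wrapped to (−90°, 90°] with y taken to point up so
angles are counter-clockwise from the A–P axis — weighted by squared
gradient magnitude, in 2° bins. The dominant angle is the center of a
Gaussian fitted to the bins within ±15° of the highest peak (circularly,
ties to the lower angle); if the fit fails, the weighted circular mean of
doubled angles is used. Both estimators are exposed; the peak fit is the
default because it ignores secondary lobes. Deviation from vertical is
|90° − α| folded into [0°, 90°]. Measured accuracy: ≤ 0.6° worst-case on
sinusoidal gratings at SNR 5 across 12 angles (bound: 1.5°).

## Timing

Landmark annotations are inputs, never detected from images. Tied event
times are allowed (zero intervals); only decreasing times are rejected.
Fold-delays are round-half-up of the ratio of medians (so 298/53 = 5.62
reports as sixfold); completion percentages round half-up to integers
(11/12 → 92%); quartiles use linear interpolation (type 7). Significance
testing is out of scope — the summary tables expose the inputs such
tests need.

## Problem sizes

Default test and acceptance runs use 192 × 128–256 × 160 px movies of
2–26 frames for PIV (≈ 600 vectors per condition series), 8-point τ½
sweeps on 64 × 64 px FRAP movies of 60–170 frames, and 100 × 100 px
gratings at 12 angles — sizes chosen so the full suite and the
acceptance script each complete in well under a minute while every
statistical check retains comfortable margin.

## Known limitations

- Two passes only; no window deformation, no multigrid, no 3-D PIV.
- The erratic flow model is a deterministic sinusoid bank, not a
  physical active-gel simulation; it reproduces incoherence statistics,
  not mechanism.
- Single-exponential FRAP only; no reaction–diffusion models.
- No per-filament segmentation; orientation is texture-level.
- The period of persistent unidirectional flow is an input window, not
  detected automatically.
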