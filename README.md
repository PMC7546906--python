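# cortexflow

Quantitative image analysis of cytokinetic cortical flows in the one-cell
*C. elegans* embryo.

During cytokinesis, the actomyosin cortex flows from the posterior pole
toward the cell equator, where a contractile ring of F-actin, non-muscle
myosin II (NMY-2) and crosslinkers assembles and constricts. Testing
whether these flows matter — for ring assembly timing, for myosin
accumulation in the furrow, for F-actin bundle alignment — requires
turning time-lapse fluorescence movies into numbers. `cortexflow`
implements that measurement pipeline as a tested, reusable library with a
command-line front end, together with a seeded synthetic-movie generator
that provides exact ground truth for every stage, so the whole chain is
verifiable without access to microscope data.

## What it computes

**Cortical flow fields (PIV).** Two-pass particle image velocimetry on
consecutive frame pairs: a 64 × 64 px interrogation window (first pass)
followed by 32 × 32 px (second pass, search window offset by the
interpolated first-pass displacement), 50% window overlap, FFT normalized
cross-correlation with three-point Gaussian sub-pixel localization and
normalized-median outlier validation. Velocities are calibrated to
μm/min with x along the anterior–posterior (A–P) axis; negative Vx means
posterior-to-anterior flow. The standard region of interest is
192 × 128 px (34.1 × 22.8 μm), split at pixel 108/109 (19.2/19.4 μm)
into anterior and posterior halves.

**Flow statistics.** Per-region velocity time courses aligned to a
landmark event; longitudinal velocity profiles Vx(x) averaged over the
50 s window of persistent unidirectional flow; the compression rate by
flow,

    rate(x) = −∂Vx/∂x   [s⁻¹],

positive where flow converges, evaluated in 10-s bins and averaged over
the equatorial band (15–25 μm); flow coherence as the mean pairwise
cosine similarity

    cos(w_i, w_j) = w_i · w_j / (‖w_i‖ ‖w_j‖)

binned by inter-vector distance; and space–time kymographs from a
150 × 5 px strip.

**FRAP turnover kinetics.** Three-ROI trace extraction (bleached region,
whole embryo, camera background), simple-ratio bleaching correction,
double normalization (pre-bleach ≡ 1), single-exponential fitting
N(t) = N₀ + A(1 − e^(−t/τ)), and the dissociation rate

    k_off = ln 2 / τ½,   τ½ = τ ln 2.

**Bundle alignment.** Local-gradient orientation histograms
(derivative-of-Gaussian gradients, gradient-energy weighting, 2° bins)
over a 30 × 70 px equatorial ROI; the dominant angle α per frame and the
deviation from vertical |90° − α| folded into [0°, 90°] — 0° means
bundles perpendicular to the long axis, as in a properly forming ring.

**Stage timing.** Ring assembly / furrow initiation / ring constriction
intervals from event annotations (anaphase onset, shallow deformation,
back-to-back configuration, full ingression), cohort summary tables,
fold-delays of medians, and completion percentages.

**Synthetic data.** `simulate_cortex_movie` renders Gaussian-spot
particles advected by prescribed flow fields (uniform, control-like
posterior ramp, flat-erratic, bidirectional) with first-order molecular
turnover and camera noise; `simulate_frap_experiment` produces bleaching
movies with known recovery half-time; `simulate_filament_band` renders
line textures with a programmed orientation schedule. Every generator
returns the ground truth alongside the movie and is bit-reproducible for
a fixed seed.

## Worked example

```python
from cortexflow import *

cfg = SimConfig(n_frames=26, seed=7)
flow = FlowModel(kind="control_like", vmax_um_min=4.5, ramp_time_s=40.0)
movie, truth = simulate_cortex_movie(cfg, flow, koff=0.02)
series = run_piv(movie)

prof = ap_profile(series, window_start_s=40.0, window_len_s=50.0)
print(f"peak flow: {prof.mean_vx_um_min.min():.2f} um/min")

comp = compression_profile(series)
print(f"max equatorial compression: {comp.equatorial_mean_s.max():.4f} 1/s")

curve = cosine_vs_distance(series, window=(40.0, 90.0))
print(f"cosine similarity: {curve.mean_cosine[0]:.3f} (nearest) "
      f"-> {curve.mean_cosine[-1]:.3f} (opposite poles)")
```

prints

```
peak flow: -4.48 um/min
max equatorial compression: 0.0021 1/s
cosine similarity: 0.991 (nearest) -> 0.957 (opposite poles)
```

The simulated control cortex is programmed with a 4.5 μm/min peak
anterior-directed flow in the posterior half; PIV recovers −4.48 μm/min.
The velocity gradient across the equator yields a positive (converging)
compression rate in the 15–25 μm band, and flow coherence stays near 1
out to vectors on opposite poles — the signature of persistent
unidirectional flow. A FRAP experiment simulated with τ½ = 4.9 s refits
to τ½ = 5.00 s and k_off = ln 2/τ½ = 0.139 s⁻¹, and
`fold_delay(155.0, 53.0)` reports `{'ratio': 2.92, 'fold': 3}` — a
threefold ring-assembly delay.

The same stages are available from the shell:

```sh
cortexflow simulate --out movie.tif
cortexflow piv movie.tif --out vectors.csv
cortexflow kymo movie.tif --out kymo.tif
cortexflow frap frap_movie.tif --out fit.json
cortexflow orient band_movie.tif --out trace.csv
cortexflow report embryo*.json --reference control --out cohort.csv
```

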