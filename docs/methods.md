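# Methods

## The excitable-medium model

The synthetic monolayer is a two-variable reaction–diffusion system of
Barkley type on a regular grid with no-flux boundaries:

    ∂u/∂t = D ∇²u + (1/ε) u (1 − u) (u − (v + b)/a)
    ∂v/∂t = (u − v) / τ_v

`u` is the fast excitation variable (dimensionless; rest ≈ 0, excited
≈ 1), `v` the slow recovery variable.  Parameters and units:

| parameter | meaning | units | typical |
|---|---|---|---|
| `D` | diffusion coefficient (sets conduction speed, c ∝ √(D/ε)) | μm²/s | 0.8–2.5 × 10⁷ |
| `ε` | excitation (upstroke) time scale | s | 0.004–0.010 |
| `τ_v` | recovery time scale (sets APD and wavelength) | s | 0.08–0.12 |
| `a`, `b` | threshold shape: excitation threshold is (v + b)/a | — | a 0.75–0.8, b 0.02–0.06 |
| `pixel_size` | grid spacing | μm | 125 (128 px = 16 mm field) |
| `frame_interval` | stored frame spacing | s | 0.02 (50 Hz) |

Integration is explicit Euler with a 5-point Laplacian (numba-compiled);
the step is chosen automatically as `min(0.18 dx²/D, ε/3)` and the frame
stride rounds it down, never up, so the diffusion stability bound is
respected.  A divergence check raises an instability error naming the
offending parameters.  Frame `f` holds the state at `t = f·frame_interval`.

Ground truth recorded during integration: per-pixel upstroke times
(sub-step interpolated crossings of u = 0.5 with a Schmitt release at
0.4), per-frame phase-singularity counts on the state-space phase
`atan2(v − 0.35, u − 0.5)`, and for plane waves the front speed fitted
on an independent quasi-1D strip of the same kinetics (paced at the same
period, third front, so the mild rate dependence of conduction is
included).  `diffusion_for_speed` inverts the c ∝ √D law with a second
calibration pass that absorbs the small finite-grid departure from pure
square-root scaling.

## Regimes

Presets (`REGIME_PRESETS`) were calibrated once so that plane-front
speeds land in the 25–40 mm/s band typical of confluent neonatal-rat
monolayers and each regime robustly produces its advertised topology:

- **plane** / **target** — paced kinetics (a=0.75, b=0.03, ε=6 ms,
  τ_v=120 ms).  Stimuli are restamped periodically (0.7 s / 0.6 s); their
  geometry scales with the front width √(Dε) (and, for the focal disk,
  with the curvature-limited 2-D critical nucleus ≈ 2× that) so ignition
  never fails as D varies.
- **single_spiral** / **multi_spiral** — broken-bar initiation (a thin
  excited bar with a refractory tail; its free ends curl into rotors),
  with more excitable kinetics (b=0.02, ε=4 ms): persistent spirals need
  an effective stiffness ε/τ_v ≲ 0.04 and a wavelength below the 16 mm
  field.  One bar end gives one rotor; two counter-oriented bars give a
  stable figure-of-two pair.
- **wavelets** — a frozen smoothed Gaussian field (σ = 5 px) modulates
  both the threshold offset (`b + a·h·g`, h = 0.25) and the recovery
  time (dispersion of refractoriness), producing scattered conduction
  blocks that fragment wavefronts.  The wavelet state in a 16 mm domain
  is metastable; whenever the medium goes fully quiet (< 2% excited)
  fresh bars are stamped.  The re-ignition is gated on quiescence, so it
  can never reset live activity, and all randomness is seeded.

## Optical rendering and noise

`render_optical` maps the state video to voltage-dye-like contrast
(monotone identity on u) or dye-free motion-like contrast (|Δu|/Δt,
which produces transients at both wavefront and waveback — the known
ambiguity of dye-free recordings; analyses of motion-like videos are
therefore only trusted for front timing).  Spatial Gaussian blur and
i.i.d. additive Gaussian noise per pixel per frame follow.  No published
SNR characterization of the dye-free camera exists, so the default study
conditions (noise SD 0.02 on a unit-amplitude signal, 1 px blur,
SNR ≈ 50) are this package's choice.

The generator does **not** emulate photobleaching, illumination
vignetting, motion artifacts from contraction, pixel-correlated camera
noise, realistic AP morphology (notch, alternans), or 3-D tissue;
passing tests show the analyzers recover what they claim under the
stated noise model, not under every camera pathology.

## Spike traces and dose response

`simulate_spike_trace` draws spikes from a two-rate inhomogeneous
Poisson process (thinning), rate `baseline_rate` outside stimulation
windows and `baseline_rate × g(ratio)` inside, with an enforced dead
time equal to the spike-template duration.  The dose gain is a
saturating Hill map `g(r) = 1 + 4 r/(r + 0.03)`: g(0) = 1, monotone,
half-saturating between the 1:100 and 1:20 plating ratios, giving
gains ≈ 1.0, 2.0, 3.5, 4.5 across the ratios 10⁻⁵, 0.01, 0.05, 0.2.
Spikes are rendered as a linear 20 ms rise and 120 ms exponential decay
on Gaussian noise; the embedded train is returned as exact truth.

## Analyzers

**Baseline subtraction** — running median per pixel; the window (default
2 s) must span several beat periods, otherwise the median follows the
beats and distorts the waveform.

**Activation times** — per pixel, the trace is normalized between its
5th percentile and its maximum (a high percentile instead of the maximum
would shift with duty cycle and bias crossings early); upward crossings
of `threshold_frac` (default 0.5) are linearly interpolated, with a
Schmitt release at `threshold_frac − 0.15` and a 150 ms dead time.
Pixels with amplitude below 4× their high-frequency noise are masked.
Cycle index = ordinal crossing number per pixel.

**Wave speed** — local speed is 1/‖∇T‖ per cycle in mm/s.  The gradient
comes from local least-squares *plane fits* of the activation-time
surface rather than smoothing-then-differencing: activation times are
quantized by the frame clock into a staircase of spatial period
c·frame_interval, which plane fitting averages out while a smoothing
filter would spread its flat treads into spurious fast patches.  The
fit window adapts to that period (at least 2(σ+1)+1 px, σ default 3).
Two passes: a fine-scale pass flags gradient-degenerate zones (collision
lines, wall pile-ups, stimulus plateaus; > 1.6× the median speed) which
are masked before the wide fit so they cannot bleed into the bulk.
Speeds above 200 mm/s are masked as degenerate; each cycle's earliest
10% and latest 20% activation quantiles are excluded (waves are born at
stimulus sites still accelerating and die in collisions, and the wall's
influence extends over the front tail length D/c); the first paced beat
is skipped when ≥ 3 cycles exist because it propagates into fully rested
tissue and is systematically fast.  `p90_speed` is the linearly
interpolated 90th percentile pooled over valid pixels × cycles — the
pooling convention over pixels and cycles is this package's
operationalization.

**Phase and singularities** — per-pixel instantaneous phase from the
analytic (Hilbert) signal of band-passed traces (0.5–10 Hz default),
with the *complex* signal smoothed spatially (σ = 1 px) before the angle
is taken — during diastole the analytic signal sits near the origin and
raw pixel noise would wind the phase arbitrarily.  Singularities are
2×2 plaquettes whose wrapped-phase loop sum is ±2π.  Detections are
linked frame-to-frame into rotor tracks (same chirality, ≤ 6 px);
classification counts only singularities on tracks persisting ≥ 3
frames, which suppresses the flickering phase-noise defects that remain.

**Classification** — post-transient (first 20% of frames skipped)
statistics of the per-frame rotor count S: median > 3 or 90th percentile
≥ 5 → wavelets (sustained breakup, or the bursts of fragmented
short-lived rotors typical of the metastable wavelet state); median ≥ 2
→ multi_spiral; a single rotor present in ≥ 80% of frames →
single_spiral; no rotors with a repeating focal origin (earliest-5%
activation centroid dispersion ≤ 15 px across cycles) → target.
Recordings shorter than 10 s with fewer than 10 observed cycles, or with
no detected activity, return an *inconclusive* status rather than a
guess.  target/single_spiral are "simple", the rest "complex".

## Transects and innervation geometry

Random transects have uniform interior start points (rejection-sampled
so the whole segment lies inside the image) and uniform angles in
[0, π).  Lines are sampled at 0.25 px steps and consecutive boundary
hits merge into one crossing, so counts are independent of the drawn
line thickness.  Spacing is L/mean(N) with first-order error propagation
L·sd(N)/mean(N)² (per-transect reciprocals are undefined at N = 0).
Innervated-cell counts divide a process length by the spacing; under the
worked-example convention the spacing is first rounded to integer μm,
and all counts round to nearest with raw quotients reported alongside.
The boundary mosaic is a Voronoi tessellation of a uniform point process
with intensity matched to the requested mean cell area, boundaries one
pixel wide where the nearest-seed label changes.

Neurite-length summaries report both weighting conventions (per-neuron
and per-segment) because the field's "weighted average" is ambiguous.

## Reproducibility

One global seed is expanded into independent substreams keyed by
(seed, stage label) via CRC-32, so adding a stage never perturbs another
stage's randomness.  Identical configuration and seed give bit-identical
videos, traces, masks and derived files.  Pipeline outputs carry a
sidecar with stage, parameters, seed, config hash and package version;
outputs are staged in a temporary directory and moved into place only on
success.

## Problem sizes

Default study conditions: 128 × 128 grid (16 × 16 mm at 125 μm/px),
300–500 frames at 50 Hz (6–10 s).  Statistical checks use 20 seeds per
regime for classification, 100 synthetic traces for spike detection,
1,000 Poisson trains for the firing-score null, 1,000 transects for
spacing recovery — sizes chosen so each check's Monte-Carlo error is
well inside the tolerance it asserts.

## Known limitations

- The linear-recovery kinetics have no APD restitution, so sustained
  fibrillation-like breakup requires frozen heterogeneity plus
  re-ignition; wavelet episodes self-terminate, as they also do in small
  real preparations.
- The phase analyzer's rotor counts are an operationalization; its
  absolute counts in the wavelets regime differ from state-space truth
  (they agree in regime-level statistics, which is what the classifier
  uses).
- Wave-speed estimates assume locally planar fronts over the fit window;
  strongly curved tips bias local speeds low near rotor cores (those
  regions are largely excluded by the degenerate-zone masking).
- The 2-D innervation estimate counts boundary crossings, equating each
  crossing with one innervated cell; it is an upper-bound-style estimate
  inherited from the experimental design.
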