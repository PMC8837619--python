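# Methods

## Problem setting

`thermotomo` studies whether the 3D temperature distribution inside a
tissue-like object can be recovered from planar infrared images taken
around it.  Infrared radiation does not penetrate tissue, so a thermal
camera only ever sees the surface; classical tomographic reconstruction
therefore produces volumes whose apparent heat is concentrated near the
object's edges.  The package implements the full synthetic pipeline: a
transient bioheat simulation of a cylindrical phantom with spherical
heat sources, an orthographic projection renderer, unfiltered
backprojection, a convolutional autoencoder that learns to map the
backprojection to the true interior distribution, and a five-metric
evaluation harness.

## Phantom and heat sources

The phantom is a homogeneous cylinder, radius R = 5 cm, height
H = 5 cm, with muscle-like thermal properties:

| parameter | symbol | default | unit |
|---|---|---|---|
| thermal conductivity | k | 0.49 | W/(m·°C) |
| mass density | ρ | 1103 | kg/m³ |
| specific heat | Cp | 3322 | J/(kg·°C) |
| emissivity | ε | 0.95 | – |
| ambient / initial temperature | T∞ | 20 | °C |

Thermal diffusivity is α = k/(ρCp) ≈ 1.34·10⁻⁷ m²/s.  Heat sources are
spheres of 5 mm diameter held at a fixed temperature above ambient
(Dirichlet condition); temperatures are carried differentially
(ΔT relative to 20 °C).  The deterministic single-source family places
the sphere at radial offsets d and heights h from 0.5 to 4.5 cm in
0.5 cm steps (81 locations, azimuth 0).  The random multi-source
sampler draws 1–5 spheres uniformly over the admissible region
(sphere strictly inside the cylinder), with ΔT uniform in 1–5 °C and
pairwise centre distances ≥ 10 mm, by seeded rejection sampling.

## Conduction solvers

The governing equation is transient heat conduction
ρCp ∂T/∂t = ∇·(k∇T) with no volumetric heating; the outer boundary
loses heat radiatively, −k ∂T/∂n = εσ(T⁴ − T∞⁴), evaluated in Kelvin
(σ = 5.670374419·10⁻⁸ W/(m²K⁴)).  Two independent discretizations are
provided and cross-validated against each other:

* a **3D finite-volume solver** on the voxel grid, with a stair-step
  cylinder boundary.  Explicit (forward Euler / FTCS) stepping by
  default with Δt at half the stability bound; an unconditionally
  stable implicit axis-splitting scheme (batched Thomas solves per
  axis) is available for long, low-contrast runs.
* an **axisymmetric (r, z) finite-volume FTCS reference** for on-axis
  sources, exploiting the φ-symmetry of the centred-source problem.

Numerical choices that matter:

* **Sharp-interface Dirichlet sources.**  Clamping whole voxels to the
  source temperature makes the effective source size fluctuate by half
  a voxel with grid alignment, which at 1–2.5 mm spacing distorts the
  far field by ~10%.  Both solvers therefore couple interface cells to
  the *continuous* sphere surface at its sub-cell distance d using the
  second-order non-uniform 3-point stencil (weights 2Δ²/(d(d+Δ)) to the
  surface value and 2Δ/(d+Δ) to the opposite neighbour).  The surface
  coupling is stiff when a cell centre grazes the sphere, so it is
  integrated point-implicitly (a local backward-Euler relaxation),
  leaving the explicit stability bound governed by the regular
  voxel couplings.
* **Perimeter-corrected radiation.**  The stair-step lateral wall has
  4/π times the area of the true cylinder, so lateral exposed faces
  carry a π/4 weight in the radiative flux; top/bottom faces are flat
  and carry weight 1.
* **Validation.**  For the centred source (d = 0, h = 2.5 cm,
  ΔT = 30 °C) after 60 min of heating, the 3D solver at 2.5 mm and the
  axisymmetric reference at 0.5 mm agree on the maximum surface
  temperature to < 0.05 °C (the reference itself is converged to
  ~0.002 °C by 0.5 mm).  `thermotomo validate-solver` reproduces this
  check with a 0.07 °C pass threshold.
* **Grid independence.**  Following the usual mesh-independence recipe,
  the 60-min surface Tmax is tracked over a descending spacing sequence
  and the mesh is accepted when the change between consecutive rows
  falls below 0.1%.  The sequence 2.5 → 2 → 1.5625 mm crosses the
  criterion at 1.5625 mm (0.06% change), which is the declared
  production solver spacing.  Convergence is not monotone: because the
  discrete sphere's alignment with cell planes shifts with spacing, the
  monitored value still wobbles by 0.2–0.8% at 1.25 and 1 mm around the
  converged value (≈ 2.50 °C).  The criterion should therefore be read
  the way mesh-independence criteria are used in practice — an
  engineering stopping rule, not an error bound.
* Production volumes are solved at the production spacing and
  trilinearly resampled onto the canonical 1 mm output grid
  (100×100×50) when the two differ.

## Imaging model

An orthographic camera circles the phantom (default 360 views at 1°).
The detector has one column per millimetre and one row per axial slice.
Because infrared imaging is non-penetrating, a pixel carries the
surface temperature where its ray first enters the cylinder.  Pixel
values are sampled by support-aware bilinear interpolation at the
analytic ray-entry point, pulled 1.25 voxels inward so that every
interpolation corner lies inside the discretized support: this makes
the renderer angle-stable (axisymmetric fields render near-identically
at all angles), which voxel first-hit sampling cannot achieve on a
stair-step boundary.  Rays that miss the phantom produce exactly-zero
background pixels.

The initial reconstruction is plain **unfiltered backprojection**: per
axial slice, each in-support voxel accumulates the linearly
interpolated projection value at its detector coordinate
s = x·cosθ + y·sinθ over all angles, and the sum is divided by the
number of views.  Out-of-support voxels are zero.  Detector
coordinates in the outer half-bin use nearest-bin extrapolation so
that constant projections backproject to the same constant.  The
result concentrates apparent heat near the rim at the source azimuth —
the physical reason a learned refinement stage is needed.

## Datasets

Three experiment presets mirror the study conditions:

* `single_hot` — 81 locations × 10 captures (minute 15…60 in 5-min
  steps) at ΔT = 30 °C → 810 paired samples;
* `single_low` — 81 locations × ΔT ∈ {1,…,5} °C, one capture after
  300 min → 405 samples (3600 minutes of simulated heating per
  location family);
* `multi_low` — 1000 seeded random multi-source phantoms, one capture
  at 300 min.

Each sample stores the simulation target and its backprojection input
(computed once, at build time) plus provenance (source centres, ΔT,
capture time, rotation angle).  Splits are a seeded 80/10/10 random
partition (810 → 648/81/81).  Training-time augmentation rotates every
pair by ten random axial angles per epoch (bilinear, identical angle
for input and target; multiples of 90° use the exact permutation).
Test-time expansion appends nine 36°-step rotations per case
(81 → 810; 405 → 4050), with provenance centres rotated in closed form
for the location-error reference.

## Reconstruction network

Axial slices are treated as channels of a 2D convolutional
autoencoder: a 100×100×50 volume is zero-padded to 128×128×50.  The
encoder stacks blocks of 3×3 convolution → batch normalization → leaky
ReLU (slope 0.01) → 2×2 max pooling with 32, 64, 128, 256 filters
(bottleneck 8×8×256); a five-block variant adds 512 filters
(bottleneck 4×4×512).  The decoder mirrors the schedule with stride-2
3×3 transposed convolutions, and a final linear 3×3 convolution maps
to 50 channels, centrally cropped to 100×100.  Training minimizes
voxelwise MSE on raw ΔT (no normalization — the experiments use
different ΔT scales and are trained separately) with Adam
(lr 10⁻³ by default), batch 32, ≤ 500 epochs, early stopping with
patience 25 on validation loss, best-validation checkpointing.

The network, its layers (im2col-style 3×3 convolutions, transposed
convolutions, batch norm, pooling) and Adam are implemented directly
on numpy arrays in float32.  All layer gradients are verified against
central finite differences in the test suite; training is
deterministic under a seed.  Checkpoints are `.npz` plus an
architecture YAML.

## Evaluation metrics

All intensity metrics are computed over support voxels only (the
background is identically zero in both volumes and would inflate
correlation-type scores):

* **NMSE** = Σ(recon − ref)² / Σ ref²;
* **CC** — Pearson correlation;
* **PSNR** = 10·log₁₀(peak²/MSE) in dB, peak = reference maximum
  (per-volume convention), capped at 100 dB for exact matches;
* **SSIM** — per-axial-slice 2D structural similarity with a Gaussian
  window (σ = 1.5), K₁ = 0.01, K₂ = 0.03, dynamic range = reference
  peak, averaged over slices;
* **HSLE** — heat-source location error in mm: Euclidean distance from
  the true centre to the intensity-weighted centroid of voxels ≥ 90%
  of the volume maximum.  The weighted centroid (rather than a bare
  argmax) gives sub-voxel localization; the metric is only defined for
  single-source cases and is omitted from multi-source reports.

Reports carry per-case values plus mean ± SD, median and 25–75
percentiles per metric (CSV and JSON).

## What the synthetic data does and does not capture

The generator reproduces the study conditions exactly: geometry,
material constants, source families, capture schedules, view count.
It does not emulate camera noise, emissivity or atmospheric
attenuation, tissue heterogeneity, convective or basal contact losses,
or acquisition time (a real 360° sweep takes minutes during which the
object keeps heating).  Passing tests therefore demonstrate the
internal consistency of the pipeline and the learnability of the
simulated inverse problem, not performance on real tissue.

## Problem sizes used by the test suite

The default test run keeps the physics and geometry fixed but uses
economical discretizations: solver checks at 2.5 mm spacing (40×40×20
voxels), dataset-cardinality checks at 2.5 mm with shortened heating
for the 300-min presets (counts are resolution-independent), and the
learning-sanity experiment on a 50×50×25 grid (2 mm spacing) with 100
samples, a reduced filter schedule (8, 16, 24, 32) and a few dozen
epochs.  Headline-table reconstruction quality at the full
810-sample, 128×128×50, ≤500-epoch scale requires a long GPU or
multi-day CPU training run of the same pipeline (`thermotomo run`)
and is not reproduced by the desk-scale suite.

## Known limitations

* The stair-step support makes renderer values slightly
  angle-dependent (~10⁻³ of the field peak at 2.5 mm) and the
  mesh-independence monitor non-monotone below 2 mm.
* The implicit splitting scheme is first-order in time (Lie
  splitting); it is intended for the 300-min low-contrast runs where
  the explicit step count would be large.
* Backprojection assumes parallel rays and noiseless surface readings.
* The numpy network trains at roughly laptop-GPU-free speeds; the
  full-scale configuration is compute-bound (months of single-core
  FLOPs) and is only practical at reduced scale in CI-like settings.
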