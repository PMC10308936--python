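# Methods

This note documents the models, conventions, parameters and numerical
choices behind duofilm, and what the synthetic test-bed does and does not
establish about real data.

## Coordinate and intensity conventions

* Arrays are indexed (z, y, x). z = 0 is the **attachment surface**; z
  increases toward the bulk medium and light source. Voxel k along an axis
  of spacing d covers [k·d, (k+1)·d) µm; every membership decision (object
  rasterization, depth-segment assignment) uses the voxel **center**
  (k+0.5)·d. This makes volumes exact integer voxel counts times the voxel
  volume, with no fractional voxels and no blending at segment boundaries
  (sharp per-segment threshold transitions are intentional and documented).
* Depth segments are half-open [z_lo, z_hi); the standard stratification is
  0–10, 10–20, 20–30 µm. Stacks deeper than the configured segments are
  accepted; voxels past the last segment are excluded from green
  segmentation and counted in an `unsegmented_voxels` tally.
* Intensities are stored 8-bit (0–255), matching the magnitude of the
  conventional quality thresholds (10–30). Files whose first page is the
  far side declare `z_flipped` in the JSON sidecar.

## Phantom generator

The generator emulates the structures of a young two-species phototrophic
biofilm so that segmentation and quantification can be validated against a
known ground truth.

* **Filaments** (red channel) are random-walk tubes: fixed step length
  (default 1 µm), Gaussian heading perturbation (SD 0.35 µm per step),
  reflecting boundaries, initial position near the surface and initial
  heading biased toward +z (the light-facing side). Radius default 2 µm,
  length 60 µm. The field's imaging shows, but does not parameterize,
  filament geometry; these are configuration, not claims.
* **Rods** (green channel) are capsules — cylinder plus hemispherical caps,
  total length 3 µm, radius 0.6 µm (a realistic *Pseudomonas* envelope) —
  with orientation uniform on the sphere. A fraction
  `seeding_layer_fraction` (default 0.8) is placed entirely below 10 µm
  (so the whole capsule, not merely the centroid, lies in the seeding
  layer); a fraction `coloc_fraction` (default 0.5) is placed with centroid
  within `coloc_radius` (default 1.5 µm) of a filament axis vertex,
  rejection-sampled to respect the seeding layer when both constraints
  apply. When no valid co-localized position exists after 200 draws the rod
  falls back to seeded placement and is counted in `coloc_unsatisfied`
  (layer membership is treated as the harder constraint).
* **Image formation**, in order: constant per-channel emission on the truth
  mask (overlapping cells take the maximum, i.e. cells are opaque, not
  additive) → exponential depth attenuation `exp(−(z_max − z)/L)` with the
  detector at the high-z (objective/light) face, L = 100 µm by default →
  Gaussian PSF, σ = (0.5, 0.3, 0.3) µm → Poisson resampling at
  `poisson_scale` = 2 photons per intensity unit → additive Gaussian read
  noise (SD 6) → clip to [0, 255] and round. With emitted intensities
  200 (red) and 180 (green) the in-mask SNR is ≈ 12, comfortably above 5.
  Any consistent detector-side convention would do; this one (imaging
  through the biofilm from the medium side) is fixed and documented.
* **Determinism**: geometry and noise use independent child generators
  spawned from the seed, so truth masks are bit-identical across runs that
  differ only in noise parameters, and identical parameters regenerate
  bit-identical stacks. Growth series use `seed_day = seed + 10007·day` and
  round-half-up object counts.
* **Validation guards**: radii or PSF sigmas below half a voxel are
  rejected as unresolvable geometry (σ = 0 disables the PSF).
* Default grid: 60×120×120 voxels at 0.5 µm isotropic — a 30 µm-deep zoomed
  region of interest sized so the full test-bed runs in seconds per
  phantom. Default populations: 5 filaments, 400 rods.

## Segmentation

"Isosurface quality" thresholding from GUI-based workflows is interpreted
here as a strict threshold on (optionally Gaussian-smoothed) intensity on
the 8-bit scale — a transparent, testable operator, documented as an
interpretation rather than a claim of equivalence to any proprietary
implementation. Connectivity is 26-neighbor in 3-D; `smoothing_sigma` is
given in µm and converted per axis; `min_object_voxels` (default 8)
suppresses shot-noise speckle and is set to 1 in oracle tests.

The green channel is **masked by the red mask before thresholding** (the
overestimation guard). Because smoothing after masking can leak intensity
back across the red boundary, the thresholded green mask is re-intersected
with the complement of the red mask before small-object removal; masked
voxels are by definition not heterotroph cells. This guarantees the
exclusivity invariant (green ∧ red = ∅) unconditionally.

### Matched thresholds for phantom recovery

Recovery experiments need thresholds matched to the generator's imaging
model. Half-maximum thresholding recovers object boundaries only when
objects are large relative to the PSF; rods (radius 0.6 µm ≈ 2 lateral PSF
sigmas) are barely resolved and would be undercounted by ~50% at half
maximum. `phantom.matched_thresholds` therefore uses a **volume-preserving
calibration** — the microscopy analog of calibrating on beads of known
size: render canonical capsules of the channel's geometry at unit intensity
under the generator's PSF (noise-free, fixed internal seed) and take the
threshold fraction at which the count of supra-threshold voxels equals the
truth count. That fraction, scaled by the attenuated plateau intensity
(per depth-segment midpoint for green; at the mean segment midpoint for
the single red threshold), is the matched threshold. The calibration
depends only on generator parameters. For recovery runs smoothing is
disabled (the large threshold margin over the noise floor makes it
unnecessary, and smoothing would re-introduce the thin-object bias) and
`min_object_voxels` = 4.

Residual accuracy, measured on five default phantoms per setting: red
biovolume within ~5% of truth per segment, green within ~10% (a consistent
positive bias of 5–10% remains from noise crossing near the threshold,
halo merging of adjacent rods, and blur bleeding across the red-mask
boundary). In the noise-free limit with thresholds below the plateau,
segmentation equals truth voxel-for-voxel (Jaccard = 1). Green truth is
compared after shielding by the red mask, since cross-channel masking
redefines the green measurand as "green outside the red isosurface".

## Quantification and statistics

* Biovolume % = 100 · (cell voxels with center in segment) / (all voxels
  with center in segment); segment volumes are voxel-count exact, so cell
  volumes sum exactly across disjoint segments.
* Species ratios are computed **per replicate** and then summarized (not as
  a ratio of means), pairing green/red records on (condition, day,
  replicate, segment); zero red biovolume flags the record undefined and
  excludes it from summaries with a logged count.
* Box statistics: type-7 (linear-interpolation) quartiles — the common
  default; the original plotting software's algorithm is not verifiable —
  Tukey whiskers at the most extreme data within 1.5×IQR, clamped never to
  fall inside the box (the standard drawing convention), values beyond them
  reported as outliers.
* The two-sample comparison is **Welch's** unequal-variance t-test (the
  depth-stratified biovolumes show strongly unequal spread between layers,
  so the pooled-variance test would be anti-conservative), two-sided, with
  Welch–Satterthwaite degrees of freedom. The statistic is computed in
  closed form in this package and cross-checked in the test suite against
  scipy's independent implementation to 1e-10; box statistics are
  cross-checked against matplotlib's `boxplot_stats` the same way. Raw
  p-values are reported; a Benjamini–Hochberg column (via statsmodels) is
  an optional, clearly labelled extra.

## Proteomics ranking

Within-sample ranking (most abundant = 1) with average-of-positions for
ties; a "competition" policy is available by flag (ties are not addressed by
the source workflow's description; average is the reversible default).
ND means *no abundance value in that sample*; zero abundance is invalid
input. Per-condition summaries report mean and sample SD (ddof = 1) of
ranks over detected replicates — SD 0.0 with a detected-replicates count of
1 flags single-replicate estimates; a half-range option ((max−min)/2) is
available since for n = 2 the two conventions differ by √2 and the source
layout does not disambiguate. Exclusive detection is strict by default: a
protein must be detected in every replicate of the focal condition and in
none of the other. The synthesizer plants a known exclusive set in an
otherwise fully detected log-normal table (~2,300 proteins, two replicates
per condition, natural-log abundance SD 2 with replicate scatter 0.25), so
planted-set recovery is exact by construction; detection dropout is
deliberately not modelled. Internal-standard normalization (division by a
named reference protein per sample) is exposed but does not affect ranks.

## CFU accounting

`CFU/L = colonies × dilution_factor / plated_volume`; resident:detached
ratios use means per (condition, source), with optional delta-method error
propagation `sd(r) = r·√((sd_R/R)² + (sd_D/D)²)`. On the built-in reference
plate-count means the N₂-fixing : nitrate-fed retention fold evaluates to
≈ 2.84 — consistent with the "almost twice as high" phrasing of the
results it summarizes; the stronger "three times higher" phrasing that
appears elsewhere in the same source is not supported by the printed means,
and the package simply reports the computed value.

## What the phantom tests do and do not show

Passing recovery tests establish that the segmentation and quantification
chain is unbiased to within ~10% under the generator's imaging model:
opaque constant-emission cells, shift-invariant Gaussian PSF, single-
exponential depth attenuation, mixed Poisson–Gaussian noise, and no
extracellular matrix signal, heterocysts, motion, or refractive-index
heterogeneity. Real stacks violate several of these (depth-dependent PSF,
autofluorescence gradients, EPS scattering), so phantom accuracy bounds
are a necessary, not sufficient, condition for accuracy on real data.
Thresholds for real stacks remain the user's responsibility; the defaults
(30 red; 14/12/10 green) reproduce the conventional workflow's settings,
while `matched_thresholds` applies only to phantoms whose imaging
parameters are known.

## Known limitations

* No image registration: retention analysis assumes aligned grids (phantom
  pairs are generated aligned).
* No per-cell instance segmentation or filament tracing; masks are
  voxel sets.
* The CLI's `all` subcommand analyzes phantoms only; real stacks go through
  `segment` / `quantify` / `profile` with explicit thresholds.
* Proprietary microscopy containers (.ims, .czi) are not read; convert to
  multi-page TIFF with a JSON sidecar.
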