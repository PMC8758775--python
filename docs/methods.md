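# Methods

This note documents the models, parameter choices and numerical conventions
behind `choroidchip`, and what the synthetic benchmarks do and do not show
about real data.

## 1. Image model and synthetic scenes

The recruitment pipeline consumes two-channel 3D stacks of the stromal
(melanocyte) compartment. The synthetic generator emulates the acquisition
geometry those stacks have: 43 z-slices in 3 µm steps (slice centers span
126 µm) sampled at 1.66 µm in xy, on a 16-bit-like intensity scale
[0, 65535].

**Cells.** PBMCs are spheres with radii drawn from a clipped normal
(mean 5.5 µm, sd 0.75 µm, clipped to 4.0–7.5 µm, i.e. diameters within
8–15 µm). The red (cytoplasmic cell-tracker) channel holds the full sphere
at foreground intensity (default 10 000 over a background of 200) with a
mild quadratic radial falloff (`center_weighting`, default 12%). The falloff
matters: a perfectly flat, hard-edged sphere is unphysical — real cells are
shaded toward their rim by the point-spread function and dye distribution —
and under three rounds of unsharp masking a flat sphere develops a
rim-bright "crater" whose two pole maxima can exceed the seed-suppression
window and split one cell into two. The foreground level was chosen so that
preprocessed cell cores sit comfortably above the fixed red seeds threshold
(1000) while the background stays far below the image threshold (500).

**T cells.** The first `round(tcell_fraction · n)` placed cells carry, in
the green (CD3) channel, a hollow shell of thickness 1.5 µm straddling the
sphere surface, the interior staying at background — mimicking surface
staining, which is exactly what the morphological closing step exists to
fill.

**Placement.** Cells are placed by rejection sampling with a minimum
center-to-center distance of `max(r_i + r_j + shell, 13 µm)` and a full
margin to the scene faces; a bounded retry budget raises a "scene too
crowded" error. The 13 µm floor is the generator's operational definition of
*well-separated*: seed detection suppresses non-maxima within a Chebyshev
radius of 4 cubic voxels (6.6 µm per axis, up to ~11.5 µm diagonally), so
two cells packed tighter than that share one seed and merge — in synthetic
and in real data alike. Consequently the exact-recovery benchmarks say
nothing about clumped infiltrates; on real tissue the pipeline undercounts
aggregates, which is an inherent property of the published parameters, not
of this implementation.

**Noise.** Noise is Gaussian per voxel with shot-like scaling: the standard
deviation equals `noise_sd · sqrt(I/fg)` at a voxel of noise-free intensity
I, i.e. `noise_sd` *is* the foreground noise level, and the dark background
is correspondingly quiet, as photon-limited detection makes it. A
constant-variance alternative was evaluated and rejected: with noise at 10%
of foreground spread uniformly over the dark background, the green channel's
per-chip threshold constants (4.4%/2.2% of max_green) land inside the
post-filter noise tail and produce hundreds of spurious green seeds per
scene — a regime in which no implementation of the published green
normalization can classify T cells, and one that does not correspond to any
realistic acquisition of a dark background. The generator does not model
PSF blur, photobleaching, melanocyte autofluorescence or tile-stitching
artifacts; recovery results transfer to real data only to the extent that
those effects are secondary to counting statistics.

## 2. Preprocessing

Order of operations: z-rescale → unsharp (per-channel repeats) → hybrid
median (red/green) → closing (green). All filters reflect at borders, which
avoids the edge darkening a zero pad would cause in seed detection near the
compartment boundaries.

- **z-rescale** (factor 1.8): linear interpolation along z onto
  `round(nz · 1.8)` slices with endpoints fixed; output z spacing is
  `old/1.8` exactly (3/1.8 = 1.667 µm). Because the conventional report of
  this step declares the result cubic at the xy edge (1.66 µm), the
  pipeline's default `snap_to_xy` labels the output spacing cubic when z is
  within 2% of xy; the realized edge is always available on the stack.
- **Unsharp masking** (σ = 5 voxels, kernel truncated at 3σ): each pass
  subtracts the Gaussian-blurred copy from the input and clamps negatives to
  zero, preserving the non-negativity the watershed thresholds assume. Red
  and green get three passes, blue one.
- **Hybrid 3D median**: each voxel becomes the median of three values — the
  median of its in-plane 3×3 neighbourhood, the median of the 3D
  axis-diagonal neighbourhood (8 cube corners + center), and the center
  voxel itself. This median-of-medians preserves thin structures (shells,
  small cells) that a plain 3×3×3 median erodes; the plain variant is
  available behind `plain_median`.
- **Closing** (green, ball radius 2): grayscale dilation-then-erosion; fills
  shell interiors narrower than the ball, is extensive and idempotent.

## 3. Seeded watershed

Seeds are voxels ≥ the seeds threshold whose intensity is maximal over the
Chebyshev ball of radius 4; a flat plateau of tied maxima yields one seed at
its lexicographically smallest (z, y, x) index (adjacent tied maxima are
necessarily equal-valued, so plateaus are 26-connected components of the
candidate mask). Flooding assigns voxels ≥ the image threshold in order of
descending intensity, ties resolved first-in-first-out, each voxel taking
the label of the already-assigned neighbour that first enqueued it; seeds
are pre-assigned before flooding starts, and 26-connectivity is used
throughout. This makes results deterministic across runs and platforms.
Contested boundary voxels therefore go to whichever basin reaches them
first at equal priority (greedy assignment, no watershed lines) — note that
implementations which pop markers by their own intensity (e.g.
scikit-image's) can order contested voxels differently; the tests compare
against scikit-image only where the partition is unique.

Red thresholds are the fixed 1000/500. Green thresholds are
0.043574883 · max_green and 0.021787442 · max_green, with max_green taken
from the *preprocessed* green channel (the image the thresholds are applied
to); a switch to the raw maximum exists. A blank green channel
(max_green ≤ 0) is reported as an error at the threshold level and as a
zero-T-cell result at the pipeline level.

## 4. Quantification

Centroids are unweighted means of member-voxel centers (voxel i at
`i · spacing`); volumes are voxel counts times the voxel-volume product,
with a warning when the spacing is not cubic. The size filter drops objects
*strictly* smaller than 30 voxels, so a 30-voxel object is kept
(30 · 1.66³ = 137.22888 ≈ the conventionally printed 137.22 µm³). T-cell
classification takes the maximum of the binarized green map over each red
object's voxels: one shared voxel suffices. Depth bins default to 0–63 µm
(bottom) and 64–126 µm (top); a centroid is *bottom* iff z ≤ 63 µm, which
assigns fractional centroids in the open gap (63, 64) to the top bin while
preserving the printed bottom range exactly. Centroids outside the analyzed
depth are counted in the nearest bin and logged. Tiled chips are quantified
tile by tile and summed, assuming overlap-free tiling.

## 5. Permeability kinetics

Traces are min/max-normalized per channel (minimum = background from the
pre-perfusion reference frame, maximum = plateau). The fit model is a
Hill-type sigmoid in time with asymptotes fixed at 0/1 on normalized data,
`response(t) = 1/(1 + (t50/t)^h)`, chosen over the 4-parameter variant
(available via `free_asymptotes`) because two parameters are stable at 181
samples. Initialization is deterministic and data-driven: t50 at the first
upward 0.5 crossing (linear interpolation), slope at 1. Least squares, no
outlier handling. A fit is *converged* only when the optimizer succeeded
and t50 lies inside the sampled range; lags are defined only between
converged fits and unconverged channels are reported, never dropped
silently. The synthetic trace generator uses the same Hill family (default
t50 = 600 s, h = 4, 0–2700 s at 15 s steps — a realistic mid-window filling
curve), so noise-free recovery isolates optimizer behaviour; with free
asymptotes or real traces the model-mismatch error would add to it.

## 6. Seeding density

`cells_in_channel = fraction · V_channel / (π/6 · d³ · expansion)`, with
V in µm³ (1 µL = 10⁹ µm³), then concentration = cells/V_channel and total
cells = concentration × seeding volume. Defaults: channel 1.5 µL, seeding
volume 5 µL, expansion factor 3.68, diameter 28.5 µm, fractions 5%/50%.

## 7. Problem sizes and tolerances

The test suite and acceptance script run on 96×96×43-voxel scenes with 20
cells (8 noise-free and 20 noisy scenes in the tests; 4 and 10 in the
acceptance script), 200 random ≤ 512-voxel grids for the brute-force oracle
battery, and 100 noisy traces for fit calibration — sizes at which every
check completes in seconds while counting statistics remain meaningful.
Recovery is asserted exactly for noise-free scenes, within ±5% of pooled
counts at foreground noise 10%, within 1% for noise-free t50, and <5%
median error for noisy t50; oracle comparisons are exact for integer
filters and to 1e-8 for floating-point convolution.

## 8. Known limitations

- No PSF/optics simulation; no autofluorescent melanocyte texture; the
  green channel contains nothing but shells and noise.
- Absolute recruitment counts per condition (treatment effects, donor
  variability) are experimental quantities outside what synthetic scenes
  can reproduce.
- The watershed is greedy; cells touching within the seed-suppression
  window merge (see §1).
- No absolute permeability coefficient; the lag readout is relative by
  design and hydrogel-vs-medium diffusion differences between channels are
  not modelled.
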