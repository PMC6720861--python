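# Methods

This note records the models, conventions and numerical choices behind
cytotile, and what the synthetic-data tests do and do not demonstrate.

## Experiment model and configuration

An experiment is a 7-D acquisition: `regions × grid_rows × grid_cols ×
cycles × channels_per_cycle × z_planes × (y, x)`.  Exactly one channel per
cycle has the `reference` role (a nuclear stain imaged in every cycle);
other channels are `expression` or `membrane`.  All counts may be 1, so the
smallest legal experiment is a single 2-D grayscale image — subject to a
minimum tile edge of 88 pixels, enforced as a named policy constant
(`MIN_TILE_EDGE`) with an explicit `allow_small_tiles` escape hatch rather
than as a hard-coded magic number, because it is policy, not physics.

Indices in configuration files and raw file names may be 1-based
(acquisition convention, the default) and are normalized to 0-based at
parse time; every index inside the library is 0-based.  Tile overlap is
one-sided (trailing edge): tile (r, c) sits at
`(r·(H−oy), c·(W−ox))` in region coordinates.  This convention is a choice;
the alternative (symmetric per-edge overlap) would shift all positions by a
constant and change nothing structural.

Deltas address serialized-config leaves by dotted paths with numeric list
indices (`channels.1.name`).  Unknown paths are errors except under
`operations`, where new keys may be created — pluggable operations need
room for their own parameters, but a typo in core geometry must not pass
silently.  Delta application is last-write-wins and associative over
sequential application.

## Tile assembly and prefetch

Raw planes must be unsigned 8- or 16-bit; anything else is rejected rather
than silently converted, and missing files abort by default
(`allow_missing` fills zeros and is meant for salvage only, since silent
zeros corrupt quantification).  The prefetch iterator acquires a queue slot
*before* assembling a tile, so at most `queue_capacity` assembled-but-
unconsumed volumes exist at any time; capacity affects buffering only,
never content or order (row-major by region then tile).

Hyperstacks are ImageJ-convention TIFFs with cycles→frames (T), z→slices
(Z), channels→channels (C); channel names ride in the ImageJ `Info`
metadata and round-trip through `read_hyperstack`.

## Cycle registration

Drift is modeled as one 2-D translation per cycle.  It is estimated between
maximum-intensity z-projections of the reference channels of cycle 0 and
cycle c — projections are robust to focus differences between cycles, and
no axial drift correction is attempted.  All cycles register to cycle 0
rather than chaining cycle-to-cycle, avoiding error accumulation.

The estimator is frequency-domain cross-correlation: the integer peak of
`ifft2(F_ref · conj(F_mov))`, refined to 1/u pixel by evaluating the
correlation on a u× upsampled grid in a ~1.5-pixel neighbourhood of the
peak via a matrix-multiply DFT.  Equal maxima (possible on periodic
content) are broken deterministically: smallest |dy|+|dx|, then smallest
dy, then dx.  The reported `error` is the standard normalized-RMSE metric
derived from the correlation peak.  An independent implementation of the
same algorithm (scikit-image's phase cross-correlation) serves as a
cross-check in the test suite, and a brute-force argmax over all integer
shifts pins the integer path.

Applying a shift: integer translations use pure array slicing with zero
fill (bit-exact, the u = 1 path); fractional translations use a
frequency-domain phase shift with the wrapped margin zeroed.  Cycle-0 data
are never modified.  Constant reference images make drift unidentifiable;
they produce a zero shift flagged `degenerate` instead of failing the tile.

## PSF generation and deconvolution

The PSF model is the scalar-diffraction Gibson–Lanni pupil integral with
optical path difference `W(ρ; z) = z·√(n_i²−NA²ρ²) + p_z·√(n_s²−NA²ρ²)`
(defocus through immersion plus emitter depth in the sample; default depth
0).  Rather than quadrature per voxel, the oscillatory factor `exp(ikW)` is
fit per z-plane, by least squares over 1000 radial pupil samples, to a
basis of scaled Bessel functions J₀(σ_m ρ) with σ spacing 1.5; each basis
term has a closed-form integral against J₀(βρ)·ρ, so the field reduces to
one small matrix product per z.  The basis size adapts to the maximum phase
frequency (bounded by the axial extent) and is capped at 600.  The kernel
is sampled from the radial profile — hence exactly mirror-symmetric in x
and y — and normalized to unit sum.  A slow adaptive-quadrature evaluation
of the same integral lives in the test suite only and agrees with the fast
path to well under 1%.

Richardson–Lucy uses multiplicative updates with FFT convolutions.  Each
convolution re-pads the current estimate with reflection padding of half
the PSF extent and crops afterwards; re-padding every application (rather
than padding once) makes the FFT path match a per-convolution reflective
spatial filter, so no wrap-around contamination accumulates across
iterations — the suite holds the 10-iteration result to within 1e-4
relative error of a literal spatial-domain implementation.  The ratio
denominator carries a guard ε = 1e-12; the PSF is renormalized internally,
making the output invariant to kernel scaling; `n_iter = 0` returns the
observed volume as float.  Default 10 iterations — flux is approximately
conserved (within 5% on interior-supported volumes; exact conservation is
not claimed under edge padding) and restoration error on bead phantoms is
well below the blurred input's.  One PSF per emission wavelength is cached
per run, since the kernel is identical across tiles by construction.
Whether the reference channel is deconvolved is controlled by the same
per-channel mechanism as other channels and defaults to on.

## Focus scoring and best-z

Scorers are registered by name behind one interface, replacing a learned
image-quality classifier with classical metrics so no trained weights are
required; any model can be plugged in.  Two scorers ship:

- `laplacian_variance` — variance of the discrete Laplacian of the min-max
  normalized plane; the classical textbook metric and the `score_focus`
  default.
- `log_variance` — variance of a Laplacian-of-Gaussian (σ = 2 px) of the
  mean/std-standardized plane; the *pipeline* default.  The reason for the
  distinction: with shot/read noise at realistic photon budgets, min-max
  normalization amplifies the (equally sharp) pixel noise of dim defocused
  planes until it dominates the Laplacian variance and can rank defocused
  planes above the focal plane.  The σ = 2 pre-smoothing suppresses pixel
  noise while barely affecting structure at the scale of nuclei, and
  standardization keeps the score exactly invariant under a·I + b, a > 0.

Best-z is selected once per tile on the cycle-0 reference channel and
reused for all channels, keeping masks and intensities on one coherent
plane; ties go to the smallest z.

## Segmentation

Probability generation and nucleus post-processing are deliberately
decoupled.  The bundled generator is classical — Gaussian smooth (σ = 2
default), Otsu threshold, hole fill; eroded mask = interior, rim =
boundary, complement = background; hard masks softened to 0.9/0.05/0.05
margins so the output is a genuine per-pixel distribution with the argmax
preserved.  Any semantic segmentation model producing the same 3-class
contract can replace it.

Nucleus post-processing is fixed: pixels whose argmax class is the
interior, 4-connected components, removal below `min_nucleus_size`,
relabeling 1..K in scan order, then a one-pixel dilation that never merges
labels.  The dilation assigns each background pixel in the 8-neighbourhood
of a label to its *nearest* label (edge adjacency, distance 1, beats
diagonal adjacency, √2) with exact ties to the smaller label; it is
implemented by exact nearest-site queries (KD-tree over labeled pixels)
rather than a distance-transform feature map, because the feature map
breaks ties arbitrarily.

Cell expansion preserves, in every mode, the invariants: identical label
sets for nuclei and cells, nucleus k inside cell k, cells confined to the
allowed mask.

- *Fixed radius*: all pixels within Euclidean distance r of a nucleus, ties
  to the smaller label (same exact nearest-site machinery).
- *Watershed*: the smoothed membrane image is thresholded (Otsu default)
  into a mask, union-ed with nucleus support; the watershed floods the
  distance-to-nearest-nucleus landscape from the nucleus seeds restricted
  to that mask.  Mask components containing no seed are dropped first —
  they are unreachable, and dropping them keeps pixel conservation (total
  cell area = masked area) exact.
- *Propagation*: seeded lowest-cost growing in Dijkstra order over the
  4-connected masked grid; the step cost between adjacent pixels is
  `(I(p) − I(q))² + λ` on the max-normalized membrane image, i.e. squared
  intensity difference plus λ times the squared unit step.  λ → ∞ recovers
  the nearest-seed partition (geodesic within the mask); λ = 0 makes
  boundaries follow intensity ridges.  Default λ = 1 on the unit intensity
  scale.  Cost ties resolve to the smaller label via the heap ordering.
  The exact cost combination is implementation-defined and isolated in one
  function.

Border-touching cells are kept by default; `exclude_border_cells` drops
them (and their nuclei) when partial cells would bias morphology.

Everything is 2-D on the best-focus plane: the single-cell output of this
kind of assay is two-dimensional per tile, and 3-D segmentation is out of
scope.

## Quantification

`regionprops` supplies areas, centroids and the weighted boundary-segment
perimeter estimator; circularity 4πA/P² with that estimator stays in
[0.9, 1.05] for discs down to radius ~10 px, whereas a raw pixel-edge
perimeter would bias it far from 1.  Diameter is defined as 2√(A/π)
exactly.  Intensity means are taken on the best-z plane of each channel on
the processed (registered, optionally deconvolved) scale with no
normalization — normalization is an analysis decision for downstream
gating tools.  Adjacency is 4-connected: neighbors share ≥ 1 cross-label
pixel pair, the contact boundary counts such pairs, and the relation is
symmetric; a brute-force all-pixel scan pins the implementation in tests.
An optional all-z averaging mode exists but is off by default.

## Export

CSV carries every column (floats at %.17g, which round-trips float64
exactly); FCS 3.1 carries the numeric columns as little-endian float32
list-mode events, one per cell, no transformations — written by a small
writer covering exactly the needed subset of the standard, with a matching
reader used for round-trip tests.  Montages paste tiles row-major at their
physical positions; the later tile overwrites the earlier tile's trailing
overlap strip (deterministic trim; blending is a non-goal).  Downscaling is
stride subsampling so label/boundary images survive without interpolation
artifacts.  Global cell coordinates always refer to region pixel space at
scale 1, independent of montage downscaling.

## Synthetic data generator

The generator emulates the features each stage consumes, not tissue
realism: nuclei are Gaussian intensity profiles (σ = r/1.5) at
non-overlapping random centers (minimum spacing 2·r_cell_max + margin by
rejection sampling; infeasible densities are an error, not a hang);
membrane channels are rings at the cell radius; expression channels are
per-cell constant discs with 1-px anti-aliased rims.  Axial structure is a
Gaussian intensity falloff around a mid-stack focal plane *plus* defocus
blur growing 1.5 px of σ per plane off focus — dimming alone carries no
focus information for any scale-invariant scorer, blur does.  Per-cycle
drift (cycle 0 anchored at zero) translates the rendered scene, optionally
fractionally; registration must recover its negation.  Noise is Poisson at
a configurable photon budget plus additive Gaussian, then 16-bit
quantization at 20000 counts per unit intensity.  One integer seed drives
all randomness; regeneration is byte-identical.

What passing tests show: geometric contracts, drift recovery to ≤ 0.5 px at
drifts up to 8 px, cell-count recovery within 5%, and nucleus-mean
expression recovery to well under 2% under zero-to-moderate noise.  What
they do not show: robustness to illumination fields, photobleaching,
overlapping or irregular cells, debris, or contrast regimes where a learned
probability model would outperform Otsu — real-data performance depends on
the probability generator plugged in.

## Problem sizes

Default test and acceptance runs use deliberately small instances chosen as
the smallest sizes that exercise every code path meaningfully: 96–160 px
tiles, 2×2 grids, 2–3 cycles, 3 z-planes, ~10 cells per tile, 16³–48³
deconvolution volumes, and one full-scale stitch (9×7 grid of 1008×1344
tiles) to pin mosaic geometry at realistic dimensions.

## Known limitations

- Translation-only registration; rotation or deformation between cycles is
  not modeled.
- The Gibson–Lanni model assumes design-condition immersion and a single
  sample index; no empirical PSFs, no blind deconvolution.
- Propagation segmentation is O(pixels · log pixels) in pure Python and is
  the slowest cell mode on large tiles.
- FCS support is the float32 list-mode subset sufficient for these tables,
  not a general FCS reader.
- Parallel tile execution is permitted by the contract (results must be
  schedule-independent) but the bundled executor is sequential with
  prefetch.
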