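# Methods

This note records the models behind `favf`, the defaults and why they were
chosen, the numerical decisions that matter, and what the synthetic
benchmarks do and do not demonstrate.

## The imaging model

A cell is modelled as a uniform fluorescent disc of focused diameter `D`
(µm).  With the image plane `|z|` µm from the cell's focal plane the blur
diameter follows the linear law

    D_n = D + blur_slope · pixel_size · |z|,

and the observed image is the focused disc convolved with an isotropic 2-D
Gaussian point-spread function of spread

    σ = psf_sigma_per_blur · (D_n − D) / 2.

The kernel integrates to one, so a cell's total brightness is conserved
under defocus — only dispersed.  Images at `+z` and `−z` are identical for
a centred cell; the sign ambiguity that the depth module must resolve is
therefore genuinely present in the simulator.  Beyond `valid_depth_range`
(default 40 µm) the emission is attenuated to the noise floor, modelling
fluorescence becoming too weak to recognise.  Noise is additive Gaussian
followed by clipping to the grey range; shot noise is not modelled.

Rendering is performed on a 4× supersampled grid (disc rasterisation and
PSF convolution, then exact box binning).  This keeps the edge profile the
physical one: at the ordinary grid, the rasterisation ramp acts as an extra
~0.3 px pseudo-blur that does not scale with defocus and visibly bends the
width-versus-depth law near focus.

Default optics: `pixel_size` 1 µm/px, `blur_slope` 0.4 px/µm,
`psf_sigma_per_blur` 1.25, background 8 grey levels, read noise σ = 1 grey
level, cells 16 µm in diameter at peak 180 (NIH/3T3-like mouse fibroblasts
at a typical 1:100 red:green staining mixture).  These were fixed together
so that (a) the blur diameter recovered by the measurement pipeline tracks
the model `D_n` (the calibration criterion for `psf_sigma_per_blur`), and
(b) the default 5-scale × 1.15 template pyramid spans the 0–40 µm working
range, where `D_n(40 µm) = 2 D`.  A peak signal-to-noise ratio of ~180 is
high but representative of a cooled CCD imaging a brightly stained
membrane dye.

The pipette is a thick segment with a round cap at the tip, red-emitting,
19 µm wide (the pulled tip's inner diameter), defocused by the same law.
The tip simulator can fade the emission per frame (quenching), grow the
apparent width (impurity adsorption) and slowly rotate the shaft about the
tip — appearance drift that leaves the true tip position unchanged, which
is the clean way to exercise template updating.

## Planar locating

The correlation score is the mean-subtracted cross-correlation divided by
the L2 norms of the mean-subtracted template and window, giving
`R ∈ [−1, 1]`.  The normalisation is what makes one acceptance threshold
(default 0.6) transferable across template scales; without it the score
scales with template size and energy.  Zero-variance windows and constant
templates score 0.  The map is computed with an FFT cross-correlation plus
integral-image window statistics and is verified in the tests against a
direct double-sum oracle.

Rough locating pools local maxima over all pyramid scales and applies
greedy non-maximum suppression (radius = half the winning template's
width; ties broken toward the smaller (x, y)), so each target keeps its
best-fitting scale.  ROIs are the detection boxes expanded 1.5× — blur
grows during the depth sweep and must stay inside the ROI.  Precise
locating refines the peak with a 1-D parabolic fit per axis (clamped to
±0.5 px).

## Depth from defocus

Depth follows from similar triangles:

    d_n = (D_n − D) / (D_n+1 − D_n) · d.

Per-plane measurement: grayscale conversion (channel maximum — each object
emits in one channel), Gaussian smoothing, 1-D k-means on grey values with
k = 3 (background / blur edge / cell body; quantile-seeded Lloyd
iterations, deterministic), merge edge+body, keep the qualifying connected
component (largest, or nearest the ROI centre when the ROI was cut around
a specific detection), convex hull, image moments for the centre, and the
width of the cell along the horizontal line through the centre as `D_n`.

Numerical decisions that proved essential, in the order they matter:

- **Cut level.**  The width is cut at the k-means background/edge decision
  boundary, floored at 15% of the body amplitude: on a crisply focused
  cell the three clusters split the background rather than the skirt, and
  an unfloored boundary falls into the noise.
- **One level per estimate.**  All widths entering one depth equation (or
  one linearity fit) are re-cut at a single common level (the lowest of
  the per-plane boundaries).  Per-plane levels shift as blur spreads, and
  that shift is larger than the sub-pixel width differences the equation
  divides.
- **Quadratic edge interpolation.**  Crossings are solved on local
  3-point parabolas (both brackets, averaged).  Linear interpolation
  carries a sampling-phase-dependent bias of up to ~0.2 px per edge on the
  curved Gaussian flank — harmless for locating, fatal for a denominator
  of ~0.5 px at the 2 µm step interval.
- **Profile row.**  The PGDC is sampled at the fractional centre row by
  bilinear interpolation, and preprocessing smooths more strongly across
  rows (σ 1.0) than along them (σ 0.25): row pooling averages read noise
  without blurring the horizontal edges that carry the width signal.
- **Focused diameter.**  `D` comes from the intersections of
  centre-aligned profiles from different planes.  Only strict sign changes
  of the difference count; crossings below a grey floor (background
  noise), outside the narrowest measured blur radius (physically
  impossible), or far from mirror symmetry about the centre are rejected;
  among the surviving symmetric pairs the outermost wins.  In the
  iterative estimator the running `D` refuses single-round jumps larger
  than 20% — near focus the profiles nearly coincide and their crossings
  turn unreliable.

The three-image estimator brackets the current plane at ±d.  The side of
the cell follows from the flank comparison (less blur = nearer).  Two
closed-form geometric regimes exist — cell beyond the bracket (blur
changes by α·d per step) and cell inside it (V-shaped blur profile) — and
the one whose predicted diameters better match the three measurements is
used; candidates implying a depth beyond the visibility range are
discarded, single hops are clamped to half the range, and a hop that would
still leave the range while the cell remains measurable stops the
iteration instead (that contradiction indicates a corrupted ROI, e.g. two
cells at different depths, not an out-of-range cell).  Out-of-range status
is reserved for targets whose fluorescence is unrecognisable at every
plane of the first bracket, and for single-pass estimates beyond the
range.  Convergence is declared when a hop falls below 1 µm; two or three
rounds suffice on clean input.

The single-pass evaluation (`run_error_sweep`) images each cell at
defocus `d_i` and `d_i + d`, moving away from the focal plane, and applies
the equation once.  Pairs whose second plane would exceed the 40 µm
visibility limit are recorded OOR rather than scored — which is why, at
step 12 µm, initial depths of 30 µm and beyond cannot be evaluated.
Accuracy is reported with `e = |d_n − d_i| / (|d_n| + D) · 100%`, the
focused diameter acting as a regulariser for near-zero depths.

## Instance segmentation

The chain is channel threshold → Otsu binarisation → opening (disc radius
2 px) → Euclidean distance transform → threshold at 0.6 of the maximum for
markers → marker-controlled watershed on the inverted smoothed intensity
(bright centres are basins).  The background water hole is a 5×5 block in
the top-left corner, falling back to the emptiest corner if the foreground
reaches it.  Cell centres are intensity-weighted centroids of the flooded
regions, because each basin also sweeps up part of the flat background
plateau.

The marker threshold is 0.6 rather than the midpoint because overlapping
fluorescence is additive: the waist between two merged discs is brighter
and therefore *fatter* after binarisation than the geometric intersection,
and a 0.5 threshold leaves the distance cores connected.  Even at 0.6 the
scheme has a geometric separability limit near centre spacings of ~1.7
cell radii; the cluster benchmarks place adjacent cells at 1.8–2.0 radii —
footprints genuinely intersecting, but separable.  Under-segmentation is
reported in the result, never retried with altered thresholds, so the
closed loop stays deterministic.

## Tracking

The search window has three times the template's *area* (side × √3),
centred on the last match; a side-tripling mode is available.  The overlap
score is intersection-over-union with the 70% accuracy criterion.  The
template refreshes from the newest match only when the appearance has
actually drifted (score in [0.8, 0.95)) and at most every 5 frames:
refreshing a pristine match only accumulates re-registration drift, which
measurably *hurts* — with this policy the adaptive tracker dominates the
frozen-template tracker under appearance drift at every drift rate tested.
The reference speed of 5 µm/frame corresponds to 300 µm/s at 60 fps.

## Sorting loop

Aspiration physics is reduced to a capture radius (9.5 µm, the pipette
inner radius) around the tracked — not the true — tip position, plus an
optional mis-capture probability (default 0).  Per-FOV flow: rough locate
on the red channel (pipette lifted out of view during detection), MDFD per
ROI, refocus, precise locate, watershed separation for overlapping boxes,
stepwise pipette approach (≤ 5 µm per step) under tracking with
re-initialisation on loss, aspirate, remove the cell from the world,
repeat; unresolvable targets are skip-listed.  Fields of view raster the
dish serpentine-fashion with 10% overlap so border cells are never missed.
Speed is reported as cells per simulation step, never wall-clock.

## Evaluation protocols and problem sizes

- Blur linearity: 10 cells × 6 unequally spaced planes at 2–20 µm (the
  precise working regime), mild noise; mean R² of the per-cell
  depth-vs-width line.
- Iterative depth: 10 cells, random signed depths 4–20 µm, step 6 µm, run
  to convergence; mean relative error and iteration count.
- Single-pass sweep: initial depths {4, 6, 8} µm × steps {2 … 12} µm × 10
  cells; the reported number is the worst cell-mean in the grid.
- Detection: 9 depth groups spanning 0–40 µm × 20 single-target scenes;
  a trial counts only with exactly one detection within 5 px.
- Tracking: 1500 frames at 5 µm/frame with slow quenching fade.
- Sorting: a noise-free 420 µm square virtual dish with 20 targets among
  2× background cells.

These sizes keep the full benchmark suite in a few minutes on one core
while leaving the statistics stable across seeds.

## What passing these benchmarks shows — and what it does not

The simulator realises exactly the modelling assumptions the algorithms
are built on: linear blur growth, an isotropic Gaussian PSF, energy
conservation, uniform disc cells, additive Gaussian noise, a static scene
between frames.  Passing therefore demonstrates internal consistency and
numerical correctness of the vision chain — sub-pixel measurement,
symmetry resolution, convergence — under controlled conditions, including
conditions (exact ±z symmetry, known ground truth) that are hard to set up
physically.  It does not demonstrate robustness to the things real
microscopy adds: non-Gaussian and spatially varying PSFs, aberrations,
shot noise, debris and impurities, non-circular or textured cells,
photobleaching during the sweep, or stage backlash.  Real deployments
should expect the detection and depth margins measured here to shrink.

## Known limitations

- Depth estimation assumes one cell per ROI; a second cell at a different
  depth degrades the estimate to "estimated" status rather than failing
  loudly, and the closed loop recovers only because aspirating one member
  of a pair frees the other.
- The watershed separability limit (~1.7 radii centre spacing) is
  inherent to single-scale distance-transform markers.
- The sweep protocol cannot score depths where `d_i + d` exceeds the
  visibility range (reported OOR), so the far half of the range is only
  covered by the iterative estimator.
- `kmeans_segment` clusters grey values only (no spatial term); heavily
  textured backgrounds would need the spatial variant.
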