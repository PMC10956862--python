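# Methods

This note records the model, the parameter choices, the numerical decisions,
and the limits of what the synthetic-phantom validation demonstrates.

## Local center of mass

The LCM of position n is the index average of all positions weighted by
w_{m,n} = exp(−|D_m − D_n|), with D the cumulative weighted edge magnitude
D_n = α Σ_{i<n} |f_{i+1} − f_i|^p. Two indexing conventions for D are
implemented:

* `edge_complete` (default): D_1 = 0 and the sum runs to n−1, so
  D_n − D_m (m < n) counts exactly the edges strictly *between* the two
  positions. Immediately adjacent positions across an edge then attenuate
  each other by the full edge weight.
* `as_printed`: the sum runs to n (with f_{N+1} = f_N), i.e. each position's
  own right-hand edge is included. Kept for fidelity experiments; the two
  differ only by a one-sample shift of D.

Parameters: α (default 2000) controls how opaque an edge of magnitude s is
(weight across it ~ exp(−α s^p)); p (default 1) is the edge exponent. With
α s^p ≥ 50 plateaus are numerically isolated and the profile is piecewise
constant at the interval centers. α is dimensionless relative to the [0, 1]
intensity scale.

### O(N) evaluation

The textbook factorization e^{−D_n} Σ e^{D_m} overflows at α ≈ a few
hundred. Splitting the sums at n and using monotonicity of D gives
recurrences in which every exponent is ≤ 0:

    A_n  = A_{n−1} e^{D_{n−1}−D_n} + n        (prefix numerator, A_1 = 1)
    B_n  = e^{D_n−D_{n+1}} (B_{n+1} + (n+1))  (suffix numerator, B_N = 0)

with primed analogues accumulating +1 for the denominators and
C_n = (A_n + B_n)/(A′_n + B′_n). This is an exact algebraic rearrangement;
agreement with the O(N²) brute force is < 1e−6 (tested over 200 random
signals, α ∈ {1, 200, 2000}, p ∈ {1, 2}) and the recurrences remain finite
at α = 5000. Batched signals of unequal length are padded with a +1e9
energy offset so padded samples carry exactly zero weight without
generating inf−inf NaNs.

## 2D segmentation

For each of K orientations (evenly spaced over [0°, 180°); angle 0 scans
along rows) a family of parallel scanlines at unit spacing is intersected
with the frame; image intensities are sampled bilinearly at unit steps
along each line. C_n − n converts to a signed displacement along the line's
unit vector; each pixel reads the displacement of its nearest line,
linearly interpolated along the line, and the per-pixel field V is the
unweighted mean over orientations.

Tracker iteration: phase 1 advects one tracker per pixel, x ← x + V(x)
(bilinear field interpolation, positions clamped to the frame); phase 2
replaces each tracker by the mean of all trackers within `merge_radius`
(2 px). Trackers closer than 0.25 px are carried as a single weighted
representative — the phase-2 mean is unchanged by this collapsing, which
keeps the update quadratic only in the number of *distinct* accumulation
points. Final representatives within `cluster_eps` (1 px, single linkage)
share a label; labels are numbered by first appearance in row-major order,
making the whole procedure deterministic.

The full-scale profile is K=180, 1000 iterations with 250 in phase 2; the
desk profile (used for all phantom studies and tests, and selected with
`--desk` or `PipelineConfig.desk()`) is K=8, 50 iterations with 12 in
phase 2, preserving the 1:4 phase-2 fraction. Fewer orientations coarsen
the displacement field but leave the attractor structure intact.

An elongated curved structure does *not* generally collapse to a single
accumulation point: its trackers pile up at a handful of modes spaced along
the column (at K=8, tens of pixels apart). Region identity for the spine is
therefore decided at the mask stage, not by demanding one label.

## Pipeline

Read (DICOM/PNG/JPG → grayscale [0, 1], integer dtypes rescaled by dtype
maximum, ≤3 channels collapsed by Rec. 709 luminance, >3 channels rejected)
→ bilinear resize to 256×256 → CLAHE (clip limit 0.01, 8×8 tiles) →
projection-histogram ROI crop (threshold 0.25 of the maximum row/column
projection) → Gaussian denoise (σ=1) → two-level Otsu normalization → LCM
segmentation → background subtraction → Canny (σ=1) → center curve →
classification and angle.

Decisions worth recording:

* **Two-level normalization before segmentation.** The cumulative edge
  energy at α=2000 treats per-pixel noise of σ≈0.02 as ~45 units of energy
  per step, which isolates every pixel. Reducing the ROI to two flat levels
  restores the piecewise-constant regime the LCM weighting is designed for
  and concentrates D at anatomical boundaries. A crop with dynamic range
  below 0.15 contains no background to separate (the ROI collapsed onto the
  spine) and is treated as all-foreground.
* **Background subtraction, not label selection.** Per-label mean
  intensities are split at the midpoint of their extremes; labels below are
  background, the union of the rest (largest 4-connected component) is the
  spine mask. A histogram threshold over a handful of label means is
  ill-posed, hence the midpoint rule. A single-label selection heuristic
  (bright × centered, ties by area) is available as
  `select_spine_label` and via the `--spine-label` override.
* **Center curve.** Per-row midpoint of the outermost Canny wall pixels
  (mean-of-all-edges available as an option), gaps linearly interpolated,
  then a centered moving average of half-width 5 rows with symmetrically
  shrinking end windows. End rows whose wall span is under 90% of the local
  full span are corner slivers of a tilted end vertebra; their midpoints are
  biased by up to half the structure width, so their values are replaced by
  linear extrapolation (slope fit over the 8 nearest reliable rows). This
  keeps the curve's row span, and hence the chord, at the structure's full
  extent.
* **Angle conventions.** `mon` (default) is the angle ∠MON at the
  perpendicular intersection O — equal to 2·atan(|MP|/|OP|) when the
  construction is symmetric, but computed from the rays OM/ON directly
  because the doubled one-sided form amplifies apex jitter into
  multi-degree errors when the apex sits off-center. `eq5_printed` is the
  supplement 180° − ∠MON (identical to 2·atan(|OP|/|MP|) in the symmetric
  case); the two always sum to 180°. The apex is the maximum-|deviation|
  point (literal minimum-column rule available as `min_x`). For S-shaped
  curves the dominant bow is measured and interior chord crossings are
  reported as diagnostics.
* **No-scoliosis branch.** Maximum perpendicular deviation from the
  endpoint chord below `min_dev_px` (3 px at 256×256) reports angle 0 with
  no construction. The threshold is a working-frame pixel scale, not a
  clinical degree threshold.

## Synthetic phantoms

A phantom renders n_vertebrae (12) rectangular blocks of width 24 px,
centered on and aligned with a parametric center curve (circular arc,
cosine bow, or straight), at intensity 0.8 on background 0.2, with optional
additive Gaussian noise (seeded `numpy` `default_rng`; the truth mask is the
noiseless foreground). Blocks occupy equal arc-length slots; the default
gap of 0 renders a contiguous column (a nonzero gap renders dark disc
spaces, which are genuine intensity edges and legitimately split the
column). Contiguous blocks overlap by 0.5 px to avoid wedge notches where
tilted rectangles meet.

Ground truth is defined by the *same* chord/apex/perpendicular construction
applied to the continuous curve at 10× supersampling (apex sample included
exactly by odd sample counts), so the end-to-end error isolates the pixel
pipeline rather than mixing in a second angle definition. For a circular
arc of central angle φ the truth is φ/2 analytically, which the supersampled
construction reproduces to < 1e−6°.

What the phantoms do **not** emulate: ribs, pelvis and shoulder clutter,
projection physics and scatter, intensity inhomogeneity, vertebral rotation
and endplate wedging. Passing the phantom battery therefore demonstrates
the internal consistency and pixel-level accuracy of the measurement chain
under its own geometric definition of truth — not clinical-grade accuracy
against endplate-based Cobb readings.

## Accuracy budget (desk profile, arc phantoms 20–90°)

The batch maximum deviation is ~2.7° and is dominated by deterministic
curve-extraction bias at high curvature (wall-midpoint inward bias of a
horizontally cut annulus, linear end extrapolation of a curved midline,
block-chord flattening), not by noise: the maximum is stable across noise
seed sets. Mean deviation is ~1.1°.

## Known limitations

* The scanline sampling lattice is not exactly equivariant under 90°
  rotation (line offsets are quantized per orientation), so background
  cluster topology can differ after rotating the input; foreground regions
  map consistently.
* `n_regions` for a curved structure grows with curvature at small K; only
  the mask stage, not the label count, is scale-free.
* S-curves are measured on the dominant bow only.
* Multi-frame DICOM, color-calibrated output and vertebra-level endplate
  measurement are out of scope.
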