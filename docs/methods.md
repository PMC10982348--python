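# Methods

## Problem and coordinate conventions

A corneal B-scan is a grid `I(x, y)` with the column `x` a lateral A-scan
position and the row `y` the axial depth (0 at the top). Layer interfaces
appear as over-exposed bright bands; the task is to return, per interface,
an axial position for every usable column. Internally everything is
0-based; CSV exports are 1-based and say so in their header.

An interface position is defined as the **last row above the intensity
transition**. This is the row where the forward-difference gradient
`g(x, y) = (I(x, y+1) − I(x, y))/2` of the transition lives, so the coarse
stage (which finds the first bright pixel) reports `top − 1`, and all
stages, the phantom ground truth included, share one convention. Without
this, coarse and gradient-refined results would disagree by one row
systematically.

Intensities are normalised to `[0, 1]` on load, whatever the source bit
depth; all configuration thresholds live on that scale.

## Pipeline

`segment_bscan` runs: apex detection → crop → horizontal-artifact removal →
central-artifact detection → adaptive (Wiener) denoising → coarse anterior
(boundary function) → parabola fit → gradient refinement → Savitzky–Golay
smoothing → per deeper interface: shift estimation → two-pass refinement.
Final curves are returned in the original frame coordinates, rounded to
pixel rows (boundaries are pixel locations, as manual annotations are);
columns cropped away or inside a detected saturation artifact are masked
invalid rather than interpolated (an optional post-step fills interior gaps
linearly).

Notable choices, stage by stage:

- **Apex detection** takes the first strict local maximum of the row-wise
  intensity summation that exceeds the mean summation, treating a plateau
  as one maximum at its first row; if none qualifies, the global argmax.
  The plateau rule matters for saturated bands whose row sums are exactly
  constant over several rows.
- **Crop margins.** 15 rows are kept above the apex. The depth extent
  defaults to `ceil(1.5 mm / axial resolution)` — comfortably beyond
  corneal thickness plus sag — and `width/16` columns are trimmed per side
  as the low-SNR periphery. All three are configurable.
- **Horizontal artifacts** (full-width bright stripes) are removed by
  subtracting each row's mean; a single global offset then restores
  non-negativity, so each row ends with the same mean and the operation is
  idempotent. Side effect worth knowing: lateral variations in band
  coverage leak a small per-row offset into every column (see
  *Limitations*).
- **Central artifact.** The frame is split laterally into thirds; a middle
  column is excluded when its mean exceeds `4/3 ×` the peripheral-thirds
  mean. The factor is deliberately configurable: reference material prints
  an implausible constant, and a modest multiple of the peripheral mean is
  the defensible reading. With a quadratic peripheral SNR falloff of 0.5
  the centre/periphery column-mean ratio stays below 4/3, so the falloff
  alone never triggers exclusions.
- **Denoising** is the classic pixel-wise adaptive Wiener filter with a
  5×5 window. The global noise power is the **median** of the local window
  variances, which makes the filter an exact no-op on noise-free images
  (the median of mostly-zero variances is zero) and keeps strong edges
  nearly untouched. A mean-based estimate would blur clean phantoms.
- **Coarse anterior.** Candidates are strict A-scan local maxima (plateaus
  contribute their first index) that reach a contrast floor of
  `min + 0.5·(max − min)` of their A-scan — the prior that the brightest
  OCT response sits at the corneal boundary, which keeps dim background
  speckle peaks out of the pair enumeration. Pairs within a
  thickness-derived separation window (2 px to `ceil(1.2 mm/axial res)`)
  are scored with `G = |I(y₁) − I(y₂)| − min I` over the enclosed interval
  (the interval minimum, not only candidate pixels: the formula over the
  printed interval is the self-consistent reading). The winner's top
  member is walked up to the top of its bright run; ties prefer the
  shallower pair.
- **Parabola fit** is two-pass least squares: fit, drop points with
  absolute residual above `3 ×` the median absolute residual, refit. The
  fitted polynomial bridges every column; artifact exclusions are
  re-applied afterwards.
- **Refinement** seeds at the central valid column with the in-window
  `|g|` argmax, then walks outward. A candidate offset δ is scored by its
  own `|g|` plus `Σⱼ w(dⱼ)·|g|` of the committed profile rigidly shifted
  by δ, with `w(d) = p(1−p)^d`, `d` = column distance − 1 (the adjacent
  column gets weight `p`), truncated where `w < 1e-6·w(0)`. The search
  window stays anchored on the coarse curve, so refined output can never
  drift beyond `search_radius_px` (default 5) from its initialisation.
  Ties take the shallowest offset. With radius 0 the coarse curve is
  returned untouched. Invalid columns are skipped and bridged — the
  distance keeps counting, so influence still decays across a gap.
- **Deeper interfaces.** The rigid-shift estimator uses `|g|` (a signed
  sum would cancel dark-to-bright against bright-to-dark edges). Default
  search bands: 30–120 µm below the anterior for the epithelium–stroma
  interface, 300–1200 µm for the posterior surface, converted to pixels
  per image. Refinement pass 1 uses a per-column decay constant growing
  linearly from 0.3 at the centre to 0.9 at the edge (peripheral columns
  explore the gradient more freely, reflecting peripheral corneal
  thickening); pass 2 re-anchors on pass 1 with constant p = 0.3 for
  smoothing; a 5-column median filter replaces the polynomial model that
  deeper boundaries lack. Crossings are resolved by clipping the deeper
  curve to one pixel below the shallower one.
- **3D.** Frames share one crop window (min apex top, max bottom) so the
  volume stays rectangular; a frame failing preprocessing is masked, not
  fatal. Per-frame coarse picks are pooled into a weighted quadratic
  surface fit (same outlier rule). Refinement processes positions in
  order of city-block geodesic distance from the valid position nearest
  the lateral centroid; committed neighbours within city-block radius 8
  contribute with `w(d)`, `d` = geodesic-distance difference. The height
  map is median-filtered 3×3 (a height map is two-dimensional; filtering
  it is the reading of "median smoothing of the surface" that actually
  smooths the surface) and clamped within the search radius of its
  initialisation.

Everything is deterministic; the `rng_seed` in the configuration is
provenance metadata only.

## Synthetic phantoms

The generator renders, from closed-form geometry, the intensity structure
the method relies on: per interface a bright band (brightest at its top
row, tapering downward, so the upper transition always carries the
strongest gradient), tissue fill between interfaces, dark background above
the cornea and in the aqueous. Interface depth is quadratic in the lateral
(and, for volumes, frame) coordinate plus an optional sinusoid, so
boundaries are deliberately *not* representable by the polynomial models
used inside the pipeline — coarse fits alone cannot pass the tests, the
gradient refinement must do real work. Degradations: multiplicative
log-normal speckle (mean-one, one σ parameter), additive Gaussian noise, a
quadratic lateral contrast falloff, and the two clinical artifact types
(full-width stripe; saturated central columns). Artifacts are injected
after noise, so paired specs differing only in artifacts share their
speckle field pixel-for-pixel — the basis of the artifact experiments.

Ground truth is computed analytically and shares no code with the
segmenter. Because bands are rendered on the pixel grid, reported truth is
the pixel-quantised boundary actually present in the image (the analytic
sub-pixel curve is also available). The canonical study phantom is
256 × 400 at 5 µm axial / 60 µm lateral resolution: anterior at depth 80 px
with 8 px of quadratic sag, epithelium–stroma 12 px (60 µm) deeper,
posterior 130 px (650 µm) deeper, each 2 px thicker toward the periphery,
all perturbed by a 1.5 px sinusoid (period 180 px). The perturbation
wavelength and phase are chosen so the pixel-quantised boundaries are fixed
points of the pipeline's final smoothing steps (order-1/21-column
Savitzky–Golay for the anterior, 5-column median for deeper curves) — a
prerequisite for testing exact recovery at all. The noise study uses
speckle σ = 0.15 with peripheral contrast falloff 0.5; the volume study
uses a 20 × 64 × 300 stack with σ = 0.1.

What the phantoms do **not** model: coherent speckle statistics (fully
developed Rayleigh speckle), the imaging PSF, refraction at interfaces,
iris/eyelid structures, motion between frames. Passing tests therefore
demonstrate the algorithmic properties of the pipeline under controlled
OCT-like structure, not clinical-grade performance.

## Numerical notes and known limitations

- **Near-exact, not exact, clean recovery.** On the noiseless study
  phantom the pipeline recovers the anterior to ≈ 0.05 px mean error
  (roughly one column in twenty off by a single pixel) and deeper
  interfaces to ≤ 0.05 px. The residual is structural: at columns where
  the quantised true boundary steps relative to the rounded parabola
  anchor, the refinement margin between the true offset and the
  neighbour-consistent offset shrinks to `(1 − Σw)·|g_edge|` (the
  geometric weights sum to ≈ 1) plus tiny pseudo-gradients that row-mean
  subtraction leaves in flat regions; which side wins is then decided at
  the 10⁻³ level. The same mechanism caps the 3D greedy refinement: with
  many equidistant committed neighbours, the neighbourhood vote dominates
  single-pixel disagreements, which regularises against speckle but
  rounds off single-pixel bumps.
- The boundary function as printed favours the pair with the *largest*
  intensity difference; without the candidate contrast floor it locks
  onto (dim background peak, bright band) pairs under any noise. The
  floor operationalises the stated brightest-response prior and is
  exposed as `min_peak_fraction`.
- Savitzky–Golay smoothing reproduces affine curves exactly and is applied
  per contiguous valid run, shrinking its window on short runs rather than
  discarding them; endpoints evaluate the terminal-window polynomial.
- Degenerate inputs fail loudly: a gradient field with no signal in a
  shift band raises instead of returning an arbitrary shift; a column with
  fewer than two candidates is marked invalid, never guessed; a
  single-frame "volume" is redirected to the 2D path.
- Runtime is dominated by the Wiener filter and the per-column pair
  enumeration; a 256 × 400 B-scan segments in ~0.1 s and the 20 × 64 × 300
  volume in well under a minute on one core. The desk-scale problem sizes
  (256-column B-scans, 20-frame volumes) were chosen to keep the full test
  bench fast while preserving every algorithmic regime (curvature,
  periphery, artifacts).
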