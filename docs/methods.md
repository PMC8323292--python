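# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `atnav`, and what the synthetic test harness does and does
not establish about real samples.

## Coordinate frames and calibration

Two Cartesian frames are used and never mixed inside one operation:
*overview pixels* (x right, y down, origin at the mosaic's top-left) and
*stage micrometres*. The stage is calibrated by declaring one overview pixel
— in practice a section corner near the centre of the field of view — to be
stage (0, 0); thereafter `s = axis_signs ⊙ (p − origin_px) · pixel_size`.
`axis_signs` defaults to (+1, +1) (stage +x = image right, +y = image down)
and is configurable, since stage conventions vary between instruments.
Declared pixel densities per magnification default to 20x = 2.96,
100x = 15.38, 4kx = 43.03, 12kx = 129.08, 30kx = 322.69 pixels/μm and are
config-overridable.

## Transfinite (bilinear isoparametric) ROI propagation

Each section is modelled as a quadrilateral with corners in fixed
counter-clockwise cyclic order (in image coordinates). A point inside it is
addressed by natural coordinates (ξ, η) ∈ [−1, 1]² via the standard 4-node
shape functions N₁ = (1−ξ)(1−η)/4 … N₄ = (1−ξ)(1+η)/4, corner 1 at (−1, −1).
The natural-coordinate range and corner numbering are this package's
conventions (any fixed choice works; consistency across a ribbon is what
matters, and the detection module guarantees it by construction).

The inverse map is solved by damped Newton on the 2×2 bilinear system from
the element centre (0, 0), tolerance 1e−9, at most 50 iterations; on a stall,
the best seed of a coarse 41×41 grid restarts Newton. For convex quads the
inversion is unique; simple non-convex quads are accepted with a warning and
the branch reachable from the centroid returned. Because Σ Nᵢ = 1, carrying
a point from section i to j (`forward(j, inverse(i, p))`) is exactly
equivariant under affine deformations — the property that makes one user
click transferable along a ribbon whose sections shear, shrink and rotate.

## Overview construction and preprocessing

Tile offsets are estimated pairwise between 4-neighbours: a phase-correlation
estimate on the nominal overlap strips seeds a local normalized-cross-
correlation search (±8 px around the nominal offset, quadratic sub-pixel
refinement). The NCC verification exists because this sample class is full
of long straight boundary lines, which are translation-symmetric along their
own direction: the raw phase peak then sits on a ridge and can return a
confident but wrong in-line offset. Global tile positions are the
least-squares solution of the pairwise-offset graph anchored at tile (0,0);
pairs with featureless or implausible estimates fall back to the nominal
grid offset with weight 0.05 in the solve. Overlaps are feather-blended.

Preprocessing stages, each switchable and recorded in the output metadata:
percentile contrast stretch (0.5–99.5%), Gaussian blur (σ = 2 px), Laplacian
magnitude, Otsu threshold, connected-component size filter (min 100 px²),
morphological closing/opening (disk radius 2). The final response is the
Laplacian magnitude under the cleaned mask, softened by a Gaussian (σ = 3 px)
and normalized to max 1 — retaining relative ridge strength matters, because
the faint double edge of a glue strip runs parallel to the true section
boundary a few μm away and must lose to it. Thresholds and sizes are user
parameters; the defaults suit the synthetic fixtures.

## Active-contour section detection

The contour is a quadrilateral-constrained snake with energy
E = −(mean edge response along the perimeter, 24 samples/side)
  + λ_shape · (mean relative side-length deviation + mean corner-angle
  deviation / π, relative to the init), λ_shape = 0.3.
It is minimized by greedy pattern search over nine handles (4 corners,
4 edge midpoints moving both end corners, whole-quad translation), 8
directions each, step halving from `search_radius` = 10 px down to 1 px
(0.25 px at the finest level), inside a block-mean pyramid (×4, ×2, ×1).
Block-mean downsampling is used deliberately: it commutes with translations
that are multiples of the level factor, keeping detection translation-
equivariant. The search only ever accepts energy-decreasing moves, and the
finest level restarts from the better of {pyramid result, original init}, so
the fit never ends above the init's energy. Fits whose area collapses below
25% of the init are rejected with a low-confidence flag.

Ribbon growth: from one seed quad per ribbon, detection alternates
extrapolation and fitting in both directions. The next init translates the
last quad by the per-corner drift averaged over up to the last three
inter-section steps (averaging stops single-fit noise from being doubled
into the next init). From a lone seed the pitch is bootstrapped by trying a
few gap factors (1.02–1.3) of the seed's own leading→trailing axis and
keeping the best-scoring fit. A candidate section is accepted only if
(a) its score ≥ 0.4 × the seed score, (b) ≥ 55% of its perimeter samples lie
on active edge response (phantom fits beyond the ribbon end catch one shared
ridge and fail this), and (c) its centroid advances along the ribbon (a
phantom that slides back onto the previous section fails this). These three
stop rules replace any prior knowledge of section count.

`boundary_error` is the maximum over the four corners of the Euclidean
distance to the corresponding ground-truth corner, in μm — the stricter
(max-corner) reading of a per-section localization error.

## Focus surface

Sibson natural-neighbor interpolation, computed from first principles: the
query point is inserted into the anchors' Voronoi diagram and each weight is
the area its cell steals from an existing cell (cells made finite by distant
ghost sites; for interior queries the stolen areas are ghost-independent).
This gives exactness at anchors and linear precision (verified to 1e−6).
Outside the anchors' convex hull — and whenever fewer than three
non-collinear anchors exist — the nearest anchor's z is returned with an
extrapolation flag; the interior method says nothing about extrapolation, so
nearest-anchor is this module's own conservative rule. EM-level acquisition
assumes the microscope's autofocus and is modelled as exact focus.

## Navigation plan and acquisition

The plan holds one entry per (ROI, section, magnification) with stage target,
focus z and a status (`pending`/`done`/`failed`), serialized as JSON and
re-saved after every entry, so an interrupted acquisition resumes with only
the pending entries and a completed run is a no-op. ROI predictions are
computed independently per ROI, so a multi-ROI plan equals the concatenation
of single-ROI plans. Entries are ordered by section within each ROI by
default ("section" interleaving is a flag). A failed stage move marks the
entry failed, continues the loop, and raises a summary error carrying the
completed stacks at the end. The commanded settle wait between moves
defaults to 2.0 s (metadata in simulation; no wall-clock wait).

## Stepwise refinement

Stacks are registered by sub-pixel phase correlation (Fourier upsampling,
0.1 px) chained pairwise — section k against k−1, because neighbouring
sections are the most similar — and accumulated to frame 0. Correlation is
amplitude-weighted (no spectral whitening): the tracked structure is the
highest-contrast content in the frame, and weighting by amplitude makes the
peak follow *it* rather than the surrounding section texture, which drifts
relative to the ROI from section to section. Confidence is the correlation
peak-to-RMS ratio; featureless frames contribute zero shift at zero
confidence. `rigid` mode adds a coarse ±5° (0.5° step) rotation search;
translation-only is the default, matching the stage-offset error model —
whether rotations should ever feed back into stage targets is left off by
default.

The accumulated shift of section k, scaled by the stack pixel size and the
axis signs, is added to that section's stage targets at every magnification
at or above the next rung (already-acquired rungs are never touched).
Corrections are additive and zero shifts change nothing. Per-section
corrections are logged as (Δx, Δy, √(Δx²+Δy²)) μm in a CSV.

The refinement chain is anchored at the ROI's definition section (frame 0):
corrections equalize every section's error to that section's own residual.
Stage repeatability jitter therefore sets an irreducible error floor of
about √2 × the per-axis jitter σ (the section's draw minus the reference
frame's draw), which no amount of registration precision can remove.

## Synthetic scene generator and simulated microscope

The generator emulates the physical samples this workflow is built for.
Defaults (chosen once, as the study conditions):

- 6 ribbons totalling 126 sections, 15–27 per ribbon; trapezoidal sections
  110 × 70 μm (trailing edge 12% narrower), 6 μm inter-section gap, 4 μm
  glue strips on the leading/trailing edges, ribbons 185 μm apart, per-ribbon
  rotation up to ±1°, per-corner jitter 0.8 μm, 0.2%/section linear shrink,
  0.001/section shear; curvature available as a stressor parameter
  (default 0). Physical sections are often a few hundred μm wide; these
  dimensions keep the 126-section overview raster at ~2800 × 6600 px
  (2.96 px/μm) — the geometry-to-pixel ratios that matter (gap vs boundary
  width, drift per section vs section size) are preserved. The layout
  occupies ~1.1 × 2.1 mm of the 22 × 22 mm coverslip.
- one tracked ROI per scene by default: a 3–5-lobe dark structure (Golgi
  impregnation stand-in, ~8 μm across, gray ~35 on interior ~175), identical
  across sections, whose centroid trajectory is the transfinite address of
  its anchor plus a cumulative random drift ≤ 0.4 μm/section (0.5 in the
  end-to-end stress condition); lobes are recentred so the trajectory is the
  structure's area centroid.
- section interiors carry band-limited texture (2 μm lattice, ±9 gray)
  evolving as an AR(1) chain (ρ = 0.85) along the cutting order — real
  consecutive 150 nm sections are highly similar, and without that
  correlation stack registration would face artificially hostile data; the
  background is a coverslip-scale mottle (8 μm lattice, ±3 gray).
- focus surface: plane (3 and 2 μm per mm tilt) plus a 1 μm ripple at 900 μm
  period, z₀ = 50 μm.
- rendering: 8-bit, boundaries drawn 1 μm wide at gray 55, glue at 132,
  optics blur 0.2 μm; one rendering path serves the overview, the tile
  grid and the simulated camera, so cross-magnification geometry is
  consistent by construction.
- degradations (all seeded): additive Gaussian noise, salt-and-pepper,
  per-section corner/side erasure to background, glue blobs.
- simulated microscope: renders the FOV at the declared pixel density
  (160 px frames at 20x — below one section pitch, so a frame never contains
  a neighbouring section's structure — 384 px elsewhere); Gaussian stage
  jitter on the realised position; LM defocus blur σ_px = 0.5·|Δz|·(pixel
  density ratio to 20x), a simple monotone stand-in for a defocus model.

Everything is deterministic given (params, seed), including textures
(seeded by stable CRC-derived keys, not process-dependent hashes).

**What passing tests show, and what they do not.** The harness exercises the
full geometric and control chain — detection under noise and erasures,
coordinate transfer, plan resumability, registration feedback — with exact
ground truth. It does not model shading/vignetting, stitching-induced local
distortion, wrinkles or partial section folds, stain variability, charging,
or structures that change shape quickly between sections; accuracy numbers
on the synthetic sample are therefore a validation of the algorithms under
controlled conditions, not a field measurement.

## Problem sizes and test conditions

The bundled checks run the full 126-section layout for detection (one seed
per ribbon), three noise conditions (σ = 10, 40, 70 gray levels, 8-bit) on
the first ribbon with noise-free template inits, and a 20-section
single-ribbon scene for the 20x → 100x refinement loop (stage jitter
σ = 1 μm, ROI drift ≤ 0.5 μm/section). The refinement-ladder monotonicity
property is tested with a perfect stage (jitter 0), since at realistic
jitter the later rungs sit at the jitter floor described above, where the
median fluctuates within ±0.1 μm.

## Known limitations

- Quadrilateral sections only; non-quadrilateral shapes are out of scope.
- Detection of two sections whose facing edges nearly touch (< ~2 px gap)
  can land on the neighbour's ridge, bounded in practice by the gap size
  (≤ ~5 μm here); the score/coverage flags do not catch this case because
  the wrong fit lies on genuine edge response.
- Inversion of strongly non-convex quads may be multivalued; the returned
  branch is the one reachable from the centroid, flagged.
- Registration assumes the tracked structure dominates frame contrast; a
  low-contrast ROI in high-contrast context would degrade to tracking the
  section, not the ROI.
- The stitcher is a minimal translation-only mosaicker (no MLE overlap
  refinement, shading correction or nonlinear deformation).
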