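# Methods

This note documents the models, algorithms, parameter defaults and
numerical choices behind `nammold`, and what the synthetic validation does
and does not establish.

## Synthetic neonatal cleft anatomy

The generator models a digitized plaster cast of a newborn maxilla with a
unilateral cleft as an analytic implicit solid, meshed by marching cubes at
the requested resolution (default 0.5 mm, ~20–40 k faces):

- **Alveolar arch**: a rounded wall (capsule of half-width
  `ridge_halfwidth`, default 2.5 mm, height `ridge_height`, default 4 mm)
  swept along a planar elliptic arc `(b sin φ, a cos φ)`, φ ∈ ±110°; the
  posterior ends are the tubera. The arch is interrupted over the cleft.
- **Cleft**: the wall gap is solved (Brent root-finding on the gap
  half-angle) so that the shortest surface-to-surface distance across the
  cleft — the SA–SA′ definition — equals `cleft_width` exactly, including
  any rigid `segment_shift` of the smaller segment (default 1 mm lateral,
  0.5 mm vertical; the shift models the displaced smaller segment without
  out-of-plane arch warp).
- **Palatal vault**: a surface depressed by `palate_depth` (default 5 mm)
  at the center, meeting the ridge shoulder at the arch; a wedge-shaped
  palatal channel (subtending the cleft, reaching inward to 0.45 of the
  elliptic radius) represents the posterior hard-palate cleft and carries
  the SD/SD′ landmarks on its margins.
- **Pedestal**: a 3 mm flat base, as on a trimmed plaster cast.
- **Fillets**: all implicit junctions use polynomial smooth-min/max blending
  (radius 1 mm) — mucosa-covered anatomy has no sharp creases, and the
  plate pipeline's voxel remeshing assumes finite surface curvature.
- **Noise**: i.i.d. Gaussian vertex displacement along vertex normals
  (default σ = 0.05 mm) emulates scanner roughness without changing
  topology.

Default dimensions (`ellipse_a` = 20.7 mm, `ellipse_b` = 18.3 mm,
`cleft_width` = 10 mm) were solved from the median arch length (A–MT ≈
27.8 mm) and tuberal width (T–T′ ≈ 34.4 mm) of published neonatal
unilateral-CLP cohorts; the resulting seven-distance table lies inside the
published min–max ranges. Cohort sampling draws `ellipse_a`, `ellipse_b`
and `cleft_width` from truncated normals calibrated to the same summaries
(cleft 11.4 ± 5.0 mm on [4.5, 19.5]), applies a per-subject multiplicative
arch growth (1.07 ± 0.02 over the molding period) and a cleft reduction
(6.4 ± 1.5 mm), and adds observer landmark-placement error
(`landmark_sigma`, default 0.3 mm) to the emitted "measured" landmark sets;
ground-truth landmarks stay exact.

Ground-truth crest polylines are computed analytically and then projected
onto the emitted mesh, so they are on-surface to numerical precision while
staying within one marching-cubes interpolation error (~0.01 mm) of the
analytic crest.

**What this does not show**: the generator has a planar arch, a single
smooth vault and no rugae, frenula, impression artifacts or bilateral
clefts. Passing tests demonstrate the pipeline's geometric correctness on
plausible shapes and sizes, not segmentation robustness on real scans.

## Crest detection and ellipse fit

The occlusal frame is the principal frame of the vertex cloud: w is the
least-variance direction, with signs fixed by third central moments
(rotation-equivariant and deterministic). Crest extraction bins the
upper-half vertices (w above the median) by angle about their in-plane
centroid (default 180 bins) inside a radial band of 0.25–2.5× the median
radius; each bin's crest candidate is the maximum-w vertex (ties: smaller
radius, then lower index). Bins are gated against a robustly fitted crest
plane (the crest is nearly planar; the plane also absorbs residual frame
tilt): bins more than 1.8 mm below it are empty. Contiguity, plus a 2 mm
positional-jump rule, splits the crest into the greater and smaller
segment; curves are smoothed by a 3-point moving average and re-projected
onto the surface. This detector is a self-contained re-design honoring the
observable contract (crest polylines + fitted ellipse + editable result),
not a port of any particular clinical implementation.

The arch ellipse is fitted by the numerically stable Halir–Flusser
partitioning of the direct least-squares conic fit with the ellipse
constraint (deterministic, no initialization), after centering for
conditioning; residuals are geometric point-to-ellipse distances via robust
per-point root-finding. Crest arc parameters and the cleft `gap_span` are
angles about the fitted ellipse center; with two segments the cleft is the
shorter of the two empty intervals (the longer is the open posterior side).
The surface gap width (SA–SA′ analogue) is measured as the minimum
distance between upper-wall vertices near the two gap-facing crest
endpoints.

## Plate construction

- **Bridging**: the guiding strip is a closed swept capsule (radius 2.5 mm,
  wall height 4 mm) whose spine follows the fitted-ellipse arc between the
  gap-facing crest endpoints, extended half a radius into each segment. The
  cast is untouched (original vertices bit-identical); the bridged model is
  the watertight compound of cast and strip. A `residual_gap` parameter
  leaves a centered channel open — the mechanism of the closure schedule.
  The design choice of a closed overlapping strip (instead of stitching a
  loft into the cast surface) keeps the cast exact and lets the Boolean
  stage handle the union.
- **Shelling**: the bridged solid is voxel-unioned (column-crossing
  rasterization with the nonzero-winding rule, signed-EDT marching cubes,
  then vertex re-projection onto the exact sources). The retained region is
  the vertically reachable top surface (no solid above a probe just outside
  each face — vertical walls are reachable, undercuts are not) inside the
  arch footprint (+2 mm), trimmed at the tuberal line posteriorly and
  `trim_height` (default 3 mm) below the crest on the vestibular side; the
  palatal side is always covered. The intaglio is that patch verbatim; the
  outer surface sits at the smoothed-normal lateral offset with height from
  a rolling-ball envelope of the patch (equals the plain normal offset on
  smooth regions, rounds concave creases without fold-over, clearance ≥
  thickness); rim walls close every boundary loop, with small interior
  holes fan-filled first.
- **Pin / hole**: Boolean union with a capped cylinder seated on the outer
  anterior face (default radius 1.5 mm, length 10 mm, 45° above the
  occlusal plane) and Boolean difference with a vertical cylinder (default
  radius 1 mm) offset 6 mm palatally from the anterior midline. These
  dimensions are clinical placeholders — not standardized in the
  literature — exposed in `PlateSpec`. The voxel engine (default pitch
  0.15 mm) re-projects marching-cubes vertices onto the exact previous
  surfaces, with the stored intaglio patch as a priority target so repeated
  remeshing cannot accumulate error on the fit; occupancy is cleaned
  (pinhole closing, largest component, cavity filling) so results stay
  watertight and manifold with the expected genus. "Grinding" adjustments
  reuse the same difference machinery with a user-supplied tool mesh
  (`carve`).
- **Smoothing**: Taubin λ/μ (0.5/0.53, default 10 iterations), with
  intaglio vertices clamped to ≤ 0.05 mm displacement.

Intaglio fidelity is reported as the maximum distance from retained cast
surface vertices to the plate, where "retained" means the projection lands
at least 1 mm inside the intaglio patch boundary and outside the bridged
channel (within 7 mm in-plane of the gap arc the intaglio follows the strip,
not the cast) and outside the ventilation hole. At default settings the
full pipeline stays below 0.05 mm.

## Growth series

Plate k of n (default 6, two weeks apart) targets the detected ellipse
scaled by `(1+g)^(k·interval/4.345)` — 4.345 weeks per month = 365.25/12/7 —
and a residual gap of `initial_gap · (n−k)/(n−1)` (linear closure, zero at
the last plate). The target anatomy is the cast scaled in-plane about the
ellipse center (both axes equally; anisotropic growth is not modeled, the
ellipse-parameter interface leaves it open) and re-bridged to the residual
gap; uniform scaling guarantees the passive, rotation-free guidance that
the series tests verify by re-detection. The default g = 0.02/month is an
explicit placeholder: a clinically grounded monthly relative growth
fraction must come from longitudinal measurements of healthy newborns and
is a required input for clinical use; all synthetic studies use a known
generator growth rate instead.

## Morphometrics and statistics

MT is always derived as the T–T′ midpoint, never stored. Summaries use
type-7 (linear-interpolation) quartiles and the n−1 standard deviation,
with rounding to one decimal only at presentation; the quartile convention
is a documented choice, as published tables rarely state theirs. The exact
signed-rank p is the two-sided tail probability of |W − E[W]| over all 2^n
sign assignments of the (mid)ranked absolute differences, computed by
dynamic programming on the doubled integer ranks — mathematically identical
to full enumeration, and tested against a literal enumerator; zeros are
excluded by default (Pratt's method by flag), ties use midranks, n ≤ 25 in
exact mode. The exact rank-sum test enumerates all C(n1+n2, n1) rank
assignments (combined n ≤ 20). The asymptotic signed-rank variant uses the
tie-corrected variance Σr²/4 with a 0.5 continuity correction. Box-plot
statistics follow the q1/median/q3 box with Tukey 1.5·IQR whiskers and
listed outliers.

## Numerical choices and limitations

- Vertex merge tolerance 1e-6 mm on mesh read (below scanner resolution,
  above float noise); STL round trips preserve topology exactly and
  geometry to ≤ 1e-5 mm.
- Grid origins carry fixed fractional jitters so flat model surfaces never
  coincide with voxel centers (which would create degenerate marching-cubes
  configurations), and the signed field carries a ≤ 1e-3-voxel hash dither
  to break exact distance-transform ties.
- The voxel Boolean engine trades exactness for robustness: surfaces are
  exact where re-projection applies (single nearest source), and within
  ~half a pitch near intersection curves. Volumes are accurate to ~1 % at
  the default pitch.
- The occlusal frame needs a height-asymmetric vertex distribution (true
  for cast-like meshes with a pedestal); perfectly symmetric inputs fall
  back to a farthest-vertex rule.
- Detection assumes one connected cast with a single cleft; bilateral
  clefts and dentate ridges are out of scope.
- End-to-end runtimes at default settings on one CPU: cast generation
  ~0.3 s, detection ~0.05 s, one full plate ~40 s, a six-plate series a few
  minutes. The test suite uses these same sizes.
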