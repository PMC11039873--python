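# Methods

This note documents the models, algorithms and numerical choices behind
`canalssm`, in the spirit of a model-description appendix: what each stage
assumes, which knobs matter, and what the synthetic experiments do and do
not demonstrate.

## Coordinate convention

All stages share one frame: the canal's longitudinal axis is z, the most
distal cross-section sits at z = 0 and the shaft extends toward +z; x is
medio-lateral, y anterior-posterior. Units are millimetres everywhere; no
unit metadata is read from mesh files. Input meshes are expected to be
roughly axis-aligned in this frame (real canals are exported after
re-alignment along the femoral longitudinal axis; the pipeline tolerates
residual pose errors of a few degrees, which the per-segment ICP removes).
Longitudinal length La is the only feature that depends on this convention;
the remaining features are rigid-invariant up to discretization.

## Synthetic canal model

A canal is a swept tube. The centerline is a circular arc of radius Rc
(sentinel ∞ = straight) lying in a plane that contains the z axis; sections
perpendicular to z are ellipses with the major axis along x. Controllable
ground truth:

| parameter | meaning | cohort default (mean ± SD) |
|---|---|---|
| La | longitudinal length | 200 ± 15 mm |
| Rc | centerline radius of curvature | 1000 ± 150 mm |
| d_min | isthmus (minimum) diameter | 11 ± 1 mm |
| flare = d_dist − d_min | distal (condylar) flare = conicity con | 6 ± 0.6 mm |
| ell | distal ellipticity (Axmax − Axmin) | 2 ± 0.5 mm |

Draws are independent truncated normals (up to 100 retries per parameter;
at these SDs truncation is rare and does not bias the means noticeably).
Defaults are order-of-magnitude realistic for an adult distal femoral canal
ROI; they were fixed once as the package's study conditions.

Shape details, each with a reason:

- **Diameter profile** is piecewise linear: distal flare → isthmus →
  proximal (metaphyseal) flare. The two flares are *independent* (the
  proximal one is fixed at 6 mm by default), so the conicity factor does not
  mechanically drag the mean diameter along. The minimum is a short flat
  plateau (12 mm) rather than a sharp vertex, so a 10-mm slicing grid
  observes the true minimum regardless of grid phase.
- **Ellipticity** is maximal at the distal section and decays linearly to
  zero proximally; only the distal value is a measured feature.
- **Bow plane** is rotated 15° off the sagittal (y–z) plane toward lateral.
  A strictly sagittal bow with x-symmetric sections would make every canal
  exactly mirror-symmetric and left/right detection impossible in principle;
  a slightly off-sagittal bow is anatomically defensible and keeps the
  centerline an exact planar arc, so curvature recovery is unaffected (the
  extractor finds the plane itself via SVD, never assuming it).
- **Right-side canals** mirror the vertices across x = 0 while keeping the
  face list bit-identical across the cohort (iso-topology by construction);
  no stage relies on face orientation, so the flipped winding is harmless.
- **Pose** is a uniform random rotation (≤5° by default, axis uniform on the
  sphere) plus a per-component uniform translation (≤5 mm), emulating
  residual alignment error of pre-oriented scans.
- **Resolution** (48 circumferential × 101 longitudinal by default) is a free
  parameter, since the mesh density of real exports is acquisition-dependent;
  tests and experiments choose the resolution that fits their purpose. The
  generator–extractor consistency bounds (La 1%, Rc 2%, ell 0.3 mm, davg 2%,
  con 0.3 mm) hold from 64 vertices per ring and one ring per 2 mm upward.

What the generator does **not** emulate: segmentation noise, cortical-wall
roughness, non-elliptical (e.g. tear-drop) sections, axial twist of the
section orientation, and correlations between parameters (real canals
correlate length with bow radius, for instance). Passing tests therefore
demonstrate the pipeline's internal consistency and its recovery power
under the stated population model — not segmentation robustness on CT data.

## Preprocessing

**Mirroring.** Landmarks are slice centroids every 10 mm (starting half a
spacing inside the extent, tolerant of tilted poses) plus the four axis
endpoints of the most distal valid slice ellipse, axis directions
canonicalized for reproducible pairing. The rigid (no scaling) Procrustes
RMS against the reference's landmarks is evaluated for the canal as-is and
reflected across x = 0; the lower residual wins. The reference is the
cohort member with the median longitudinal extent (lower median for even
cohorts) — a reproducible proxy for "intermediate-sized" — and must be
left-sided; for synthetic cohorts it is chosen among ground-truth left
subjects.

**Segment cutting.** Fractions 0.25…1.00 in 0.05 steps (16 segments); the
distal portion z ∈ [0, f·L] is kept, the cut rim is left open, and the cut
plane is nudged 1 µm proximally so it never passes exactly through a vertex
ring. Vertices duplicated along the rim by the plane cut are merged.
Segments of one subject are nested and share the distal end.

**ICP.** Vertex-to-nearest-vertex pairing (point-to-point), optimal rigid
transform per iteration by Kabsch/SVD, initialization by centroid
superposition. Stopping: inter-iteration translation increment < 0.01 mm
AND rotation increment (axis-angle magnitude of the relative rotation)
< 0.05°; hard cap 200 iterations with a diagnostic error. For badly posed
inputs an optional principal-axis initialization aligns the principal
frames, resolving the four-fold sign ambiguity by the lowest mean
closest-vertex cost; with it, poses up to at least 20°/20 mm are recovered
to the stopping tolerances.

## Correspondence

The reference segment (template) is deformed onto each aligned subject:

1. pair every template vertex with its closest point *on the subject
   surface* (exact point-to-triangle distance on KD-tree candidates;
   vertex-to-vertex pairing cannot reach sub-micron tolerances on decimated
   meshes);
2. fit a 3-D thin-plate-spline displacement interpolant on a control subset
   — a 200-point farthest-point sample plus, each iteration, the 64
   currently worst-residual vertices, so unresolved regions attract
   controls — with smoothing annealed geometrically from 1.0 by factor 0.5
   (coarse-to-fine);
3. apply it to all template vertices; if the TPS step fails to reduce the
   maximum pair distance by at least 30%, project every vertex directly onto
   its paired closest point instead (the displacement is normal to the
   surface, so the projection is tangentially benign and drives the residual
   toward zero).

The stopping statistic is the **maximum** pair distance (< 0.001 mm;
a config flag switches to the mean); the iteration cap is 50, and an
unconverged result is returned flagged rather than discarded. The residual
history is monotone by construction. An extent-matching initialization
scales the template along its own principal axis to the subject's extent
(equivariant under a common rigid motion of both inputs, unlike scaling
along the global z).

Tie-breaking is deliberately index-based wherever exact geometric ties occur
(farthest-point selection, worst-residual selection, equidistant closest
feet on symmetry planes): tube-like meshes are full of exact ties, and
float-noise tie-breaking would make the algorithm non-deterministic under
rigid motion of its inputs.

Accuracy: registering a canal's own grid onto a re-meshed copy of the same
surface recovers the grid to < 0.05 mm. Registering the single template
across *subjects* is accurate to the surface (residual ≈ 0) but its
tangential (arc-length) correspondence is only as good as the closest-point
assumption — of the order of the inter-subject shape differences in the
worst case. The shape-model experiments below validate that this is
sufficient for variance decomposition and parameter attribution.

## Shape model

The mean is a rigid-only generalized Procrustes average (no scaling — size,
above all canal length, is a real anatomical mode that scaling would
destroy), iterated until the mean moves < 1e-6 mm. PCA is an SVD of the
centered (Nt × 3Nn) coordinate matrix with sample normalization 1/(Nt−1),
numerically safer than forming the 3Nn × 3Nn covariance. Component signs
are fixed (largest-magnitude coordinate positive) for reproducible ±2σ
labelling; at most Nt−1 modes are retained, and four are reported in
variation tables. Mode shapes are M̄ + s·√λ_i·m_i; projection is the plain
inner product against the centered shape. Eigenvalues below 1e-18 mm² are
treated as exact zeros (reconstruction returns the mean; explained variance
is undefined below 1e-15 mm² total).

**Convergence analysis.** For each subset size, random subsets are drawn
(seeded) and sub-models built; reported are the RMS vertex distance of the
rigidly re-aligned sub-mean to the full-cohort mean, and the total-variance
ratio sub/full, each as mean ± SD over repetitions. Both statistics flatten
as the size approaches the cohort; the specific statistics are this
package's choice of stability measures.

## Feature extraction

Slices every 10 mm from the distal end, stations strictly inside the
extent. Two robustness details: every cutting plane is nudged 0.001 mm off
its nominal station (never exactly on a vertex ring or the open distal rim),
and the distal-most station probes inward in small steps (up to 2 mm)
because the rim of an aligned — hence slightly tilted — canal is not exactly
planar in z. If a plane cuts several loops, the largest-area loop wins
(canals are single tubes; extra loops indicate noise).

Each loop is fitted with a direct least-squares ellipse (conic constrained
to ellipses); axes are reported as **full** lengths, and the area used for
the equivalent diameter is the analytic ellipse area πab, with the polygon
area kept only as a 20% sanity check. Rc comes from the slice centroids
lifted to 3D: center on the mean, SVD best-fit plane, algebraic (Kåsa)
circle fit refined by one Gauss-Newton step on the geometric residuals.
Exactly collinear centroids and radii above 50 000 mm (configurable) are
reported as the straight sentinel (∞). Conicity is distal minus minimum
slice diameter — non-negative by construction since the minimum ranges over
a set containing the distal slice.

## Variation metric

var% = |p₊ − p₋| / ((|p₊| + |p₋|)/2) × 100 between the ±2σ shapes of each
mode. Absolute values make var% a magnitude; both-zero (and both-straight
for Rc) gives 0 by convention; a straight sentinel against a finite radius
is indeterminate (NaN, logged, excluded from highlights). Variations under
5% are flagged negligible. Per parameter, the mode with the largest var% is
highlighted, ties toward the lower index.

Known artefact: on modes with near-zero variance the ±2σ shapes differ only
by numerical noise, and the *relative* variation of a nearly constant
parameter can still reach several percent — var% is a ratio of small
differences there. Variation tables should be read jointly with the
explained-variance column.

## Scale of the packaged experiments

The test suite and the acceptance script run entirely on synthetic cohorts
regenerated at call time. Cohort sizes (10–60 subjects) and mesh
resolutions (20–64 vertices per ring) were chosen as the smallest scales at
which each property is comfortably measurable, keeping any single
experiment within seconds to a couple of minutes on one CPU; the recovery
experiments' conclusions were checked to be stable against moderate
increases of either.

## Known limitations

- Closest-point elastic registration constrains the normal direction only;
  tangential correspondence across subjects is smooth-prior-driven, not
  anatomically guaranteed.
- The percent-variation metric is undefined for mixed straight/curved mode
  pairs (reported as indeterminate rather than forced to a number).
- Mirror detection needs the bow (or some other chirality cue) to be
  geometrically expressed; a perfectly symmetric canal has no detectable
  side.
- The pipeline assumes one canal per mesh, roughly axis-aligned; it does not
  segment, repair, or re-orient arbitrary meshes.
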