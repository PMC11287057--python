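# Methods

`aortacontour` converts a sparse set of 2D cross-sectional contours of the
aortic outflow region (LVOT + aortic root) into a full 3D segmentation mask,
and derives the measurements used for TAVI prosthesis sizing.  This note
describes the models and numerical choices behind each stage, what the
synthetic phantom does and does not emulate, and the known limitations.

## Pipeline model

The pipeline assumes a contrast-enhanced CT volume in which the aortic
outflow lumen is a bright, roughly circular tube on a darker background,
plus four manually placed landmarks in world millimetres: `lvot` (below the
valve), `valve` (a point on the annulus plane), and the two coronary ostia
`rca`/`lca`.  Stages, in order:

1. **ROI crop** — an axis-aligned 80×80×80 mm³ cube centred at the centroid
   of the valve and coronary-ostia landmarks, resampled to 0.65 mm isotropic
   voxels (123 per axis).  Linear interpolation for images, nearest for
   masks; out-of-field voxels take the source minimum (air-like).  All
   geometry lives in the NIfTI affine's native world frame; voxel indices
   are 0-based and a voxel's world position is its centre.
2. **Centerline** — a cost image combines two tube cues as
   `cost = 1 − (w_v·vesselness + w_h·hough) + ε` with `w_v = w_h = 0.5` and
   `ε = 10⁻³` (so costs stay positive).  Vesselness is the multiscale
   Frangi measure (α = β = 0.5, structureness scale = half the maximum
   Hessian norm, bright-tube polarity); the Hough cue is a per-slice
   circular accumulator on the Otsu-thresholded gradient map, max over
   radii 5–18 mm, slicing perpendicular to the volume axis best aligned
   with the LVOT→valve direction.  Dijkstra (26-connectivity, a step onto
   neighbour *n* costing `cost(n)·‖step‖`) runs from the LVOT landmark to a
   point extrapolated past the sinuses along the LVOT→valve axis by twice
   the valve-to-ostia-midpoint distance; both endpoints snap to the
   lowest-cost voxel in a small ball (3 mm proximal, 8 mm distal) to absorb
   landmark imprecision.  The voxel path is smoothed (moving average, 5
   points), fitted with a cubic spline, resampled at uniform 1 mm
   arclength, and equipped with rotation-minimizing frames
   (double-reflection transport, zero twist on planar curves).
3. **Contours** — multiplanar cross-sections perpendicular to the
   centerline every 1 mm (60 mm window, 0.3 mm pixels).  On each section,
   36 equiangular rays from the centerline point sample the intensity
   profile; the boundary candidate is the first sub-pixel crossing below
   the midpoint of the lumen estimate (median within 2 mm of the centre)
   and the per-ray background estimate (median of the outer 20 % of the
   ray), provided an inward gradient peak lies within 1 mm.  Rays deviating
   more than 40 % from the median radius are rejected; a section with fewer
   than half its rays accepted is skipped.  A periodic cubic spline in
   polar form `r(θ)` through the accepted points fills rejected rays and is
   resampled at 72 equiangular vertices.  Hand-corrected contours can be
   supplied keyed by arclength and override the automatic ones — the
   file-based counterpart of an expert-correction step.
4. **Screened Poisson reconstruction** — the contour vertices with their
   outward in-plane normals form an oriented point cloud.  On a regular
   grid (cell size = longest bounding-box axis ÷ 2^depth, bounding box
   scaled ×1.1), the field χ minimizes
   `∫‖∇χ − V‖² dx + (λ/N)·Σᵢ χ(pᵢ)²` with λ = 4 (screening weight) under
   zero-Neumann boundary conditions, where V is the normal field splatted
   trilinearly and smoothed with σ = samples-per-node (=1) cells.  The
   normal equations form an SPD 7-point system solved by conjugate
   gradients (relative residual 10⁻⁶, ≤2000 iterations).  The isosurface
   at the mean field value over the samples is extracted by marching cubes
   (largest component, boundary-closed by an outside rind), voxelized by
   z-column ray parity onto the ROI grid, and clipped along the centerline
   to the contoured arclength range.  Because a contour stack bounds an
   open tube while the Poisson normal field must enclose a volume,
   synthetic cap-point rings with axial normals are added on the first and
   last contour planes before solving; the clip step trims the caps off.
   A regular grid replaces the octree of the usual implementation: at
   80 mm ROI scale a uniform 2⁷–2⁸ grid is tractable and far simpler,
   while the parameter semantics (depth, screening weight, samples per
   node, bounding-box scale) are preserved.  Default depth here is 7
   (≈0.5 mm cells), one refinement below the octree-depth-8 convention,
   which at this ROI size changes the isosurface by well under a voxel.
5. **Quantification** — the valve plane is an input (clinically it is
   annotated by experts; the phantom provides it as ground truth).  The
   mask is resampled on the plane (nearest neighbour, 0.2 mm pixels), the
   largest component's outer boundary traced as the sub-pixel 0.5-level
   contour, and diameters measured as chords through the area centroid
   over a 0.5° direction sweep: `Dmax`/`Dmin` are the extreme chords, area
   is the shoelace value.  The LVOT measurement repeats this on a parallel
   plane 3 mm toward the ventricle (against the direction of increasing
   arclength).  A diameter/area profile along the whole centerline
   supports plausibility review.
6. **Evaluation** — DSC `2|A∩B|/(|A|+|B|)` (two empty masks → 1) and
   symmetric ASD (mean vertex-to-nearest-vertex distance between the
   0.5-isosurfaces of the masks; vertex sampling keeps the metric
   resolution-consistent with reconstruction meshes).  2D per-section
   variants resample both masks on each contour plane; sections empty in
   either mask are excluded and counted.  Bland–Altman agreement uses
   differences `x − y` (annotation minus prediction) and limits of
   agreement mean ± 1.96 SD (n−1 denominator).  The offset study thins the
   1 mm stack to k = 2..10 mm — always keeping the first and last
   cross-sections so all stacks span the same range — reconstructs each,
   and reports DSC, ASD and parameter differences signed as
   (1 mm value − k mm value).

## The phantom

The generator renders a curved tube: a cubic spline through control points
(resampled at 0.25 mm), with radius piecewise linear between named stations
(LVOT 10.5 mm, annulus 12.5 mm, sinus 16 mm, sinotubular junction 13 mm,
ascending 13.5 mm; a voxel is foreground when its distance to the curve is
at most the radius at the nearest curve sample).  The default phantom is a
128³ grid at 0.65 mm with lumen 400 HU-like, background 0, Gaussian edge
blur σ = 0.8 mm (partial volume) and additive Gaussian noise σ = 20.  The
annulus sits on a short radius plateau (±3 mm), because a perpendicular cut
of a tube whose radius grows at slope *m* reads `r/√(1−m²)`: the plateau
makes the annulus section an exact 12.5 mm circle, so the analytic truth
(Dmax = Dmin = 25 mm, area = π·12.5² ≈ 490.9 mm²) is exact.  The seed
perturbs curvature and non-annulus radii sub-millimetre, giving distinct
but comparable replicates.

The phantom emulates what the pipeline relies on — a bright, blurred,
noisy, curved tube with a sinus bulge, known centerline and landmarks.  It
does **not** emulate valve leaflets, calcifications, coronary lumens
joining the sinuses, scanner-specific noise spectra, motion artifacts, or
neighbouring bright structures (spine, left atrium).  Passing tests
therefore demonstrate geometric correctness of the machinery, not clinical
segmentation accuracy on patient CT.

## Numerical choices and problem sizes

* Vesselness scales default to {6, 8, 10, 12} mm, matched to the
  10–16 mm lumen radius.  Scales well below the radius respond on the
  lumen edge rather than the centerline (the interior is locally
  constant), and their raw response magnitudes dominate the multiscale
  maximum, which would pull the shortest path onto the wall.
* The cost cues are computed on a 1.3 mm working grid: both responses vary
  on the millimetre scale of the vessel, the path is spline-smoothed
  afterwards, and the coarse grid keeps the filters and the Dijkstra graph
  fast.  The path search itself restricts to the connected low-cost
  corridor (bottom cost quartile) containing both endpoints, falling back
  to the full grid if that corridor does not connect them.
* Ray-acceptance (40 % median-radius deviation) replaces interactive
  expert correction for unattended runs; corrected contours enter through
  the contour file instead.  Contours are polar about the centerline
  point, so star-convexity about that point is assumed.
* Degenerate inputs raise rather than guess: constant sections (no
  boundary), non-watertight meshes (open-edge count reported), planes that
  miss the mask, centroids outside a polygon, unreachable path endpoints.
* Test and acceptance runs use the 128³ phantom with reconstruction depth
  7 for parameter recovery and depth 6 for the 50-reconstruction offset
  study and determinism re-runs; the sphere-recovery check uses 2000
  samples at depth 6.  These sizes were chosen as the smallest at which
  each quantity is grid-converged to well below its tolerance.

## Known limitations

* Single open centerline only — no bifurcations, no coronary take-offs.
* Star-convex contours only; a severely non-circular lumen (dissection
  flap) would be mis-contoured.
* The valve plane is never detected automatically; it is an input.
* The regular-grid Poisson solver scales as 2^(3·depth) memory; depth 9 is
  the practical ceiling, far below what an octree could do on larger
  fields of view.
* The offset-degradation trend is monotone in the large but not strictly
  per-step at the tail: with ~55 contours the keep-first-and-last rule can
  give k = 9 and k = 10 the same number of retained contours, and the
  k = 10 placement can genuinely cover the tube better, so adjacent-step
  comparisons of small-sample medians may invert while the overall decline
  remains clear.
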