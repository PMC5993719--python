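# Methods

This note documents the models and procedures implemented in
`spheroidgeom`, the conventions and defaults they use, what the synthetic
phantom generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Coordinate frames and units

All geometry lives in physical micrometres, in the stack frame: voxel
`(iz, iy, ix)` of a `(z, y, x)` array with spacing `(dz, dy, dx)` has
centre `(x, y, z) = (ix·dx, iy·dy, iz·dz)`. Voxel→µm conversion happens
only at I/O; no geometric routine sees pixel units. The default spacing is
`(1.0, 0.65, 0.65)` µm: a 1 µm z-step is the acquisition standard for
whole-spheroid LSFM stacks, and 0.65 µm is a typical 10× pixel size (the
xy value is an arbitrary but representative choice). Angles are reported
in degrees.

## Ellipsoid fit

A nucleus is parameterised as centre *c*, orthonormal axes *e₁, e₂, e₃*
and semi-axis lengths *L₁ ≥ L₂ ≥ L₃*. Input points are boundary clicks on
the three orthogonal views (xy, yz, xz) around a central plane; the view
tag is metadata and all points enter one joint 3D fit.

The fit minimises the algebraic residual Σᵢ Q(pᵢ)² over general quadrics

    Q(p) = A x² + B y² + C z² + D xy + E xz + F yz + G x + H y + I z + J

subject to ‖(A…J)‖ = 1, solved as the smallest right singular vector of
the 10-column design matrix. Points are centred and RMS-scaled before the
solve (conditioning) and the quadric is mapped back afterwards. The
quadric is decomposed via the centre (stationary point of Q) and the
eigendecomposition of its 3×3 quadratic form; if the form (after sign
normalisation) is not positive definite the input is rejected with a
"not an ellipsoid" error rather than silently returning a hyperboloid.

Choices and properties:

- **Minimum 9 points** — a normalised quadric has 9 degrees of freedom.
  Coplanar point sets are rejected by a singular-value rank check.
- **Exactness** — on noiseless points from a true ellipsoid in general
  position the recovery is exact to numerical precision (~1e-14 relative);
  this is the main correctness anchor and is retested by the acceptance
  script.
- **Noise behaviour** — with isotropic click jitter of 2 % of L₃, the
  median long-axis direction error over simulated elongated cohorts is
  ~1.5–2°, comfortably inside the 5° budget used in validation.
- **Degenerate orientation flag** — when L₁/L₂ < 1.02 the long-axis
  direction is numerically meaningless (near-oblate or spherical nucleus);
  such fits are flagged `orientation-unreliable` and excluded from angle
  statistics but retained in aspect-ratio statistics. The threshold is a
  pragmatic cut, not a claim about biology.
- Plain algebraic least squares is not the only possible solver
  (constrained or geometric-distance fits exist); the residual definition
  is documented above precisely so an alternative solver could be swapped
  in behind the same interface.

## Surface extraction

The spheroid surface proxy is the convex hull of the thresholded stack:

1. **Denoise** — Gaussian filter with an isotropic physical width
   (default σ = 2 µm; per-axis voxel sigmas σ/dᵢ). The width is a
   free parameter: the acquisition itself fixes no value, and 2 µm is
   small against a 650 µm spheroid while suppressing single-voxel noise.
2. **Threshold** — Otsu on the full 3D histogram (256 bins) by default;
   a fixed level is available and recommended for synthetic stacks where
   the half-amplitude level is known. Foreground is strictly greater than
   the threshold. A foreground fraction below 1e-4 triggers a warning
   (uneven staining can defeat envelope extraction); the run continues.
3. **Hull** — convex hull (Qhull) of foreground voxel centres in µm;
   anisotropy is handled by converting to physical coordinates before
   hulling. For masks above 100k foreground voxels the hull is computed
   on the boundary voxels only (mask minus its 6-connected erosion),
   which has the same hull as the solid set. Face normals are taken from
   the hull equations and verified outward against the centroid.
4. **Depth** — distance from a point to the hull via exact
   point-to-triangle projection (Voronoi-region classification),
   vectorised over faces; ties between equidistant faces resolve to the
   lowest face index. Depth is measured from the ellipsoid *centre*, not
   nucleus surface.

The surface normal used for angles is the face normal of the nearest
triangle (no vertex-normal interpolation): on the hull of a dense voxel
set, facets span many voxels and their normals deviate from the ideal
sphere normal by well under the angle budget (~0.5–2° depending on
radius). No morphological cleanup is applied by default; a
largest-connected-component option exists for noisy stacks.

## Orientation analysis

Per nucleus: depth from the hull, angle θ = arccos |e₁ · n| ∈ [0, 90]
(axes are lines, so the angle is sign-invariant), 90° ⇔ parallel to the
surface. A fitted centre more than 5 µm outside the hull is treated as an
annotation/stack mismatch and raises. Cohort summaries report n, median
and quartiles of L₁/L₃ over all records, the elongated fraction
(L₁/L₃ > 1.5, strict), and angle median/quartiles over the elongated and
orientation-reliable subset only. The depth shell filter is inclusive on
both bounds (default 0–100 µm). Because it is ambiguous whether elongated
fractions should be quoted inside or outside the shell, the CLI reports
both (labelled `shell` and `all`).

The analytic null used throughout validation: for an isotropically
oriented axis, cos θ is uniform on [0, 1], so the median angle is 60°.
Tangential construction gives 90°, radial 0°.

## Division axis

The metaphase plate is ingested as a flattened ellipsoid (from the same
fitting pipeline or from external center+axes exports; one CSV schema for
both). The division axis is the plate's shortest axis e₃. The reference
plate is the one with the largest frame index strictly below the anaphase
frame; if anaphase was never observed the last plate is used and flagged
`anaphase-uncensored`. A plate with L₂/L₃ ≤ 1.1 is rejected — its
shortest axis is ill-defined — the 1.1 flatness floor being a pragmatic
configurable cut. The angle convention matches the nucleus case: 90° ⇔
division axis parallel to the surface ⇔ plate perpendicular to it.

## Mitotic timing

Frame annotations per dividing cell: condensation (first non-homogeneous
nucleus), metaphase plate (thin, full, homogeneous chromosome disc),
anaphase onset (first chromatid separation). Durations in minutes with a
4 min/frame default:

- prometaphase = (metaphase − condensation) × interval,
- metaphase = (anaphase − metaphase) × interval.

Censoring: condensation predating the recording makes prometaphase a
flagged lower bound; a never-observed plate makes prometaphase a lower
bound from the last observed frame. Cohort means/SDs (sample SD, n−1)
cover fully monitored cells only. The long-prometaphase fraction
(cutoff 40 min) counts observed-long cells plus lower-bound cells whose
bound already exceeds the cutoff; lower-bound cells at or below the
cutoff are indeterminate and reported separately, with two denominators
exposed (determinate cells, and all cells with indeterminates counted as
not-long).

## Statistics

Mann-Whitney U, two-sided: exact null distribution for tie-free samples
with both n ≤ 8 (the method is recorded in the result), otherwise the
normal approximation with tie correction and continuity correction. The
exact path is cross-checked in the tests against brute-force enumeration
of all labelings. Boxplot summaries use Tukey whiskers (1.5 × IQR) and
type-7 quartiles to match R's defaults.

## Synthetic phantom generator

The generator defines the study conditions under which the pipeline is
validated; defaults are fixed once:

- **Spheroid**: a ball of radius 325 µm (650 µm spheroid); an axis-scaled
  ellipsoid variant exercises non-spherical hulls without claiming to
  model gel mechanics.
- **Nuclei**: L₃ = 4 µm (HCT116-scale nuclei), aspect ratios lognormal
  with median 1.83 (the control-cohort median) and log-sd 0.25,
  L₂ = √(L₁L₃). Centres uniform in the spheroid volume with two margins:
  non-overlap (centre distance ≥ L₁ᵢ + L₁ⱼ, rejection sampling) and a
  5 µm cytoplasmic rim between every nucleus envelope and the spheroid
  surface. The rim reflects that peripheral nuclei sit inside cells
  rather than on the aggregate boundary; without it, the PSF tails of
  bright surface-tangent nuclei bulge the thresholded envelope by up to
  ~3 µm and the extracted hull no longer measures the spheroid surface.
- **Orientation modes**: `tangential` (e₁ uniform in the local tangent
  plane, tilted by N(0, noise°)), `radial`, `isotropic`.
- **Annotations**: points on the intersection of the ellipsoid surface
  with the three world coordinate planes through its centre (what a user
  traces on orthogonal views), 5 per view, jitter 2 % of L₃.
- **Rendering**: cytoplasm 40, nuclei 200, background 0 intensity;
  depth attenuation exp(−0.002/µm × depth); Gaussian PSF σ = 1 µm;
  Poisson shot noise (scale 1 photon/intensity unit) plus Gaussian read
  noise SD 5. Float32 stacks, spacing (1, 0.65, 0.65) µm.
- **Mitosis events**: truncated-normal durations (truncation at one
  frame, 4 min), discretised to frames; condensation times uniform from
  one typical prometaphase before the movie (star-censored cells) to the
  end of a 60-frame (4 h) recording (lower-bound cells). The
  truncated-normal mean computed by quadrature is the recovery oracle.

All stages are deterministic per seed (the rendering noise stream is
derived from seed+1 so placement and noise are independent).

What the phantom does **not** emulate: light-sheet stripe artefacts and
scattering, uneven staining, nucleus-shape irregularity (real nuclei are
not exact ellipsoids), cell crowding/packing structure, gel mechanics of
confinement, and plate-segmentation errors. Passing the validation suite
therefore demonstrates the correctness of the geometry and statistics
under the stated image model, not robustness to every real-data artefact.

## Validation scales and numerical choices

The validation phantom for the full image pipeline uses radius 150 µm and
150 nuclei — large enough for realistic hull facet sizes and a populated
0–100 µm shell, small enough to run alongside the rest of the suite; the
ellipsoid-fit and geometry oracles use 100 ellipsoids and 50 hulls × 1000
queries respectively; timing cohorts use n = 500. Hull accuracy is judged
against one voxel diagonal (~1.36 µm at default spacing), depth recovery
against 2 µm, angle recovery against a 5° median and aspect ratios
against a 5 % median relative error.

Tie-breaks and tolerances: equidistant hull faces resolve to the lowest
face index; foreground is strictly above threshold; the elongation
threshold is strict (ratio 1.5 exactly is not elongated); ellipsoid axes
are canonicalised (largest component positive, right-handed) so repeated
fits are comparable; degenerate inputs (collinear triangles, coplanar
point sets, indefinite quadrics, empty samples) raise typed errors rather
than returning approximations.

## Known limitations

- The convex hull is a one-sided surface estimate: concavities of a
  deformed (e.g. ruptured or confined) spheroid are bridged, which biases
  depths near concave regions downward. This matches the intended use
  (roughly convex spheroids) but is not flagged automatically.
- Algebraic least squares weights high-curvature regions differently
  from geometric distance; with very asymmetric click placement the fit
  can be biased in ways the jitter simulations do not capture.
- The exact Mann-Whitney path requires tie-free data; discretised
  durations (frame multiples) always take the corrected normal
  approximation.
- Depth attenuation in the renderer uses the depth below the surface,
  not the optical path along the detection axis; it emulates signal loss
  with depth, not the physics of a specific light-sheet geometry.
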