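# Methods

## Scope and model

`trabmech` treats a trabecular specimen as a cubic region of interest
(ROI) cut from an isotropically sampled HU-valued volume, with the
compression (gravity) axis along z.  Four labeled quadrants
(SA/SP/IA/IP) of an articular process, a vertebral level (C2–C7) and a
side (left/right) identify each ROI in the statistical design.  The
facet-plane angle θ (degrees between gravity and the shear force on the
facet) accompanies each ROI and enters only the allowable-stress
correction [σ] = σ_yield/cos θ; θ defaults to 45°, the typical cervical
facet inclination, and is freely configurable per region since
per-level values are not tabulated anywhere authoritative.

## Morphometry

Binarization is a global threshold (bone = HU ≥ t).  The threshold is a
required input; Otsu's method is available as an explicit opt-in, never
a silent default, because phantom and scanner histograms differ too
much for one automatic rule.

*Thickness/separation.*  Local thickness follows the
largest-inscribed-sphere definition: the thickness at a point is the
diameter of the largest sphere that fits inside the phase and contains
the point; Tb.Th and Tb.Sp are the volume-weighted means over bone and
marrow.  The implementation uses the Euclidean distance transform for
candidate sphere radii and sweeps radii in descending order, stamping
each sphere's diameter onto the voxels it covers.  Numerical choices:

- Distances between voxel centres overestimate the true half-thickness
  by half a voxel, so diameters are reported as 2r − h (h = spacing).
  This makes odd-thickness plates exact and even-thickness plates one
  voxel low — within the one-voxel quantum that any voxel method has.
- The ROI border counts as a phase interface (the phase mask is padded
  with the opposite phase before the distance transform).  Without
  this, structures touching the cube face inherit inflated spheres and
  a 5-voxel boundary plate reads as 9 voxels thick.
- Radii are quantized to at most 128 distinct values (an evenly strided
  subsample of the observed distances) to bound the sweep; the
  sub-voxel quantization error is far below the voxel quantum.

*Surface area.*  BS and BS/BV come from a triangulated 0.5-level
isosurface (marching cubes) of the zero-padded mask.  The mask is
smoothed with a 1-voxel Gaussian first: raw binary isosurfaces carry a
staircase overestimate of about +8 % on a digital sphere, while the
smoothed surface is within ≈1 % for radii above ~15 voxels (at the cost
of a few percent rounding loss on sharp edges).  Padding closes the
boundary faces, so a solid cube reports its closed-box surface.

*Pattern factor.*  Tb.Pf = (S₁ − S₂)/(V₁ − V₂) across a single-voxel
6-connected dilation; S from the isosurface above, V as voxel counts.
Dilation fills concavities, so well-connected lattices score low or
negative and isolated convex bodies positive.  Undefined (and reported
as NaN in batch mode) when the mask fills the grid.

*Tb.N* is the model-independent (BV/TV)/Tb.Th; the classical
plate-model variants are not used because they presume an architecture
the measurement should reveal.  BMD is a linear HU calibration
(slope, intercept) that must be supplied — scanner phantom calibrations
vary and no universal coefficients exist.

## Voxel micro-FE

Each foreground voxel becomes one trilinear 8-node hexahedron (2×2×2
Gauss quadrature, isotropic linear elasticity).  This is the standard
micro-FE discretization: it preserves the segmented geometry exactly,
and all elements share one unit stiffness matrix scaled by the element
modulus, which keeps assembly cheap.

Materials follow the calibrated power law density = 0.00097·GV (g/cc
per HU), E = 19.04·density^1.64 (MPa), ν = 0.3.  The HU→g/cc→MPa unit
reading is a convention of the calibration; both scale factors are
configurable.  Negative gray values are clamped at a configurable
density floor with a warning; elements whose modulus falls below a
stiffness floor are reported because they can make the system singular.

Boundary conditions are displacement-controlled axial compression in
three modes: `fixed_top_tangential` (bottom fully fixed, top driven
with tangential components pinned — the platen-friction condition of a
physical test, the default), `free_top_tangential` (top driven in z
only), and `frictionless` (both faces constrain z only, plus minimal
in-plane pins against rigid-body motion — the configuration whose
analytic solution is uniform uniaxial stress, used for verification).
The physical test's strain rate is quasi-static at the scales of
interest, so rate is recorded as metadata only and never enters the
static solve.

Mesh hygiene: floating fragments produce singular systems, so by
default every face-connected component that spans the loading axis is
retained and the rest dropped.  All spanning components are parallel
load paths; keeping only the largest (available as an option) would
mis-state the stiffness of architectures with several independent
columns or plates.  If nothing spans, a no-load-path error names the
gap.

The reduced SPD system is solved directly (sparse LU) below 50 000 free
unknowns and by Jacobi-preconditioned conjugate gradients at 1e-10
relative residual above.  Strains and stresses are recovered at element
centroids; von Mises and eigen-sorted principal values follow.  The
apparent modulus is (reaction / loaded area)/(|u_z| / height) with the
loaded area the **full grid cross-section** (apparent, not bone,
area — the specimen-level convention) and the height the meshed column
extent.

The optional elastoplastic extension ramps the displacement in
increments; within each increment the element modulus is replaced by
the bilinear tissue law's secant modulus at the element's von Mises
equivalent strain (sign from the volumetric strain selects the 0.8 %
compressive or 0.48 % tensile transition) and the system re-solved
until the moduli settle.  This is a small-strain secant method — it
captures post-yield softening of the load–displacement response, not
localization or large deformation.

Field summaries report min/max/mean von Mises, the range and mean of
the elements **at or below a quantile** of von Mises (default 0.75 —
the "lower 75 %" reading of a percentile-trimmed stress summary, which
discards the singular stress concentrations at constrained corners),
principal stress/strain extremes, and per-axis displacement extents.

## Curve reduction

Compression records store stress and strain as positive magnitudes.
The elastic modulus is the least-squares slope over a detected initial
linear window.  Detection: local secant slopes over a stride of ~n/6
samples (single-sample secants amplify noise by 1/Δε and are useless),
longest contiguous run within ±5 % of the run median, constrained to
start within the first quarter of the strain range (otherwise a long
post-yield hardening segment outscores the elastic region), then
robust trimming of trailing samples whose residual from the window fit
exceeds 3× the MAD scale.  A manual window overrides all of this.

The 0.2 %-offset yield is the intersection of the record with
σ = E(ε − 0.002), located by linear interpolation between the
bracketing samples — deterministic, no smoothing.  A record the offset
line never catches is reported as "no yield" (elastic to failure).
Bilinear fits use a free-breakpoint continuous two-segment least
squares (grid over sample strains with the hinge basis
{1, ε, (ε − b)₊}); collinear data set a degeneracy flag since the
breakpoint is then unidentifiable.

## Statistics

The factorial ANOVA is fixed-effects with Type III sums of squares on
sum-to-zero contrasts (matching the conventional software default for
unbalanced designs); designs with empty cells fall back to Type II.
Partial η² = SS_effect/(SS_effect + SS_error), reported also as
Eta % = 100·η².  A Bartlett test across design cells is run first and
its p-value reported.  Terms with zero sum of squares report F = 0,
p = 1, η² = 0 even when the residual variance is also zero (a constant
response carries no effects).  Simple effects are one-way ANOVAs of the
test factor within each stratum of the fixed factor, optionally against
the pooled error of the full model; Bonferroni-adjusted p-values
(family = strata) accompany the raw ones because the follow-up family
is multiple by construction.  The 144-observation default design
(4 regions × 6 levels × 2 sides × 3 replicates) mirrors the standard
facet-study layout; replicates are treated as independent, a choice the
analysis inherits from that design and that a mixed model would refine.

Regressions are OLS with adjusted R² = 1 − (1 − R²)(n−1)/(n−2) and the
two-sided Pearson p; ridge solves (ZᵀZ + λI)b = Zᵀy_c on z-scored
predictors and reduces exactly to OLS at λ = 0.

## Synthetic data: what it does and does not emulate

Phantoms are axis-aligned plate or rod lattices (plus iid-voxel
"homogeneous" fields and solid cubes) with exact ground-truth masks,
two HU phases (2000/0 by default, so midpoint thresholding is exact),
additive Gaussian HU noise, and an optional 1-voxel Gaussian blur for
partial-volume effects.  Plates are placed as evenly spaced whole
slabs, so the achieved BV/TV is quantized to whole plates — within half
a plate quantum of the target — and thickness/separation have closed
forms.  Curves are exact bilinear laws plus iid stress noise, with the
yield strain always a grid point.  Paired tables are y = ax + b + noise
with the design labels cycling over the region × level × side grid.

Deliberately absent: scanner physics (beam hardening, rings),
anatomically realistic architecture, anisotropy ellipsoids, correlated
noise, rate effects, and damage.  Passing tests therefore demonstrate
correctness of the measurement and solution machinery on structures
with known truth — not robustness to every artifact of real scans.

## Problem sizes and defaults

The shipped demo and the reproducibility checks run a 64³ phantom
(5 mm cube at 78 µm) with four 32×32×64-voxel quadrant ROIs
(~15 000 elements each, direct solve); solver verification uses a 16³
homogeneous cube against the analytic uniaxial solution and 2×2×2
heterogeneous meshes against an independently assembled dense system.
Monte-Carlo checks use 200 noisy curve replicates and 500 regression
replicates at n = 144.  These sizes exercise every code path at desk
scale; the machinery itself is size-independent up to memory.

## Known limitations

- Voxel meshes carry stress singularities at re-entrant corners; the
  percentile-trimmed summaries mitigate but do not remove them.
- The secant plasticity is not an incremental return-mapping scheme;
  unloading paths are not modeled.
- Tb.Pf depends on the dilation element (6-connected, 1 voxel, as
  classically defined) and on the surface estimator; compare values
  only within one pipeline.
- The smoothed isosurface slightly rounds sharp edges (few percent on
  cubes); raw binary surfaces are available via `smooth_sigma=0`.
- DICOM reading handles single-frame CT series with uniform spacing;
  multi-frame and gantry-tilted acquisitions are out of scope.
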