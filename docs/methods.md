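# Methods

## The model

Cortical folding is modeled as a mechanical instability of a growing soft
bilayer.  The brain is a tetrahedralized solid; a superficial layer of
thickness `h` (gray matter) expands tangentially relative to the bulk
(white matter).  Growth enters through the multiplicative morphoelastic
decomposition of the deformation gradient, `F = A G`, with the tangential
growth tensor

    G = sqrt(g) I + (1 - sqrt(g)) n (x) n,

where `n` is the unit direction toward the cortical surface (frozen in the
reference configuration) and `g` the tangential *area* growth ratio: `G`
stretches by `sqrt(g)` in the plane perpendicular to `n` and not at all
along `n`, so `det G = g`.  The elastic part `A = F G^-1` stores energy in
the modestly compressible neo-Hookean form

    W = mu/2 (J_A^{-2/3} tr(A^T A) - 3) + K/2 (J_A - 1)^2,    J_A = det A,

with bulk modulus `K = 5 mu` by default (Poisson ratio ~0.4).  Both the
shear modulus and the growth ratio follow the same sigmoid depth profile

    q(d) = q_w + (q_g - q_w) / (1 + exp[10 (d/h - 1)]),

where `d` is the reference distance to the cortical surface; the profile
is exactly halfway at `d = h`, near-surface values saturate at `q_g`, deep
values at `q_w`.  The cortical thickness may shrink linearly in the
normalized growth time, `h(t) = h0 - h_slope * t`.

Total energy is `sum_tets V_ref * W` (linear P1 tetrahedra, one-point
quadrature) plus a self-contact penalty, quadratic in the penetration of
boundary-vertex pairs below the contact range.  Contact pairs are found
with a k-d tree and exclude pairs that are within a few rings of each
other on the reference surface, since material neighbors legitimately sit
within contact range.  A vertex-pair penalty was chosen over vertex-
triangle projection for its simple exact-gradient kernel; at the contact
ranges used (~0.75 of a surface edge length) the boundary resolution makes
the two essentially equivalent.

## Mechanics of the study conditions

The cross-species study conditions are growth ratio `g = 1.8`, stiffness
ratio `mu_g/mu_w = 1`, normalized cortical thickness `h = 0.1` (lengths in
units of half the longitudinal extent).  These put the cortex under
equibiaxial compression of `1 - 1/sqrt(1.8) ~ 25%`, which is *marginally*
at the sulcification (creasing) threshold of an equal-modulus neo-Hookean
bilayer (~25% equibiaxial).  A single continuous ramp to `g = 1.8`
therefore produces only faint dimpling.  Robust folding arises from the
step-wise protocol: at each stage boundary the current relaxed geometry is
adopted as the new stress-free reference (as when successive fetal
geometries are treated as new initial conditions) and the surface ramp
restarts from 1, so compression accumulates geometrically across stages.
The ferret-like demo uses this protocol with two growth episodes; the
folding reproduction uses five (four reference resets), mirroring the
ferret's four successive initial geometries (P0/P4/P8/P16) plus the
final maturation stretch to the folded adult state.

At this scale a hemisphere spans only two to three fold wavelengths, and
that bounds how closely the shape-index histogram can approach its
asymptotic structure.  A gyral crown has cross-fold curvature
`k1 ~ 1/(1.5 h)` but keeps the background ellipsoid curvature
`k2 ~ 1/R` along the fold, which shifts the ridge peak from +0.5 to
about `0.5 + (2/pi)(k2/k1)`; a sulcal floor stays convex along the fold
for the same reason, shifting the rut peak to about `-0.5 + (2/pi)
(k2/|k1|)`.  With `h = 0.1` and `R ~ 1.2` this predicts peaks near
-0.42 and +0.58 — precisely where the measured histogram peaks sit
(-0.42, stable across seeds, and +0.55 to +0.67 across stage counts and
seeds).  Reaching
peaks within one histogram bin (1/32) of the +-0.5 asymptote requires
roughly a tenfold larger fold-to-brain scale separation than the study
thickness allows at this mesh size.

## Relaxation

The quasi-static equilibrium after each growth increment (increments of
at most `g_increment = 0.02` by default) is found by explicit energy
minimization with FIRE (fast inertial relaxation engine): per-vertex
pseudo-masses are lumped from element stiffness (`V (mu + K) ||Dm^-1||^2`
summed over incident tets), the pseudo-time step grows up to 10x its base
value while the motion descends (power `f.v > 0`) and collapses with a
velocity reset when it does not.  A best-energy safeguard reverts runaway
ascent, and element inversion backtracks to the best state with a smaller
step.  Plain fixed-step damped dynamics was tried first and rejected: on
a wrinkling bilayer fixture it grew the folding instability roughly
thirty times more slowly, which matters because a folding run spends most
of its time amplifying soft unstable modes whose residual forces start
below any practical tolerance.  For the same reason, instability fixtures
must either carry a geometric perturbation (the brain-like solids'
spherical-harmonic boundary modulation) or be seeded explicitly; an
unperturbed symmetric state is an equilibrium at any growth ratio.

`force_tol` is an infinity-norm on nodal forces; the default 1e-4 (in
units of `mu L^2`) is adequate for stress relief, but runs that must
develop an instability use 1e-5 together with the increment cap.

## Synthetic geometry

Brain-like solids are ellipsoids (longitudinal semi-axis first, aligned
with x) whose boundary radius is modulated by a seeded random real
spherical-harmonic mixture of degrees 1..n_modes, amplitude-normalized so
the peak relative perturbation equals `amplitude` (default 0.05; kept
below 0.2 so the surface stays star-shaped and genus 0).  The interior is
meshed by extruding the icosphere tessellation inward through concentric
shells graded toward the surface (default interfaces near the surface at
roughly one boundary-edge spacing, growing 1.6x per shell) and closing
the core with a cone of tets at the center.  This trades interior element
quality for a guaranteed-conforming, fully deterministic mesh whose
surface layers — where folding happens — are well resolved.  The folding
reproduction uses shell interfaces at radial fractions
(1, 0.95, 0.88, 0.78, 0.62), i.e. two to three elements through the
cortical thickness, ~66k tets for a subdivision-4 boundary.

Landmark curves emulate hand-traced major sulci: endpoint pairs drawn
uniformly from (interior) surface vertices, connected by shortest paths
on the edge graph, with all vertices within `min_separation` of earlier
curves blocked, so curves are vertex-disjoint and separated by
construction.  Real sulci are valley-bottom curves; the synthetic ones
are arbitrary geodesics, which exercises the registration machinery
identically but carries no anatomical meaning.

## Morphometry

Mean curvature comes from the cotangent-Laplacian mean-curvature normal
and Gaussian curvature from the angle defect, both over Meyer mixed
Voronoi areas; the sign convention is outward normals with `H > 0` on
outward-convex (gyral) regions.  The shape index
`SI = (2/pi) arctan(H / sqrt(H^2 - K))` degenerates at umbilic points
(`H^2 -> K`), where it snaps to `sign(H)`.  Discrete estimates of
`H^2 - K` carry truncation noise of relative size ~1e-3 on a
subdivision-4 icosphere (measured; second-order convergence), so the
umbilic test uses a relative tolerance, `H^2 - K <= 2e-3 max(H^2, |K|)`,
rather than an absolute one: on a refined sphere every vertex is
correctly recognized as umbilic while a cylindrical ridge
(`H^2 - K = H^2`) is three orders of magnitude away from the cutoff.
Boundary vertices, whose one-rings are incomplete, are masked and
excluded from histograms and similarity counts.

Histograms use 64 equal-width bins on [-1, 1], Gaussian-smoothed with a
1.5-bin kernel; modes are local maxima with prominence at least 0.1 of
the global maximum.

## Disk mapping and registration

A dissected hemisphere (single boundary loop, Euler characteristic 1) is
flattened by: boundary to the unit circle with arclength-proportional
spacing, interior by mean-value (Tutte) weights — an embedding, so the
initial parameterization has no flipped triangles — then up to three
Beltrami correction passes.  Each pass measures the per-face Beltrami
coefficient mu of the map from locally flattened surface triangles to the
parameter domain, transports `-mu fz/conj(fz)` to the disk, and solves a
linear Beltrami system for a disk-to-disk correction, backtracking if a
full step would flip a face.  On a smooth hemisphere the achieved mean
|mu| is ~0.013.

The linear Beltrami solver minimizes the least-squares residual
`sum_faces area |f_zbar - mu f_z|^2` over complex vertex positions — its
null space is exactly the discrete Beltrami equation, so a constant mu
plus two pinned vertices reproduces the corresponding affine map to
machine precision — subject to hard (eliminated) and soft (penalty)
point constraints.

Landmark registration holds the circle boundary fixed, matches each
source landmark vertex to the same normalized-arclength position on the
target curve, and alternates Beltrami-clamped solves (|mu| chopped at
0.95) with a geometric soft-weight ramp (x4 per round from 10) until the
resampled mismatch drops below the tolerance (default 1e-3).  Landmark
vertices lying on the disk boundary are dropped from the constraints:
they are pinned to the circle and cannot follow a target.  Scalar fields
are pulled back by barycentric interpolation on the target disk
(trapezoid-map point location, with a nearest-centroid fallback for
degenerate target triangulations); points that spill outside the disk
numerically are radially projected onto the boundary first.

## Similarity

`s(S1, S2) = 1 - ||I1 - I2 o (g2^-1 o f12 o g1)||_p / (2 m^(1/p))` for
descriptor fields in [-1, 1] (shape index or rescaled mean curvature),
with `m` the number of non-boundary S1 vertices with valid curvature —
whether boundary vertices should count is not determined by the formula
alone; the choice (excluded) is recorded in every report's provenance.
The formula is asymmetric in (S1, S2); both directions can be computed.
For p = infinity the norm is the max absolute difference and
`m^(1/p) = 1`.

## Numerical choices and degenerate inputs

- Vertices exactly on a cutting plane belong to the kept side; a cut that
  produces more than one boundary loop is reported as an error.
- `normalize_halflength` rescales by half the *x*-extent; callers align
  the longitudinal axis with x beforehand.
- Constant fields have no rescaled mean curvature (error), and empty
  fields no histogram.
- The brain-like mesher reorients any negative tets it produces and fails
  loudly if a tet is degenerate (amplitude too large for the edge bound).
- Seeds: every generator and the pipeline are deterministic functions of
  their explicit seeds; reruns produce bit-identical meshes and hashes.

## Problem sizes

Unit tests run on subdivision-3/4 icospheres (642–2562 vertices), ~5k-tet
brain solids and ~11k-tet slabs.  The folding reproduction uses a ~66k-tet
brain-like solid (subdivision-4 boundary, 2562 surface vertices), four
step-wise stages at growth ratio 1.8, thickness 0.1 - 0.005 t, stiffness
ratio 1 — a deliberately desk-scale version of the study conditions; the
demo pipeline uses a coarser solid (~9k tets, two stages) where the
property of record is reproducibility rather than fold fidelity.

## Known limitations

- The wavelength-selection invariant (fold spacing proportional to
  cortical thickness) does not emerge cleanly at these resolutions: with
  stiffness ratio 1 creasing is essentially scale-free, and in stiff-film
  fixtures the substrate depth and clamped ends dominated the selected
  wavelength in every configuration tried.  The tests therefore assert
  the sharp below/above-threshold contrast in fold amplitude instead.
- Synthetic landmarks are geodesics, not valley-following sulcal curves;
  similarity values between two different synthetic brains are not
  comparable to values computed on real cortices with hand-traced sulci.
- The contact penalty prevents interpenetration at the resolution of the
  boundary mesh; sub-edge-length penetration of sharp crease cusps is
  possible.
- Interior cone elements near the solid's center are highly anisotropic;
  they only provide bulk support and should not be used to measure
  interior fields.
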