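# Methods

## The packing score

A cluster is N equal spheres of diameter sigma_c with no pair of centers
closer than sigma_c (relative tolerance 1e-9).  Its packing fraction is
measured against the tightest convex container, the convex hull of the
balls: the Minkowski sum of the center hull with a ball of radius
r = sigma_c/2.  For a full-dimensional center hull the dilated volume is the
Steiner decomposition

    V_ch = V_hull + A_hull·r + (Σ_e ℓ_e γ_e / 2)·r² + (4π/3)·r³,

where γ_e is the exterior dihedral angle of edge e.  The facets delivered by
qhull are triangles; edges interior to a merged facet simply contribute
γ ≈ 0 (the arccos of near-unity normals introduces noise at the 1e-8 level,
far below every tolerance used).  Degenerate clusters are detected from the
singular values of the centered coordinate matrix (relative threshold 1e-8,
no perturbation): coplanar clusters use the dilated-polygon form
2rA + (π/2)r²P + (4π/3)r³, collinear ones the spherocylinder form
πr²L + (4π/3)r³, a single sphere the ball volume.  The choice of the exact
dilation (rather than a triangulated approximation of the ball surfaces)
makes the score consistent with the closed-form sausage reference
η_lin(N) = 2N/(3N−1) to machine precision; a rejection-sampling Monte-Carlo
oracle in the test suite confirms the dilation on random clusters to three
standard errors.

Near the tetrahedron/line crossing the margin between η_ch and η_lin is a
few parts in 10⁴, so implementations that approximate the dilation can move
the apparent crossing size; the 1e-3 relative band used when reporting the
crossing reflects that sensitivity.

## Cluster families

All generators place centers on close-packed lattices with minimum distance
exactly one diameter (the Mackay icosahedron is the one exception: its
twenty FCC grains are ~5% strained, and only the minimum distance is
normalized).  Octahedron vertices sit on fourfold axes, so their caps are
square-pyramidal numbers (1, 5, 14, ...); tetrahedron and bipyramid-apex
caps are tetrahedral numbers (1, 4, 10, ...).  The triangular bipyramid is
two FCC tetrahedra sharing their base layer; the lower half is the mirror
twin of the upper, which keeps every interlayer contact exact (a valid
Barlow stacking).  Equatorial caps for bipyramids were evaluated during
development and added no clusters beyond the apex-cut family in the
56–70 window, so the shipped family uses apex layer cuts only.  General
Barlow stacks ("ABAB", ...) are available through `make_barlow_stack` for
HCP-type comparisons.

## The irregular truncation search

Complete-vertex-cap truncations alone do not exhaust the efficient packings
(no complete-cap cluster reaches the line at N = 58 or 64).  The search
therefore refines the enumeration with greedy partial cuts: starting
from every complete-cap truncation that already beats the sausage (bases up
to m = 9 for T, 6 for O, 8 for B; seeds up to 14 spheres above the window),
spheres are removed one at a time, each step deleting the sphere whose
removal maximizes η_ch.  Ties break on the lowest construction index, so
the search is deterministic.  This realizes cuts whose sizes are not
figurate cap numbers and yields, in 56 ≤ N ≤ 70, sausage-beating clusters
at every N except 57 — including N = 58 and N = 64 (reached from m = 8
tetrahedra with vertex-cap depth profiles (3,3,4,4) and (2,3,4,4)) and a
bipyramid-derived packing at N = 63 whose small margin over η_lin(63) the
test suite cross-checks against the Monte-Carlo hull oracle.  At N = 57 the
best cluster found falls just short of the line — effectively a tie,
consistent with 57 remaining sausage-optimal.  Every refined cluster is a
valid overlap-free packing scored exactly, so each beater is a certificate
regardless of how it was found.  Catalogue rows are deduplicated by (N,
family, base,
sorted cap multiset, number of refinement removals) and written with 12
significant digits so repeated runs are byte-identical.

## Order parameters and classification

kappa² is the relative shape anisotropy of the unweighted gyration tensor
(identical colloids make mass weighting irrelevant): 0 for isotropic, 1/4
for symmetric planar, 1 for collinear configurations.  Conformations are
labelled cluster (< 0.15), plate ([0.15, 0.35)), intermediate ([0.35, 0.5))
and linear (≥ 0.5); the explicit intermediate band avoids forcing a label in
the gap between the plate and linear regimes.  Steinhardt q6 uses a distance
cutoff of 1.33 diameters, the midpoint of the first and second FCC shells
(the ideal FCC shell gives 0.5745, HCP 0.4848; both are frozen in the tests
from an independent evaluation of the bond-order sum).

Vesicle volume and area come from a watertight surface reconstruction of
the membrane bead cloud: an alpha complex (Delaunay tetrahedra with
circumradius below 2× the median bead spacing) whose boundary faces are
oriented outward, with a convex-hull fallback when the complex is not
closed.  Volume follows from the divergence theorem.  On bead-sampled
sphere, prolate, discoid and spherocylinder fixtures of 3000 beads the
reduced volume is recovered within 3%, matching the error budget of typical
image-based estimates; the 2:1 prolate spheroid has ν = 0.8950 from the
closed-form area.

Bistability detection smooths kappa²(t) with a 20-sample moving average,
classifies each sample, and dissolves segments shorter than a 50-sample
minimum dwell into their neighbors (both parameters exposed); a series is
bistable when exactly two states alternate at least twice with resolvable
dwells.  The synthetic telegraph generator draws dwells from a shifted
exponential with a 60-sample floor so that every planted segment is
resolvable by construction, making exact alternation-count recovery a
well-posed test.

## Membrane simulator

Membrane beads carry unit orientation vectors and interact through the
orientation-dependent potential (repulsive r⁻⁴/r⁻² core below
r_min = 2^{1/6}σ, a cos^{2ξ} attractive tail to r_c = 2.6σ, and the
alignment weight φ = 1 + μ(a − 1)); defaults are ε = 1, ξ = 4, μ = 3,
sinθ₀ = 0, k_BT/ε = 0.23, colloid diameter 12σ — the standard fluid-
membrane set.  Colloids and solvent are WCA spheres with Lorentz contact
mixing; solvent lives only in the shell between the membrane and a
repulsive spherical wall, so its density sets the osmotic pressure on the
vesicle.  Analytic pair forces and orientation gradients are verified
against central differences at 1e-6 relative — the critical test for the
orientation terms.  Translation uses BAOAB Langevin splitting (velocity
Verlet when the thermostat is off); orientations follow an overdamped
rotational Langevin update, the gradient projected orthogonally to n and
the vector renormalized every step, which preserves unit norm by
construction.  The NVE check (orientations frozen) holds energy drift below
1e-3 over 10⁴ steps at dt = 0.002τ.

### Desk-scale deflation

The published-scale protocol (12σ colloids, ~10⁴ beads) is out of desk
scope; the shipped demonstration uses a reduced system chosen so the same
physics is visible in minutes: N = 4 colloids of diameter 4.6σ in a vesicle
of radius 6.5σ (~580 beads at one bead per 0.92σ², the spacing the membrane
itself relaxes to at k_BT/ε = 0.23), confining wall at 10σ.  N = 4 is the
smallest count with a three-dimensional compact state (a tetrahedron; three
colloids are always coplanar, so their kappa² can never reach the cluster
band).  The geometry is a deliberate compromise found by scanning the
colloid-to-vesicle size ratio: much tighter vesicles jam — the membrane
shrink-wraps the tetrahedron and no amount of pressure dislodges it — while
much looser ones elongate readily but leave the colloids free to diffuse
after re-inflation, so no compact state is recovered.  At this ratio the
rounded vesicle still cages the colloids (equilibrium kappa² well inside
the cluster band) yet the deflation pathway to the plate conformation
remains accessible.

Deflation adds outer solvent in increments of 100 with 3500 Langevin steps
of equilibration between increments, stopping when the stage kappa² leaves
the cluster band (the ν target itself is not reachable at this scale: the
membrane accommodates part of the osmotic stress by compressing its bead
spacing, because its soft r⁻⁴ core gives it a much lower effective area
modulus than a tense lipid bilayer, so ν responds more slowly than an
area-conserving membrane would).  Re-inflation removes the solvent again
and the colloids relax back into the compact cluster over a few ×10⁴
further steps.  The qualitative cluster → plate → cluster cycle survives
this reduction; the quantitative ν-boundaries of the full-scale state
diagram do not, and reaching the linear conformation reliably requires the
larger systems documented as long-running.  Membrane integrity is
monitored as connectivity of the bead neighbor graph (cutoff 1.6σ);
rupture aborts the protocol with a diagnostic.

## What the synthetic fixtures do and do not emulate

Surface fixtures are area-weighted random samplings of ideal closed
surfaces with exact ground-truth V, A, ν — they emulate bead coverage, not
thermal roughness, so the 3% recovery tolerance reflects mesh discretization
only.  Colloid archetypes are ideal line / triangular-plate / compact-FCC
geometries with isotropic Gaussian noise re-projected to contact; they
exercise the classifier bands, not packing dynamics.  The telegraph series
emulates two-state switching with memoryless dwells and Gaussian
observation noise; real trajectories have correlated fluctuations within a
state.  Passing these tests therefore validates the measurement pipeline,
not the realism of membrane dynamics.

## Numerical choices and limitations

* Overlap tolerance diameter·(1 − 1e-9); inputs violating it must pass
  through the hard-sphere projection first (uniform rescale about the
  centroid by default; the optional `tighten` descent is off by default so
  at-contact constructions pass through unmodified).
* `tighten` uses numerical hull-volume gradients, fixed step 1e-3·diameter,
  deterministic index-order sweeps, and accepts only non-increasing-volume
  moves, so η_ch never decreases.
* The greedy refinement is a local search: it certifies the beaters it
  finds (each output cluster is a valid packing scored exactly) but cannot
  prove absence — "no beater at 57" means none within this family and
  refinement.
* Simulation pair lists rebuild every 10 steps with a 0.6σ skin; a particle
  displacing more than r_c/2 in one step raises an unstable-dt error.
* Solvent insertion is rejection sampling in the membrane–wall shell and
  saturates near fluid densities; the deflation loop stops early (with a
  log message) when no increment can be placed.
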