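# Methods

`wssbench` compares numerical evaluations of wall shear stress (WSS) from
finite-element solutions of incompressible flow. This note records the
models, the discretizations, the evaluation methods, and the numerical and
design choices a maintainer would need to reassess them.

## Flow models

**Stationary Stokes.** Find velocity `v` and pressure `p` with

    div T(v,p) + f = 0,   div v = 0,   T = -p I + nu grad(v)

on a polygonal/polyhedral domain, with Dirichlet (velocity) and Neumann
(traction) boundary segments. The full velocity gradient is used in the 2D
benchmark; the 3D problems use the symmetric stress `T = -p I + 2 nu D(v)`
with `D = (grad v + grad v^T)/2`. When every boundary segment is Dirichlet
the pressure is determined up to a constant and is gauge-fixed to zero
mean.

**Navier–Stokes, steady state.** The transient equations
`rho (v_t + (grad v) v) = div T`, `div v = 0` are marched to steady state
with variable-step BDF2 pseudo-time stepping: the flow starts at rest, the
inflow data are ramped linearly over 0.5 s, and the step grows
geometrically (factor 1.5 after a fast Newton solve, halved on divergence)
within `[1e-2, 1e5]` s until the relative L2 rate of change
`||v^n - v^(n-1)|| / (dt ||v^n||)` falls below `1e-5` per second. The
momentum equation can be density-scaled (divided by `rho`), in which case
pressure and WSS are reported "per density"; the Poiseuille benchmark uses
this convention, so its exact WSS magnitude is the familiar 8.

## Discretizations

* **Taylor–Hood P2/P1** — inf-sup stable; Dirichlet data imposed strongly
  at the velocity nodes (including mid-edge nodes, which on curved walls
  lie inside the true domain — this is the geometric-error mechanism the
  cylinder benchmark exposes).
* **Stabilized equal-order P1/P1** — continuous interior penalty (CIP) for
  Stokes: facet jumps of the pressure normal gradient (weight
  `gamma_p h_K^(s+1)`) and of the velocity divergence (`gamma_v h_K^(s+1)`),
  with `s = 2` where `nu >= h_K` and `s = 1` otherwise, decided per cell
  with that cell's circumdiameter. For Navier–Stokes an interior-penalty
  stabilization with full gradient jumps is used instead: weights
  `alpha_v = 1e-3`, `alpha_p = 1`, and a streamline term `alpha_i = 1e-3`
  scaled by the facet integral of `(v.n)^2`; the streamline factor is
  frozen at the previous time step inside each Newton solve so the
  Jacobian stays exact.
* **Nitsche boundary enforcement** — the non-symmetric variant with
  penalty `beta nu / h` (default `beta = 10`, configurable; the method is
  well-posed at `beta = 0`). The stabilized P1/P1 pair always enforces
  Dirichlet data weakly; for it the package enforces *every* velocity
  constraint weakly — inlet profile, wall no-slip, and the tangential-only
  outlet constraint (a tangentially projected Nitsche term) — so that the
  discrete momentum equations hold for all wall-supported test functions.
  That choice is what makes the boundary-flux WSS recovery algebraically
  identical to the P1 projection for this pair (see below).

Default stabilization weights per benchmark: `gamma_p = gamma_v = 1e-2`
(unit square), `gamma_p = 1`, `gamma_v = 1e-3` (cylinder).

## WSS evaluation

The wall traction is `t = T n`; WSS is its tangential part
`tau = t - (t.n) n` (per-facet outward normals throughout; no nodal normal
averaging is performed anywhere).

**Projection.** Solve `(tau, phi)_Gamma = (t_tang, phi)_Gamma` for all
test functions of a continuous P1 space or of facet-local DG-1/DG-0
spaces. The pressure drops out of the tangential traction identically, so
the integrand uses only the viscous stress. Continuous-space systems are
assembled on the whole mesh with non-wall rows replaced by identity and
zero data (interior degrees of freedom are exactly zero); DG systems are
solved facet by facet in closed form.

**Boundary flux.** The variationally consistent recovery: test the
momentum residual with wall-supported functions `phi`,

    (tau_b, phi)_Gwall = rho (v_t + (grad v) v, phi) + (T, grad phi)
                         - (f, phi) + S(v, p; phi, 0)
                         - ((T n).n, n.phi)_Gwall
                         - (T n, phi)_Gin+Gout  [+ Nitsche terms],

and solve a wall mass-matrix system restricted to wall-supported degrees
of freedom. When a non-wall segment was weakly enforced, its full Nitsche
terms replace the plain traction subtraction, and on a weakly enforced
wall the consistency and penalty terms are retained on the right-hand
side. With those terms the right-hand side equals, row for row, the
discrete equations' expression for the wall flux; consequently, for the
stabilized P1/P1 pair the recovered `tau_b` coincides with the P1
projection up to linear-solver precision — the package treats that
equivalence as an invariant and tests it at 1e-6.

**Corners.** On polygonal domains the exact WSS is discontinuous at
corners (on the unit-square benchmark the top side carries `60x` while the
right side carries a constant of different direction). A single continuous
field over the whole boundary cannot converge past O(h^1/2) there, so on
the square every method — boundary flux *and* projections — is evaluated
side by side: each side is recovered with the remaining sides treated as
traction-subtracted segments, and errors are accumulated per side. This
segment-wise evaluation is what restores the quadratic convergence the
continuous methods are capable of.

## Benchmarks

* **2D Stokes, unit square** (`nu = 1`, `f = 0`): the polynomial pair
  `v = (20xy^3, 5x^4 - 5y^4)`, `p = 60x^2y - 20y^3 - 5`. Verified
  symbolically (divergence and momentum residual) at construction; the
  per-side exact WSS is derived symbolically from the stress. Meshes are
  structured crossed-diagonal triangulations with `N = 8..256` elements
  per side (each square split into four triangles through its centre —
  symmetric about both axes).
* **3D Poiseuille, cylinder** (R = 1 mm, L = 2 mm, parabolic inflow with
  peak 1 m/s, `mu = 4e-3` Pa s, density-scaled): exact WSS magnitude
  `2 mu u_m / R = 8`, directed against the flow. The outlet fixes the
  tangential velocity components and leaves the normal direction natural.
  Because the convective term vanishes identically for this flow, the
  shipped studies compute the steady state with the stationary Stokes
  solver; the pseudo-time Navier–Stokes solver is available and tested to
  agree (to discretization accuracy) on the same meshes.

**Cylinder meshes.** A disc is triangulated over concentric point rings
(Delaunay) and extruded along the axis into prisms, each split into three
tetrahedra with a sorted-vertex diagonal rule that guarantees conforming
faces. The boundary-layer family inserts four graded rings against the
wall (first height 10% of the surface edge length, growth ratio 1.1) ahead
of a uniform core. The generator is deterministic; the mesh family is more
structured than the commercial unstructured meshes one would use on real
anatomy, which matters for error *constants* and can let smooth quantities
superconverge (the studies fit rates against the nominal edge length, the
abscissa on which the benchmark results are reported). Study sizes used
by the shipped studies: edge lengths 3.0–1.2 e-4 m (P1/P1) and
3.0–1.6 e-4 m (P2/P1), chosen so a study completes in minutes on one
core while the fitted slopes are stable under dropping the coarsest level.

**What the generators do not emulate:** anatomical curvature and tag
layouts of real vessels, anisotropic surface remeshing, and unstructured
mesh irregularity. Passing benchmarks therefore validate the formulations
and their implementation, not robustness to imaging-derived geometry; the
`external_mesh` pipeline accepts tagged MSH/XDMF meshes for that purpose
but requires user-supplied fluid properties and tag maps.

## Hemodynamic indicators

Over a tagged dome region: max/min of `|tau|` on the method's native
evaluation set (wall nodes for continuous spaces, facet nodes for DG-1,
facets for DG-0), area-weighted average via facet quadrature, and the low
shear area LSA = percentage of dome area where `|tau|` is below 10% of the
parent-artery mean WSS, accumulated quadrature-point-wise (facet-wise
thresholding, same WSS method for dome and parent).

## Linear algebra

Saddle-point systems are solved by (a) a pressure Schur complement with
GMRES preconditioned by the inverse lumped pressure mass over viscosity,
with the velocity block factorized directly — per scalar component when
the stress form leaves components uncoupled — or (b) for large
component-coupled blocks, GMRES on the full saddle system with a
block-diagonal field-split preconditioner (per-component scalar LU +
pressure mass). Dirichlet-only problems deflate the constant pressure
mode and shift to exact zero mean afterwards. Linear tolerances are 1e-13
(Schur) and 1e-11 (field-split) relative; Newton uses 1e-8 relative to
each step's initial residual with a floor at the rounding level of the
assembled terms. Quadrature: volume forms at degree `2k` (convection
`3k-1`) for velocity degree `k`; boundary integrals at `2k+1`; error norms
at degree 6–10.

## Known limitations

* Affine elements only; no curved (isoparametric) boundary cells, so the
  polyhedral geometry error of curved walls is a first-class citizen of
  the cylinder results (that is the point of the benchmark, but it caps
  attainable WSS accuracy).
* The pressure error of the cylinder benchmark superconverges on this
  structured mesh family (the exact pressure is linear and exactly
  representable, so its error is purely consistency-driven); fitted
  pressure slopes land near 2 rather than the ~1.6 reported on
  unstructured commercial meshes of the same resolution range.
* The interior-penalty streamline term is time-lagged (see above), so the
  pseudo-time Jacobian is exact for the lagged operator, not the fully
  implicit one; with the benchmark's step-size controller this has shown
  no practical effect.
* MSH support is ASCII v4.1 with simplex elements and facet physical tags;
  binary MSH and mixed-element meshes are out of scope.
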