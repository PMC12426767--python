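# wssbench

Finite-element evaluation of **wall shear stress (WSS)** — the tangential
component of the fluid traction `T·n` on a vessel wall — is not as settled
as its ubiquity in cardiovascular CFD suggests: the same velocity/pressure
solution yields visibly different WSS depending on how the traction is
recovered and in which finite-element space it is represented. `wssbench`
is a self-contained benchmark suite and library for quantifying those
differences. It is aimed at computational-hemodynamics practitioners and
method developers who need to choose (or defend) a WSS evaluation method.

It implements, from a common discretization core:

* incompressible **Stokes** and steady **Navier–Stokes** solvers (BDF2
  pseudo-time marching) with Taylor–Hood **P2/P1** or stabilized
  equal-order **P1/P1** elements (continuous-interior-penalty jumps
  `γ h_K^{s+1} [[n·∇p]][[n·∇q]]` and divergence jumps; interior-penalty
  gradient jumps for Navier–Stokes), and strong or **non-symmetric
  Nitsche** Dirichlet enforcement with penalty `β ν / h`;
* WSS by **L2 projection** of the tangential traction
  `τ = T n − (T n·n) n` onto continuous P1 or facet-local DG-1 / DG-0
  spaces on the wall;
* WSS by **variationally consistent boundary-flux recovery**: the
  momentum residual tested with wall-supported functions,

      (τ_b, φ)_Γwall = ρ(∂t v + (∇v)v, φ) + (T, ∇φ) − (f, φ) + S(v,p; φ,0)
                       − ((T n)·n, n·φ)_Γwall − (T n, φ)_Γin∪Γout
                       [+ retained Nitsche terms on weak walls],

  including the Nitsche-consistent variant and corner-safe per-segment
  evaluation on polygonal domains;
* analytic benchmarks (a polynomial 2D Stokes flow on the unit square and
  3D Poiseuille flow in a cylinder, both verified symbolically), mesh
  generators (structured crossed-square triangulations; ring-extruded
  tetrahedral cylinders with optional four-layer geometric near-wall
  grading), L2 error norms, log-log rate fitting, and the dome
  **max/min/avg WSS** and **low-shear-area (LSA)** indicators for tagged
  vascular meshes (MSH 4.1 / XDMF input).

A notable property implemented and tested here: for the stabilized P1/P1
pair with fully weak (Nitsche) velocity enforcement, the boundary-flux
recovery is *algebraically identical* to the P1 projection — the package
reproduces this to machine precision — while for P2/P1 the two families
genuinely differ, and near-wall mesh grading on a curved wall can make
every WSS method *worse* (a polyhedral geometry-approximation effect).

## Worked example

Run a small mesh-convergence study of the manufactured 2D Stokes flow
(`v = (20xy³, 5x⁴−5y⁴)`, `p = 60x²y−20y³−5`, ν = 1) with Taylor–Hood
elements and three WSS methods:

```bash
$ wssbench stokes2d --levels 8 --levels 16 --levels 32 \
      --element p2p1 --wss bflux-p1,p1,dg0 --out demo_out
wrote demo_out/stokes2d_p2p1_uniform.csv
  rate         velocity: 3.014
  rate         pressure: 2.006
  rate     wss_bflux-p1: 2.167
  rate           wss_p1: 2.257
  rate          wss_dg0: 1.000
```

The numbers are fitted log-log slopes of relative L2 errors against 1/N:
cubic velocity and quadratic pressure convergence (the theoretical
Taylor–Hood orders), quadratic WSS for the boundary-flux recovery and the
side-wise P1 projection, and first order for the piecewise-constant DG-0
representation — one order lower because the exact WSS grows linearly
along the top side, which a facet-constant field can only track to O(h).
The CSV contains the per-level errors plus a final `rate` row; a
`manifest.json` records the configuration hash for reproducibility.

The same interface runs the cylinder benchmark
(`wssbench poiseuille --element p1p1 ...`), where every method's WSS
magnitude converges to the analytic `2μu_m/R = 8` (density-scaled), and
`wssbench mesh-run --config vessel.yaml` for externally supplied tagged
meshes (inlet/outlet/wall/dome regions, parabolic inflow, steady
Navier–Stokes, WSS indicators incl. LSA).

Library use mirrors the CLI:

```python
from wssbench import (build_cylinder_mesh, FluidProperties, solve_stokes,
                      project_wss, boundary_flux_wss)
from wssbench.benchmarks import poiseuille_config, poiseuille_exact
```

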