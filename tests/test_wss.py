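"""WSS evaluator tests: tangential projection, projection spaces, the
boundary-flux recovery, and single-cell brute-force oracles."""

import numpy as np
import pytest
import sympy as sym

from wssbench import (BC, BCSpec, DiscretizationConfig, FluidProperties,
                      StabilizationWeights, boundary_flux_wss,
                      boundary_flux_wss_per_segment, project_wss,
                      tangential_part, tangentiality_ratio)
from wssbench.fem import assemble as asm
from wssbench.fem.spaces import FunctionSpace
from wssbench.solver import FlowSolution
from wssbench.wss import WSSField

from conftest import single_triangle_mesh


class TestTangentialPart:
    def test_pure_normal_gives_zero(self):
        n = np.array([0.0, 0.0, 1.0])
        assert tangential_part(n, n) == pytest.approx(np.zeros(3))

    def test_pure_tangent_unchanged(self):
        n = np.array([1.0, 0.0])
        a = np.array([0.0, 2.5])
        assert tangential_part(a, n) == pytest.approx(a)

    def test_axis_aligned_example(self):
        a = np.array([1.0, 2.0, 3.0])
        n = np.array([0.0, 0.0, 1.0])
        assert tangential_part(a, n) == pytest.approx([1.0, 2.0, 0.0])

    def test_result_orthogonal_to_normal(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(20, 3))
        n = rng.normal(size=(20, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        t = tangential_part(a, n)
        assert np.abs((t * n).sum(1)).max() < 1e-12


def _linear_solution(mesh, A, b, c, nu=1.0, element="p1p1",
                     enforcement="strong"):
    """Manually built FlowSolution with v = A x + b, p = c0 + c.x."""
    Vv = FunctionSpace(mesh, 1)
    Qp = FunctionSpace(mesh, 1)
    v = Vv.dof_coords @ A.T + b
    p = c[0] + Qp.dof_coords @ c[1:]
    cfg = DiscretizationConfig(
        element_pair=element, enforcement=enforcement,
        stress_form="full_gradient",
        stabilization=StabilizationWeights(gamma_p=1e-2, gamma_v=1e-2),
    )
    props = FluidProperties(kinematic_viscosity=nu, density=1.0)
    zero = lambda x: np.zeros_like(np.atleast_2d(x))
    tags = np.unique(mesh.boundary_facet_tags)
    bcs = BCSpec(regions={int(t): BC("dirichlet", zero) for t in tags})
    return FlowSolution(v=v, p=p, mesh=mesh, Vv=Vv, Qp=Qp, config=cfg,
                        props=props, bcs=bcs, problem="stokes")


class TestProjectionOracles:
    def test_zero_velocity_gives_zero_wss(self, poiseuille_sol_p1p1):
        sol = poiseuille_sol_p1p1
        zero_sol = FlowSolution(
            v=np.zeros_like(sol.v), p=np.zeros_like(sol.p), mesh=sol.mesh,
            Vv=sol.Vv, Qp=sol.Qp, config=sol.config, props=sol.props,
            bcs=sol.bcs, problem="stokes",
        )
        for space in ("P1", "DG1", "DG0"):
            f = project_wss(zero_sol, 3, space)
            assert np.abs(f.values).max() < 1e-14

    def test_dg0_equals_facet_average_of_tangential_traction(self):
        mesh = single_triangle_mesh()
        A = np.array([[1.2, -0.3], [0.4, 0.8]])
        sol = _linear_solution(mesh, A, np.array([0.1, 0.2]),
                               np.array([0.5, 1.0, -2.0]), nu=1.7)
        f = project_wss(sol, 1, "DG0")
        n = np.array([0.0, -1.0])  # bottom edge outward normal
        tn = 1.7 * A @ n  # full-gradient traction (pressure excluded)
        tt = tn - (tn @ n) * n
        assert f.values[0] == pytest.approx(tt, rel=1e-13)

    def test_p1_projection_reproduces_constant_traction(self):
        mesh = single_triangle_mesh()
        A = np.array([[0.0, 2.0], [-1.0, 0.5]])
        sol = _linear_solution(mesh, A, np.zeros(2), np.array([1.0, 0, 0]))
        f = project_wss(sol, 1, "P1")
        n = np.array([0.0, -1.0])
        tn = A @ n
        tt = tn - (tn @ n) * n
        for node in (0, 1):  # wall nodes of the bottom edge
            assert f.values[node] == pytest.approx(tt, abs=1e-13)
        assert np.abs(f.values[2]).max() < 1e-14  # interior-zero restriction

    def test_interior_dofs_exactly_zero(self, stokes2d_sol_p2p1):
        f = project_wss(stokes2d_sol_p2p1, (4,), "P1")
        wall_dofs = f.W.facet_dofs(f.facet_ids)
        mask = np.ones(f.W.n_dofs, dtype=bool)
        mask[wall_dofs] = False
        assert np.abs(f.values[mask]).max() == 0.0


def _bflux_oracle_single_cell(A, b, c, nu):
    """Sympy assembly of the boundary-flux right-hand side and wall mass
    solve on the reference triangle: wall = bottom edge, the other two
    edges Neumann-subtracted, normal traction removed on the wall."""
    x, y = sym.symbols("x y", real=True)
    phi = [1 - x - y, x, y]
    vexp = sym.Matrix(A) * sym.Matrix([x, y]) + sym.Matrix(b)
    pexp = c[0] + c[1] * x + c[2] * y
    T = -pexp * sym.eye(2) + nu * vexp.jacobian([x, y])
    R = np.zeros((3, 2))
    for i in range(3):
        gphi = sym.Matrix([phi[i].diff(x), phi[i].diff(y)])
        for a in range(2):
            gp = sym.zeros(2, 2)
            gp[a, :] = gphi.T  # grad(phi_i e_a)
            term = sym.integrate(
                sym.integrate(sum(T[k, l] * gp[k, l] for k in range(2)
                                  for l in range(2)), (y, 0, 1 - x)),
                (x, 0, 1),
            )
            R[i, a] += float(term)
    # subtract evaluated tractions on the hypotenuse and the left edge
    t = sym.symbols("t", nonnegative=True)
    edges = [
        # (param point, n, jacobian |ds/dt|)
        ((1 - t, t), sym.Matrix([1, 1]) / sym.sqrt(2), sym.sqrt(2)),  # hyp
        ((0, 1 - t), sym.Matrix([-1, 0]), 1),  # left edge
    ]
    for (px, py), n, jac in edges:
        Te = T.subs({x: px, y: py})
        tn = Te * n
        for i in range(3):
            phie = phi[i].subs({x: px, y: py})
            for a in range(2):
                R[i, a] -= float(sym.integrate(tn[a] * phie * jac, (t, 0, 1)))
    # subtract the normal component on the wall (y = 0, n = (0, -1))
    nwall = sym.Matrix([0, -1])
    Tw = T.subs({y: 0})
    tn = Tw * nwall
    tnn = tn.dot(nwall)
    for i in range(3):
        phie = phi[i].subs({y: 0})
        for a in range(2):
            R[i, a] -= float(sym.integrate(tnn * nwall[a] * phie, (x, 0, 1)))
    # wall mass solve on nodes 0, 1
    M = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
    tau = np.linalg.solve(M, R[:2])
    return tau


class TestBoundaryFluxOracle:
    def test_single_cell_matches_symbolic_assembly(self):
        mesh = single_triangle_mesh()
        A = np.array([[0.7, -1.1], [0.3, 0.9]])
        b = np.array([0.2, -0.1])
        c = np.array([0.4, 2.0, -1.5])
        nu = 1.3
        sol = _linear_solution(mesh, A, b, c, nu=nu)
        f = boundary_flux_wss(sol, 1, "P1")
        oracle = _bflux_oracle_single_cell(A, b, c, nu)
        assert f.values[:2] == pytest.approx(oracle, rel=1e-12, abs=1e-13)
        assert np.abs(f.values[2]).max() < 1e-14

    def test_space_exceeding_velocity_degree_rejected(self, stokes2d_sol_p1p1):
        with pytest.raises(ValueError, match="exceeds the velocity degree"):
            boundary_flux_wss(stokes2d_sol_p1p1, (4,), "P2")


class TestEquivalenceAndInvariants:
    def test_bflux_p1_equals_p1_projection_for_stabilized_p1p1(
            self, poiseuille_sol_p1p1):
        """For the Nitsche-enforced stabilized P1/P1 pair the boundary-flux
        recovery is algebraically identical to the P1 projection."""
        sol = poiseuille_sol_p1p1
        fb = boundary_flux_wss(sol, 3, "P1")
        fp = project_wss(sol, 3, "P1")
        rel = (np.linalg.norm(fb.values - fp.values)
               / np.linalg.norm(fp.values))
        assert rel < 1e-6

    def test_tangentiality_projection(self, stokes2d_sol_p2p1):
        for tag in (1, 2, 3, 4):
            f = project_wss(stokes2d_sol_p2p1, (tag,), "P1")
            assert tangentiality_ratio(f) < 1e-8

    def test_tangentiality_boundary_flux(self, poiseuille_sol_p1p1):
        f = boundary_flux_wss(poiseuille_sol_p1p1, 3, "P1")
        # identical to the projection for P1/P1, hence tangential up to the
        # per-facet normal variation of the polyhedral wall
        assert tangentiality_ratio(f) < 5e-3

    def test_tangentiality_boundary_flux_flat_sides(self, stokes2d_sol_p1p1):
        f = boundary_flux_wss_per_segment(stokes2d_sol_p1p1, (1, 2, 3, 4))
        assert tangentiality_ratio(f) < 1e-6

    def test_single_segment_degenerates_to_plain_bflux(
            self, poiseuille_sol_p1p1):
        sol = poiseuille_sol_p1p1
        fs = boundary_flux_wss_per_segment(sol, (3,))
        fb = boundary_flux_wss(sol, 3)
        assert fs.values == pytest.approx(fb.values, abs=1e-14)

    def test_zero_solution_zero_on_every_side(self, stokes2d_sol_p1p1):
        sol = stokes2d_sol_p1p1
        zero_sol = FlowSolution(
            v=np.zeros_like(sol.v), p=np.zeros_like(sol.p), mesh=sol.mesh,
            Vv=sol.Vv, Qp=sol.Qp, config=sol.config, props=sol.props,
            bcs=BCSpec(regions={
                t: BC("dirichlet", lambda x: np.zeros_like(np.atleast_2d(x)))
                for t in (1, 2, 3, 4)}),
            problem="stokes",
        )
        f = boundary_flux_wss_per_segment(zero_sol, (1, 2, 3, 4))
        assert np.abs(f.values).max() < 1e-12

    def test_overlapping_segments_rejected(self, stokes2d_sol_p1p1):
        with pytest.raises(ValueError, match="overlapping"):
            boundary_flux_wss_per_segment(stokes2d_sol_p1p1, (1, 1, 2))

    def test_global_equilibrium_of_recovered_traction(self, stokes2d_sol_p2p1):
        """Dirichlet-only Stokes with f = 0: the full traction recovered
        over the whole boundary at once integrates to zero net force (the
        partition-of-unity identity of the consistent flux)."""
        sol = stokes2d_sol_p2p1
        f = boundary_flux_wss(sol, (1, 2, 3, 4), "P2", subtract_normal=False)
        net = np.zeros(2)
        scale = 0.0
        for tag in (1, 2, 3, 4):
            fids = sol.mesh.facets_with_tag(tag)
            fq = asm.FacetQuad(sol.mesh, fids, 5)
            vals = f.eval_on(fq)
            net += np.einsum("fq,fqd->d", fq.wq, vals)
            scale += float((fq.wq * np.linalg.norm(vals, axis=2)).sum())
        assert np.linalg.norm(net) < 1e-9 * scale

    def test_empty_wall_rejected(self, stokes2d_sol_p1p1):
        with pytest.raises(KeyError):
            boundary_flux_wss(stokes2d_sol_p1p1, 99)
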