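"""FEM kernel tests: quadrature, elements, and independently assembled
oracles for the Nitsche boundary terms and interior-facet stabilizations."""

import math

import numpy as np
import pytest
import sympy as sym

from wssbench.fem.quadrature import simplex_quadrature
from wssbench.fem.elements import LagrangeElement
from wssbench.fem.spaces import FunctionSpace
from wssbench.fem import assemble as asm
from wssbench.solver import StabilizationWeights

from conftest import single_triangle_mesh, two_tet_mesh


def monomial_integral(exponents):
    """Exact integral of prod(x_i^a_i) over the unit simplex."""
    a = list(exponents)
    num = np.prod([math.factorial(k) for k in a])
    return num / math.factorial(sum(a) + len(a))


class TestQuadrature:
    @pytest.mark.parametrize("dim", [1, 2, 3])
    @pytest.mark.parametrize("degree", [1, 2, 3, 4, 5, 6, 8])
    def test_monomial_exactness(self, dim, degree):
        pts, w = simplex_quadrature(dim, degree)
        rng = np.random.default_rng(0)
        for _ in range(5):
            expo = rng.integers(0, degree + 1, size=dim)
            while expo.sum() > degree:
                expo = rng.integers(0, degree + 1, size=dim)
            vals = np.prod(pts**expo, axis=1)
            assert w @ vals == pytest.approx(monomial_integral(expo), rel=1e-12)

    def test_weights_positive_and_sum_to_measure(self):
        for dim, meas in [(1, 1.0), (2, 0.5), (3, 1 / 6)]:
            _, w = simplex_quadrature(dim, 5)
            assert np.all(w > 0)
            assert w.sum() == pytest.approx(meas, rel=1e-13)


class TestElements:
    @pytest.mark.parametrize("dim", [2, 3])
    @pytest.mark.parametrize("degree", [1, 2])
    def test_nodal_basis_property(self, dim, degree):
        el = LagrangeElement(dim, degree)
        tab = el.tabulate(el.nodes)
        assert tab == pytest.approx(np.eye(el.n_nodes), abs=1e-13)

    @pytest.mark.parametrize("dim", [2, 3])
    @pytest.mark.parametrize("degree", [1, 2])
    def test_partition_of_unity(self, dim, degree):
        el = LagrangeElement(dim, degree)
        pts = np.random.default_rng(1).uniform(0, 0.3, size=(7, dim))
        assert el.tabulate(pts).sum(axis=1) == pytest.approx(np.ones(7))
        assert el.tabulate_grad(pts).sum(axis=1) == pytest.approx(
            np.zeros((7, dim)), abs=1e-12
        )

    def test_p2_reproduces_quadratics(self):
        mesh = single_triangle_mesh()
        V = FunctionSpace(mesh, 2)
        f = lambda x: 1 + 2 * x[:, 0] + x[:, 1] + 3 * x[:, 0] * x[:, 1] - x[:, 1] ** 2
        coeffs = V.interpolate(f)
        cq = asm.CellQuad(mesh, 4)
        for ch in cq.chunks():
            vals = ch.eval_scalar(V, coeffs)
            exact = f(ch.xq.reshape(-1, 2)).reshape(vals.shape)
            assert vals == pytest.approx(exact, abs=1e-13)


class TestFacetGeometry:
    def test_normals_outward_unit(self):
        mesh = single_triangle_mesh()
        areas, normals, cents = mesh.boundary_geometry
        assert np.linalg.norm(normals, axis=1) == pytest.approx(np.ones(3))
        centroid = mesh.vertices.mean(axis=0)
        assert np.all(np.einsum("fd,fd->f", normals, cents - centroid) > 0)
        assert sorted(areas) == pytest.approx([1.0, 1.0, np.sqrt(2)])


def _nitsche_oracle_bottom_edge(nu, beta, vbc_coeffs):
    """Sympy line-integral assembly of the non-symmetric Nitsche terms on
    the bottom edge of the reference triangle (full-gradient stress).

    vbc_coeffs: (a0, a1) with vbc = (a0[0] + a1[0] x, a0[1] + a1[1] x).
    Returns dense (A_vv, A_vp, A_pv, rhs_v, rhs_p)."""
    x = sym.symbols("x", nonnegative=True)
    phi = [1 - x, x, sym.Integer(0)]  # P1 traces on y=0
    grads = [(-1, -1), (1, 0), (0, 1)]
    n = (0, -1)
    h = math.sqrt(2)  # circumdiameter of the right unit triangle
    A_vv = np.zeros((6, 6))
    A_vp = np.zeros((6, 3))
    A_pv = np.zeros((3, 6))
    rhs_v = np.zeros(6)
    rhs_p = np.zeros(3)
    a0, a1 = vbc_coeffs
    vbc = [a0[0] + a1[0] * x, a0[1] + a1[1] * x]
    for i in range(3):
        for j in range(3):
            dgn_j = grads[j][0] * n[0] + grads[j][1] * n[1]
            dgn_i = grads[i][0] * n[0] + grads[i][1] * n[1]
            cons = float(sym.integrate(dgn_j * phi[i], (x, 0, 1)))
            adj = float(sym.integrate(dgn_i * phi[j], (x, 0, 1)))
            mass = float(sym.integrate(phi[i] * phi[j], (x, 0, 1)))
            for a in range(2):
                A_vv[2 * i + a, 2 * j + a] += (
                    -nu * cons + nu * adj + beta * nu / h * mass
                )
        for k in range(3):
            m = float(sym.integrate(phi[k] * phi[i], (x, 0, 1)))
            for a in range(2):
                A_vp[2 * i + a, k] += m * n[a]
                A_pv[k, 2 * i + a] += -m * n[a]
        dgn_i = grads[i][0] * n[0] + grads[i][1] * n[1]
        for a in range(2):
            rhs_v[2 * i + a] += nu * float(
                sym.integrate(dgn_i * vbc[a], (x, 0, 1))
            ) + beta * nu / h * float(sym.integrate(phi[i] * vbc[a], (x, 0, 1)))
    for k in range(3):
        nvb = vbc[0] * n[0] + vbc[1] * n[1]
        rhs_p[k] += -float(sym.integrate(phi[k] * nvb, (x, 0, 1)))
    return A_vv, A_vp, A_pv, rhs_v, rhs_p


class TestNitscheOracle:
    def test_single_edge_matches_symbolic_assembly(self):
        mesh = single_triangle_mesh()
        Vv = FunctionSpace(mesh, 1)
        Qp = FunctionSpace(mesh, 1)
        nu, beta = 1.3, 2.7
        a0, a1 = np.array([0.2, -0.4]), np.array([1.1, 0.7])
        vbc = lambda p: a0 + a1 * p[:, :1]
        fid = mesh.facets_with_tag(1)
        A_vv, A_vp, A_pv, rv, rp = asm.nitsche_system(
            Vv, Qp, fid, nu, beta, sym=False, vbc=vbc
        )
        oA, oVp, oPv, orv, orp = _nitsche_oracle_bottom_edge(nu, beta, (a0, a1))
        assert A_vv.toarray() == pytest.approx(oA, abs=1e-12)
        assert A_vp.toarray() == pytest.approx(oVp, abs=1e-12)
        assert A_pv.toarray() == pytest.approx(oPv, abs=1e-12)
        assert rv == pytest.approx(orv, abs=1e-12)
        assert rp == pytest.approx(orp, abs=1e-12)

    def test_zero_beta_drops_penalty_only(self):
        mesh = single_triangle_mesh()
        Vv, Qp = FunctionSpace(mesh, 1), FunctionSpace(mesh, 1)
        fid = mesh.facets_with_tag(1)
        nu = 0.8
        A1, *_ = asm.nitsche_system(Vv, Qp, fid, nu, 0.0, sym=False)
        A2, *_ = asm.nitsche_system(Vv, Qp, fid, nu, 5.0, sym=False)
        M = asm.boundary_mass(Vv, fid, 3)
        h = mesh.cell_diameter[0]
        diff = (A2 - A1) - (5.0 * nu / h) * M
        assert abs(diff).max() < 1e-13

    def test_consistency_terms_vanish_when_v_equals_vbc(self):
        """With v interpolating the (linear) Dirichlet data and p = 0, the
        Nitsche residual reduces to the flux term -int (nu grad v) n . w."""
        mesh = single_triangle_mesh()
        Vv, Qp = FunctionSpace(mesh, 1), FunctionSpace(mesh, 1)
        fid = mesh.facets_with_tag(1)
        nu, beta = 1.0, 7.0
        a0, a1 = np.array([0.5, 0.2]), np.array([-0.3, 0.9])
        vbc = lambda p: a0 + a1 * p[:, :1]
        A_vv, A_vp, A_pv, rv, rp = asm.nitsche_system(
            Vv, Qp, fid, nu, beta, sym=False, vbc=vbc
        )
        vcoef = (a0[None, :] + a1[None, :] * Vv.dof_coords[:, :1]).ravel()
        resid = A_vv @ vcoef - rv
        # oracle for -int (nu grad v) n . w over the edge
        fq = asm.FacetQuad(mesh, fid, 3)
        gv = fq.eval_vector_grad(Vv, vcoef.reshape(-1, 2))
        tn = nu * np.einsum("fqkl,fl->fqk", gv, fq.normals)
        expect = -asm.facet_functional(Vv, fq, tn)
        assert resid == pytest.approx(expect, abs=1e-13)
        # and the pressure-row data terms cancel as well
        assert A_pv @ vcoef == pytest.approx(rp, abs=1e-13)


def _linear_fit_gradient(pts, vals):
    A = np.column_stack([np.ones(len(pts)), pts])
    coef = np.linalg.solve(A, vals)
    return coef[1:]


class TestCIPOracle:
    def _two_triangle_mesh(self):
        from wssbench.meshing import TaggedMesh
        verts = np.array([[0.0, 0], [1.0, 0], [0.0, 1], [1.0, 1]])
        cells = np.array([[0, 1, 2], [1, 3, 2]])
        return TaggedMesh(verts, cells, lambda c: 1, {1: "b"})

    @pytest.mark.parametrize("nu,s_expected", [(1.5, 2), (1e-6, 1)])
    def test_pressure_jump_matches_hand_assembly(self, nu, s_expected):
        mesh = self._two_triangle_mesh()
        Qp = FunctionSpace(mesh, 1)
        Vv = FunctionSpace(mesh, 1)
        gamma_p = 0.01
        S_v, S_p = asm.cip_matrices(Vv, Qp, gamma_p, 0.0, nu)
        rng = np.random.default_rng(3)
        p = rng.normal(size=4)
        q = rng.normal(size=4)
        # oracle: linear fit per cell, jump of normal gradient on the
        # shared edge (1,2), weight (gamma/2) sum h_K^{s+1} * |F|
        g0 = _linear_fit_gradient(mesh.vertices[[0, 1, 2]], p[[0, 1, 2]])
        g1 = _linear_fit_gradient(mesh.vertices[[1, 3, 2]], p[[1, 3, 2]])
        gq0 = _linear_fit_gradient(mesh.vertices[[0, 1, 2]], q[[0, 1, 2]])
        gq1 = _linear_fit_gradient(mesh.vertices[[1, 3, 2]], q[[1, 3, 2]])
        n = np.array([1.0, 1.0]) / np.sqrt(2)  # normal of the shared edge
        h = mesh.cell_diameter
        w = 0.5 * gamma_p * (h[0] ** (s_expected + 1) + h[1] ** (s_expected + 1))
        expected = w * np.sqrt(2) * (n @ (g0 - g1)) * (n @ (gq0 - gq1))
        assert q @ (S_p @ p) == pytest.approx(expected, rel=1e-12)

    def test_globally_linear_pressure_gives_zero(self):
        mesh = self._two_triangle_mesh()
        Qp = FunctionSpace(mesh, 1)
        Vv = FunctionSpace(mesh, 1)
        _, S_p = asm.cip_matrices(Vv, Qp, 1.0, 1.0, 1.0)
        p = 2.0 + 3.0 * mesh.vertices[:, 0] - mesh.vertices[:, 1]
        assert np.abs(S_p @ p).max() < 1e-12

    def test_divergence_jump_term(self):
        mesh = self._two_triangle_mesh()
        Qp = FunctionSpace(mesh, 1)
        Vv = FunctionSpace(mesh, 1)
        gamma_v = 1e-3
        nu = 1.5  # >= h = sqrt(2), so the jump exponent rule picks s = 2
        S_v, _ = asm.cip_matrices(Vv, Qp, 0.0, gamma_v, nu)
        rng = np.random.default_rng(4)
        v = rng.normal(size=(4, 2))
        div0 = sum(_linear_fit_gradient(mesh.vertices[[0, 1, 2]], v[[0, 1, 2], a])[a]
                   for a in range(2))
        div1 = sum(_linear_fit_gradient(mesh.vertices[[1, 3, 2]], v[[1, 3, 2], a])[a]
                   for a in range(2))
        h = mesh.cell_diameter
        w = 0.5 * gamma_v * (h[0] ** 3 + h[1] ** 3)
        expected = w * np.sqrt(2) * (div0 - div1) ** 2
        assert v.ravel() @ (S_v @ v.ravel()) == pytest.approx(expected, rel=1e-12)


class TestInteriorPenalty:
    def test_linear_fields_give_zero(self):
        mesh = two_tet_mesh()
        Vv, Qp = FunctionSpace(mesh, 1), FunctionSpace(mesh, 1)
        v = mesh.vertices @ np.array([[1.0, 0.2, 0], [0, -1.0, 0.5], [0.3, 0, 0.7]])
        p = 1.0 + mesh.vertices @ np.array([2.0, -1.0, 0.5])
        S_v, S_p = asm.interior_penalty_matrices(Vv, Qp, v, 1e-3, 1e-3, 1.0)
        assert np.abs(S_v @ v.ravel()).max() < 1e-12
        assert np.abs(S_p @ p).max() < 1e-14

    def test_default_weights(self):
        st = StabilizationWeights()
        assert (st.alpha_v, st.alpha_p, st.alpha_i) == (1e-3, 1.0, 1e-3)

    def test_h2_scaling_quadruples_S(self):
        """Doubling the mesh size at fixed nodal values: gradients halve
        (jump product / 4), facet area x4, h^2 x4 -> S x4 in 3D."""
        rng = np.random.default_rng(5)
        v = rng.normal(size=(5, 3))
        p = rng.normal(size=5)
        vals = []
        for scale in (1.0, 2.0):
            mesh = two_tet_mesh(scale)
            Vv, Qp = FunctionSpace(mesh, 1), FunctionSpace(mesh, 1)
            S_v, S_p = asm.interior_penalty_matrices(Vv, Qp, v, 0.0, 1e-3, 1.0)
            vals.append(v.ravel() @ (S_v @ v.ravel()))
        assert vals[1] / vals[0] == pytest.approx(4.0, rel=1e-12)
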