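"""Vectorized assembly of the forms used by the flow solvers and the WSS
evaluators.

Conventions
-----------
* scalar dofs come from :class:`FunctionSpace`; vector dofs are blocked as
  ``vdof = node * gdim + comp``;
* all routines return ``scipy.sparse.csr_matrix`` or dense numpy vectors;
* cell loops are chunked so peak memory stays modest on the finest meshes.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .quadrature import simplex_quadrature

__all__ = [
    "CellQuad",
    "FacetQuad",
    "vector_cell_dofs",
    "assemble_viscous",
    "assemble_divergence",
    "assemble_vector_mass_volume",
    "assemble_load",
    "pressure_mean_vector",
    "assemble_convection",
    "cip_matrices",
    "interior_penalty_matrices",
    "nitsche_system",
    "boundary_mass",
    "stress_gradtest_functional",
]

_CHUNK = 40000


def vector_cell_dofs(space, gdim: int) -> np.ndarray:
    """Blocked vector dofs per cell, shape (nc, nloc*gdim); local ordering is
    node-major: (node0_x, node0_y[, node0_z], node1_x, ...)."""
    cd = space.cell_dofs
    return (cd[:, :, None] * gdim + np.arange(gdim)).reshape(len(cd), -1)


def _csr(rows, cols, vals, shape):
    m = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=shape,
    )
    return m.tocsr()


class CellQuad:
    """Chunked cell quadrature over a mesh."""

    def __init__(self, mesh, degree: int):
        self.mesh = mesh
        self.qp, self.qw = simplex_quadrature(mesh.dim, degree)

    def chunks(self):
        mesh = self.mesh
        J, invJ, detJ = mesh.jacobians
        v0 = mesh.vertices[mesh.cells[:, 0]]
        nq = len(self.qw)
        for s in range(0, mesh.n_cells, _CHUNK):
            e = min(s + _CHUNK, mesh.n_cells)
            sl = slice(s, e)
            wdet = self.qw[None, :] * detJ[sl, None]  # (m, nq)
            xq = v0[sl, None, :] + np.einsum(
                "cde,qe->cqd", J[sl], self.qp
            )  # (m, nq, d)
            yield _CellChunk(self, sl, wdet, xq, invJ[sl])


class _CellChunk:
    def __init__(self, cq, sl, wdet, xq, invJ):
        self.cq = cq
        self.sl = sl
        self.wdet = wdet
        self.xq = xq
        self._invJ = invJ

    def basis(self, space):
        return space.element.tabulate(self.cq.qp)  # (nq, nloc)

    def grad(self, space):
        gref = space.element.tabulate_grad(self.cq.qp)  # (nq, nloc, dref)
        return np.einsum("qne,ced->cqnd", gref, self._invJ)

    def dofs(self, space):
        return space.cell_dofs[self.sl]

    def eval_scalar(self, space, coeffs):
        """(m, nq) values of a scalar FE function."""
        return np.einsum("qn,cn->cq", self.basis(space), coeffs[self.dofs(space)])

    def eval_vector(self, space, coeffs):
        """(m, nq, gdim); coeffs shaped (n_dofs, gdim)."""
        return np.einsum("qn,cnd->cqd", self.basis(space), coeffs[self.dofs(space)])

    def eval_vector_grad(self, space, coeffs):
        """(m, nq, gdim, d): entry [.., k, l] = d v_k / d x_l."""
        return np.einsum("cqnl,cnk->cqkl", self.grad(space), coeffs[self.dofs(space)])


# ----------------------------------------------------------------------
# volume forms
# ----------------------------------------------------------------------

def assemble_viscous(Vv, nu: float, sym: bool, degree: int) -> sp.csr_matrix:
    """Viscous block on vector dofs: ``nu * grad(v):grad(w)`` for the full
    gradient stress, or ``2 nu D(v):D(w)`` for the symmetric form."""
    gdim = Vv.mesh.dim
    n = Vv.n_dofs * gdim
    cq = CellQuad(Vv.mesh, degree)
    rows, cols, vals = [], [], []
    for ch in cq.chunks():
        g = ch.grad(Vv)  # (m, nq, nloc, d)
        K = np.einsum("cq,cqid,cqjd->cij", ch.wdet, g, g)  # grad.grad
        vdofs = vector_cell_dofs(Vv, gdim)[ch.sl]  # (m, nloc*gdim)
        m, nloc = K.shape[0], K.shape[1]
        # block-diagonal delta_ab * K
        loc = np.zeros((m, nloc * gdim, nloc * gdim))
        for a in range(gdim):
            loc[:, a::gdim, a::gdim] += nu * K
        if sym:
            # + nu * int d_a(phi_j) d_b(phi_i):  block (i,a),(j,b)
            for a in range(gdim):
                for b in range(gdim):
                    loc[:, a::gdim, b::gdim] += nu * np.einsum(
                        "cq,cqj,cqi->cij", ch.wdet, g[:, :, :, a], g[:, :, :, b]
                    )
        rows.append(np.repeat(vdofs, vdofs.shape[1], axis=1).ravel())
        cols.append(np.tile(vdofs, (1, vdofs.shape[1])).ravel())
        vals.append(loc.ravel())
    return _csr(rows, cols, vals, (n, n))


def assemble_divergence(Vv, Qp, degree: int) -> sp.csr_matrix:
    """B[k, (j,b)] = int psi_k d_b(phi_j) dx  (pressure test x velocity)."""
    gdim = Vv.mesh.dim
    cq = CellQuad(Vv.mesh, degree)
    rows, cols, vals = [], [], []
    for ch in cq.chunks():
        g = ch.grad(Vv)
        psi = ch.basis(Qp)
        loc = np.einsum("cq,qk,cqjb->ckjb", ch.wdet, psi, g)  # (m, npl, nvl, d)
        m, npl, nvl, d = loc.shape
        loc = loc.reshape(m, npl, nvl * d)
        pd = ch.dofs(Qp)
        vd = vector_cell_dofs(Vv, gdim)[ch.sl]
        rows.append(np.repeat(pd, nvl * d, axis=1).ravel())
        cols.append(np.tile(vd, (1, npl)).reshape(m, npl, nvl * d).ravel())
        vals.append(loc.ravel())
    return _csr(rows, cols, vals, (Qp.n_dofs, Vv.n_dofs * gdim))


def assemble_vector_mass_volume(Vv, degree: int, coeff: float = 1.0) -> sp.csr_matrix:
    gdim = Vv.mesh.dim
    n = Vv.n_dofs * gdim
    cq = CellQuad(Vv.mesh, degree)
    rows, cols, vals = [], [], []
    for ch in cq.chunks():
        phi = ch.basis(Vv)
        M = coeff * np.einsum("cq,qi,qj->cij", ch.wdet, phi, phi)
        vd = vector_cell_dofs(Vv, gdim)[ch.sl]
        m, nloc = M.shape[0], M.shape[1]
        loc = np.zeros((m, nloc * gdim, nloc * gdim))
        for a in range(gdim):
            loc[:, a::gdim, a::gdim] = M
        rows.append(np.repeat(vd, vd.shape[1], axis=1).ravel())
        cols.append(np.tile(vd, (1, vd.shape[1])).ravel())
        vals.append(loc.ravel())
    return _csr(rows, cols, vals, (n, n))


def assemble_load(Vv, f, degree: int) -> np.ndarray:
    """int f . w dx on vector dofs; ``f(points) -> (m, gdim)``."""
    gdim = Vv.mesh.dim
    out = np.zeros(Vv.n_dofs * gdim)
    cq = CellQuad(Vv.mesh, degree)
    for ch in cq.chunks():
        fx = np.asarray(f(ch.xq.reshape(-1, gdim))).reshape(*ch.xq.shape)
        phi = ch.basis(Vv)
        loc = np.einsum("cq,qi,cqa->cia", ch.wdet, phi, fx)
        vd = vector_cell_dofs(Vv, gdim)[ch.sl]
        np.add.at(out, vd.ravel(), loc.reshape(len(vd), -1).ravel())
    return out


def pressure_mean_vector(Qp, degree: int = 2) -> np.ndarray:
    """Vector c with c_k = int psi_k dx (for the mean-zero pressure gauge)."""
    out = np.zeros(Qp.n_dofs)
    cq = CellQuad(Qp.mesh, degree)
    for ch in cq.chunks():
        psi = ch.basis(Qp)
        loc = np.einsum("cq,qk->ck", ch.wdet, psi)
        np.add.at(out, ch.dofs(Qp).ravel(), loc.ravel())
    return out


def assemble_convection(Vv, vcoef: np.ndarray, rho: float, degree: int):
    """Convective residual  rho * int (grad v) v . w  and its Newton Jacobian
    rho * int ((grad u) v + (grad v) u) . w  at state ``vcoef`` (n_dofs, gdim).

    Returns (residual_vector, jacobian_csr) on vector dofs.
    """
    gdim = Vv.mesh.dim
    n = Vv.n_dofs * gdim
    res = np.zeros(n)
    cq = CellQuad(Vv.mesh, degree)
    rows, cols, vals = [], [], []
    for ch in cq.chunks():
        phi = ch.basis(Vv)  # (nq, nloc)
        g = ch.grad(Vv)  # (m, nq, nloc, d)
        vq = ch.eval_vector(Vv, vcoef)  # (m, nq, d)
        gv = ch.eval_vector_grad(Vv, vcoef)  # (m, nq, k, l)
        conv = np.einsum("cqkl,cql->cqk", gv, vq)  # (grad v) v
        loc_r = rho * np.einsum("cq,qi,cqa->cia", ch.wdet, phi, conv)
        vd = vector_cell_dofs(Vv, gdim)[ch.sl]
        np.add.at(res, vd.ravel(), loc_r.reshape(len(vd), -1).ravel())
        # Jacobian: trial u = phi_j e_b
        # term1: (grad u) v . w = phi_i delta_ab? no:
        #   (grad u) v = e_b (grad phi_j . v)  -> component a: delta_ab (gphi_j.v)
        t1 = np.einsum("cqjl,cql->cqj", g, vq)  # (m, nq, nloc)
        A1 = rho * np.einsum("cq,qi,cqj->cij", ch.wdet, phi, t1)
        # term2: (grad v) u . w -> component a: gv[a,b] phi_j
        A2 = rho * np.einsum("cq,qi,qj,cqab->ciajb", ch.wdet, phi, phi, gv)
        m, nloc = A1.shape[0], A1.shape[1]
        loc = np.zeros((m, nloc * gdim, nloc * gdim))
        for a in range(gdim):
            loc[:, a::gdim, a::gdim] += A1
            for b in range(gdim):
                loc[:, a::gdim, b::gdim] += A2[:, :, a, :, b]
        rows.append(np.repeat(vd, vd.shape[1], axis=1).ravel())
        cols.append(np.tile(vd, (1, vd.shape[1])).ravel())
        vals.append(loc.ravel())
    return res, _csr(rows, cols, vals, (n, n))


# ----------------------------------------------------------------------
# interior-facet stabilizations (P1 fields: gradients constant per cell)
# ----------------------------------------------------------------------

def _p1_cell_gradients(space):
    """Constant physical gradients of P1 basis per cell: (nc, nloc, d)."""
    if space.degree != 1:
        raise ValueError("interior-facet stabilizations require P1 fields")
    mesh = space.mesh
    _, invJ, _ = mesh.jacobians
    gref = space.element.tabulate_grad(np.zeros((1, mesh.dim)))[0]  # (nloc, d)
    return np.einsum("ne,ced->cnd", gref, invJ)


def _jump_rows(space, direction=None):
    """Sparse jump operator over interior facets for P1 gradients.

    direction=None -> rows of the normal-gradient jump  [[n . grad u]]
    direction=k    -> rows of the jump of d u / d x_k.
    Returns (nf x n_dofs) csr."""
    mesh = space.mesh
    grads = _p1_cell_gradients(space)  # (nc, nloc, d)
    _, normals, _ = mesh.interior_geometry
    c0 = mesh.interior_facet_cells[:, 0]
    c1 = mesh.interior_facet_cells[:, 1]
    nf = len(c0)
    if direction is None:
        e0 = np.einsum("fnd,fd->fn", grads[c0], normals)
        e1 = np.einsum("fnd,fd->fn", grads[c1], normals)
    else:
        e0 = grads[c0][:, :, direction]
        e1 = grads[c1][:, :, direction]
    nloc = e0.shape[1]
    rows = np.repeat(np.arange(nf), 2 * nloc)
    cols = np.column_stack([space.cell_dofs[c0], space.cell_dofs[c1]]).ravel()
    vals = np.column_stack([e0, -e1]).ravel()
    return sp.csr_matrix((vals, (rows, cols)), shape=(nf, space.n_dofs))


def _facet_pair_weights(mesh, exponent_fn):
    """Per-interior-facet weight  area * (w(h_K0) + w(h_K1))."""
    areas, _, _ = mesh.interior_geometry
    h = mesh.cell_diameter
    c0, c1 = mesh.interior_facet_cells[:, 0], mesh.interior_facet_cells[:, 1]
    return areas * (exponent_fn(h[c0]) + exponent_fn(h[c1]))


def cip_matrices(Vv, Qp, gamma_p: float, gamma_v: float, nu: float):
    """Continuous-interior-penalty stabilization for the equal-order P1/P1
    pair: pressure normal-gradient jumps and velocity divergence jumps.

    The exponent s is chosen per cell: s=2 where nu >= h_K, else s=1, and
    each interior facet receives (1/2) gamma h_K^{s+1} from both cells.

    Returns ``(S_v, S_p)`` on vector velocity dofs / scalar pressure dofs.
    """
    mesh = Vv.mesh
    gdim = mesh.dim

    def wfun(hk):
        s = np.where(nu >= hk, 2.0, 1.0)
        return 0.5 * hk ** (s + 1.0)

    w = _facet_pair_weights(mesh, wfun)

    # pressure jumps
    Jp = _jump_rows(Qp)
    S_p = (Jp.T @ sp.diags(gamma_p * w) @ Jp).tocsr()

    # velocity divergence jumps: row over vector dofs
    mesh_grads = _p1_cell_gradients(Vv)
    c0, c1 = mesh.interior_facet_cells[:, 0], mesh.interior_facet_cells[:, 1]
    nf = len(c0)
    nloc = mesh_grads.shape[1]
    # div contribution of phi_j e_b in cell c is grads[c, j, b]
    e0 = mesh_grads[c0].reshape(nf, nloc * gdim)  # (f, j*b) since last axis is b
    e1 = mesh_grads[c1].reshape(nf, nloc * gdim)
    vd0 = vector_cell_dofs(Vv, gdim)[c0]
    vd1 = vector_cell_dofs(Vv, gdim)[c1]
    rows = np.repeat(np.arange(nf), 2 * nloc * gdim)
    cols = np.column_stack([vd0, vd1]).ravel()
    vals = np.column_stack([e0, -e1]).ravel()
    Jv = sp.csr_matrix((vals, (rows, cols)), shape=(nf, Vv.n_dofs * gdim))
    S_v = (Jv.T @ sp.diags(gamma_v * w) @ Jv).tocsr()
    return S_v, S_p


def interior_penalty_matrices(Vv, Qp, vcoef, alpha_i, alpha_v, alpha_p):
    """Interior-penalty stabilization for P1/P1 Navier-Stokes: full-gradient
    jumps of velocity and pressure with weight h_K^2, plus a streamline term
    weighted by the facet integral of (v.n)^2.

    Returns (S_v, S_p); S_v depends on the current velocity ``vcoef``
    through the streamline term.
    """
    mesh = Vv.mesh
    gdim = mesh.dim
    areas, normals, _ = mesh.interior_geometry
    h = mesh.cell_diameter
    c0, c1 = mesh.interior_facet_cells[:, 0], mesh.interior_facet_cells[:, 1]
    wh2 = areas * (h[c0] ** 2 + h[c1] ** 2)

    # facet integral of (v.n)^2 (P1 velocity: quadratic on the facet)
    qp, qw = simplex_quadrature(mesh.dim - 1, 2)
    fverts = mesh.vertices[mesh.interior_facets]  # (nf, nvf, d)
    # facet shape functions on reference facet simplex
    lam = np.column_stack([1.0 - qp.sum(axis=1), qp])  # (nq, nvf)
    xq = np.einsum("qn,fnd->fqd", lam, fverts)
    # velocity on the facet from cell0 (continuous field)
    vfac = _eval_p1_on_points(Vv, vcoef, c0, xq)
    vn = np.einsum("fqd,fd->fq", vfac, normals)
    ref_measure = qw.sum()
    int_vn2 = (vn**2 @ qw) * (areas / ref_measure)

    Jg = [_jump_rows(Qp, direction=k) for k in range(gdim)]
    Wp = sp.diags(alpha_p * wh2)
    Sp = sum((J.T @ Wp @ J) for J in Jg).tocsr()

    Wv = sp.diags(alpha_v * wh2 + alpha_i * (h[c0] ** 2 + h[c1] ** 2) * int_vn2)
    blocks = sum((J.T @ Wv @ J) for J in Jg).tocsr()
    Sv = sp.kron(blocks, sp.eye(gdim), format="csr")
    # kron ordering: block dof = node*gdim + comp  -> kron(scalar, I) matches
    return Sv, Sp


def _eval_p1_on_points(space, coeffs, cells, xq):
    """Evaluate a P1 vector field at physical points xq (nf, nq, d) lying in
    the given cells."""
    mesh = space.mesh
    _, invJ, _ = mesh.jacobians
    v0 = mesh.vertices[mesh.cells[cells, 0]]
    Xr = np.einsum("fed,fqd->fqe", invJ[cells], xq - v0[:, None, :])
    lam = np.concatenate([1.0 - Xr.sum(axis=2, keepdims=True), Xr], axis=2)
    return np.einsum("fqn,fnd->fqd", lam, coeffs[space.cell_dofs[cells]])


# ----------------------------------------------------------------------
# boundary facet machinery
# ----------------------------------------------------------------------

class FacetQuad:
    """Quadrature and adjacent-cell basis data on a set of boundary facets."""

    def __init__(self, mesh, facet_ids, degree: int):
        self.mesh = mesh
        self.ids = np.asarray(facet_ids, dtype=int)
        areas, normals, _ = mesh.boundary_geometry
        self.areas = areas[self.ids]
        self.normals = normals[self.ids]
        self.cells = mesh.boundary_facet_cells[self.ids]
        self.h = mesh.cell_diameter[self.cells]
        qp, qw = simplex_quadrature(mesh.dim - 1, degree)
        fverts = mesh.vertices[mesh.boundary_facets[self.ids]]
        lam = np.column_stack([1.0 - qp.sum(axis=1), qp])
        self.facet_shape = lam  # (nq, n_facet_vertices)
        self.xq = np.einsum("qn,fnd->fqd", lam, fverts)  # (nf, nq, d)
        ref_measure = qw.sum()
        self.wq = np.outer(self.areas / ref_measure, qw)  # (nf, nq)
        # reference coordinates inside the adjacent cell
        _, invJ, _ = mesh.jacobians
        v0 = mesh.vertices[mesh.cells[self.cells, 0]]
        self.Xref = np.einsum(
            "fed,fqd->fqe", invJ[self.cells], self.xq - v0[:, None, :]
        )
        self._invJ = invJ[self.cells]
        self._basis_cache = {}

    @property
    def n_facets(self):
        return len(self.ids)

    def basis(self, space):
        key = ("b", id(space))
        if key not in self._basis_cache:
            nf, nq, d = self.Xref.shape
            tab = space.element.tabulate(self.Xref.reshape(-1, d))
            self._basis_cache[key] = tab.reshape(nf, nq, -1)
        return self._basis_cache[key]

    def grad(self, space):
        key = ("g", id(space))
        if key not in self._basis_cache:
            nf, nq, d = self.Xref.shape
            gref = space.element.tabulate_grad(self.Xref.reshape(-1, d))
            gref = gref.reshape(nf, nq, -1, d)
            self._basis_cache[key] = np.einsum("fqne,fed->fqnd", gref, self._invJ)
        return self._basis_cache[key]

    def cell_dofs(self, space):
        return space.cell_dofs[self.cells]

    def vector_cell_dofs(self, space):
        return vector_cell_dofs(space, self.mesh.dim)[self.cells]

    def eval_vector(self, space, coeffs):
        return np.einsum("fqn,fnd->fqd", self.basis(space), coeffs[self.cell_dofs(space)])

    def eval_scalar(self, space, coeffs):
        return np.einsum("fqn,fn->fq", self.basis(space), coeffs[self.cell_dofs(space)])

    def eval_vector_grad(self, space, coeffs):
        return np.einsum(
            "fqnl,fnk->fqkl", self.grad(space), coeffs[self.cell_dofs(space)]
        )

    def traction(self, Vv, Qp, vcoef, pcoef, nu, sym, with_pressure=True):
        """Discrete traction T(v,p) n at quadrature points: (nf, nq, d)."""
        gv = self.eval_vector_grad(Vv, vcoef)  # (f,q,k,l)
        if sym:
            tn = nu * np.einsum("fqkl,fl->fqk", gv + gv.transpose(0, 1, 3, 2), self.normals)
        else:
            tn = nu * np.einsum("fqkl,fl->fqk", gv, self.normals)
        if with_pressure and pcoef is not None:
            p = self.eval_scalar(Qp, pcoef)
            tn = tn - p[:, :, None] * self.normals[:, None, :]
        return tn


def boundary_mass(W, facet_ids, degree: int) -> sp.csr_matrix:
    """Boundary mass matrix on vector dofs of space W over the given facets."""
    mesh = W.mesh
    gdim = mesh.dim
    fq = FacetQuad(mesh, facet_ids, degree)
    phi = fq.basis(W)
    M = np.einsum("fq,fqi,fqj->fij", fq.wq, phi, phi)
    vd = fq.vector_cell_dofs(W)
    nf, nloc = M.shape[0], M.shape[1]
    loc = np.zeros((nf, nloc * gdim, nloc * gdim))
    for a in range(gdim):
        loc[:, a::gdim, a::gdim] = M
    rows = np.repeat(vd, vd.shape[1], axis=1).ravel()
    cols = np.tile(vd, (1, vd.shape[1])).ravel()
    n = W.n_dofs * gdim
    return sp.csr_matrix((loc.ravel(), (rows, cols)), shape=(n, n))


def facet_functional(W, fq: FacetQuad, values: np.ndarray) -> np.ndarray:
    """Assemble int_F values . phi dS over the facets of ``fq``;
    ``values`` has shape (nf, nq, gdim).  Returns vector on W's vector dofs."""
    gdim = W.mesh.dim
    phi = fq.basis(W)
    loc = np.einsum("fq,fqi,fqa->fia", fq.wq, phi, values)
    vd = fq.vector_cell_dofs(W)
    out = np.zeros(W.n_dofs * gdim)
    np.add.at(out, vd.ravel(), loc.reshape(len(vd), -1).ravel())
    return out


# ----------------------------------------------------------------------
# Nitsche boundary terms (non-symmetric variant, optional penalty)
# ----------------------------------------------------------------------

def nitsche_system(Vv, Qp, facet_ids, nu, beta, sym, vbc=None, tangential=False,
                   degree=None):
    """Matrix and RHS contributions of the non-symmetric Nitsche enforcement
    of a Dirichlet condition on the given facets.

    With ``tangential=True`` only the tangential velocity components are
    constrained (used for outflow planes where the normal part is natural);
    pressure terms drop out in that case since P n = 0.

    Returns (A_vv, A_vp, A_pv, rhs_v, rhs_p); matrices are csr, rhs dense.
    ``vbc(points) -> (m, gdim)`` or None (homogeneous).
    """
    mesh = Vv.mesh
    gdim = mesh.dim
    if degree is None:
        degree = 2 * Vv.degree + 1
    fq = FacetQuad(mesh, facet_ids, degree)
    phi = fq.basis(Vv)  # (f,q,i)
    g = fq.grad(Vv)  # (f,q,i,d)
    n = fq.normals  # (f,d)
    w = fq.wq  # (f,q)
    dgn = np.einsum("fqid,fd->fqi", g, n)  # grad(phi_i).n
    nv = Vv.n_dofs * gdim
    npd = Qp.n_dofs
    nloc = phi.shape[2]
    vd = fq.vector_cell_dofs(Vv)
    pd = fq.cell_dofs(Qp)
    nplq = pd.shape[1]
    psi = fq.basis(Qp)

    P = np.eye(gdim)[None] - n[:, :, None] * n[:, None, :] if tangential else None

    loc_vv = np.zeros((fq.n_facets, nloc * gdim, nloc * gdim))
    # scalar kernels
    K_cons = np.einsum("fq,fqj,fqi->fij", w, dgn, phi)  # (grad phi_j.n) phi_i
    K_mass = np.einsum("fq,fqi,fqj->fij", w, phi, phi)
    pen = (beta * nu / fq.h)[:, None, None]
    if not tangential:
        for a in range(gdim):
            # -nu cons + nu adjoint + penalty  (delta_ab part)
            loc_vv[:, a::gdim, a::gdim] += (
                -nu * K_cons + nu * K_cons.transpose(0, 2, 1) + pen * K_mass
            )
        if sym:
            # cross terms: -nu n_b d_a(phi_j) phi_i  + nu n_a d_b(phi_i) phi_j
            Kab = np.einsum("fq,fqja,fqi->fija", w, g, phi)  # d_a phi_j * phi_i
            for a in range(gdim):
                for b in range(gdim):
                    loc_vv[:, a::gdim, b::gdim] += -nu * n[:, None, None, b] * Kab[
                        :, :, :, a
                    ] + nu * n[:, None, None, a] * Kab[:, :, :, b].transpose(0, 2, 1)
    else:
        for a in range(gdim):
            for b in range(gdim):
                Pab = P[:, a, b][:, None, None]
                loc_vv[:, a::gdim, b::gdim] += Pab * (
                    -nu * K_cons + nu * K_cons.transpose(0, 2, 1) + pen * K_mass
                )
        if sym:
            Kab = np.einsum("fq,fqja,fqi->fija", w, g, phi)
            Pg_j = np.einsum("fab,fqjb->fqja", P, g)  # (P grad phi_j)_a
            KPg = np.einsum("fq,fqja,fqi->fija", w, Pg_j, phi)
            for a in range(gdim):
                for b in range(gdim):
                    loc_vv[:, a::gdim, b::gdim] += (
                        -nu * n[:, None, None, b] * KPg[:, :, :, a]
                        + nu * n[:, None, None, a] * KPg[:, :, :, b].transpose(0, 2, 1)
                    )

    rows = np.repeat(vd, nloc * gdim, axis=1).ravel()
    cols = np.tile(vd, (1, nloc * gdim)).ravel()
    A_vv = sp.csr_matrix((loc_vv.ravel(), (rows, cols)), shape=(nv, nv))

    if not tangential:
        # pressure consistency: + int psi_k n_a phi_i   (A_vp)
        Kp = np.einsum("fq,fqk,fqi->fik", w, psi, phi)  # (f, i, k)
        loc_vp = np.einsum("fik,fa->fiak", Kp, n).reshape(
            fq.n_facets, nloc, gdim, nplq
        )
        loc_vp = loc_vp.reshape(fq.n_facets, nloc * gdim, nplq)
        r = np.repeat(vd, nplq, axis=1).ravel()
        c = np.tile(pd, (1, nloc * gdim)).ravel()
        A_vp = sp.csr_matrix((loc_vp.ravel(), (r, c)), shape=(nv, npd))
        # adjoint pressure: - int psi_k n_b phi_j  (A_pv)
        loc_pv = -np.einsum("fjk,fb->fkjb", Kp.transpose(0, 1, 2), n).reshape(
            fq.n_facets, nplq, nloc * gdim
        )
        r2 = np.repeat(pd, nloc * gdim, axis=1).ravel()
        c2 = np.tile(vd, (1, nplq)).ravel()
        A_pv = sp.csr_matrix((loc_pv.ravel(), (r2, c2)), shape=(npd, nv))
    else:
        A_vp = sp.csr_matrix((nv, npd))
        A_pv = sp.csr_matrix((npd, nv))

    rhs_v = np.zeros(nv)
    rhs_p = np.zeros(npd)
    if vbc is not None:
        if tangential:
            raise NotImplementedError(
                "tangential Nitsche is only provided for homogeneous data"
            )
        vb = np.asarray(vbc(fq.xq.reshape(-1, gdim))).reshape(fq.n_facets, -1, gdim)
        # + nu int (grad phi_i . n) vb_a   (+ sym cross) + penalty
        loc_rv = nu * np.einsum("fq,fqi,fqa->fia", w, dgn, vb)
        if sym:
            # (2 nu D(w) n) . vb with w = phi_i e_a:
            #   nu[(grad phi_i.n) vb_a + n_a (grad phi_i . vb)]
            loc_rv += nu * np.einsum("fq,fqid,fqd,fa->fia", w, g, vb, n)
        loc_rv += (beta * nu / fq.h)[:, None, None] * np.einsum(
            "fq,fqi,fqa->fia", w, phi, vb
        )
        np.add.at(rhs_v, vd.ravel(), loc_rv.reshape(fq.n_facets, -1).ravel())
        if not tangential:
            # - int psi_k (n . vb)
            nvb = np.einsum("fqa,fa->fq", vb, n)
            loc_rp = -np.einsum("fq,fqk,fq->fk", w, psi, nvb)
            np.add.at(rhs_p, pd.ravel(), loc_rp.ravel())
    return A_vv, A_vp, A_pv, rhs_v, rhs_p


# ----------------------------------------------------------------------
# volume stress-against-test-gradient functional (boundary-flux RHS core)
# ----------------------------------------------------------------------

def stress_gradtest_functional(W, Vv, Qp, vcoef, pcoef, nu, sym, degree) -> np.ndarray:
    """int_Omega T(v, p) : grad(phi) dx for all vector test functions phi of
    space W (which may differ from the velocity space Vv)."""
    mesh = W.mesh
    gdim = mesh.dim
    out = np.zeros(W.n_dofs * gdim)
    cq = CellQuad(mesh, degree)
    for ch in cq.chunks():
        gv = ch.eval_vector_grad(Vv, vcoef)  # (m,q,k,l)
        T = nu * (gv + gv.transpose(0, 1, 3, 2)) if sym else nu * gv
        if pcoef is not None:
            p = ch.eval_scalar(Qp, pcoef)
            idx = np.arange(gdim)
            T = T.copy()
            T[:, :, idx, idx] -= p[:, :, None]
        gw = ch.grad(W)  # (m,q,i,l)
        # phi = phi_i e_a: grad(phi)_{kl} = delta_ka d_l phi_i
        loc = np.einsum("cq,cqal,cqil->cia", ch.wdet, T, gw)
        vd = vector_cell_dofs(W, gdim)[ch.sl]
        np.add.at(out, vd.ravel(), loc.reshape(len(vd), -1).ravel())
    return out
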