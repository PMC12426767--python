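"""Wall shear stress evaluation from a discrete flow solution.

Two families of methods:

* **Projection** (:func:`project_wss`): L2-project the tangential discrete
  traction ``(T n)_t`` (pressure drops out of the tangential part
  identically) onto a continuous P1 space or onto facet-local DG-1 / DG-0
  spaces on the wall.

* **Boundary flux** (:func:`boundary_flux_wss`): variationally consistent
  recovery -- test the discrete momentum residual with wall-supported
  functions, subtract the known boundary terms on the other segments and
  the normal traction component, and solve a wall mass-matrix system for
  the tangential traction.  When the wall no-slip condition was enforced
  weakly (Nitsche), the consistency and penalty terms are retained on the
  right-hand side so that the recovered flux is algebraically consistent
  with the discrete equations.

All systems are assembled on the full space with non-wall rows replaced by
identity and zero data, so interior degrees of freedom are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import assemble as asm
from .fem.spaces import FunctionSpace
from .solver import FlowSolution

__all__ = [
    "WSSField",
    "tangential_part",
    "project_wss",
    "boundary_flux_wss",
    "boundary_flux_wss_per_segment",
    "tangentiality_ratio",
]


def tangential_part(a: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Tangential projection a - (a.n) n; broadcasts over leading axes."""
    an = np.sum(a * n, axis=-1, keepdims=True)
    return a - an * n


@dataclass
class WSSField:
    """Boundary vector field tau on a tagged wall region.

    kind "continuous": ``values`` are nodal (n_dofs, gdim) on space ``W``
    with zeros at every non-wall dof; "dg1": per-facet nodal values
    (nf, n_facet_vertices, gdim); "dg0": per-facet constants (nf, gdim).
    ``segments`` optionally holds per-segment nodal solutions from the
    segment-wise boundary-flux evaluation.
    """

    method: str  # "projection" | "boundary_flux"
    space: str  # "P1" | "P2" | "DG1" | "DG0"
    kind: str  # "continuous" | "dg1" | "dg0"
    mesh: object
    region_tags: tuple
    facet_ids: np.ndarray
    values: np.ndarray
    W: Optional[FunctionSpace] = None
    restriction: str = "whole_domain_interior_zero"
    segments: Optional[dict] = None  # tag -> nodal values (continuous kinds)

    def eval_on(self, fq: asm.FacetQuad, segment_tag=None) -> np.ndarray:
        """Values at the quadrature points of ``fq`` (facets must belong to
        this field's wall region); shape (nf, nq, gdim)."""
        if self.kind == "continuous":
            vals = self.values
            if segment_tag is not None and self.segments is not None:
                vals = self.segments[segment_tag]
            return np.einsum("fqn,fnd->fqd", fq.basis(self.W),
                             vals[self.W.cell_dofs[fq.cells]])
        pos = _positions_in(self.facet_ids, fq.ids)
        if self.kind == "dg0":
            return np.broadcast_to(
                self.values[pos][:, None, :],
                (len(pos), fq.wq.shape[1], self.values.shape[1]),
            ).copy()
        # dg1: facet-local linear
        return np.einsum("qn,fnd->fqd", fq.facet_shape, self.values[pos])

    def magnitudes_native(self) -> np.ndarray:
        """|tau| on the method's native evaluation set (wall nodes for
        continuous spaces, facet nodes for DG-1, facets for DG-0)."""
        if self.kind == "continuous":
            wall_dofs = self.W.facet_dofs(self.facet_ids)
            return np.linalg.norm(self.values[wall_dofs], axis=1)
        if self.kind == "dg0":
            return np.linalg.norm(self.values, axis=1)
        return np.linalg.norm(self.values, axis=2).ravel()


def _positions_in(universe: np.ndarray, query: np.ndarray) -> np.ndarray:
    order = np.argsort(universe)
    pos = np.searchsorted(universe, query, sorter=order)
    idx = order[pos]
    if np.any(universe[idx] != query):
        raise ValueError("facets outside the field's wall region")
    return idx


def _facet_shape(fq: asm.FacetQuad):
    # barycentric shape functions of the facet simplex at the facet
    # quadrature points (cached on the FacetQuad)
    return fq.facet_shape


def _projection_traction(sol: FlowSolution, fq: asm.FacetQuad) -> np.ndarray:
    """Tangential traction integrand of the projection method (pressure
    excluded: it cancels in the tangential projection)."""
    nu = sol.props.momentum_viscosity
    tn = fq.traction(sol.Vv, sol.Qp, sol.v, None, nu,
                     sol.config.symmetric_stress, with_pressure=False)
    n = fq.normals[:, None, :]
    return tangential_part(tn, n)


def project_wss(sol: FlowSolution, wall_tags, space: str = "P1",
                restriction: str = "whole_domain_interior_zero") -> WSSField:
    """L2 projection of the tangential traction onto P1, DG-1 or DG-0."""
    mesh = sol.mesh
    wall_tags = _as_tuple(wall_tags)
    fids = mesh.facets_with_tag(wall_tags)
    if len(fids) == 0:
        raise ValueError("empty wall region")
    gdim = mesh.dim
    qdeg = 2 * sol.Vv.degree + 1
    fq = asm.FacetQuad(mesh, fids, qdeg)
    tt = _projection_traction(sol, fq)

    if space.upper() in ("P1", "P2"):
        deg = 1 if space.upper() == "P1" else 2
        W = sol.Vv if deg == sol.Vv.degree else FunctionSpace(mesh, deg)
        rhs = asm.facet_functional(W, fq, tt)
        vals = _wall_restricted_solve(W, fids, qdeg, rhs)
        return WSSField("projection", space.upper(), "continuous", mesh,
                        wall_tags, fids, vals, W=W, restriction=restriction)
    if space.upper() == "DG0":
        integ = np.einsum("fq,fqd->fd", fq.wq, tt)
        vals = integ / fq.areas[:, None]
        return WSSField("projection", "DG0", "dg0", mesh, wall_tags, fids, vals)
    if space.upper() == "DG1":
        lam = _facet_shape(fq)  # (nq, nvf)
        rhs = np.einsum("fq,qn,fqd->fnd", fq.wq, lam, tt)
        nvf = lam.shape[1]
        # facet mass (area/denominator)*(I + ones): invert in closed form
        denom = {2: 6.0, 3: 12.0}[nvf]
        s = rhs.sum(axis=1, keepdims=True)
        vals = (denom / fq.areas[:, None, None]) * (rhs - s / (1.0 + nvf))
        return WSSField("projection", "DG1", "dg1", mesh, wall_tags, fids, vals)
    raise ValueError(f"unknown projection space {space!r}")


def _as_tuple(tags):
    if isinstance(tags, (int, np.integer)):
        return (int(tags),)
    return tuple(int(t) for t in tags)


def _wall_restricted_solve(W, fids, qdeg, rhs):
    """Solve the wall boundary mass system; dofs without support on the
    wall facets are identity rows with zero data, so only the wall
    submatrix is ever factorized."""
    mesh = W.mesh
    gdim = mesh.dim
    M = asm.boundary_mass(W, fids, qdeg)
    wall_sdofs = W.facet_dofs(fids)
    wall_vdofs = (wall_sdofs[:, None] * gdim + np.arange(gdim)).ravel()
    Msub = M[wall_vdofs][:, wall_vdofs].tocsc()
    vals = np.zeros(W.n_dofs * gdim)
    vals[wall_vdofs] = spla.splu(Msub).solve(rhs[wall_vdofs])
    return vals.reshape(-1, gdim)


# ----------------------------------------------------------------------
# boundary-flux evaluation
# ----------------------------------------------------------------------

def _nitsche_functional(W, fq, sol, vbc, tangential, include_flux_term):
    """Nitsche boundary terms of the momentum residual at the discrete
    solution, tested with functions of space W:

      [-int (T(v,p)n).phi]  +  int T(phi,0)n.(v-vbc)  +  beta nu/h int (v-vbc).phi

    (first term only when ``include_flux_term``); with ``tangential`` all
    factors are projected tangentially and vbc is taken as zero.
    """
    mesh = sol.mesh
    gdim = mesh.dim
    nu = sol.props.momentum_viscosity
    sym = sol.config.symmetric_stress
    beta = sol.config.nitsche_beta
    n = fq.normals  # (f, d)
    w = fq.wq
    phi = fq.basis(W)
    gphi = fq.grad(W)
    dv = fq.eval_vector(sol.Vv, sol.v)  # v at quad points
    if tangential:
        diff = dv - np.einsum("fqd,fd->fq", dv, n)[:, :, None] * n[:, None, :]
    else:
        if vbc is not None:
            vb = np.asarray(vbc(fq.xq.reshape(-1, gdim))).reshape(dv.shape)
        else:
            vb = 0.0 * dv
        diff = dv - vb
    out = np.zeros(W.n_dofs * gdim)
    vd = fq.vector_cell_dofs(W)

    if include_flux_term:
        tn = fq.traction(sol.Vv, sol.Qp, sol.v, sol.p, nu, sym)
        if tangential:
            tn = tangential_part(tn, n[:, None, :])
        loc = -np.einsum("fq,fqi,fqa->fia", w, phi, tn)
        np.add.at(out, vd.ravel(), loc.reshape(len(vd), -1).ravel())

    # adjoint-consistency term: T(phi,0) n . diff
    dgn = np.einsum("fqid,fd->fqi", gphi, n)
    loc = nu * np.einsum("fq,fqi,fqa->fia", w, dgn, diff)
    if sym:
        loc += nu * np.einsum("fq,fqid,fqd,fa->fia", w, gphi, diff, n)
    np.add.at(out, vd.ravel(), loc.reshape(len(vd), -1).ravel())

    # penalty term
    pen = (beta * nu / fq.h)[:, None, None]
    loc = pen * np.einsum("fq,fqi,fqa->fia", w, phi, diff)
    np.add.at(out, vd.ravel(), loc.reshape(len(vd), -1).ravel())
    return out


def _subtract_traction(W, fq, sol):
    """- int_F (T(v,p) n) . phi dS  (Neumann-style subtraction, Eq-style)."""
    nu = sol.props.momentum_viscosity
    tn = fq.traction(sol.Vv, sol.Qp, sol.v, sol.p, nu,
                     sol.config.symmetric_stress)
    return -asm.facet_functional(W, fq, tn)


def _stab_functional(W, sol):
    """Stabilization tested with (phi, 0).

    For CIP only the divergence-jump term survives; for the interior
    penalty the velocity gradient-jump and streamline terms survive.
    Requires the test space to coincide with the velocity space (always the
    case for the stabilized P1/P1 pair)."""
    cfg = sol.config
    if cfg.element_pair != "p1p1":
        return 0.0
    if W.degree != sol.Vv.degree:
        raise ValueError(
            "boundary-flux test space must match the velocity space of the "
            "stabilized P1/P1 pair"
        )
    st = cfg.stabilization
    nu = sol.props.momentum_viscosity
    vflat = sol.v.ravel()
    if sol.problem == "stokes":
        S_v, _ = asm.cip_matrices(sol.Vv, sol.Qp, st.gamma_p, st.gamma_v, nu)
    else:
        S_v, _ = asm.interior_penalty_matrices(
            sol.Vv, sol.Qp, sol.v, st.alpha_i, st.alpha_v, st.alpha_p
        )
    return S_v @ vflat


def _volume_functional(W, sol):
    """Volume terms of the momentum residual tested with phi in W:
    int T:grad(phi) - int f.phi  (+ rho*(dv/dt + (grad v)v).phi for NS)."""
    mesh = sol.mesh
    gdim = mesh.dim
    nu = sol.props.momentum_viscosity
    sym = sol.config.symmetric_stress
    deg = 2 * max(W.degree, sol.Vv.degree)
    R = asm.stress_gradtest_functional(
        W, sol.Vv, sol.Qp, sol.v, sol.p, nu, sym, deg
    )
    if sol.bcs.body_force is not None:
        R -= asm.assemble_load(W, sol.bcs.body_force, deg + 2)
    if sol.problem == "navier_stokes":
        rho = sol.props.momentum_density
        degc = 3 * sol.Vv.degree - 1
        cq = asm.CellQuad(mesh, degc)
        extra = np.zeros(W.n_dofs * gdim)
        for ch in cq.chunks():
            vq = ch.eval_vector(sol.Vv, sol.v)
            gv = ch.eval_vector_grad(sol.Vv, sol.v)
            acc = np.einsum("cqkl,cql->cqk", gv, vq)
            if sol.time_derivative is not None:
                acc = acc + ch.eval_vector(sol.Vv, sol.time_derivative)
            phi = ch.basis(W)
            loc = rho * np.einsum("cq,qi,cqa->cia", ch.wdet, phi, acc)
            vd = asm.vector_cell_dofs(W, gdim)[ch.sl]
            np.add.at(extra, vd.ravel(), loc.reshape(len(vd), -1).ravel())
        R += extra
    return R


def boundary_flux_wss(sol: FlowSolution, wall_tags, space: str = "P1",
                      subtract_normal: bool = True,
                      restriction: str = "whole_domain_interior_zero",
                      _volume_cache: Optional[dict] = None,
                      ) -> WSSField:
    """Variationally consistent boundary-flux WSS on the tagged wall.

    Every non-wall boundary segment is handled according to how the solver
    treated it: weakly (Nitsche) enforced segments contribute their full
    Nitsche terms, all others have their evaluated traction subtracted.
    With ``subtract_normal=False`` the full traction (normal + tangential)
    is recovered instead of the wall shear stress.
    """
    mesh = sol.mesh
    gdim = mesh.dim
    wall_tags = _as_tuple(wall_tags)
    fids_wall = mesh.facets_with_tag(wall_tags)
    if len(fids_wall) == 0:
        raise ValueError("empty wall region")
    all_tags = set(int(t) for t in np.unique(mesh.boundary_facet_tags))
    other_tags = sorted(all_tags - set(wall_tags))

    deg = 1 if space.upper() == "P1" else 2
    if space.upper() not in ("P1", "P2"):
        raise ValueError("boundary-flux space must be P1 or P2")
    if deg > sol.Vv.degree:
        raise ValueError(
            f"boundary-flux space {space} exceeds the velocity degree "
            f"of the {sol.config.element_pair} pair"
        )
    W = sol.Vv if deg == sol.Vv.degree else FunctionSpace(mesh, deg)
    qdeg = 2 * sol.Vv.degree + 1

    # volume residual + stabilization do not depend on the wall choice;
    # cache them across the per-segment evaluations
    if _volume_cache is not None and deg in _volume_cache:
        R = _volume_cache[deg].copy()
    else:
        R = _volume_functional(W, sol) + _stab_functional(W, sol)
        if _volume_cache is not None:
            _volume_cache[deg] = R.copy()

    enforcement = sol.config.enforcement
    for tag in other_tags:
        fids = mesh.facets_with_tag(tag)
        if len(fids) == 0:
            continue
        fq = asm.FacetQuad(mesh, fids, qdeg)
        bc = sol.bcs.regions[tag]
        if enforcement == "nitsche" and bc.kind == "dirichlet":
            R += _nitsche_functional(W, fq, sol, bc.value, False, True)
        elif enforcement == "nitsche" and bc.kind == "zero_tangential_velocity":
            R += _nitsche_functional(W, fq, sol, None, True, True)
        else:
            R += _subtract_traction(W, fq, sol)

    fq_wall = asm.FacetQuad(mesh, fids_wall, qdeg)
    wall_bc = sol.bcs.regions.get(wall_tags[0])
    wall_is_nitsche = (
        enforcement == "nitsche"
        and wall_bc is not None
        and wall_bc.kind == "dirichlet"
    )
    if wall_is_nitsche:
        R += _nitsche_functional(W, fq_wall, sol, wall_bc.value, False, False)

    if subtract_normal:
        nu = sol.props.momentum_viscosity
        tn = fq_wall.traction(sol.Vv, sol.Qp, sol.v, sol.p, nu,
                              sol.config.symmetric_stress)
        n = fq_wall.normals[:, None, :]
        tn_nn = np.sum(tn * n, axis=-1, keepdims=True) * n
        R -= asm.facet_functional(W, fq_wall, tn_nn)

    vals = _wall_restricted_solve(W, fids_wall, qdeg, R)
    return WSSField("boundary_flux", space.upper(), "continuous", mesh,
                    wall_tags, fids_wall, vals, W=W, restriction=restriction)


def boundary_flux_wss_per_segment(sol: FlowSolution, segment_tags,
                                  space: str = "P1") -> WSSField:
    """Boundary-flux WSS computed separately on each boundary segment (the
    corner-safe variant for polygonal domains): each segment in turn plays
    the wall role while the others are subtracted, and the contributions
    are summed into one field.  Per-segment solutions are kept for
    segment-wise error evaluation."""
    tags = [int(t) for t in segment_tags]
    if len(set(tags)) != len(tags):
        raise ValueError("overlapping segment tags")
    segments = {}
    total = None
    fids_all = []
    W = None
    cache: dict = {}
    for tag in tags:
        f = boundary_flux_wss(sol, (tag,), space=space, _volume_cache=cache)
        segments[tag] = f.values
        total = f.values if total is None else total + f.values
        fids_all.append(f.facet_ids)
        W = f.W
    fids = np.concatenate(fids_all)
    return WSSField("boundary_flux", space.upper(), "continuous", sol.mesh,
                    tuple(tags), fids, total, W=W, segments=segments)


def wss_magnitude_table(field: WSSField):
    """Per-facet WSS magnitudes as a pandas DataFrame with columns
    ``facet``, the centroid coordinates, and ``tau_mag`` (the facet-mean
    magnitude)."""
    import pandas as pd

    mesh = field.mesh
    fq = asm.FacetQuad(mesh, field.facet_ids, 2)
    vals = field.eval_on(fq)
    mag = np.linalg.norm(vals, axis=2)
    mean_mag = (fq.wq * mag).sum(axis=1) / fq.wq.sum(axis=1)
    _, _, cents = mesh.boundary_geometry
    c = cents[field.facet_ids]
    cols = {"facet": field.facet_ids}
    for k, name in enumerate("xyz"[: mesh.dim]):
        cols[name] = c[:, k]
    cols["tau_mag"] = mean_mag
    return pd.DataFrame(cols)


def tangentiality_ratio(field: WSSField, qdeg: int = 4) -> float:
    """Normal-component energy fraction  int (tau.n)^2 / int |tau|^2  over
    the wall (per-facet normals; segment-wise for segmented fields)."""
    mesh = field.mesh
    num = den = 0.0
    tags = field.region_tags if field.segments is not None else [None]
    for tag in tags:
        if tag is None:
            fids = field.facet_ids
        else:
            fids = mesh.facets_with_tag(tag)
        fq = asm.FacetQuad(mesh, fids, qdeg)
        vals = field.eval_on(fq, segment_tag=tag)
        vn = np.einsum("fqd,fd->fq", vals, fq.normals)
        num += float((fq.wq * vn**2).sum())
        den += float((fq.wq * (vals**2).sum(-1)).sum())
    return num / max(den, 1e-300)
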