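"""Continuous Lagrange function spaces on a :class:`~wssbench.meshing.TaggedMesh`.

Scalar spaces only; vector-valued fields use the blocked-dof convention
``vdof = node * gdim + component`` handled by the assembly routines.
"""

from __future__ import annotations

import numpy as np

from .elements import SIMPLEX_EDGES, LagrangeElement

__all__ = ["FunctionSpace"]


class FunctionSpace:
    """Scalar P1 or P2 Lagrange space.

    Attributes
    ----------
    n_dofs : number of scalar degrees of freedom (vertices, plus unique
        mesh edges for P2)
    cell_dofs : (n_cells, n_local) global dof numbers per cell, ordered to
        match :class:`LagrangeElement` local nodes
    dof_coords : (n_dofs, dim) coordinates of the nodal points
    """

    def __init__(self, mesh, degree: int):
        self.mesh = mesh
        self.degree = int(degree)
        self.element = LagrangeElement(mesh.dim, self.degree)
        nv = mesh.n_vertices
        if self.degree == 1:
            self.n_dofs = nv
            self.cell_dofs = mesh.cells.copy()
            self.dof_coords = mesh.vertices.copy()
            self._edge_key_sorted = None
        else:
            loc_edges = np.array(SIMPLEX_EDGES[mesh.dim])
            pairs = mesh.cells[:, loc_edges]  # (nc, nedg, 2)
            pairs = np.sort(pairs, axis=2)
            keys = pairs[..., 0].astype(np.int64) * nv + pairs[..., 1]
            uniq, inv = np.unique(keys, return_inverse=True)
            inv = inv.reshape(keys.shape)
            self.n_dofs = nv + len(uniq)
            self.cell_dofs = np.hstack([mesh.cells, nv + inv])
            va = mesh.vertices[(uniq // nv)]
            vb = mesh.vertices[(uniq % nv)]
            self.dof_coords = np.vstack([mesh.vertices, 0.5 * (va + vb)])
            self._edge_key_sorted = uniq

    # ------------------------------------------------------------------
    def edge_dof(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Global dof numbers of the midpoint nodes of edges (a, b)."""
        if self.degree != 2:
            raise ValueError("edge dofs exist only for P2")
        nv = self.mesh.n_vertices
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        keys = lo.astype(np.int64) * nv + hi
        pos = np.searchsorted(self._edge_key_sorted, keys)
        if np.any(self._edge_key_sorted[pos] != keys):
            raise KeyError("edge not present in mesh")
        return nv + pos

    def facet_dofs(self, facet_ids) -> np.ndarray:
        """Scalar dofs whose nodes lie on the given boundary facets
        (facet vertices, plus midpoints of facet edges for P2)."""
        facets = self.mesh.boundary_facets[np.asarray(facet_ids, dtype=int)]
        dofs = [facets.ravel()]
        if self.degree == 2:
            nvf = facets.shape[1]
            for i in range(nvf):
                for j in range(i + 1, nvf):
                    dofs.append(self.edge_dof(facets[:, i], facets[:, j]))
        return np.unique(np.concatenate(dofs))

    def interpolate(self, fn) -> np.ndarray:
        """Nodal interpolation of ``fn(points) -> values``; scalar fns return
        shape (n_dofs,), vector fns (n_dofs, gdim)."""
        vals = np.asarray(fn(self.dof_coords), dtype=float)
        return vals
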