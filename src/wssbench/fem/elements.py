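"""Reference Lagrange elements on simplices (degrees 1 and 2).

Local node ordering: vertices first, then edge midpoints.  Edges follow the
``(i, j), i < j`` vertex-pair ordering, e.g. for the tetrahedron:
(0,1), (0,2), (0,3), (1,2), (1,3), (2,3).
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["LagrangeElement", "SIMPLEX_EDGES"]

# local edges of the reference simplex, ordered (i, j) with i < j
SIMPLEX_EDGES = {
    1: [(0, 1)],
    2: [(0, 1), (0, 2), (1, 2)],
    3: [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
}


class LagrangeElement:
    """Scalar Lagrange element of degree 1 or 2 on a ``dim``-simplex."""

    def __init__(self, dim: int, degree: int):
        if dim not in (1, 2, 3) or degree not in (1, 2):
            raise ValueError(f"unsupported element: dim={dim}, degree={degree}")
        self.dim = dim
        self.degree = degree
        self.edges = SIMPLEX_EDGES[dim]
        self.n_vertices = dim + 1
        self.n_nodes = dim + 1 if degree == 1 else dim + 1 + len(self.edges)
        verts = np.vstack([np.zeros(dim), np.eye(dim)])
        if degree == 1:
            self.nodes = verts
        else:
            mids = np.array([0.5 * (verts[i] + verts[j]) for i, j in self.edges])
            self.nodes = np.vstack([verts, mids])

    # -- barycentric coordinates and their (constant) gradients -------------
    def _bary(self, x: np.ndarray) -> np.ndarray:
        lam0 = 1.0 - x.sum(axis=1)
        return np.column_stack([lam0, x])

    def _bary_grad(self) -> np.ndarray:
        g = np.vstack([-np.ones(self.dim), np.eye(self.dim)])
        return g  # (n_vertices, dim)

    def tabulate(self, points: np.ndarray) -> np.ndarray:
        """Basis values, shape ``(n_points, n_nodes)``."""
        points = np.atleast_2d(points)
        lam = self._bary(points)
        if self.degree == 1:
            return lam
        vert = lam * (2.0 * lam - 1.0)
        edge = np.column_stack([4.0 * lam[:, i] * lam[:, j] for i, j in self.edges])
        return np.hstack([vert, edge])

    def tabulate_grad(self, points: np.ndarray) -> np.ndarray:
        """Reference gradients, shape ``(n_points, n_nodes, dim)``."""
        points = np.atleast_2d(points)
        g = self._bary_grad()
        if self.degree == 1:
            return np.broadcast_to(g, (len(points), *g.shape)).copy()
        lam = self._bary(points)
        out = np.empty((len(points), self.n_nodes, self.dim))
        for i in range(self.n_vertices):
            out[:, i, :] = (4.0 * lam[:, i, None] - 1.0) * g[i]
        for k, (i, j) in enumerate(self.edges):
            out[:, self.n_vertices + k, :] = 4.0 * (
                lam[:, j, None] * g[i] + lam[:, i, None] * g[j]
            )
        return out
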