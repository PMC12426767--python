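"""Simplicial meshes with tagged boundary regions.

The central container is :class:`TaggedMesh`: a triangle or tetrahedral mesh
whose boundary facets each carry exactly one integer region tag (inlet,
outlet, wall, ...).  Geometry needed by the solvers -- affine cell Jacobians,
per-cell circumdiameters ``h_K`` (diameter of the circumscribed circle or
sphere), outward facet normals -- is computed once and cached.

Two generators cover the benchmark geometries:

* :func:`build_unit_square_mesh` -- structured, symmetric (crossed-diagonal)
  triangulation of the unit square, one tag per side;
* :func:`build_cylinder_mesh` -- tetrahedral mesh of an axis-aligned
  cylinder built by triangulating a disc with concentric point rings and
  extruding prisms along z, optionally with a four-layer geometrically
  graded near-wall refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "TaggedMesh",
    "BoundaryLayerSpec",
    "build_unit_square_mesh",
    "build_cylinder_mesh",
    "region_area",
]

_GEOM_TOL = 1e-12


@dataclass(frozen=True)
class BoundaryLayerSpec:
    """Near-wall refinement: ``n_layers`` prismatic layers, the first with
    height ``first_layer_fraction`` of the surface edge length, each
    subsequent layer thicker by ``growth_ratio``."""

    n_layers: int = 4
    first_layer_fraction: float = 0.1
    growth_ratio: float = 1.1

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 < self.first_layer_fraction < 1.0:
            raise ValueError("first_layer_fraction must be in (0, 1)")
        if self.growth_ratio < 1.0:
            raise ValueError("growth_ratio must be >= 1")

    def layer_heights(self, edge_length: float) -> np.ndarray:
        """Layer heights from the wall inwards."""
        h0 = self.first_layer_fraction * edge_length
        return h0 * self.growth_ratio ** np.arange(self.n_layers)


def _simplex_faces(cells: np.ndarray) -> np.ndarray:
    """All (dim-1)-faces of each cell; face k omits local vertex k.

    Returns array of shape (ncells, dim+1, dim)."""
    nloc = cells.shape[1]
    idx = [[j for j in range(nloc) if j != k] for k in range(nloc)]
    return cells[:, idx]


class TaggedMesh:
    """Simplicial mesh (triangles in 2D, tetrahedra in 3D) with boundary
    facet tags.

    Parameters
    ----------
    vertices : (n_vertices, dim) float array
    cells : (n_cells, dim+1) int array, zero-based
    facet_tags : dict mapping sorted boundary-facet vertex tuples to int,
        or a callable ``tag(centroid) -> int`` applied to every boundary
        facet centroid.
    region_names : dict mapping tag -> label
    """

    def __init__(self, vertices, cells, facet_tags, region_names=None):
        self.vertices = np.ascontiguousarray(vertices, dtype=float)
        self.cells = np.ascontiguousarray(cells, dtype=np.int64)
        self.dim = self.vertices.shape[1]
        if self.dim not in (2, 3):
            raise ValueError("only 2D and 3D meshes are supported")
        if self.cells.shape[1] != self.dim + 1:
            raise ValueError("cells must be simplices of the ambient dimension")
        self.region_names = dict(region_names or {})
        self._orient_cells()
        self._build_facets(facet_tags)
        self._geometry_cache: dict = {}

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    def _orient_cells(self):
        """Ensure positive Jacobian determinant (positively oriented cells)."""
        J = self._jacobians_of(self.cells)
        det = np.linalg.det(J)
        if np.any(np.abs(det) < _GEOM_TOL * np.max(np.abs(det))):
            raise ValueError("mesh contains degenerate (zero-volume) cells")
        flip = det < 0
        if np.any(flip):
            c = self.cells[flip].copy()
            c[:, [-2, -1]] = c[:, [-1, -2]]
            self.cells[flip] = c

    def _jacobians_of(self, cells):
        v = self.vertices
        J = np.stack(
            [v[cells[:, k + 1]] - v[cells[:, 0]] for k in range(self.dim)], axis=2
        )
        return J  # (ncells, dim, dim); column k is edge vector v_{k+1}-v_0

    def _build_facets(self, facet_tags):
        faces = _simplex_faces(self.cells)  # (nc, dim+1, dim)
        nc, nfpc, nvf = faces.shape
        flat = np.sort(faces.reshape(-1, nvf), axis=1)
        owner = np.repeat(np.arange(nc), nfpc)
        uniq, inv, counts = np.unique(
            flat, axis=0, return_inverse=True, return_counts=True
        )
        # boundary facets appear exactly once
        bnd_mask = counts[inv] == 1
        self.boundary_facets = flat[bnd_mask]
        self.boundary_facet_cells = owner[bnd_mask]
        # interior facets: two owners each
        int_ids = np.nonzero(counts == 2)[0]
        order = np.argsort(inv, kind="stable")
        inv_sorted = inv[order]
        owner_sorted = owner[order]
        starts = np.searchsorted(inv_sorted, int_ids)
        self.interior_facets = uniq[int_ids]
        self.interior_facet_cells = np.column_stack(
            [owner_sorted[starts], owner_sorted[starts + 1]]
        )
        # tags
        if callable(facet_tags):
            cent = self.vertices[self.boundary_facets].mean(axis=1)
            tags = np.array([facet_tags(c) for c in cent], dtype=np.int64)
        else:
            try:
                tags = np.array(
                    [facet_tags[tuple(f)] for f in self.boundary_facets],
                    dtype=np.int64,
                )
            except KeyError as exc:
                raise ValueError(
                    "untagged boundary: boundary facet without a region tag"
                ) from exc
        self.boundary_facet_tags = tags

    # ------------------------------------------------------------------
    # cached geometry
    # ------------------------------------------------------------------
    def _geom(self, key):
        if key not in self._geometry_cache:
            getattr(self, "_compute_" + key)()
        return self._geometry_cache[key]

    def _compute_jacobians(self):
        J = self._jacobians_of(self.cells)
        detJ = np.linalg.det(J)
        invJ = np.linalg.inv(J)
        self._geometry_cache["jacobians"] = (J, invJ, detJ)

    @property
    def jacobians(self):
        """(J, invJ, detJ) with J of shape (n_cells, dim, dim)."""
        return self._geom("jacobians")

    @property
    def cell_volumes(self):
        _, _, detJ = self.jacobians
        fact = 2.0 if self.dim == 2 else 6.0
        return detJ / fact

    def _compute_cell_diameter(self):
        """Circumdiameter h_K: diameter of the circumscribed circle/sphere."""
        v = self.vertices[self.cells]  # (nc, dim+1, dim)
        a = v[:, 1:, :] - v[:, :1, :]  # (nc, dim, dim)
        rhs = 0.5 * np.einsum("ckd,ckd->ck", a, a)
        center = np.linalg.solve(a, rhs[..., None])[..., 0]  # relative to v0
        radius = np.linalg.norm(center, axis=1)
        self._geometry_cache["cell_diameter"] = 2.0 * radius

    @property
    def cell_diameter(self):
        return self._geom("cell_diameter")

    def _facet_geometry(self, facets, adj_cells):
        """Area (measure), unit outward normal, centroid for given facets."""
        v = self.vertices[facets]  # (nf, nvf, dim)
        cent = v.mean(axis=1)
        if self.dim == 2:
            t = v[:, 1] - v[:, 0]
            area = np.linalg.norm(t, axis=1)
            n = np.column_stack([t[:, 1], -t[:, 0]]) / area[:, None]
        else:
            c = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
            nrm = np.linalg.norm(c, axis=1)
            area = 0.5 * nrm
            n = c / nrm[:, None]
        cell_cent = self.vertices[self.cells[adj_cells]].mean(axis=1)
        sign = np.sign(np.einsum("fd,fd->f", n, cent - cell_cent))
        n = n * sign[:, None]
        return area, n, cent

    def _compute_boundary_geometry(self):
        self._geometry_cache["boundary_geometry"] = self._facet_geometry(
            self.boundary_facets, self.boundary_facet_cells
        )

    @property
    def boundary_geometry(self):
        """(areas, outward unit normals, centroids) of boundary facets."""
        return self._geom("boundary_geometry")

    def _compute_interior_geometry(self):
        # normal oriented from cell 0 towards cell 1
        self._geometry_cache["interior_geometry"] = self._facet_geometry(
            self.interior_facets, self.interior_facet_cells[:, 0]
        )

    @property
    def interior_geometry(self):
        return self._geom("interior_geometry")

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    @property
    def n_vertices(self):
        return len(self.vertices)

    @property
    def n_cells(self):
        return len(self.cells)

    def facets_with_tag(self, tags) -> np.ndarray:
        """Indices (into the boundary facet arrays) of facets whose tag is in
        ``tags`` (an int or an iterable of ints)."""
        tags = self._as_tag_set(tags)
        return np.nonzero(np.isin(self.boundary_facet_tags, list(tags)))[0]

    def _as_tag_set(self, tags):
        if isinstance(tags, (int, np.integer)):
            tags = [int(tags)]
        tags = {int(t) for t in tags}
        known = set(np.unique(self.boundary_facet_tags).tolist())
        unknown = tags - known
        if unknown:
            raise KeyError(
                f"unknown boundary tag(s) {sorted(unknown)}; available: {sorted(known)}"
            )
        return tags

    def tag_of(self, name: str) -> int:
        for tag, label in self.region_names.items():
            if label == name:
                return tag
        raise KeyError(f"no region named {name!r}; have {self.region_names}")

    def retagged(self, fn) -> "TaggedMesh":
        """New mesh with boundary tags ``fn(centroid, old_tag)``; used e.g.
        to carve a 'dome' region out of a wall for indicator tests."""
        _, _, cent = self.boundary_geometry
        old = self.boundary_facet_tags
        mapping = {
            tuple(f): int(fn(c, t))
            for f, c, t in zip(self.boundary_facets, cent, old)
        }
        return TaggedMesh(self.vertices, self.cells, mapping, self.region_names)


def region_area(mesh: TaggedMesh, tag) -> float:
    """Total measure (length in 2D, area in 3D) of the tagged boundary region."""
    idx = mesh.facets_with_tag(tag)
    areas, _, _ = mesh.boundary_geometry
    return float(areas[idx].sum())


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------

def build_unit_square_mesh(n_per_side: int) -> TaggedMesh:
    """Structured symmetric triangulation of [0,1]^2.

    Each of the ``n x n`` squares is split into four triangles through its
    centre (crossed-diagonal pattern), which is symmetric about both axes.
    Side tags: 1=left, 2=right, 3=bottom, 4=top.
    """
    n = int(n_per_side)
    if n < 1:
        raise ValueError(f"n_per_side must be a positive integer, got {n_per_side}")
    xs = np.linspace(0.0, 1.0, n + 1)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])  # (n+1)^2 corner nodes
    cx = 0.5 * (xs[:-1] + xs[1:])
    mx, my = np.meshgrid(cx, cx, indexing="ij")
    centers = np.column_stack([mx.ravel(), my.ravel()])  # n^2 centres
    verts = np.vstack([grid, centers])

    def gid(i, j):
        return i * (n + 1) + j

    ncorner = (n + 1) ** 2
    cells = []
    for i in range(n):
        for j in range(n):
            c = ncorner + i * n + j
            a, b = gid(i, j), gid(i + 1, j)
            d, e = gid(i + 1, j + 1), gid(i, j + 1)
            cells += [[a, b, c], [b, d, c], [d, e, c], [e, a, c]]
    cells = np.array(cells, dtype=np.int64)

    def tag(cent):
        x, y = cent
        if x < _GEOM_TOL:
            return 1
        if x > 1.0 - _GEOM_TOL:
            return 2
        if y < _GEOM_TOL:
            return 3
        return 4

    names = {1: "left", 2: "right", 3: "bottom", 4: "top"}
    return TaggedMesh(verts, cells, tag, names)


def _disc_points(radius: float, edge_length: float, bl: BoundaryLayerSpec | None):
    """Concentric-ring point layout of a disc of given radius.

    Returns (points, n_wall) where n_wall is the number of points on the
    outermost (wall) ring.
    """
    n_wall = max(6, int(round(2.0 * np.pi * radius / edge_length)))
    theta_wall = 2.0 * np.pi * np.arange(n_wall) / n_wall

    rings: list[tuple[float, np.ndarray]] = []
    r_core = radius
    if bl is not None:
        heights = bl.layer_heights(edge_length)
        r = radius
        # graded rings share the wall ring's angular layout -> prismatic strips
        rings.append((r, theta_wall))
        for h in heights:
            r = r - h
            rings.append((r, theta_wall))
        r_core = r
        if r_core <= 0:
            raise ValueError(
                "boundary-layer stack thicker than the radius; reduce edge_length"
            )
    else:
        rings.append((radius, theta_wall))

    n_core = max(1, int(round(r_core / edge_length)))
    pts = [np.column_stack([r * np.cos(t), r * np.sin(t)]) for r, t in rings]
    for j in range(n_core - 1, 0, -1):
        r = r_core * j / n_core
        m = max(6, int(round(2.0 * np.pi * r / edge_length)))
        off = 0.5 * (2.0 * np.pi / m) * (j % 2)
        t = 2.0 * np.pi * np.arange(m) / m + off
        pts.append(np.column_stack([r * np.cos(t), r * np.sin(t)]))
    pts.append(np.zeros((1, 2)))
    return np.vstack(pts), n_wall


def _prism_split(tri: np.ndarray, bot: np.ndarray, top: np.ndarray) -> list:
    """Split one prism into three tetrahedra with globally consistent quad
    diagonals (sorted-vertex rule)."""
    order = np.argsort(tri)
    b = bot[order]
    t = top[order]
    return [
        [b[0], b[1], b[2], t[2]],
        [b[0], b[1], t[2], t[1]],
        [b[0], t[1], t[2], t[0]],
    ]


def build_cylinder_mesh(
    radius: float,
    length: float,
    edge_length: float,
    bl: BoundaryLayerSpec | None = None,
) -> TaggedMesh:
    """Tetrahedral mesh of the cylinder {x^2+y^2 <= R^2, 0 <= z <= L}.

    A disc triangulation (Delaunay over concentric point rings) is extruded
    along z into prisms, each split into three tetrahedra.  With ``bl`` the
    disc carries geometrically graded rings next to the wall; the axial
    spacing stays uniform at ``edge_length``.

    Tags: 1=inlet (z=0), 2=outlet (z=L), 3=wall (lateral surface).
    """
    for name, val in [("radius", radius), ("length", length), ("edge_length", edge_length)]:
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    if edge_length >= radius:
        raise ValueError(
            f"edge_length={edge_length} must be smaller than radius={radius}"
        )

    disc_pts, _ = _disc_points(radius, edge_length, bl)
    tri = Delaunay(disc_pts).simplices
    # guard against degenerate slivers from cocircular ring points
    p = disc_pts[tri]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    areas2 = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    tri = tri[np.abs(areas2) > 1e-14 * radius**2]

    nz = max(1, int(round(length / edge_length)))
    zs = np.linspace(0.0, length, nz + 1)
    npd = len(disc_pts)
    verts = np.column_stack(
        [np.tile(disc_pts, (nz + 1, 1)), np.repeat(zs, npd)]
    )
    cells = []
    for k in range(nz):
        off_b, off_t = k * npd, (k + 1) * npd
        for t3 in tri:
            cells.extend(_prism_split(t3, t3 + off_b, t3 + off_t))
    cells = np.array(cells, dtype=np.int64)

    ztol = 1e-9 * length

    def tag(cent):
        if cent[2] < ztol:
            return 1
        if cent[2] > length - ztol:
            return 2
        return 3

    names = {1: "inlet", 2: "outlet", 3: "wall"}
    mesh = TaggedMesh(verts, cells, tag, names)
    # sanity: all vertices inside the cylinder
    r = np.linalg.norm(mesh.vertices[:, :2], axis=1)
    if r.max() > radius * (1 + 1e-10):
        raise ValueError("cylinder mesher produced vertices outside the radius")
    return mesh
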