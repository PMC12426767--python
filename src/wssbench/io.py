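"""Mesh and field I/O.

Formats:

* **XDMF/HDF5** -- mesh plus boundary facet tags (heavy data in an ``.h5``
  sidecar referenced from the XML), round-trip safe;
* **MSH 4.1 ASCII** -- reads/writes nodes, boundary facets and volume
  elements, with facet tags carried as the elements' entity/physical tag
  (one-based node indices converted on read);
* **VTU (ASCII)** -- export for visual inspection, with optional point
  data;
* YAML sidecars mapping integer region tags to names (inlet/outlet/...).
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

import h5py
import numpy as np
import yaml

from .meshing import TaggedMesh

__all__ = [
    "write_xdmf", "read_xdmf", "write_msh", "read_msh",
    "write_vtu", "read_tagged_mesh", "write_region_names",
    "read_region_names",
]

_TOPO_NAME = {2: "Triangle", 3: "Tetrahedron"}
_FACET_NAME = {2: "Polyline", 3: "Triangle"}


def _facet_tag_dict(facets, tags):
    return {tuple(sorted(f)): int(t) for f, t in zip(facets, tags)}


def write_region_names(path: str, region_names: dict):
    with open(path, "w") as fh:
        yaml.safe_dump({int(k): str(v) for k, v in region_names.items()}, fh)


def read_region_names(path: str) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {int(k): str(v) for k, v in data.items()}


# ----------------------------------------------------------------------
# XDMF
# ----------------------------------------------------------------------

def write_xdmf(mesh: TaggedMesh, path: str):
    """Write mesh + facet tags as XDMF XML with an HDF5 heavy-data file."""
    h5path = os.path.splitext(path)[0] + ".h5"
    h5name = os.path.basename(h5path)
    with h5py.File(h5path, "w") as h5:
        h5["vertices"] = mesh.vertices
        h5["cells"] = mesh.cells
        h5["facets"] = mesh.boundary_facets
        h5["facet_tags"] = mesh.boundary_facet_tags
        h5.attrs["region_names"] = yaml.safe_dump(
            {int(k): v for k, v in mesh.region_names.items()}
        )
    root = ET.Element("Xdmf", Version="3.0")
    dom = ET.SubElement(root, "Domain")
    grid = ET.SubElement(dom, "Grid", Name="mesh", GridType="Uniform")
    topo = ET.SubElement(
        grid, "Topology",
        TopologyType=_TOPO_NAME[mesh.dim],
        NumberOfElements=str(mesh.n_cells),
    )
    d = ET.SubElement(topo, "DataItem",
                      Dimensions=f"{mesh.n_cells} {mesh.dim + 1}",
                      NumberType="Int", Format="HDF")
    d.text = f"{h5name}:/cells"
    geom = ET.SubElement(grid, "Geometry",
                         GeometryType="XY" if mesh.dim == 2 else "XYZ")
    d = ET.SubElement(geom, "DataItem",
                      Dimensions=f"{mesh.n_vertices} {mesh.dim}",
                      Format="HDF")
    d.text = f"{h5name}:/vertices"
    fgrid = ET.SubElement(dom, "Grid", Name="facet_tags", GridType="Uniform")
    nbf, nvf = mesh.boundary_facets.shape
    ftopo = ET.SubElement(fgrid, "Topology",
                          TopologyType=_FACET_NAME[mesh.dim],
                          NumberOfElements=str(nbf))
    if mesh.dim == 2:
        ftopo.set("NodesPerElement", "2")
    d = ET.SubElement(ftopo, "DataItem", Dimensions=f"{nbf} {nvf}",
                      NumberType="Int", Format="HDF")
    d.text = f"{h5name}:/facets"
    attr = ET.SubElement(fgrid, "Attribute", Name="tags", Center="Cell")
    d = ET.SubElement(attr, "DataItem", Dimensions=str(nbf),
                      NumberType="Int", Format="HDF")
    d.text = f"{h5name}:/facet_tags"
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_xdmf(path: str, region_names: dict | None = None) -> TaggedMesh:
    h5path = os.path.splitext(path)[0] + ".h5"
    if not os.path.exists(path) or not os.path.exists(h5path):
        raise FileNotFoundError(f"missing XDMF pair {path} / {h5path}")
    with h5py.File(h5path, "r") as h5:
        vertices = h5["vertices"][()]
        cells = h5["cells"][()]
        if "facets" not in h5 or "facet_tags" not in h5:
            raise ValueError("untagged boundary: XDMF file lacks facet tags")
        facets = h5["facets"][()]
        tags = h5["facet_tags"][()]
        names = region_names
        if names is None and "region_names" in h5.attrs:
            names = yaml.safe_load(h5.attrs["region_names"])
    return TaggedMesh(vertices, cells, _facet_tag_dict(facets, tags), names)


# ----------------------------------------------------------------------
# MSH 4.1 (ASCII)
# ----------------------------------------------------------------------

_MSH_TYPE = {2: {"facet": 1, "cell": 2}, 3: {"facet": 2, "cell": 4}}
_MSH_NNODES = {1: 2, 2: 3, 4: 4}


def write_msh(mesh: TaggedMesh, path: str):
    """Minimal MSH 4.1 ASCII writer: one discrete entity per boundary
    region (tagged with a matching physical group) plus one volume entity."""
    dim = mesh.dim
    utags = np.unique(mesh.boundary_facet_tags)
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    # entities: one (dim-1)-entity per region, one dim-entity for the volume
    lines.append("$Entities")
    if dim == 2:
        # header: numPoints numCurves numSurfaces numVolumes
        lines.append(f"0 {len(utags)} 1 0")
        for t in utags:
            lines.append(f"{t} 0 0 0 0 0 0 1 {t} 0")
        lines.append("1 0 0 0 0 0 0 1 1 0")
    else:
        lines.append(f"0 0 {len(utags)} 1")
        for t in utags:
            lines.append(f"{t} 0 0 0 0 0 0 1 {t} 0")
        lines.append("1 0 0 0 0 0 0 1 1 0")
    lines.append("$EndEntities")
    # nodes: all on the volume entity
    nv = mesh.n_vertices
    lines.append("$Nodes")
    lines.append(f"1 {nv} 1 {nv}")
    lines.append(f"{dim} 1 0 {nv}")
    lines.extend(str(i + 1) for i in range(nv))
    for v in mesh.vertices:
        coords = list(v) + [0.0] * (3 - dim)
        lines.append(" ".join(repr(float(c)) for c in coords))
    lines.append("$EndNodes")
    # elements: one block per boundary region + one volume block
    ftype = _MSH_TYPE[dim]["facet"]
    ctype = _MSH_TYPE[dim]["cell"]
    blocks = []
    eid = 1
    for t in utags:
        idx = np.nonzero(mesh.boundary_facet_tags == t)[0]
        rows = []
        for f in mesh.boundary_facets[idx]:
            rows.append(f"{eid} " + " ".join(str(v + 1) for v in f))
            eid += 1
        blocks.append((dim - 1, int(t), ftype, rows))
    rows = []
    for c in mesh.cells:
        rows.append(f"{eid} " + " ".join(str(v + 1) for v in c))
        eid += 1
    blocks.append((dim, 1, ctype, rows))
    lines.append("$Elements")
    lines.append(f"{len(blocks)} {eid - 1} 1 {eid - 1}")
    for edim, etag, etype, rows in blocks:
        lines.append(f"{edim} {etag} {etype} {len(rows)}")
        lines.extend(rows)
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path: str, region_names: dict | None = None) -> TaggedMesh:
    """Read an ASCII MSH 4.1 file with tagged boundary facets.

    The facet tag is the physical tag of the facet's entity when the
    $Entities section provides one, else the entity tag itself."""
    with open(path) as fh:
        text = fh.read()

    def section(name):
        try:
            body = text.split(f"${name}\n", 1)[1].split(f"$End{name}", 1)[0]
        except IndexError:
            raise ValueError(f"malformed MSH file: missing ${name}")
        return body.strip().split("\n")

    fmt = section("MeshFormat")[0].split()
    if not fmt[0].startswith("4.1"):
        raise ValueError(f"unsupported MSH version {fmt[0]} (need 4.1 ASCII)")

    # entity -> physical tag map per dimension
    ent_phys = {}
    if "$Entities" in text:
        lines = section("Entities")
        counts = list(map(int, lines[0].split()))
        i = 1
        for edim, cnt in enumerate(counts):
            for _ in range(cnt):
                parts = lines[i].split()
                i += 1
                tag = int(parts[0])
                if edim == 0:
                    nphys = int(parts[4]) if len(parts) > 4 else 0
                    phys = int(parts[5]) if nphys else None
                else:
                    nphys = int(parts[7])
                    phys = int(parts[8]) if nphys else None
                ent_phys[(edim, tag)] = phys

    lines = section("Nodes")
    hdr = lines[0].split()
    nblocks, nnodes = int(hdr[0]), int(hdr[1])
    i = 1
    coords = {}
    for _ in range(nblocks):
        bdim, btag, _, cnt = map(int, lines[i].split())
        i += 1
        ids = [int(lines[i + k]) for k in range(cnt)]
        i += cnt
        for k in range(cnt):
            xyz = list(map(float, lines[i + k].split()))
            coords[ids[k]] = xyz
        i += cnt
    node_ids = sorted(coords)
    remap = {nid: j for j, nid in enumerate(node_ids)}

    lines = section("Elements")
    hdr = lines[0].split()
    nblocks = int(hdr[0])
    i = 1
    cells = []
    facets = []
    facet_tags = []
    dim = _mesh_dim(text)
    for _ in range(nblocks):
        edim, etag, etype, cnt = map(int, lines[i].split())
        i += 1
        nn = _MSH_NNODES.get(etype)
        if nn is None:
            raise ValueError(f"unsupported MSH element type {etype}")
        is_cell = (etype == 4) or (etype == 2 and dim == 2)
        for k in range(cnt):
            parts = list(map(int, lines[i + k].split()))
            nodes = [remap[n] for n in parts[1 : 1 + nn]]
            if is_cell:
                cells.append(nodes)
            else:
                phys = ent_phys.get((edim, etag))
                facets.append(nodes)
                facet_tags.append(phys if phys is not None else etag)
        i += cnt
    if not cells:
        raise ValueError("MSH file contains no volume elements")
    verts = np.array([coords[nid][:dim] for nid in node_ids])
    if not facets:
        raise ValueError("untagged boundary: MSH file has no tagged facets")
    tag_map = _facet_tag_dict(np.array(facets), np.array(facet_tags))
    return TaggedMesh(verts, np.array(cells), tag_map, region_names)


def _mesh_dim(text: str) -> int:
    # tetrahedra present -> 3D, else 2D
    return 3 if " 4 " in _elements_header_types(text) else 2


def _elements_header_types(text: str) -> str:
    body = text.split("$Elements\n", 1)[1].split("$EndElements", 1)[0]
    lines = body.strip().split("\n")
    nblocks = int(lines[0].split()[0])
    types = []
    i = 1
    for _ in range(nblocks):
        edim, etag, etype, cnt = map(int, lines[i].split())
        types.append(etype)
        i += 1 + cnt
    return " " + " ".join(map(str, types)) + " "


# ----------------------------------------------------------------------
# VTU export
# ----------------------------------------------------------------------

_VTK_TYPE = {2: 5, 3: 10}  # triangle, tetra


def write_vtu(mesh: TaggedMesh, path: str, point_data: dict | None = None):
    """ASCII VTU export with optional nodal vector/scalar data."""
    nv, nc = mesh.n_vertices, mesh.n_cells
    nloc = mesh.dim + 1
    pts = np.column_stack(
        [mesh.vertices, np.zeros((nv, 3 - mesh.dim))]
    )
    out = []
    out.append('<?xml version="1.0"?>')
    out.append('<VTKFile type="UnstructuredGrid" version="0.1" '
               'byte_order="LittleEndian">')
    out.append("<UnstructuredGrid>")
    out.append(f'<Piece NumberOfPoints="{nv}" NumberOfCells="{nc}">')
    out.append('<Points><DataArray type="Float64" NumberOfComponents="3" '
               'format="ascii">')
    out.append("\n".join(" ".join(map(repr, row)) for row in pts))
    out.append("</DataArray></Points>")
    out.append("<Cells>")
    out.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    out.append("\n".join(" ".join(map(str, c)) for c in mesh.cells))
    out.append("</DataArray>")
    out.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    out.append(" ".join(str((i + 1) * nloc) for i in range(nc)))
    out.append("</DataArray>")
    out.append('<DataArray type="UInt8" Name="types" format="ascii">')
    out.append(" ".join([str(_VTK_TYPE[mesh.dim])] * nc))
    out.append("</DataArray></Cells>")
    out.append("<PointData>")
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        if ncomp == 2:  # pad 2D vectors for VTK
            arr = np.column_stack([arr, np.zeros(len(arr))])
            ncomp = 3
        out.append(f'<DataArray type="Float64" Name="{name}" '
                   f'NumberOfComponents="{ncomp}" format="ascii">')
        flat = arr.reshape(len(arr), -1)
        out.append("\n".join(" ".join(map(repr, row)) for row in flat))
        out.append("</DataArray>")
    out.append("</PointData>")
    out.append("</Piece></UnstructuredGrid></VTKFile>")
    with open(path, "w") as fh:
        fh.write("\n".join(out))


def read_tagged_mesh(path: str, region_names=None) -> TaggedMesh:
    """Read a tagged mesh from MSH 4.1 or XDMF; ``region_names`` may be a
    dict or a path to a YAML sidecar mapping tags to labels."""
    if isinstance(region_names, (str, os.PathLike)):
        region_names = read_region_names(region_names)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".msh":
        return read_msh(path, region_names)
    if ext == ".xdmf":
        return read_xdmf(path, region_names)
    raise ValueError(f"unknown mesh format {ext!r} (use .msh or .xdmf)")
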