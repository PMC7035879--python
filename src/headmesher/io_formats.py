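"""Readers/writers for the standard formats the pipeline touches.

NIfTI segmentations come in through nibabel; triangle surfaces go through
trimesh (OFF/PLY/STL); tetrahedral meshes are written as legacy-ASCII VTK
unstructured grids, Gmsh MSH v2.2, or TetGen-style .node/.ele pairs.  All
other modules operate purely on the in-memory domain types.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from .grid import VolumeGrid
from .surface import TriSurface
from .tetmesh import TetMesh

__all__ = [
    "read_segmentation",
    "write_segmentation",
    "read_surface",
    "write_surface",
    "read_tetmesh",
    "write_tetmesh",
]

_SURFACE_FORMATS = ("off", "ply", "stl")
_TET_FORMATS = ("vtk", "msh", "node_ele")


def _grid_geometry(img) -> tuple:
    """Spacing/origin from a NIfTI affine; oblique (rotated) affines are
    rejected because the gap operators are grid-axis-aligned.  Pure axis
    flips are folded into the returned flip mask."""
    aff = np.asarray(img.affine, dtype=np.float64)
    R = aff[:3, :3]
    spacing = np.linalg.norm(R, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("non-positive voxel spacing in NIfTI header")
    off_diag = np.abs(R) - np.diag(np.abs(np.diag(R)))
    if np.any(off_diag > 1e-4 * spacing):
        raise ValueError(
            "oblique NIfTI affine (rotation) is not supported; resample the "
            "volume to an axis-aligned grid first"
        )
    flips = np.diag(R) < 0
    origin = aff[:3, 3].copy()
    return spacing, origin, flips


def read_segmentation(path, kind: str):
    """Read a NIfTI segmentation as VolumeGrid(s).

    3-D files return a single grid.  A 4-D file is accepted only for
    ``kind="probability"`` and returns one grid per 4th-dimension index.
    Probability values may exceed [0, 1] by at most 1e-6 (clamped); larger
    excursions are rejected.
    """
    if kind not in ("probability", "label"):
        raise ValueError(f"kind must be 'probability' or 'label', got {kind!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing, origin, flips = _grid_geometry(img)
    if data.ndim == 4:
        if kind != "probability":
            raise ValueError("4-D input is only accepted for probability maps")
        vols = [data[..., i] for i in range(data.shape[3])]
    elif data.ndim == 3:
        vols = [data]
    else:
        raise ValueError(f"expected a 3-D or 4-D NIfTI volume, got ndim={data.ndim}")

    out = []
    for v in vols:
        v = np.asarray(v, dtype=np.float64)
        for ax in range(3):
            if flips[ax]:
                v = np.flip(v, axis=ax)
        o = origin.copy()
        for ax in range(3):
            if flips[ax]:
                o[ax] = origin[ax] - spacing[ax] * (v.shape[ax] - 1)
        out.append(VolumeGrid(v, spacing=tuple(spacing), origin=tuple(o), kind=kind))
    return out[0] if data.ndim == 3 else out


def write_segmentation(vol: VolumeGrid, path):
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    data = vol.values
    if vol.kind == "probability":
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    nib.save(img, str(path))
    return Path(path)


def write_surface(surface: TriSurface, path, fmt: str | None = None):
    """Write a surface as OFF/PLY/STL (format from extension if omitted).

    STL stores no connectivity, so an open (non-manifold) surface is only
    warned about; other formats round-trip vertices within 1e-6 mm and
    faces exactly.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _SURFACE_FORMATS:
        raise ValueError(f"unknown surface format {fmt!r}; use one of {_SURFACE_FORMATS}")
    if surface.n_faces == 0:
        raise ValueError("refusing to write an empty surface")
    if not surface.is_closed_manifold():
        if fmt == "stl":
            warnings.warn(f"writing open surface {surface.tag!r} to STL")
        else:
            warnings.warn(f"surface {surface.tag!r} is not a closed manifold")
    tm = trimesh.Trimesh(vertices=surface.vertices, faces=surface.faces, process=False)
    tm.export(str(path), file_type=fmt)
    return path


def read_surface(path, tag: str = "") -> TriSurface:
    tm = trimesh.load(str(path), process=False, force="mesh")
    return TriSurface(np.asarray(tm.vertices), np.asarray(tm.faces), tag=tag)


def _check_mesh_writable(mesh: TetMesh):
    from .quality import tet_volumes

    v = tet_volumes(mesh.tets(), signed=True)
    bad = np.where(np.abs(v) <= 1e-12)[0]
    if len(bad):
        raise ValueError(
            f"mesh has degenerate (zero-volume) elements, e.g. index {int(bad[0])}"
        )


def write_tetmesh(mesh: TetMesh, path, fmt: str = "vtk"):
    """Write a labeled tetrahedral mesh; returns the file path(s).

    vtk : legacy ASCII unstructured grid with a ``tissue`` cell-data field.
    msh : Gmsh MSH v2.2 ASCII, label as the physical/elementary tag.
    node_ele : TetGen-style 1-based .node/.ele pair with region attributes.
    """
    if fmt not in _TET_FORMATS:
        raise ValueError(f"unknown tetmesh format {fmt!r}; use one of {_TET_FORMATS}")
    _check_mesh_writable(mesh)
    path = Path(path)
    if fmt == "vtk":
        _write_vtk(mesh, path)
        return path
    if fmt == "msh":
        _write_msh(mesh, path)
        return path
    node = path.with_suffix(".node")
    ele = path.with_suffix(".ele")
    _write_node_ele(mesh, node, ele)
    return node, ele


def _write_vtk(mesh: TetMesh, path: Path):
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nheadmesher tetrahedral mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            f.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        f.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        for e in mesh.elements:
            f.write(f"4 {e[0]} {e[1]} {e[2]} {e[3]}\n")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        f.write("\n".join(["10"] * mesh.n_elements) + "\n")
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        f.write("SCALARS tissue int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(l)) for l in mesh.labels) + "\n")
        f.write(f"# label_names: {' '.join(mesh.label_names)}\n")


def _read_vtk(path) -> TetMesh:
    lines = Path(path).read_text().splitlines()
    i = 0
    nodes, cells, labels, names = None, None, None, None

    while i < len(lines):
        ln = lines[i].split()
        if ln and ln[0] == "POINTS":
            n = int(ln[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals += [float(x) for x in lines[i].split()]
                i += 1
            nodes = np.array(vals).reshape(n, 3)
            continue
        if ln and ln[0] == "CELLS":
            n = int(ln[1])
            cells = np.array(
                [[int(x) for x in lines[i + 1 + k].split()[1:]] for k in range(n)]
            )
            i += n + 1
            continue
        if ln and ln[0] == "SCALARS" and ln[1] == "tissue":
            n = len(cells)
            vals = []
            i += 2
            while len(vals) < n:
                vals += [int(x) for x in lines[i].split()]
                i += 1
            labels = np.array(vals)
            continue
        if lines[i].startswith("# label_names:"):
            names = lines[i].split(":", 1)[1].split()
        i += 1
    if names is None:
        names = [str(x) for x in sorted(set(labels.tolist()))]
    return TetMesh(nodes, cells, labels, names)


def _write_msh(mesh: TetMesh, path: Path):
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write("$Nodes\n")
        f.write(f"{mesh.n_nodes}\n")
        for i, p in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        f.write("$EndNodes\n$Elements\n")
        f.write(f"{mesh.n_elements}\n")
        for i, (e, l) in enumerate(zip(mesh.elements, mesh.labels), start=1):
            f.write(
                f"{i} 4 2 {int(l)} {int(l)} {e[0]+1} {e[1]+1} {e[2]+1} {e[3]+1}\n"
            )
        f.write("$EndElements\n")
        f.write("$Comments\nlabel_names: " + " ".join(mesh.label_names) + "\n$EndComments\n")


def _read_msh(path) -> TetMesh:
    lines = Path(path).read_text().splitlines()
    nodes, elements, labels, names = [], [], [], None
    i = 0
    while i < len(lines):
        if lines[i].strip() == "$Nodes":
            n = int(lines[i + 1])
            for k in range(n):
                parts = lines[i + 2 + k].split()
                nodes.append([float(x) for x in parts[1:4]])
            i += n + 2
        elif lines[i].strip() == "$Elements":
            n = int(lines[i + 1])
            for k in range(n):
                parts = [int(x) for x in lines[i + 2 + k].split()]
                if parts[1] != 4:
                    continue
                ntags = parts[2]
                labels.append(parts[3])
                elements.append([v - 1 for v in parts[3 + ntags:]])
            i += n + 2
        elif lines[i].startswith("label_names:"):
            names = lines[i].split(":", 1)[1].split()
            i += 1
        else:
            i += 1
    labels = np.array(labels)
    if names is None:
        names = [str(x) for x in range(int(labels.max()) + 1)]
    return TetMesh(np.array(nodes), np.array(elements), labels, names)


def _write_node_ele(mesh: TetMesh, node: Path, ele: Path):
    with open(node, "w") as f:
        f.write(f"{mesh.n_nodes} 3 0 0\n")
        for i, p in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    with open(ele, "w") as f:
        f.write(f"{mesh.n_elements} 4 1\n")
        for i, (e, l) in enumerate(zip(mesh.elements, mesh.labels), start=1):
            f.write(f"{i} {e[0]+1} {e[1]+1} {e[2]+1} {e[3]+1} {int(l)}\n")


def _read_node_ele(node, ele) -> TetMesh:
    nl = Path(node).read_text().split("\n")
    n = int(nl[0].split()[0])
    nodes = np.array([[float(x) for x in nl[1 + k].split()[1:4]] for k in range(n)])
    el = Path(ele).read_text().split("\n")
    m = int(el[0].split()[0])
    rows = [[int(x) for x in el[1 + k].split()] for k in range(m)]
    elements = np.array([r[1:5] for r in rows]) - 1
    labels = np.array([r[5] if len(r) > 5 else 0 for r in rows])
    names = [str(x) for x in range(int(labels.max()) + 1)]
    return TetMesh(nodes, elements, labels, names)


def read_tetmesh(path, fmt: str | None = None, ele_path=None) -> TetMesh:
    """Read back a mesh written by :func:`write_tetmesh` (round-trip support)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "vtk":
        return _read_vtk(path)
    if fmt == "msh":
        return _read_msh(path)
    if fmt in ("node", "node_ele"):
        return _read_node_ele(path.with_suffix(".node"), ele_path or path.with_suffix(".ele"))
    raise ValueError(f"unknown tetmesh format {fmt!r}")
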