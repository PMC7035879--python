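"""Mesh-quality and volume-conservation metrics.

Two per-element shape metrics are reported: the Joe-Liu quality
``12 (3V)^(2/3) / sum(l_ij^2)`` (1 for the regular tetrahedron, 0 for a
degenerate one, scale invariant) and the radius-edge ratio ``R / L_min``
(circumsphere radius over shortest edge, sqrt(6)/4 for the regular
tetrahedron).  Volume conservation is summarized per tissue by ``Vrel``, the
enclosed volume of the tissue boundary divided by the segmentation volume of
the same tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .grid import TissueStack

__all__ = ["joe_liu", "radius_edge", "tet_volumes", "v_rel", "qc_report", "QualityReport"]

REGULAR_RADIUS_EDGE = np.sqrt(6.0) / 4.0
_PAIRS = list(combinations(range(4), 2))


def _as_tets(tet) -> np.ndarray:
    t = np.asarray(tet, dtype=np.float64)
    if t.shape == (4, 3):
        t = t[None]
    if t.ndim != 3 or t.shape[1:] != (4, 3):
        raise ValueError(f"expected (4,3) or (n,4,3) points, got {t.shape}")
    return t


def tet_volumes(tet, signed: bool = False) -> np.ndarray:
    t = _as_tets(tet)
    v = np.einsum(
        "ni,ni->n", t[:, 1] - t[:, 0], np.cross(t[:, 2] - t[:, 0], t[:, 3] - t[:, 0])
    ) / 6.0
    return v if signed else np.abs(v)


def joe_liu(tet):
    """Joe-Liu shape quality in [0, 1]; 0 for coincident/coplanar points."""
    t = _as_tets(tet)
    v = tet_volumes(t)
    s = np.zeros(len(t))
    for i, j in _PAIRS:
        s += np.sum((t[:, i] - t[:, j]) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 12.0 * (3.0 * v) ** (2.0 / 3.0) / s
    q = np.where((v <= 0) | (s <= 0), 0.0, q)
    return q if q.shape != (1,) else float(q[0])


def circumcenters(tet):
    """Circumcenter of each tetrahedron; rows of NaN for degenerate ones."""
    t = _as_tets(tet)
    a = t[:, 0]
    A = 2.0 * (t[:, 1:] - a[:, None])
    rhs = np.einsum("nij,nij->ni", t[:, 1:], t[:, 1:]) - np.einsum("ni,ni->n", a, a)[:, None]
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-300
    cc = np.full((len(t), 3), np.nan)
    if ok.any():
        cc[ok] = np.linalg.solve(A[ok], rhs[ok][..., None])[..., 0]
    return cc


def radius_edge(tet):
    """Circumsphere radius over shortest edge; +inf for degenerate elements."""
    t = _as_tets(tet)
    cc = circumcenters(t)
    R = np.linalg.norm(cc - t[:, 0], axis=1)
    L = np.full(len(t), np.inf)
    for i, j in _PAIRS:
        L = np.minimum(L, np.linalg.norm(t[:, i] - t[:, j], axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        q = R / L
    q = np.where(np.isnan(R) | (L <= 0), np.inf, q)
    return q if q.shape != (1,) else float(q[0])


def v_rel(mesh_or_surfaces, tissue: str, segmentation: TissueStack) -> float:
    """Volume-conservation ratio for one tissue.

    With a list of nested boundary surfaces (innermost tissue first, tags
    naming tissues), the numerator is the enclosed volume of the tissue's
    boundary minus that of the next-inner boundary.  With a labeled TetMesh,
    the numerator is the summed volume of the tissue's elements.  The
    denominator is the segmentation volume of the tissue at threshold 0.5
    (cumulative-partition semantics for probabilistic stacks).
    """
    denom = segmentation.tissue_voxel_volume(tissue)  # raises if absent/zero
    from .tetmesh import TetMesh  # local import to avoid a cycle

    if isinstance(mesh_or_surfaces, TetMesh):
        mesh = mesh_or_surfaces
        if tissue not in mesh.label_names:
            raise ValueError(f"tissue {tissue!r} not present in mesh labels")
        li = mesh.label_names.index(tissue)
        vols = tet_volumes(mesh.nodes[mesh.elements])
        num = float(vols[mesh.labels == li].sum())
    else:
        surfaces = list(mesh_or_surfaces)
        tags = [s.tag for s in surfaces]
        if tissue not in tags:
            raise ValueError(f"tissue {tissue!r} not among surface tags {tags}")
        i = tags.index(tissue)
        num = surfaces[i].signed_volume()
        if i > 0:
            num -= surfaces[i - 1].signed_volume()
    return num / denom


@dataclass
class QualityReport:
    """Aggregated QC metrics for a labeled tetrahedral mesh."""

    n_nodes: int
    n_elements: int
    joe_liu_mean: float
    joe_liu_min: float
    radius_edge_max: float
    volume_min: float
    volume_max: float
    volume_total: float
    volume_histogram: dict
    v_rel: dict = field(default_factory=dict)
    label_volumes: dict = field(default_factory=dict)
    label_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_elements": self.n_elements,
            "joe_liu_mean": self.joe_liu_mean,
            "joe_liu_min": self.joe_liu_min,
            "radius_edge_max": self.radius_edge_max,
            "volume_min": self.volume_min,
            "volume_max": self.volume_max,
            "volume_total": self.volume_total,
            "volume_histogram": self.volume_histogram,
            "v_rel": self.v_rel,
            "label_volumes": self.label_volumes,
            "label_counts": self.label_counts,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_markdown(self) -> str:
        d = self.to_dict()
        lines = ["# Mesh quality report", ""]
        lines.append(f"- nodes: {d['n_nodes']}, elements: {d['n_elements']}")
        lines.append(
            f"- Joe-Liu quality: mean {d['joe_liu_mean']:.4f}, min {d['joe_liu_min']:.4f}"
        )
        lines.append(f"- max radius-edge ratio: {d['radius_edge_max']:.4f}")
        lines.append(
            f"- element volume [mm^3]: min {d['volume_min']:.4g}, "
            f"max {d['volume_max']:.4g}, total {d['volume_total']:.6g}"
        )
        if self.v_rel:
            lines.append("")
            lines.append("| tissue | Vrel | mesh volume [mm^3] | elements |")
            lines.append("|---|---|---|---|")
            for k in self.v_rel:
                lines.append(
                    f"| {k} | {self.v_rel[k]:.4f} | "
                    f"{self.label_volumes.get(k, float('nan')):.6g} | "
                    f"{self.label_counts.get(k, 0)} |"
                )
        return "\n".join(lines)


def qc_report(mesh, surfaces=None, segmentation: TissueStack | None = None,
              n_bins: int = 20) -> QualityReport:
    """Compute the QC summary for a mesh (optionally with Vrel per tissue)."""
    tets = mesh.nodes[mesh.elements]
    jl = np.atleast_1d(joe_liu(tets))
    re = np.atleast_1d(radius_edge(tets))
    vols = tet_volumes(tets)
    hist, edges = np.histogram(vols, bins=n_bins)
    label_volumes, label_counts, vrel = {}, {}, {}
    for li, name in enumerate(mesh.label_names):
        sel = mesh.labels == li
        if not sel.any():
            continue
        label_volumes[name] = float(vols[sel].sum())
        label_counts[name] = int(sel.sum())
    if segmentation is not None:
        for name in segmentation.names:
            if name in label_volumes:
                try:
                    if surfaces is not None:
                        vrel[name] = v_rel(surfaces, name, segmentation)
                    else:
                        vrel[name] = v_rel(mesh, name, segmentation)
                except ValueError:
                    continue
    return QualityReport(
        n_nodes=len(mesh.nodes),
        n_elements=len(mesh.elements),
        joe_liu_mean=float(jl.mean()),
        joe_liu_min=float(jl.min()),
        radius_edge_max=float(re.max()),
        volume_min=float(vols.min()),
        volume_max=float(vols.max()),
        volume_total=float(vols.sum()),
        volume_histogram={"edges": edges.tolist(), "counts": hist.tolist()},
        v_rel=vrel,
        label_volumes=label_volumes,
        label_counts=label_counts,
    )
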