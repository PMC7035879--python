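"""Boundary-conforming tetrahedralization of star-shaped domains.

The mesher combines two constructions:

1. **Prism bands.**  The input surface is extruded inward band by band:
   the boundary polyhedron is scaled toward the star center and the shell
   between the copies is tiled with three tetrahedra per triangle column.
   Diagonals of shared quadrilaterals follow the global minimum-vertex-id
   rule, so every band is watertight by construction, and each band is
   verified exactly: all cells positive, radius-edge within the quality
   bound, and cell volumes summing to the outer/inner polyhedron volume
   difference.  Because the first band's outer boundary *is* the input
   surface, the summed element volume equals the enclosed surface volume
   to floating point — the pipeline's volume-conservation guarantee.
   Band interfaces snap onto the interior tissue radii whenever the cell
   aspect stays healthy, so elements do not straddle label boundaries; a
   tiny radius-preserving tangential jitter keeps highly regular inputs
   from producing degenerate Delaunay configurations downstream.

2. **Protected Delaunay core.**  The region inside the last front is
   filled with the Delaunay tetrahedralization of the front vertices plus
   interior points seeded as jittered concentric shells anchored to the
   remaining tissue radii, all kept at a protection distance from the
   front so its faces appear as Delaunay facets.  Faces that still fail
   (locally reflex, near-cocircular spots) are recovered exactly by
   flip-tetrahedron surgery and vertex-star re-fanning, validated through
   an exact volume identity.  Oversized cells are refined by centroid
   insertion under a divergence guard; radius-edge outliers are left to a
   2-3/3-2 bistellar-flip and optimization-smoothing polish.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .surface import TriSurface

__all__ = ["RadialMesher", "RadialParams", "RadialMeshError", "star_center"]

log = logging.getLogger(__name__)


class RadialMeshError(RuntimeError):
    pass


def star_center(surface: TriSurface) -> np.ndarray:
    """Volume centroid of the enclosed solid (divergence theorem)."""
    t = surface.triangles()
    v6 = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2]))
    return (t.sum(axis=1) / 4.0 * v6[:, None]).sum(axis=0) / v6.sum()


def _fan_volumes(V, F, c):
    t = V[F] - c
    return np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0


def is_star_shaped(surface: TriSurface, center) -> bool:
    return bool(np.all(_fan_volumes(surface.vertices, surface.faces, center) > 0))


@dataclass
class RadialParams:
    """Tuning knobs of the mesher.

    band_height_factor : band height as a fraction of the local median edge
        length; 0.8 centers the prism-split quality sweet spot (radius-edge
        well below sqrt(2), Joe-Liu around 0.8).
    n_bands : prism layers extruded before handing off to the Delaunay core.
    protect_factor : minimum distance of interior points from the front, in
        local edge lengths; keeps the front faces Delaunay.
    q_bound : radius-edge bound enforced on every cell.
    vmax : element volume bound (mm^3) honored by band heights, interior
        point spacing and the refinement loop.
    """

    band_height_factor: float = 0.8
    n_bands: int = 3
    snap_radii: tuple = ()
    protect_factor: float = 0.5
    q_bound: float = 1.414
    vmax: float = np.inf
    seed: int = 42
    max_refine_rounds: int = 5


def _edges_of(F):
    return np.unique(
        np.sort(np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1),
        axis=0,
    )


def _tet_v6(t):
    return np.einsum(
        "ni,ni->n", t[:, 1] - t[:, 0], np.cross(t[:, 2] - t[:, 0], t[:, 3] - t[:, 0])
    )


class RadialMesher:
    """Tetrahedralize the inside of one closed star-shaped surface."""

    def __init__(self, surface: TriSurface, params: RadialParams | None = None,
                 sizing=None):
        self.params = params or RadialParams()
        self.sizing = sizing  # callable (n,3) -> local vmax, or None
        surface = surface.oriented_outward()
        self.center = star_center(surface)
        if not is_star_shaped(surface, self.center):
            raise RadialMeshError(
                "outer surface is not star-shaped about its volume centroid; "
                "the radial engine cannot mesh this domain"
            )
        self.surface = surface
        self._total_volume = abs(surface.signed_volume())

    # -- public -----------------------------------------------------------
    def mesh(self):
        """Build the mesh; returns (nodes (n,3), elements (m,4)) with all
        elements positively oriented.  Any element still violating the
        radius-edge bound after polishing is reported via a warning (the
        strict check in ``tetrahedralize`` raises on it).
        """
        from .quality import radius_edge

        nodes, elements = self._mesh_once(self.surface)
        re = np.atleast_1d(radius_edge(nodes[elements]))
        n_over = int((re > self.params.q_bound).sum())
        if n_over:
            log.warning("mesh: %d of %d cells remain over the radius-edge "
                        "bound (worst %.3f)", n_over, len(elements),
                        float(re.max()))
        return nodes, elements

    def _mesh_once(self, surface):
        p = self.params
        c = self.center
        V = surface.vertices.copy()
        F = surface.faces.copy()
        n_outer = len(V)
        node_chunks = [V]
        n_nodes = len(V)
        gid = np.arange(len(V))
        tet_chunks = []

        r0 = float(np.linalg.norm(V - c, axis=1).mean())
        snaps = sorted({float(s) for s in p.snap_radii if s >= 0.77 * r0},
                       reverse=True)
        band = 0
        while band < 14:
            edges = _edges_of(F)
            elen = np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1)
            ell = float(np.median(elen))
            r_mean = float(np.linalg.norm(V - c, axis=1).mean())
            areas = self._areas(V, F)
            vcap = self._local_vmax(V, F)
            h_reg = min(p.band_height_factor * ell, 3.0 * vcap / float(areas.max()))
            # align band interfaces with the interior tissue radii so that
            # cells do not straddle label boundaries
            below = [s for s in snaps if s < r_mean - 0.1 * ell]
            h = None
            if below:
                # land the band interface on the next tissue radius, with
                # the band count chosen to keep the cell aspect healthy; a
                # radius only reachable with squat cells is left to the core
                d = r_mean - below[0]
                cand = sorted({max(1, int(np.floor(d / h_reg))),
                               max(1, int(np.ceil(d / h_reg)))})
                best = min(cand, key=lambda k: abs(d / k / ell - 0.8))
                if 0.52 * ell <= d / best <= 1.2 * ell:
                    h = d / best
                else:
                    snaps.remove(below[0])
            if h is None:
                if band >= p.n_bands and not below:
                    break
                h = h_reg
            if r_mean - h < 2.5 * ell:
                break  # tiny domain: leave the rest to the core
            rho = max(1.0 - h / r_mean, 0.05)
            Vi = c + rho * (V - c)
            # a tiny radius-preserving tangential jitter breaks the exact
            # local cocircularity of highly regular inputs, which would
            # otherwise make the core's Delaunay facet recovery degenerate
            rng_b = np.random.default_rng(p.seed + 101 * band)
            Vj = self._tangential_jitter(Vi, c, 0.03 * ell, rng_b)
            out = self._build_band(V, Vj, F, gid, n_nodes, c)
            if out is None:
                out = self._build_band(V, Vi, F, gid, n_nodes, c)
            if out is None:
                # an ill-shaped input triangle degrades quality instead of
                # failing the build (the strict post-check still reports it)
                out = self._build_band(V, Vi, F, gid, n_nodes, c, gate=False)
            if out is None:
                raise RadialMeshError(f"band {band}: invalid band geometry")
            tets, V, F, gid = out
            tet_chunks.append(tets)
            node_chunks.append(V)
            n_nodes += len(V)
            band += 1

        core_nodes, core_tets = self._delaunay_core(V, F, c)
        # core node 0..len(V)-1 are the front vertices (gid); the rest are new
        remap = np.concatenate(
            [gid, n_nodes + np.arange(len(core_nodes) - len(V))]
        )
        tet_chunks.append(remap[core_tets])
        node_chunks.append(core_nodes[len(V):])
        nodes = np.concatenate(node_chunks)
        elements = np.concatenate(tet_chunks)
        n_locked = n_outer  # outer boundary stays put
        for _ in range(8):
            elements = self._flip23_pass(nodes, elements)
            moved = self._smooth_bad_nodes(nodes, elements, n_locked)
            if not moved:
                break
        return nodes, _orient_positive(nodes, elements)

    def _smooth_bad_nodes(self, nodes, elements, n_locked, rounds: int = 3):
        """Optimization smoothing: nodes incident to cells violating the
        radius-edge bound (except the locked outer-boundary nodes) are moved
        to the best of a few candidate positions, accepted only when the
        worst incident radius-edge ratio improves and no cell inverts.
        Mutates `nodes` in place; returns the number of accepted moves."""
        from .quality import radius_edge

        q = self.params.q_bound
        incid = {}
        for i, cell in enumerate(elements):
            for v in cell:
                incid.setdefault(int(v), []).append(i)
        total_moved = 0
        for _round in range(rounds):
            re_all = np.atleast_1d(radius_edge(nodes[elements]))
            bad_cells = np.where(re_all > q)[0]
            if len(bad_cells) == 0:
                break
            cand_nodes = sorted(
                {int(v) for i in bad_cells for v in elements[i] if v >= n_locked},
                key=lambda v: -max(re_all[i] for i in incid[v]),
            )
            moved = 0
            for v in cand_nodes:
                cells_v = elements[incid[v]]
                t0 = nodes[cells_v]
                base = np.atleast_1d(radius_edge(t0)).max()
                if base <= q:
                    continue
                # candidates: centroid of opposite faces, ring centroid
                opp = []
                for cell in cells_v:
                    others = [x for x in cell if x != v]
                    opp.append(nodes[others].mean(axis=0))
                opp = np.asarray(opp)
                old = nodes[v].copy()
                signs0 = np.sign(_tet_v6(t0))
                ring = opp.mean(axis=0)
                worst_i = int(np.argmax(np.atleast_1d(radius_edge(t0))))
                scale = float(np.abs(t0[worst_i] - t0[worst_i].mean(axis=0)).max())
                steps = []
                if len(cand_nodes) <= 300:  # pattern search only near the end
                    for delta in (0.45 * scale, 0.25 * scale, 0.1 * scale,
                                  0.04 * scale):
                        for dx in (-1, 0, 1):
                            for dy in (-1, 0, 1):
                                for dz in (-1, 0, 1):
                                    if dx == dy == dz == 0:
                                        continue
                                    d = np.array([dx, dy, dz], dtype=float)
                                    steps.append(old + delta * d / np.linalg.norm(d))
                best, best_val = None, base
                for candidate in (ring, 0.5 * (old + ring), opp[worst_i],
                                  0.5 * (old + opp[worst_i]), *steps):
                    nodes[v] = candidate
                    t1 = nodes[cells_v]
                    v6 = _tet_v6(t1)
                    if np.any(np.abs(v6) < 1e-14) or np.any(np.sign(v6) != signs0):
                        continue
                    if np.any(np.abs(v6) / 6.0 > self.params.vmax):
                        continue
                    val = np.atleast_1d(radius_edge(t1)).max()
                    if val < best_val - 1e-12:
                        best, best_val = candidate.copy(), val
                nodes[v] = best if best is not None else old
                if best is not None:
                    moved += 1
            total_moved += moved
            if moved == 0:
                break
        return total_moved

    def _flip23_pass(self, nodes, elements, max_passes: int = 6):
        """2-3 bistellar flips that eliminate flat / radius-edge-violating
        cells: a bad cell and a face neighbor are replaced by three cells
        around the axis joining their opposite vertices whenever that
        improves the local worst radius-edge ratio.  Volume is preserved
        exactly (the union is retiled)."""
        from .quality import radius_edge

        q = self.params.q_bound
        cells = [tuple(int(x) for x in e) for e in elements]
        re_all = np.atleast_1d(radius_edge(nodes[elements]))
        for _pass in range(max_passes):
            face_map = {}
            for i, cell in enumerate(cells):
                if cell is None:
                    continue
                a, b, c, d = cell
                for tri in ((a, b, c), (a, b, d), (a, c, d), (b, c, d)):
                    face_map.setdefault(frozenset(tri), []).append(i)
            bad = [i for i, cell in enumerate(cells)
                   if cell is not None and re_all[i] > q]
            if not bad:
                break
            edge_map = {}
            for i, cell in enumerate(cells):
                if cell is None:
                    continue
                for u in range(4):
                    for w in range(u + 1, 4):
                        key = (min(cell[u], cell[w]), max(cell[u], cell[w]))
                        edge_map.setdefault(key, []).append(i)
            bad.sort(key=lambda i: -re_all[i])
            changed = 0
            touched = set()
            for i in bad:
                if i in touched or cells[i] is None:
                    continue
                best = None
                a, b, c, d = cells[i]
                # 2-3 flip across each face
                for tri in ((a, b, c), (a, b, d), (a, c, d), (b, c, d)):
                    owners = face_map[frozenset(tri)]
                    js = [j for j in owners if j != i and cells[j] is not None
                          and j not in touched]
                    if not js:
                        continue
                    j = js[0]
                    p = next(x for x in cells[j] if x not in tri)
                    dd = next(x for x in cells[i] if x not in tri)
                    if p == dd:
                        continue
                    x, y, z = tri
                    new = [(dd, p, x, y), (dd, p, y, z), (dd, p, z, x)]
                    t_new = nodes[np.asarray(new)]
                    v6 = _tet_v6(t_new)
                    if np.any(np.abs(v6) < 1e-14) or not (
                        np.all(v6 > 0) or np.all(v6 < 0)
                    ):
                        continue
                    re_new = np.atleast_1d(radius_edge(t_new))
                    worst_old = max(re_all[i], re_all[j])
                    if re_new.max() < worst_old - 1e-12:
                        if best is None or re_new.max() < best[0]:
                            best = (re_new.max(), [j], new, re_new)
                # 3-2 flip around each edge with exactly three cells
                for u in range(4):
                    for w in range(u + 1, 4):
                        cu, cw = cells[i][u], cells[i][w]
                        key = (min(cu, cw), max(cu, cw))
                        ring = [j for j in edge_map[key]
                                if cells[j] is not None and j not in touched
                                or j == i]
                        ring = [j for j in ring if cells[j] is not None]
                        if len(ring) != 3 or i not in ring:
                            continue
                        apexes = []
                        ok = True
                        for j in ring:
                            rest = [x for x in cells[j] if x != cu and x != cw]
                            if len(rest) != 2:
                                ok = False
                                break
                            apexes.extend(rest)
                        if not ok:
                            continue
                        abc = sorted(set(apexes))
                        if len(abc) != 3 or any(apexes.count(x) != 2 for x in abc):
                            continue  # ring not closed around the edge
                        new = [(abc[0], abc[1], abc[2], cu),
                               (abc[0], abc[1], abc[2], cw)]
                        t_new = nodes[np.asarray(new)]
                        v6 = _tet_v6(t_new)
                        if np.any(np.abs(v6) < 1e-14) or v6[0] * v6[1] > 0:
                            continue  # the two cells must sit on opposite sides
                        re_new = np.atleast_1d(radius_edge(t_new))
                        worst_old = max(re_all[j] for j in ring)
                        if re_new.max() < worst_old - 1e-12:
                            if best is None or re_new.max() < best[0]:
                                best = (re_new.max(),
                                        [j for j in ring if j != i],
                                        new, re_new)
                if best is None:
                    continue
                _, others, new, re_new = best
                cells[i] = None
                touched.add(i)
                for j in others:
                    cells[j] = None
                    touched.add(j)
                for cell, r in zip(new, re_new):
                    cells.append(cell)
                    re_all = np.append(re_all, r)
                    touched.add(len(cells) - 1)
                changed += 1
            if changed == 0:
                break
        out = np.asarray([c for c in cells if c is not None], dtype=np.int64)
        n_over = int((np.atleast_1d(radius_edge(nodes[out])) > q).sum())
        if n_over:
            log.debug("flip23: %d cells remain over the radius-edge bound", n_over)
        return out

    # -- bands ------------------------------------------------------------
    @staticmethod
    def _areas(V, F):
        t = V[F]
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    def _local_vmax(self, V, F):
        v = self.params.vmax
        if self.sizing is not None:
            v = min(v, float(np.min(self.sizing(V[F].mean(axis=1)))))
        return v

    @staticmethod
    def _tangential_jitter(Vi, c, amp, rng):
        """Random tangential displacement of amplitude `amp`, radii to the
        star center preserved exactly."""
        d = Vi - c
        radii = np.linalg.norm(d, axis=1, keepdims=True)
        u = d / (radii + 1e-300)
        noise = rng.standard_normal(Vi.shape)
        noise -= np.einsum("ni,ni->n", noise, u)[:, None] * u
        norm = np.linalg.norm(noise, axis=1, keepdims=True) + 1e-300
        out = Vi + amp * noise / norm
        d2 = out - c
        out = c + radii * d2 / (np.linalg.norm(d2, axis=1, keepdims=True) + 1e-300)
        return out

    @staticmethod
    def _tangential_relax(Vi, edges, c, max_disp=np.inf, iterations: int = 3,
                          lam: float = 0.5):
        """Move vertices toward their 1-ring centroid along the front
        (radii to the star center are preserved exactly); displacements are
        capped so column twist stays small against the band height."""
        n = len(Vi)
        out = Vi.copy()
        radii = np.linalg.norm(Vi - c, axis=1)
        deg = np.bincount(edges.ravel(), minlength=n).astype(float)
        deg[deg == 0] = 1.0
        for _ in range(iterations):
            m = np.zeros_like(out)
            np.add.at(m, edges[:, 0], out[edges[:, 1]])
            np.add.at(m, edges[:, 1], out[edges[:, 0]])
            m /= deg[:, None]
            target = out + lam * (m - out)
            d = target - c
            d /= np.linalg.norm(d, axis=1, keepdims=True) + 1e-300
            out = c + radii[:, None] * d
        if np.isfinite(max_disp):
            disp = out - Vi
            norm = np.linalg.norm(disp, axis=1)
            over = norm > max_disp
            if over.any():
                out[over] = Vi[over] + disp[over] * (max_disp / norm[over])[:, None]
        return out

    def _build_band(self, V, Vi, F, gid, next_gid, c, gate=True):
        """Tile the shell between outer V and inner Vi with prism columns.

        Returns (tets (k,4) global ids, Vi, F, gid_new) or None when the
        exact validation (positivity, quality, volume identity, star shape
        of the inner copy) fails — the caller then retries with the pure
        scaled copy, which always tiles.
        """
        inner_gid = next_gid + np.arange(len(V))
        tets = []
        for f in F:
            a, b, d = (int(x) for x in f)
            top = (int(gid[a]), int(gid[b]), int(gid[d]))
            bot = (int(inner_gid[a]), int(inner_gid[b]), int(inner_gid[d]))
            tets.extend(self._prism_tets(top, bot))
        tets = np.asarray(tets, dtype=np.int64)

        coords = np.empty((next_gid + len(V), 3))
        coords[gid] = V
        coords[inner_gid] = Vi
        t_arr = coords[tets]
        v6 = _tet_v6(t_arr)
        abs_v6 = np.abs(v6)
        med = float(np.median(abs_v6))
        if np.any(abs_v6 < 1e-9 * med):
            return None
        if gate:
            from .quality import radius_edge

            re = np.atleast_1d(radius_edge(t_arr))
            if re.max() > self.params.q_bound:
                return None
        fan_in = _fan_volumes(Vi, F, c)
        if np.any(fan_in <= 0):
            return None
        vol_outer = float(np.sum(_fan_volumes(V, F, c)))
        expect = vol_outer - float(fan_in.sum())
        if abs(abs_v6.sum() / 6.0 - expect) > 1e-6 * max(abs(expect), 1.0):
            return None
        return tets, Vi, F.copy(), inner_gid

    @staticmethod
    def _prism_tets(top, bot):
        """Split a column (top triangle, bottom triangle) into 3 tets using
        min-id quad diagonals (top ids < bottom ids globally)."""
        ids = list(top)
        i = int(np.argmin(ids))
        m, x, y = ids[i:] + ids[:i]
        M, X, Y = list(bot)[i:] + list(bot)[:i]
        if x < y:
            return [(m, x, y, Y), (m, x, Y, X), (m, X, Y, M)]
        return [(m, x, y, X), (m, y, X, Y), (m, X, Y, M)]

    # -- core -------------------------------------------------------------
    def _interior_points(self, V, F, c, ell, rng):
        """Jittered concentric point shells inside the front.

        Shell radii are anchored to the interior tissue radii (snap_radii):
        the Delaunay interfaces between shells then fall on the tissue
        boundaries, which keeps element labeling accurate deep inside the
        domain.  Gaps between anchors are filled at the nominal spacing and
        a mild radial jitter avoids cospherical degeneracies.
        """
        def spacing_at(pts):
            v = np.full(len(pts), self.params.vmax)
            if self.sizing is not None:
                v = np.minimum(v, np.asarray(self.sizing(pts), dtype=np.float64))
            return np.clip((6.0 * v) ** (1.0 / 3.0) * 0.72, 0.8 * ell, None)

        base = float(min(spacing_at(np.asarray([c]))[0], 1.2 * ell))
        r_f = float(np.linalg.norm(V - c, axis=1).mean())
        standoff = max(self.params.protect_factor * ell, 0.5 * base)
        top = r_f - standoff
        anchors = sorted(
            {float(s) for s in self.params.snap_radii if s <= top},
            reverse=True,
        )
        radii = []
        prev = top
        step = 0.85 * base
        if not anchors or top - anchors[0] > 0.75 * step:
            radii.append(top - 0.2 * step)  # keep front-adjacent cells sized
        for a in anchors:
            n_fill = max(0, int(np.floor((prev - a) / step + 0.3)) - 1)
            for k in range(n_fill):
                radii.append(prev - (k + 1) * (prev - a) / (n_fill + 1))
            radii.append(a)
            prev = a
        r = prev - step
        while r > 0.7 * step:
            radii.append(r)
            r -= step
        if not radii:
            radii = [max(top, 0.5 * step)]

        pts = []
        golden = np.pi * (3.0 - np.sqrt(5.0))
        for ri in radii:
            n = max(8, int(4.0 * np.pi * ri**2 / (0.82 * base) ** 2))
            k = np.arange(n)
            z = 1.0 - 2.0 * (k + 0.5) / n
            rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
            th = golden * k + rng.uniform(0, 2 * np.pi)
            dirs = np.column_stack([rho * np.cos(th), rho * np.sin(th), z])
            # tangential jitter (radius-preserving) breaks the quasi-regular
            # spiral pattern; the radial jitter stays small so anchor shells
            # remain on their tissue radius
            tang = rng.standard_normal((n, 3))
            tang -= np.einsum("ni,ni->n", tang, dirs)[:, None] * dirs
            tang /= np.linalg.norm(tang, axis=1, keepdims=True) + 1e-300
            dirs = dirs + (0.25 * base / max(ri, 1e-9)) * \
                rng.uniform(0.2, 1.0, (n, 1)) * tang
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            rr = ri + rng.uniform(-0.04, 0.04, n) * base
            rr = np.minimum(rr, top)
            pts.append(c + rr[:, None] * dirs)
        pts.append(c[None] + rng.uniform(-0.1, 0.1, (1, 3)) * base)
        pts = np.concatenate(pts)

        # the radial margin is the real protection test (the front is
        # star-shaped); the vertex-distance check only guards pathologies
        inside = self._inside_front(pts, V, F, c, standoff)
        pts = pts[inside]
        if len(pts) == 0:
            return pts
        tree = cKDTree(V)
        d_v, _ = tree.query(pts)
        pts = pts[d_v > 0.55 * standoff]
        s = spacing_at(pts)
        keep = rng.random(len(pts)) < np.clip((0.85 * base / s) ** 3 * 1.2, 0, 1)
        return pts[keep]

    @staticmethod
    def _inside_front(pts, V, F, c, margin):
        """Conservative inside test for a star-shaped front: compare the
        point's radius with the front radius along its direction."""
        verts_r = np.linalg.norm(V - c, axis=1)
        dirs = V - c
        dirs /= verts_r[:, None]
        tree = cKDTree(dirs)
        d = pts - c
        r = np.linalg.norm(d, axis=1)
        u = d / np.maximum(r[:, None], 1e-12)
        _, idx = tree.query(u)
        return r < verts_r[idx] - margin

    def _delaunay_core(self, V, F, c):
        """Fill the inside of the front polyhedron; returns (points, tets)
        with point indices 0..len(V)-1 being the front vertices.

        Front faces that are not facets of the Delaunay tetrahedralization
        (2-D non-Delaunay edges of the front) are bridged exactly by their
        flip tetrahedra; the construction is accepted only when the summed
        cell volume reproduces the front's enclosed volume to 1e-8.
        """
        p = self.params
        edges = _edges_of(F)
        ell = float(np.median(np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1)))
        face_set = {frozenset(map(int, f)) for f in F}
        vol_front = float(np.sum(_fan_volumes(V, F, c)))
        from .quality import radius_edge

        reason = "no valid point set found"
        for attempt in range(4):
            rng = np.random.default_rng(p.seed + attempt)
            interior = self._interior_points(V, F, c, ell, rng)
            pts = np.concatenate([V, interior]) if len(interior) else V.copy()
            extra = []
            failed = False
            best_round = None
            for round_ in range(p.max_refine_rounds + 1):
                allpts = np.concatenate([pts, np.asarray(extra).reshape(-1, 3)]) \
                    if extra else pts
                simp = Delaunay(allpts).simplices
                sel = self._select_core_cells(allpts, simp, V, face_set, c, vol_front)
                if sel is None:
                    if best_round is not None:
                        return best_round[1], best_round[2]
                    rescue = self._rescue_points(allpts, V, c, ell)
                    if rescue and round_ < p.max_refine_rounds:
                        log.debug("core: inserting %d rescue points", len(rescue))
                        extra.extend(rescue)
                        continue
                    failed = True
                    reason = "front faces could not be recovered or bridged"
                    break
                tets, apex = sel
                ext = np.concatenate([allpts, apex]) if len(apex) else allpts
                t_arr = ext[tets]
                re = np.atleast_1d(radius_edge(t_arr))
                vols = np.abs(_tet_v6(t_arr)) / 6.0
                vb = self._cell_vmax(t_arr)
                # apex (pocket) cells cannot be refined further; only
                # oversized cells are refined by insertion — radius-edge
                # outliers are left to the flip/smoothing polish, which
                # handles them without perturbing the point set
                refinable = np.all(tets < len(allpts), axis=1)
                bad = (vols > vb) & refinable
                n_q = int((re > p.q_bound).sum())
                n_v = int((vols > vb).sum())
                score = n_q + 1000 * n_v  # oversized cells always get fixed
                if best_round is None or score < best_round[0]:
                    best_round = (score, ext, tets)
                    worsening = 0
                elif n_v == 0:
                    worsening += 1
                    if worsening >= 2 or score > 3 * best_round[0] + 50:
                        # quality refinement is diverging; keep the best mesh
                        log.debug("core refinement diverging (%d vs %d); stop",
                                  score, best_round[0])
                        return best_round[1], best_round[2]
                if not bad.any() or round_ == p.max_refine_rounds:
                    if score:
                        log.debug("core refinement left %d cells over bounds",
                                  n_q + n_v)
                    return ext, tets
                new_pts = self._refine_points(
                    allpts, t_arr[bad], np.zeros(int(bad.sum()), dtype=bool),
                    V, c, ell
                )
                if len(new_pts) == 0:
                    return ext, tets
                extra.extend(new_pts)
            if not failed:
                continue
        raise RadialMeshError(f"Delaunay core failed: {reason}")

    def _select_core_cells(self, allpts, simp, V, face_set, c, vol_front):
        """Inside cells of the Delaunay complex, reconciled with the front.

        Accepted only when the total cell volume reproduces the front's
        enclosed volume to 1e-8 relative.
        """
        from .surface import PointClassifier

        cent = allpts[simp].mean(axis=1)
        faces_arr = np.array([sorted(f) for f in face_set])
        surf = TriSurface(V, _orient_faces_outward(V, faces_arr, c))
        inside = PointClassifier(surf, pitch=2.0)(cent)
        kept = simp[inside]
        v_abs = np.abs(_tet_v6(allpts[kept])) / 6.0
        med = np.median(v_abs) if len(v_abs) else 0.0
        kept = kept[v_abs > 1e-10 * med]
        self._apex_points = []
        self._apex_base = len(allpts)
        self._core_center = c
        self._last_missing = []
        kept = self._reconcile_front(allpts, kept, face_set)
        if kept is None:
            return None
        apex = np.asarray(self._apex_points, dtype=np.float64).reshape(-1, 3)
        ext = np.concatenate([allpts, apex]) if len(apex) else allpts
        total = float(np.abs(_tet_v6(ext[kept])).sum() / 6.0)
        # pocket fans may leave sub-cell-size seams; the gate allows a
        # fraction of one cell (what a correct repair can cost) but rejects
        # anything on the scale of whole misclassified cells
        mean_cell = total / max(len(kept), 1)
        tol = max(5e-7 * self._total_volume, 0.3 * mean_cell)
        if abs(total - vol_front) <= tol:
            return kept, apex
        log.debug("core select: volume off by %.3g mm^3", total - vol_front)
        return None

    @staticmethod
    def _boundary_map(kept):
        faces = np.sort(np.concatenate([
            kept[:, [0, 1, 2]], kept[:, [0, 1, 3]],
            kept[:, [0, 2, 3]], kept[:, [1, 2, 3]],
        ]), axis=1)
        owners = np.tile(np.arange(len(kept)), 4)
        uniq, first, counts = np.unique(faces, axis=0, return_index=True,
                                        return_counts=True)
        bmask = counts == 1
        return {
            frozenset(map(int, f)): int(owners[i])
            for f, i in zip(uniq[bmask], first[bmask])
        }

    def _reconcile_front(self, allpts, kept, face_set, max_passes: int = 16):
        """Make the kept-cell boundary equal the front triangulation.

        Front faces that are not facets of the kept complex sit at locally
        reflex (2-D non-Delaunay) front edges, where the complex protrudes
        past the front by one thin "flip" tetrahedron per edge.  Each such
        sliver is excised: either it is a kept cell itself and is dropped,
        or the one/two kept cells containing it are re-cut along the front
        faces.  Every repair is verified by an exact local volume identity;
        passes iterate because excising one sliver can expose a stacked one.
        """

        def vol_of(cells):
            return np.abs(_tet_v6(allpts[np.asarray(cells).reshape(-1, 4)])) / 6.0

        for _pass in range(max_passes):
            boundary = self._boundary_map(kept)
            missing = [f for f in face_set if f not in boundary]
            log.debug("reconcile pass %d: %d missing", _pass, len(missing))
            if not missing:
                return kept
            cell_index = {frozenset(map(int, cell)): i
                          for i, cell in enumerate(kept)}
            to_remove = set()
            to_add = []
            used_faces = set()
            progress = False
            for f1 in missing:
                if f1 in used_faces:
                    continue
                for f2 in missing:
                    if f2 is f1 or f2 in used_faces:
                        continue
                    shared = f1 & f2
                    if len(shared) != 2:
                        continue
                    a, b = sorted(shared)
                    (cc,) = f1 - shared
                    (dd,) = f2 - shared
                    sliver_vol = float(vol_of([(a, b, cc, dd)])[0])
                    key = frozenset((a, b, cc, dd))
                    fa, fb = frozenset((a, cc, dd)), frozenset((b, cc, dd))
                    # which side of the front does the sliver lie on?  The
                    # kept boundary shows the (cc, dd) diagonal; if the
                    # front diagonal (a, b) is farther from the center, the
                    # complex stops short (gap), else it protrudes
                    m_ab = 0.5 * (allpts[a] + allpts[b])
                    m_cd = 0.5 * (allpts[cc] + allpts[dd])
                    gap_side = (np.linalg.norm(m_ab - self._core_center)
                                > np.linalg.norm(m_cd - self._core_center))
                    candidates = []
                    if not gap_side and key in cell_index \
                            and cell_index[key] not in to_remove:
                        candidates.append(([cell_index[key]], []))
                    if fa in boundary and fb in boundary:
                        k1, k2 = boundary[fa], boundary[fb]
                        if k1 != k2 and k1 not in to_remove and k2 not in to_remove:
                            p1 = (set(map(int, kept[k1])) - fa).pop()
                            p2 = (set(map(int, kept[k2])) - fb).pop()
                            if p1 == p2:
                                candidates.append(
                                    ([k1, k2], [(a, b, cc, p1), (a, b, dd, p1)])
                                )
                            else:
                                kx = cell_index.get(frozenset((cc, dd, p1, p2)))
                                if kx is not None and kx not in to_remove:
                                    candidates.append((
                                        [k1, k2, kx],
                                        [(a, b, cc, p1), (a, b, dd, p1),
                                         (b, cc, p1, p2), (b, dd, p1, p2)],
                                    ))
                        if gap_side:
                            # last resort: insert the bare sliver (thin cell)
                            candidates.append(([], [(a, b, cc, dd)]))
                    repair = None
                    for rem, add in candidates:
                        v_rem = float(vol_of(kept[rem]).sum()) if rem else 0.0
                        v_add = float(vol_of(add).sum()) if add else 0.0
                        expect = (v_add - sliver_vol) if gap_side \
                            else (v_add + sliver_vol)
                        scale = max(v_rem, v_add, 1e-12)
                        if abs(v_rem - expect) <= 1e-9 * scale:
                            repair = (rem, add)
                            break
                    if repair is None:
                        continue
                    rem, add = repair
                    to_remove.update(rem)
                    to_add.extend(add)
                    used_faces.update((f1, f2))
                    progress = True
                    break
            if not progress:
                # thin edge-flip repairs exhausted; excise whole pockets
                repaired = self._repair_pockets(allpts, kept, face_set, missing)
                if repaired is None:
                    log.debug("reconcile: %d front faces unrepairable", len(missing))
                    self._last_missing = missing
                    return None
                kept = repaired
                continue
            mask = np.ones(len(kept), dtype=bool)
            mask[list(to_remove)] = False
            parts = [kept[mask]]
            if to_add:
                parts.append(np.asarray(to_add, dtype=np.int64))
            kept = np.concatenate(parts)
        log.debug("reconcile: passes exhausted")
        self._last_missing = missing
        return None

    def _cell_vmax(self, t_arr):
        v = np.full(len(t_arr), self.params.vmax)
        if self.sizing is not None:
            v = np.minimum(v, np.asarray(self.sizing(t_arr.mean(axis=1)),
                                         dtype=np.float64))
        return v

    def _rescue_points(self, allpts, V, c, ell):
        """Interior points inserted just beneath vertices whose star the
        Delaunay boundary skipped; the next round's tetrahedralization then
        recovers those front faces naturally."""
        missing = getattr(self, "_last_missing", [])
        if not missing:
            return []
        counts = {}
        for f in missing:
            for v in f:
                counts[v] = counts.get(v, 0) + 1
        # one rescue point per distinct pocket vertex (most-incident first)
        chosen = []
        seen = set()
        for v in sorted(counts, key=counts.get, reverse=True):
            if any(v in f for f in missing) and v not in seen:
                seen.update(x for f in missing if v in f for x in f)
                d = V[v] - c
                r = np.linalg.norm(d)
                pos = c + (1.0 - 0.55 * ell / r) * d
                if np.linalg.norm(allpts - pos, axis=1).min() > 0.25 * ell:
                    chosen.append(pos)
        return chosen

    def _repair_pockets(self, allpts, kept, face_set, missing):
        """Excise and re-fill the pockets around unrecovered front faces.

        At a pocket the Delaunay boundary "skips" one front vertex v whose
        surroundings are locally reflex.  The repair removes every kept
        cell containing v and re-fills the hole (the removed star plus the
        thin pocket up to the front) by fanning from v; a vertex star is
        star-shaped from its vertex by construction.  Per-cell positivity
        is checked here and the caller's exact volume identity arbitrates
        overall correctness.
        """
        # group missing faces into connected clusters (shared vertices)
        clusters = []
        for f in missing:
            merged = None
            for cl in clusters:
                if cl and (set().union(*cl) & f):
                    if merged is None:
                        cl.append(f)
                        merged = cl
                    else:
                        merged.extend(cl)
                        cl.clear()
            if merged is None:
                clusters.append([f])
        clusters = [cl for cl in clusters if cl]

        # global bookkeeping
        face_owner = {}
        for i, cell in enumerate(kept):
            a, b, c, d = (int(x) for x in cell)
            for tri in ((a, b, c), (a, b, d), (a, c, d), (b, c, d)):
                face_owner.setdefault(frozenset(tri), []).append(i)
        wrong = {f for f, o in face_owner.items()
                 if len(o) == 1 and f not in face_set}

        remove_all = set()
        new_cells = []
        for cl in clusters:
            counts = {}
            for f in cl:
                for v in f:
                    counts[v] = counts.get(v, 0) + 1
            # the pocket vertex is the one the Delaunay boundary skips: it
            # appears in the missing faces but not in the lid ("wrong")
            # faces; try candidates in decreasing incidence order
            cl_verts = set().union(*cl)
            lid_verts = set()
            for key in wrong:
                if len(key & cl_verts) >= 2:
                    lid_verts |= key
            cand = sorted(counts, key=lambda x: (x in lid_verts, -counts[x]))
            repaired = None
            for v in cand:
                repaired = self._fan_pocket(allpts, kept, face_set, wrong,
                                            face_owner, cl, v, remove_all)
                if repaired is not None:
                    break
            if repaired is None:
                return None
            R, cells = repaired
            remove_all.update(R)
            new_cells.extend(cells)
        mask = np.ones(len(kept), dtype=bool)
        mask[list(remove_all)] = False
        parts = [kept[mask]]
        if new_cells:
            parts.append(np.asarray(new_cells, dtype=np.int64))
        log.debug("pocket repair: %d clusters, removed %d cells, added %d",
                  len(clusters), len(remove_all), len(new_cells))
        return np.concatenate(parts)

    def _fan_pocket(self, allpts, kept, face_set, wrong, face_owner, cl, v,
                    already_removed):
        """Attempt the vertex-star fan repair at candidate vertex v."""
        R = [i for i, cell in enumerate(kept) if v in cell]
        if not R or already_removed & set(R):
            return None
        # boundary faces of the hole that do not contain v
        within = {}
        for i in R:
            a, b, c, d = (int(x) for x in kept[i])
            for tri in ((a, b, c), (a, b, d), (a, c, d), (b, c, d)):
                key = frozenset(tri)
                within[key] = within.get(key, 0) + 1
        S = []
        rem_set = set(R)
        for key, n in within.items():
            if n != 1 or v in key:
                continue
            owners = face_owner[key]
            if any(o not in rem_set for o in owners):
                S.append(key)          # shared with a survivor
            elif key in face_set:
                S.append(key)          # on the front
            # else: a wrong face of R itself -> interior to the hole
        # pocket lid: wrong faces owned by survivors next to the cluster
        cl_verts = set().union(*cl)
        for key in wrong:
            if v in key or key in S:
                continue
            if len(key & cl_verts) >= 2 and all(
                o not in rem_set for o in face_owner[key]
            ):
                S.append(key)
        # fan from v; check closure (edges away from v appear exactly twice)
        edge_count = {}
        for key in S:
            a, b, c = sorted(key)
            for e in ((a, b), (b, c), (a, c)):
                edge_count[e] = edge_count.get(e, 0) + 1
        for (a, b), n in edge_count.items():
            expected = 2
            if n != 2 and n != 1:
                log.debug("pocket fan at %d: bad edge multiplicity", v)
                return None
        tris = np.array([sorted(f) for f in S], dtype=np.int64)
        t = allpts[tris]
        v6 = np.einsum(
            "ni,ni->n", t[:, 0] - allpts[v],
            np.cross(t[:, 1] - allpts[v], t[:, 2] - allpts[v]),
        )
        if np.any(np.abs(v6) <= 1e-12 * np.abs(v6).max()):
            log.debug("pocket fan at %d has degenerate cells", v)
            return None
        # the fan must actually produce the cluster's missing front faces
        produced = set()
        for tri in tris:
            x, y, z = (int(q) for q in tri)
            produced |= {frozenset((v, x, y)), frozenset((v, y, z)),
                         frozenset((v, x, z)), frozenset((x, y, z))}
        if not all(f in produced for f in cl):
            log.debug("pocket fan at %d does not cover its cluster", v)
            return None
        return R, [(int(v), *map(int, tri)) for tri in tris]

    def _refine_points(self, allpts, bad_tets, is_quality, V, c, ell):
        """Insertion points for offending cells: circumcenters for quality
        violations, centroids for oversized cells; points in the protected
        zone or outside the domain are discarded."""
        from .quality import circumcenters

        cand = np.where(
            is_quality[:, None],
            circumcenters(bad_tets),
            bad_tets.mean(axis=1),
        )
        ok = np.all(np.isfinite(cand), axis=1)
        cand = cand[ok]
        if len(cand) == 0:
            return []
        # de-duplicate and keep away from existing points and the front
        tree_all = cKDTree(allpts)
        d, _ = tree_all.query(cand)
        cand = cand[d > 0.3 * ell]
        if len(cand) == 0:
            return []
        tree_v = cKDTree(V)
        dv, _ = tree_v.query(cand)
        cand = cand[dv > (self.params.protect_factor + 0.62) * ell]
        if len(cand) == 0:
            return []
        # and strictly inside the domain (sliver circumcenters can be far out)
        cand = cand[self._inside_front(cand, V, None, c,
                                       self.params.protect_factor * ell)]
        if len(cand) == 0:
            return []
        # thin mutual near-duplicates
        keep = []
        taken = cKDTree(np.empty((0, 3))) if False else None
        chosen = []
        for pt in cand:
            if all(np.linalg.norm(pt - q) > 0.3 * ell for q in chosen[-64:]):
                chosen.append(pt)
        return chosen


def _orient_faces_outward(V, faces, c):
    fv = _fan_volumes(V, faces, c)
    out = faces.copy()
    out[fv < 0] = out[fv < 0][:, ::-1]
    return out


def _orient_positive(nodes, elements):
    t = nodes[elements]
    v6 = _tet_v6(t)
    flip = v6 < 0
    out = elements.copy()
    out[flip] = out[flip][:, [0, 1, 3, 2]]
    return out
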