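"""Closed-form and invariance checks for the mesh-quality metrics."""

import json

import numpy as np
import pytest

from headmesher.grid import TissueStack, VolumeGrid
from headmesher.quality import (joe_liu, qc_report, radius_edge, tet_volumes,
                                v_rel)
from headmesher.surface import TriSurface
from headmesher.tetmesh import TetMesh

REGULAR = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
)  # regular tetrahedron, edge 2*sqrt(2)
RIGHT_CORNER = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


def joe_liu_reference(t):
    """Independent re-implementation: quality = 12 (3V)^(2/3) / sum l^2."""
    a, b, c, d = np.asarray(t, dtype=float)
    vol = abs(np.dot(b - a, np.cross(c - a, d - a))) / 6.0
    ssq = sum(
        np.sum((p - q) ** 2)
        for i, p in enumerate((a, b, c, d))
        for q in (a, b, c, d)[i + 1:]
    )
    return 12.0 * (3.0 * vol) ** (2.0 / 3.0) / ssq


class TestJoeLiu:
    def test_regular_tet_scores_one(self):
        for scale in (1.0, 0.01, 37.5):
            assert joe_liu(REGULAR * scale) == pytest.approx(1.0, abs=1e-12)

    def test_coplanar_is_zero(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        assert joe_liu(flat) == 0.0
        assert joe_liu(np.zeros((4, 3))) == 0.0  # coincident points

    def test_matches_independent_implementation(self, rng):
        tets = rng.normal(size=(200, 4, 3))
        got = joe_liu(tets)
        want = np.array([joe_liu_reference(t) for t in tets])
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_rigid_motion_and_scale_invariance(self, rng):
        tets = rng.normal(size=(50, 4, 3))
        base = joe_liu(tets)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = tets @ q.T * 3.7 + rng.normal(size=3)
        np.testing.assert_allclose(joe_liu(moved), base, rtol=1e-10)


class TestRadiusEdge:
    def test_regular_tet_closed_form(self):
        assert radius_edge(REGULAR) == pytest.approx(np.sqrt(6) / 4, abs=1e-9)

    def test_right_corner_tet(self):
        # circumradius sqrt(3)/2, shortest edge 1
        assert radius_edge(RIGHT_CORNER) == pytest.approx(0.8660254, abs=1e-7)

    def test_degenerate_is_infinite(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        assert np.isinf(radius_edge(flat))

    def test_circumcenter_equidistance(self, rng):
        from headmesher.quality import circumcenters

        tets = rng.normal(size=(100, 4, 3))
        cc = circumcenters(tets)
        d = np.linalg.norm(tets - cc[:, None, :], axis=2)
        np.testing.assert_allclose(d, d[:, :1] * np.ones(4), rtol=1e-7)

    def test_invariance(self, rng):
        tets = rng.normal(size=(50, 4, 3))
        base = radius_edge(tets)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = tets @ q.T * 0.05 + 11.0
        np.testing.assert_allclose(radius_edge(moved), base, rtol=1e-8)


def _cube_stack_and_surface(n=20):
    """Axis-aligned cube occupying voxels [5,15) in a n^3 unit grid, plus the
    exactly matching boundary surface (voxel-exact correspondence)."""
    vals = np.zeros((n, n, n))
    vals[5:15, 5:15, 5:15] = 1.0
    grid = VolumeGrid(vals, spacing=1.0, kind="binary")
    stack = TissueStack(names=["cube"], grids=[grid.with_values(vals, "probability")])
    # voxel centers at integer indices => cube spans mm [4.5, 14.5]
    lo, hi = 4.5, 14.5
    corners = np.array(
        [[x, y, z] for x in (lo, hi) for y in (lo, hi) for z in (lo, hi)]
    )
    faces = np.array(
        [[0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5], [0, 4, 5], [0, 5, 1],
         [2, 3, 7], [2, 7, 6], [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3]]
    )
    surf = TriSurface(corners, faces, tag="cube").oriented_outward()
    return stack, surf


class TestVrel:
    def test_grid_aligned_cube_is_exactly_one(self):
        stack, surf = _cube_stack_and_surface()
        assert v_rel([surf], "cube", stack) == pytest.approx(1.0, abs=1e-9)

    def test_missing_tissue_raises(self):
        stack, surf = _cube_stack_and_surface()
        with pytest.raises(ValueError):
            v_rel([surf], "brain", stack)

    def test_mesh_volume_numerator(self):
        stack, surf = _cube_stack_and_surface()
        # two tets filling a known fraction of the cube volume
        nodes = np.array([[4.5, 4.5, 4.5], [14.5, 4.5, 4.5], [4.5, 14.5, 4.5],
                          [4.5, 4.5, 14.5]])
        mesh = TetMesh(nodes, [[0, 1, 2, 3]], [0], ["cube"])
        vol = tet_volumes(nodes[None, :, :])[0]
        assert v_rel(mesh, "cube", stack) == pytest.approx(vol / 1000.0, rel=1e-9)


class TestQcReport:
    def test_single_regular_tet(self):
        mesh = TetMesh(REGULAR, [[0, 1, 2, 3]], [0], ["wm"])
        rep = qc_report(mesh)
        assert rep.joe_liu_mean == pytest.approx(1.0, abs=1e-12)
        assert rep.joe_liu_min == pytest.approx(1.0, abs=1e-12)
        assert rep.radius_edge_max == pytest.approx(np.sqrt(6) / 4, abs=1e-9)

    def test_json_round_trip(self):
        mesh = TetMesh(REGULAR, [[0, 1, 2, 3]], [0], ["wm"])
        rep = qc_report(mesh)
        again = json.loads(rep.to_json())
        assert again == rep.to_dict()
        assert "Joe-Liu" in rep.to_markdown()
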