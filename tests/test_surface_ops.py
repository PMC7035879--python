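"""Surface extraction, smoothing, decimation, Booleans and rasterization."""

import numpy as np
import pytest
import trimesh

from headmesher.grid import VolumeGrid
from headmesher.phantoms import PRESETS, PhantomSpec, make_layered_phantom
from headmesher.surface import TriSurface, contains_points, surfaces_intersect
from headmesher.surface_ops import (SurfaceCriteria, boolean_union, decimate,
                                    error_summary, extract_isosurface,
                                    rasterize_surface, smooth,
                                    subtract_probability, surface_error)


def sphere_map(radius=20.0, n=56, spacing=1.0, sigma=1.0):
    c = (n - 1) / 2.0
    ax = np.arange(n) - c
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    rho = np.sqrt(X**2 + Y**2 + Z**2) * spacing
    from scipy.special import ndtr

    vals = ndtr((radius - rho) / sigma) if sigma > 0 else (rho <= radius).astype(float)
    return VolumeGrid(vals, spacing=spacing, kind="probability")


def icosphere(radius=20.0, subdivisions=3):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface(np.asarray(tm.vertices), np.asarray(tm.faces), tag="sphere")


class TestExtractIsosurface:
    def test_sphere_closed_genus0_volume(self):
        vol = sphere_map(20.0)
        surf = extract_isosurface(vol, SurfaceCriteria(rmax=2.0), "sphere")
        assert surf.is_closed_manifold()
        assert surf.euler_characteristic() == 2
        analytic = 4 / 3 * np.pi * 20**3
        assert surf.signed_volume() == pytest.approx(analytic, rel=0.03)
        assert surf.circumradii().max() <= 2.0 + 1e-9

    def test_empty_level_set_raises(self):
        vol = VolumeGrid(np.zeros((16, 16, 16)), kind="probability")
        with pytest.raises(ValueError, match="empty level set"):
            extract_isosurface(vol, SurfaceCriteria(rmax=2.0), "x")

    def test_keep_largest_removes_islands(self, five_layer):
        from headmesher.phantoms import add_noise_islands

        stack, _ = five_layer
        noisy = add_noise_islands(stack, 3, size=2, seed=11)
        # pick a tissue that received at least one island
        target = noisy.meta["islands"][0]["source"]
        vol = noisy[target]
        crit = SurfaceCriteria(rmax=2.0, keep_largest=True)
        surf = extract_isosurface(vol, crit, target)
        assert len(surf.split_components()) == 1

    def test_volume_conservation_through_extraction(self, five_layer):
        """Enclosed volume within 3% of the voxel-count volume at 1 mm."""
        stack, _ = five_layer
        for name, cum in zip(stack.names, stack.cumulative()):
            surf = extract_isosurface(cum, SurfaceCriteria(rmax=2.5), name)
            voxel = np.count_nonzero(cum.values >= 0.5) * stack.grid0.voxel_volume
            assert surf.signed_volume() == pytest.approx(voxel, rel=0.03)


class TestSmooth:
    def test_zero_iterations_identity(self):
        s = icosphere()
        out = smooth(s, "laplacian", 0)
        np.testing.assert_array_equal(out.vertices, s.vertices)

    def test_connectivity_preserved(self):
        s = icosphere()
        for method in ("laplacian", "laplacian_hc", "lowpass"):
            out = smooth(s, method, 5)
            np.testing.assert_array_equal(out.faces, s.faces)
            assert out.n_vertices == s.n_vertices

    def test_lowpass_resists_shrinkage(self):
        """Taubin smoothing keeps the volume of a noisy sphere within 2% of
        the clean one; plain Laplacian shrinks strictly more."""
        rng = np.random.default_rng(3)
        s = icosphere(20.0, 4)
        noisy_v = s.vertices * (
            1.0 + 0.025 * rng.standard_normal(s.n_vertices)[:, None]
        )
        noisy = TriSurface(noisy_v, s.faces, "noisy")
        clean_vol = s.signed_volume()
        taubin = smooth(noisy, "lowpass", 10).signed_volume()
        laplace = smooth(noisy, "laplacian", 10).signed_volume()
        assert taubin == pytest.approx(clean_vol, rel=0.02)
        assert taubin > laplace

    def test_planar_patch_stays_planar(self):
        """Interior vertices of a flat triangulated patch do not leave the
        plane (the 1-ring centroid of coplanar points is coplanar)."""
        n = 8
        xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
        patch = TriSurface(verts, np.asarray(faces), "patch")
        out = smooth(patch, "laplacian", 5)
        assert np.abs(out.vertices[:, 2]).max() < 1e-9

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            smooth(icosphere(), "magic", 3)


class TestDecimate:
    def test_keep_ratio_one_identity(self):
        s = icosphere()
        out = decimate(s, 1.0)
        assert out is s

    def test_edge_budget_and_manifoldness(self):
        s = icosphere(20.0, 4)
        out = decimate(s, 0.3)
        assert out.is_closed_manifold()
        assert out.n_edges == pytest.approx(0.3 * s.n_edges, rel=0.05)

    @staticmethod
    def dense_sphere(pitch=0.5, radius=20.0):
        from skimage import measure

        vol = sphere_map(radius, n=int(2 * (radius + 4) / pitch),
                         spacing=pitch, sigma=pitch)
        padded = np.pad(np.asarray(vol.values), 1)
        verts, faces, _, _ = measure.marching_cubes(padded, 0.5,
                                                    spacing=(pitch,) * 3)
        return TriSurface(verts, faces, "dense").oriented_outward()

    def test_error_bound_at_ratio_02(self):
        """Mean nearest-node error below 0.2 mm when keeping 20% of the
        edges of a dense sphere."""
        dense = self.dense_sphere()
        assert dense.n_edges > 40000
        out = decimate(dense, 0.2)
        err = surface_error(out, dense)
        assert err.mean() < 0.2

    def test_error_monotone_in_ratio(self):
        dense = self.dense_sphere(pitch=0.7)
        err_hi = surface_error(decimate(dense, 0.5), dense).mean()
        err_lo = surface_error(decimate(dense, 0.05), dense).mean()
        assert err_hi <= err_lo

    def test_too_small_ratio_raises(self):
        s = icosphere(5.0, 1)
        with pytest.raises(ValueError):
            decimate(s, 1e-4)


class TestSurfaceError:
    def test_identical_surfaces_zero(self):
        s = icosphere()
        assert surface_error(s, s).max() == 0.0

    def test_translation_bound(self):
        s = icosphere(20.0, 3)
        moved = TriSurface(s.vertices + [1.0, 0, 0], s.faces, "t")
        err = surface_error(moved, s)
        # nearest-node distance cannot exceed translation + sampling density
        spacing = np.median(s.edge_lengths())
        assert err.max() <= 1.0 + spacing
        assert err.min() >= 0.0

    def test_matches_brute_force(self, rng):
        a = TriSurface(rng.random((100, 3)) * 10, [[0, 1, 2]], "a")
        b = TriSurface(rng.random((80, 3)) * 10, [[0, 1, 2]], "b")
        got = surface_error(a, b)
        brute = np.min(
            np.linalg.norm(a.vertices[:, None] - b.vertices[None], axis=2), axis=1
        )
        np.testing.assert_allclose(got, brute, rtol=1e-12)

    def test_summary_fields(self, rng):
        d = rng.random(100)
        s = error_summary(d)
        assert s["q1"] <= s["median"] <= s["q3"] <= s["max"]


class TestBooleanUnion:
    def test_disjoint_spheres(self):
        a = icosphere(10.0, 3)
        b = TriSurface(icosphere(10.0, 3).vertices + [30.0, 0, 0],
                       a.faces, "b")
        u = boolean_union(a, b)
        assert len(u.split_components()) == 2
        expect = a.signed_volume() + b.signed_volume()
        assert u.signed_volume() == pytest.approx(expect, rel=0.005)

    def test_contained_sphere(self):
        a = icosphere(15.0, 3)
        b = icosphere(5.0, 2)
        u = boolean_union(a, b)
        assert u.signed_volume() == pytest.approx(a.signed_volume(), rel=0.005)

    def test_overlapping_spheres_lens_formula(self):
        r, d = 10.0, 15.0
        a = icosphere(r, 3)
        b = TriSurface(a.vertices + [d, 0, 0], a.faces, "b")
        u = boolean_union(a, b)
        lens = np.pi * (2 * r - d) ** 2 * (d**2 + 4 * d * r) / (12 * d)
        expect = 2 * (4 / 3 * np.pi * r**3) - lens
        assert u.signed_volume() == pytest.approx(expect, rel=0.01)

    def test_open_surface_rejected(self):
        s = icosphere(5.0, 1)
        open_surf = TriSurface(s.vertices, s.faces[:-2], "open")
        with pytest.raises(ValueError, match="closed"):
            boolean_union(open_surf, s)


class TestRasterize:
    def _grid(self, n=52):
        return VolumeGrid(np.zeros((n, n, n)), spacing=1.0,
                          origin=(-(n - 1) / 2.0,) * 3, kind="probability")

    def test_sphere_volume(self):
        s = icosphere(20.0, 3)
        mask = rasterize_surface(s, self._grid())
        vol = mask.values.sum() * mask.voxel_volume
        assert vol == pytest.approx(s.signed_volume(), rel=0.03)

    def test_axis_aligned_cube_exact(self):
        """A cube aligned to voxel boundaries rasterizes to exactly its
        interior voxel centers."""
        lo, hi = -5.5, 5.5  # voxel centers at integers => 11^3 inside
        corners = np.array([[x, y, z] for x in (lo, hi) for y in (lo, hi)
                            for z in (lo, hi)])
        faces = np.array(
            [[0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5], [0, 4, 5], [0, 5, 1],
             [2, 3, 7], [2, 7, 6], [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3]]
        )
        cube = TriSurface(corners, faces, "cube").oriented_outward()
        mask = rasterize_surface(cube, self._grid(31))
        assert mask.values.sum() == 11**3

    def test_agrees_with_containment_oracle(self, rng):
        s = icosphere(15.0, 3)
        mask = rasterize_surface(s, self._grid())
        pts = rng.uniform(-24, 24, size=(1000, 3))
        # exclude points within one voxel of the surface (discretization band)
        d_to_surf = np.abs(np.linalg.norm(pts, axis=1) - 15.0)
        keep = d_to_surf > 1.0
        got = mask.sample_nearest(pts[keep]) > 0.5
        want = contains_points(s, pts[keep])
        assert np.array_equal(got, want)

    def test_out_of_grid_rejected(self):
        s = icosphere(40.0, 2)
        with pytest.raises(ValueError, match="beyond"):
            rasterize_surface(s, self._grid(20))


class TestSubtract:
    def test_identity_and_annihilation(self, rng):
        p = VolumeGrid(rng.random((8, 8, 8)), kind="probability")
        zero = p.with_values(np.zeros(p.shape), kind="binary")
        np.testing.assert_array_equal(subtract_probability(p, zero).values, p.values)
        binary = p.with_values((p.values > 0.5).astype(np.uint8), kind="binary")
        both = subtract_probability(
            p.with_values((p.values > 0.5).astype(float)), binary
        )
        assert both.values.max() == 0.0

    def test_matches_formula(self, rng):
        p = VolumeGrid(rng.random((6, 6, 6)), kind="probability")
        m = VolumeGrid((rng.random((6, 6, 6)) > 0.5).astype(np.uint8), kind="binary")
        got = subtract_probability(p, m).values
        want = np.clip(p.values - m.values, 0, 1)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_shape_mismatch(self, rng):
        p = VolumeGrid(rng.random((6, 6, 6)), kind="probability")
        m = VolumeGrid(np.zeros((5, 5, 5), dtype=np.uint8), kind="binary")
        with pytest.raises(ValueError):
            subtract_probability(p, m)


def test_nested_surfaces_do_not_intersect(five_layer):
    """The pipeline's central geometric guarantee on the default phantom."""
    from headmesher.pipeline import DEFAULT_RMAX
    from headmesher.preprocess import build_layered_model

    stack, _ = five_layer
    model = build_layered_model(stack)
    surfs = []
    for name, vol in zip(model.names, model.extraction_volumes):
        surfs.append(
            extract_isosurface(vol, SurfaceCriteria(rmax=DEFAULT_RMAX[name]), name)
        )
    for s in surfs:
        s.validate()
        assert not surfaces_intersect(s)
    for inner, outer in zip(surfs, surfs[1:]):
        assert not surfaces_intersect(inner, outer)
        assert inner.signed_volume() < outer.signed_volume()
        assert contains_points(outer, inner.vertices[:25]).all()
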