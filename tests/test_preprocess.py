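"""Gap-insertion operators against independent brute-force oracles."""

import numpy as np
import pytest

from headmesher.grid import TissueStack, VolumeGrid
from headmesher.phantoms import PRESETS, PhantomSpec, make_layered_phantom
from headmesher.preprocess import (GapParams, build_layered_model, max_filter,
                                   min_filter, thicken, thin)


def brute_force_filter(vol, eps, op):
    """Reference neighborhood scan: per-voxel max/min over the clipped
    (2*eps+1)^3 Chebyshev window."""
    out = np.empty_like(vol, dtype=np.float64)
    nx, ny, nz = vol.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                w = vol[
                    max(i - eps, 0): i + eps + 1,
                    max(j - eps, 0): j + eps + 1,
                    max(k - eps, 0): k + eps + 1,
                ]
                out[i, j, k] = op(w)
    return out


@pytest.fixture(scope="module")
def random_volumes():
    rng = np.random.default_rng(42)
    vols = []
    for _ in range(50):
        shape = tuple(rng.integers(5, 13, size=3))
        vols.append(rng.random(shape))
    return vols


@pytest.mark.parametrize("eps", [1, 2, 3])
def test_max_min_filters_match_brute_force(random_volumes, eps):
    """Cubic max/min filters equal the voxelwise neighborhood scan exactly,
    including the shrinking window at grid borders."""
    for vol in random_volumes:
        np.testing.assert_array_equal(
            max_filter(vol, eps), brute_force_filter(vol, eps, np.max)
        )
        np.testing.assert_array_equal(
            min_filter(vol, eps), brute_force_filter(vol, eps, np.min)
        )


def test_filter_trivia():
    const = np.full((6, 6, 6), 0.7)
    np.testing.assert_array_equal(max_filter(const, 2), const)
    np.testing.assert_array_equal(min_filter(const, 2), const)

    spike = np.zeros((7, 7, 7))
    spike[3, 3, 3] = 1.0
    d = max_filter(spike, 1)
    expected = np.zeros_like(spike)
    expected[2:5, 2:5, 2:5] = 1.0
    np.testing.assert_array_equal(d, expected)

    hole = 1.0 - spike
    e = min_filter(hole, 1)
    np.testing.assert_array_equal(e, 1.0 - expected)

    with pytest.raises(ValueError):
        max_filter(spike, 0)


@pytest.mark.parametrize("eps", [1, 2])
def test_thicken_thin_match_formula(random_volumes, eps):
    """T+ / T- equal their voxelwise definitions on random probability pairs."""
    rng = np.random.default_rng(7)
    for vol in random_volumes[:10]:
        p_in = vol
        p_out = rng.random(vol.shape)
        got = thicken(p_out, p_in, eps)
        want = np.clip(
            np.maximum(p_in + p_out, brute_force_filter(p_in, eps, np.max)), 0, 1
        )
        np.testing.assert_allclose(got, want, atol=1e-12)

        got = thin(p_in, p_out, eps)
        union = np.clip(p_in + p_out, 0, 1)
        want = np.minimum(p_in, brute_force_filter(union, eps, np.min))
        np.testing.assert_allclose(got, want, atol=1e-12)


def test_thicken_identity_when_inner_empty():
    rng = np.random.default_rng(1)
    p_out = rng.random((6, 6, 6))
    np.testing.assert_allclose(thicken(p_out, np.zeros_like(p_out), 1), p_out)


def test_thicken_dilates_binary_spike():
    p_in = np.zeros((7, 7, 7))
    p_in[3, 3, 3] = 1.0
    out = thicken(np.zeros_like(p_in), p_in, 1)
    assert out[2:5, 2:5, 2:5].min() == 1.0
    assert out.sum() == 27.0


def test_thin_keeps_interior():
    """Where the union is 1 everywhere nearby, the inner map is untouched."""
    p_in = np.zeros((9, 9, 9))
    p_in[2:7, 2:7, 2:7] = 1.0
    p_out = 1.0 - p_in  # union == 1 everywhere
    np.testing.assert_array_equal(thin(p_in, p_out, 1), p_in)


def test_thin_recedes_at_union_boundary():
    """A binary inner region touching the union boundary recedes by exactly
    one voxel along the contact."""
    p_in = np.zeros((9, 9, 9))
    p_in[0:5, 2:7, 2:7] = 1.0  # touches the union boundary at i=4 face
    p_out = np.zeros_like(p_in)
    out = np.asarray(thin(p_in, p_out, 1))
    # interior erodes from every exposed side of the slab
    expected = brute_force_filter(p_in, 1, np.min)
    np.testing.assert_array_equal(out, expected)
    assert out.sum() < p_in.sum()


def test_containment_and_composition(random_volumes):
    """D_eps(P) >= P >= E_eps(P); D_1 o D_1 == D_2 away from borders."""
    for vol in random_volumes[:10]:
        up = np.asarray(max_filter(vol, 1))
        dn = np.asarray(min_filter(vol, 1))
        assert np.all(up >= vol) and np.all(vol >= dn)
        dd = np.asarray(max_filter(up, 1))
        d2 = np.asarray(max_filter(vol, 2))
        interior = (slice(2, -2),) * 3
        np.testing.assert_array_equal(dd[interior], d2[interior])


def test_gap_params_validation():
    with pytest.raises(ValueError):
        GapParams(epsilon=0)
    with pytest.raises(ValueError):
        GapParams(strategy={("a", "b"): "explode"})


class TestBuildLayeredModel:
    def test_separated_layers_unaltered(self, five_layer):
        """All interfaces are >= 2 voxels apart: gap insertion is a no-op
        and no altered voxels are recorded."""
        stack, _ = five_layer
        model = build_layered_model(stack, GapParams(epsilon=1))
        assert model.names == stack.names
        assert not model.altered_any().any()
        cums = stack.cumulative()
        for vol, cum in zip(model.extraction_volumes, cums):
            np.testing.assert_allclose(vol.values, cum.values, atol=1e-12)

    def test_nesting_invariant(self, merged_phantom):
        stack, _ = merged_phantom
        model = build_layered_model(stack, GapParams(epsilon=1))
        for a, b in zip(model.extraction_volumes, model.extraction_volumes[1:]):
            inner = a.values >= 0.5
            outer = b.values >= 0.5
            assert not np.any(inner & ~outer)

    def test_merged_boundary_thinned_locally(self, merged_phantom):
        """With the default thin-inner strategy the GM level set recedes in
        the merged cap only, and exactly those voxels are recorded."""
        stack, _ = merged_phantom
        model = build_layered_model(
            stack, GapParams(epsilon=1, strategy={("gm", "csf"): "thin_inner"})
        )
        altered = model.altered["gm"]
        assert altered.any()
        # altered voxels cluster in the polar cap (z > 0 half for this phantom)
        idx = np.argwhere(altered)
        center = (np.asarray(stack.grid0.shape) - 1) / 2
        assert np.all(idx[:, 2] > center[2])
        # locality: all altered voxels lie near the merged contact region,
        # i.e. near the CSF interface radius
        radii = np.linalg.norm(idx - center, axis=1)
        assert radii.min() > 30.0 and radii.max() < 34.5

    def test_empty_layer_skipped_with_warning(self):
        spec = PRESETS["five-layer"]
        stack, _ = make_layered_phantom(spec)
        grids = list(stack.grids)
        i = stack.names.index("csf")
        grids[i] = grids[i].with_values(np.zeros(stack.grid0.shape))
        broken = TissueStack(names=list(stack.names), grids=grids)
        with pytest.warns(UserWarning, match="csf"):
            model = build_layered_model(broken, GapParams())
        assert "csf" not in model.names
        assert len(model.names) == 4

    def test_cavity_carved_from_host_only(self, cavity_phantom):
        stack, _ = cavity_phantom
        model = build_layered_model(stack, GapParams())
        assert len(model.air) == 1
        host, q = model.air[0]
        assert host == "skull"
        cavity = q.values >= 0.5
        skull_idx = model.names.index("skull")
        skull_vol = model.extraction_volumes[skull_idx].values
        assert np.all(skull_vol[cavity] < 0.5)
        # outermost extraction volume still covers the cavity region
        assert np.all(model.extraction_volumes[-1].values[cavity] >= 0.5)
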