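"""Phantom generator against its analytic volume oracles."""

import numpy as np
import pytest

from headmesher.phantoms import (PRESETS, PhantomSpec, add_noise_islands,
                                 island_component_counts,
                                 make_layered_phantom)


class TestLayeredPhantom:
    def test_shell_volumes_match_analytic(self, five_layer):
        """Voxel-count volume of every shell within 3% of the closed form."""
        stack, analytic = five_layer
        for name in stack.names:
            voxel = stack.tissue_voxel_volume(name)
            assert voxel == pytest.approx(analytic[name], rel=0.03)

    def test_binary_and_blurred_level_sets_agree(self):
        """The 0.5-level enclosed volume is blur-invariant within 2%."""
        hard, _ = make_layered_phantom(PRESETS["five-layer-binary"])
        soft, _ = make_layered_phantom(PRESETS["five-layer"])
        for ch, cs in zip(hard.cumulative(), soft.cumulative()):
            vh = np.count_nonzero(ch.values >= 0.5)
            vs = np.count_nonzero(cs.values >= 0.5)
            assert vs == pytest.approx(vh, rel=0.02)

    def test_binary_maps_are_exclusive(self):
        stack, _ = make_layered_phantom(PRESETS["five-layer-binary"])
        total = sum(g.values.astype(float) for g in stack.grids)
        assert total.max() <= 1.0

    def test_merged_pair_shares_boundary(self, merged_phantom):
        """No voxel holds two tissues at >= 0.5, yet the merged pair's 0.5
        level sets are face-adjacent (zero-voxel gap) in the cap."""
        stack, _ = merged_phantom
        gm = stack["gm"].values >= 0.5
        csf = stack["csf"].values >= 0.5
        assert not np.any(gm & csf)
        # face adjacency: gm set dilated by one voxel meets the csf set
        from scipy import ndimage

        grown = ndimage.binary_dilation(gm)
        assert np.any(grown & csf)
        # and in the merged cap the *cumulative* boundaries coincide:
        # gm-cumulative reaches the csf interface radius
        cums = stack.cumulative()
        gm_cum = cums[stack.names.index("gm")].values >= 0.5
        idx = np.argwhere(gm_cum)
        center = (np.asarray(stack.grid0.shape) - 1) / 2.0
        rmax_gm = np.linalg.norm(idx - center, axis=1).max()
        assert rmax_gm > 32.0  # bulged to ~33 (base radius is 31)

    def test_merged_analytic_volumes_adjust(self, merged_phantom):
        stack, analytic = merged_phantom
        base = PRESETS["five-layer"].analytic_layer_volumes()
        assert analytic["gm"] > base["gm"]
        assert analytic["csf"] < base["csf"]
        assert analytic["gm"] + analytic["csf"] == pytest.approx(
            base["gm"] + base["csf"], rel=1e-9
        )
        for name in ("wm", "skull", "scalp"):
            assert analytic[name] == pytest.approx(base[name], rel=1e-9)

    def test_cavity_carved_and_reported(self, cavity_phantom):
        stack, analytic = cavity_phantom
        assert len(stack.air) == 1
        host, q = stack.air[0]
        assert host == "skull"
        assert analytic["cavity"] == pytest.approx(4 / 3 * np.pi * 2.8**3, rel=1e-9)
        cavity = q.values >= 0.5
        assert np.all(stack["skull"].values[cavity] < 0.5)

    def test_cavity_outside_host_rejected(self):
        spec = PhantomSpec(
            layer_radii=(42.0, 40.0, 30.0, 27.0, 24.0),
            cavity=((0.0, 0.0, 10.0), 2.8, "skull"),  # deep inside WM
        )
        with pytest.raises(ValueError, match="cavity"):
            make_layered_phantom(spec)

    def test_radii_validation(self):
        with pytest.raises(ValueError):
            PhantomSpec(layer_radii=(30.0, 35.0, 20.0, 10.0, 5.0))
        with pytest.raises(ValueError):
            PhantomSpec(layer_radii=(60.0, 36.0, 33.0, 31.0, 27.0))  # no margin

    def test_ellipsoid_volumes(self):
        stack, analytic = make_layered_phantom(PRESETS["ellipsoid"])
        for name in stack.names:
            assert stack.tissue_voxel_volume(name) == pytest.approx(
                analytic[name], rel=0.03
            )


class TestNoiseIslands:
    def test_zero_islands_is_identity(self, five_layer):
        stack, _ = five_layer
        out = add_noise_islands(stack, 0, size=2, seed=1)
        assert out is stack

    def test_deterministic_for_seed(self, five_layer):
        stack, _ = five_layer
        a = add_noise_islands(stack, 5, size=2, seed=7)
        b = add_noise_islands(stack, 5, size=2, seed=7)
        for ga, gb in zip(a.grids, b.grids):
            np.testing.assert_array_equal(ga.values, gb.values)
        c = add_noise_islands(stack, 5, size=2, seed=8)
        assert any(
            not np.array_equal(ga.values, gc.values)
            for ga, gc in zip(a.grids, c.grids)
        )

    def test_component_counts_increase_per_island(self, five_layer):
        """Each island adds exactly one connected component to the tissue it
        was written into (component labeling as the oracle)."""
        stack, _ = five_layer
        before = island_component_counts(stack)
        noisy = add_noise_islands(stack, 5, size=2, seed=7)
        after = island_component_counts(noisy)
        placed = {}
        for isl in noisy.meta["islands"]:
            placed[isl["source"]] = placed.get(isl["source"], 0) + 1
        assert sum(placed.values()) == 5
        for name in stack.names:
            assert after[name] == before[name] + placed.get(name, 0)

    def test_original_stack_untouched(self, five_layer):
        stack, _ = five_layer
        snapshot = [g.values.copy() for g in stack.grids]
        add_noise_islands(stack, 3, size=2, seed=3)
        for g, snap in zip(stack.grids, snapshot):
            np.testing.assert_array_equal(g.values, snap)
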