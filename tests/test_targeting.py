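import numpy as np
import pytest

import conntarget as ct
from conntarget.errors import EmptyMaskError, InvalidParameterError
from conntarget.signal import SeedSeries
from conntarget.targeting import ConnectivityMap
from conntarget.volumes import ScalarVolume, VolumeMask

from conftest import make_bold


def random_cmap(grid, rng, n_search=200):
    member = np.zeros(grid.n_voxels, bool)
    member[rng.choice(grid.n_voxels, n_search, replace=False)] = True
    mask = VolumeMask(grid, member.reshape(grid.shape))
    r = np.full(grid.n_voxels, np.nan)
    r[member] = rng.uniform(-1, 1, n_search)
    return ConnectivityMap(grid, r.reshape(grid.shape), mask)


class TestMapConnectivity:
    def test_perfect_coupling_gives_unit_map(self, tiny_grid, rng):
        seed = rng.standard_normal(60)
        data = np.tile(seed[:, None], (1, tiny_grid.n_voxels))
        series = make_bold(tiny_grid, data)
        mask = VolumeMask(tiny_grid, np.ones(tiny_grid.shape, bool))
        cmap = ct.map_connectivity(series, SeedSeries(seed), mask)
        np.testing.assert_allclose(cmap.defined_values(), 1.0, atol=1e-10)

    def test_white_noise_correlations_are_small(self, tiny_grid, rng):
        series = make_bold(tiny_grid, rng.standard_normal((600, tiny_grid.n_voxels)))
        seed = SeedSeries(rng.standard_normal(600))
        mask = VolumeMask(tiny_grid, np.ones(tiny_grid.shape, bool))
        cmap = ct.map_connectivity(series, seed, mask)
        assert np.mean(np.abs(cmap.defined_values()) < 0.2) >= 0.99

    def test_matches_per_voxel_pearson_loop(self, tiny_bold, tiny_grid, rng):
        member = np.zeros(tiny_grid.n_voxels, bool)
        idx = rng.choice(tiny_grid.n_voxels, 10, replace=False)
        member[idx] = True
        mask = VolumeMask(tiny_grid, member.reshape(tiny_grid.shape))
        seed = SeedSeries(rng.standard_normal(40))
        cmap = ct.map_connectivity(tiny_bold, seed, mask)
        for v in idx:
            expected = ct.pearson_r(SeedSeries(tiny_bold.data[:, v]), seed)
            assert cmap.r_value.ravel()[v] == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_voxel_assigned_zero(self, tiny_grid, rng, caplog):
        data = rng.standard_normal((30, tiny_grid.n_voxels))
        data[:, 0] = 5.0  # constant voxel
        member = np.zeros(tiny_grid.n_voxels, bool)
        member[:5] = True
        mask = VolumeMask(tiny_grid, member.reshape(tiny_grid.shape))
        with caplog.at_level("WARNING"):
            cmap = ct.map_connectivity(make_bold(tiny_grid, data), SeedSeries(rng.standard_normal(30)), mask)
        assert cmap.r_value.ravel()[0] == 0.0
        assert "zero-variance" in caplog.text


class TestTopFraction:
    def test_exact_division(self, tiny_grid, rng):
        cmap = random_cmap(tiny_grid, rng, n_search=1000)
        assert ct.select_top_fraction(cmap, 0.005).n_members == 5

    def test_ceiling_rule(self, tiny_grid, rng):
        cmap = random_cmap(tiny_grid, rng, n_search=201)
        assert ct.select_top_fraction(cmap, 0.005).n_members == 2

    def test_matches_full_sort_oracle(self, tiny_grid, rng):
        cmap = random_cmap(tiny_grid, rng, n_search=300)
        selected = ct.select_top_fraction(cmap, 0.01)
        idx = cmap.search_mask.linear_indices()
        r = cmap.r_value.ravel()[idx]
        k = int(np.ceil(0.01 * len(idx)))
        oracle = set(idx[np.argsort(-r, kind="stable")][:k])
        assert set(selected.linear_indices()) == oracle

    def test_k_nondecreasing_in_fraction(self, tiny_grid, rng):
        cmap = random_cmap(tiny_grid, rng)
        counts = [ct.select_top_fraction(cmap, f).n_members for f in (0.005, 0.01, 0.1, 0.5, 1.0)]
        assert counts == sorted(counts)
        assert counts[-1] == cmap.search_mask.n_members

    def test_invalid_fraction_rejected(self, tiny_grid, rng):
        cmap = random_cmap(tiny_grid, rng)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(InvalidParameterError):
                ct.select_top_fraction(cmap, bad)


def flood_fill_components(member, connectivity):
    """Independent BFS flood-fill partition of a boolean 3D mask."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(member, bool)
    comps = []
    for start in map(tuple, np.argwhere(member)):
        if seen[start]:
            continue
        queue, comp = [start], []
        seen[start] = True
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nb, member.shape)):
                    continue
                if member[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


class TestConnectedComponents:
    def grid(self, shape=(8, 8, 8)):
        return ct.VoxelGrid(shape, np.eye(4))

    def test_face_adjacency(self):
        g = self.grid()
        m = np.zeros(g.shape, bool)
        m[2, 2, 2] = m[2, 2, 3] = True
        comps = ct.connected_components(VolumeMask(g, m), 6)
        assert len(comps) == 1 and comps[0].n_members == 2

    def test_corner_adjacency_by_connectivity(self):
        g = self.grid()
        m = np.zeros(g.shape, bool)
        m[2, 2, 2] = m[3, 3, 3] = True
        assert len(ct.connected_components(VolumeMask(g, m), 6)) == 2
        assert len(ct.connected_components(VolumeMask(g, m), 26)) == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        g = self.grid()
        member = np.zeros(g.n_voxels, bool)
        member[rng.choice(g.n_voxels, 200, replace=False)] = True
        member = member.reshape(g.shape)
        comps = ct.connected_components(VolumeMask(g, member), connectivity)
        got = {frozenset(map(tuple, np.argwhere(c.member))) for c in comps}
        assert got == flood_fill_components(member, connectivity)

    def test_sorted_by_size_then_lowest_index(self, rng):
        g = self.grid()
        member = np.zeros(g.n_voxels, bool)
        member[rng.choice(g.n_voxels, 120, replace=False)] = True
        comps = ct.connected_components(VolumeMask(g, member.reshape(g.shape)), 6)
        keys = [(-c.n_members, c.linear_indices()[0]) for c in comps]
        assert keys == sorted(keys)

    def test_coarse_components_union_of_fine(self, rng):
        g = self.grid()
        member = np.zeros(g.n_voxels, bool)
        member[rng.choice(g.n_voxels, 150, replace=False)] = True
        mask = VolumeMask(g, member.reshape(g.shape))
        fine = ct.connected_components(mask, 6)
        coarse = ct.connected_components(mask, 26)
        for f in fine:
            f_set = set(f.linear_indices())
            assert any(f_set <= set(c.linear_indices()) for c in coarse)

    def test_empty_mask_yields_empty_list(self):
        g = self.grid()
        assert ct.connected_components(VolumeMask(g, np.zeros(g.shape, bool)), 26) == []

    def test_invalid_connectivity_rejected(self):
        g = self.grid()
        with pytest.raises(InvalidParameterError):
            ct.connected_components(VolumeMask(g, np.zeros(g.shape, bool)), 10)


class TestLocateTarget:
    def cmap_from(self, grid, values_by_voxel, search_idx):
        member = np.zeros(grid.n_voxels, bool)
        member[search_idx] = True
        r = np.full(grid.n_voxels, np.nan)
        for v, val in values_by_voxel.items():
            r[v] = val
        return ConnectivityMap(grid, r.reshape(grid.shape), VolumeMask(grid, member.reshape(grid.shape)))

    def test_singleton_cluster(self, tiny_grid):
        idx = np.arange(100)
        vals = {v: -0.5 for v in idx}
        vals[57] = 0.9
        cmap = self.cmap_from(tiny_grid, vals, idx)
        rep = ct.locate_target(cmap, fraction=0.005)
        voxel_mm = ct.voxel_to_mm(tiny_grid, np.unravel_index(57, tiny_grid.shape))
        np.testing.assert_allclose(rep.centroid_mm, voxel_mm)
        np.testing.assert_allclose(rep.snapped_voxel_mm, voxel_mm)
        np.testing.assert_allclose(rep.peak_voxel_mm, voxel_mm)
        assert rep.cluster_size == 1

    def test_two_voxel_cluster_midpoint(self):
        grid = ct.mni_grid(4.0)
        a = np.round(ct.mm_to_voxel(grid, (-42, 38, 40))).astype(int)
        b = np.round(ct.mm_to_voxel(grid, (-38, 38, 40))).astype(int)
        la = np.ravel_multi_index(tuple(a), grid.shape)
        lb = np.ravel_multi_index(tuple(b), grid.shape)
        search = np.arange(grid.n_voxels)[:: grid.n_voxels // 390][:390].tolist() + [la, lb]
        vals = {v: -0.9 for v in search}
        vals[la] = vals[lb] = 0.95
        cmap = self.cmap_from(grid, vals, np.unique(search))
        rep = ct.locate_target(cmap, fraction=2.5 / len(np.unique(search)))
        np.testing.assert_allclose(rep.centroid_mm, (-40, 38, 40))
        assert tuple(rep.snapped_voxel_mm) in {(-42.0, 38.0, 40.0), (-38.0, 38.0, 40.0)}

    def test_invariant_under_monotone_transform(self, tiny_grid, rng):
        cmap = random_cmap(tiny_grid, rng, n_search=250)
        rep = ct.locate_target(cmap, 0.02)
        transformed = ConnectivityMap(
            cmap.grid, np.tanh(2.0 * cmap.r_value + 0.1), cmap.search_mask
        )
        rep2 = ct.locate_target(transformed, 0.02)
        assert rep.centroid_mm == rep2.centroid_mm
        assert rep.cluster_size == rep2.cluster_size
        assert rep.peak_voxel_mm == rep2.peak_voxel_mm

    def test_phantom_recovery_within_two_voxels_at_default_snr(self, phantom, phantom_target):
        _, rep = phantom_target
        planted = np.array([-38.0, 36.0, 40.0])
        voxel_mm = phantom.pre.grid.voxel_size.max()
        err = np.linalg.norm(np.asarray(rep.centroid_mm) - planted)
        assert err <= 2 * voxel_mm  # within 2 voxels of the planted centre
        assert rep.n_selected >= rep.cluster_size >= 1


class TestDeltaFC:
    def test_identical_sessions_give_zero(self, phantom, phantom_target):
        _, rep = phantom_target
        d = ct.delta_fc(
            phantom.pre, phantom.pre, rep, phantom.group_weights,
            phantom.gm_mask, phantom.dlpfc_mask,
        )
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_doubled_coupling_increases_dfc(self):
        spec = ct.PhantomSpec(seed=11, post_gain_factor=2.0)
        ph = ct.make_phantom(spec)
        proc = ct.smooth_gaussian(ct.highpass(ph.pre, 0.01), 4.0)
        seed = ct.seedmap_series(proc, ph.group_weights, ph.gm_mask, ph.dlpfc_mask)
        rep = ct.locate_target(ct.map_connectivity(proc, seed, ph.dlpfc_mask))
        d = ct.delta_fc(ph.pre, ph.post, rep, ph.group_weights, ph.gm_mask, ph.dlpfc_mask)
        assert d > 0.0

    def test_fisher_z_difference_closed_form(self):
        assert ct.fisher_z(0.5) - ct.fisher_z(0.0) == pytest.approx(0.5493, abs=1e-4)


class TestEfield:
    def roi(self, grid, n=10):
        member = np.zeros(grid.n_voxels, bool)
        member[:n] = True
        return VolumeMask(grid, member.reshape(grid.shape))

    def test_uniform_above_threshold(self, tiny_grid):
        field = ScalarVolume(tiny_grid, np.full(tiny_grid.shape, 200.0))
        s = ct.efield_summary(field, self.roi(tiny_grid), 150.0)
        assert (s.mean_vpm, s.peak_vpm, s.pct_above_threshold) == (200.0, 200.0, 100.0)

    def test_uniform_below_threshold(self, tiny_grid):
        field = ScalarVolume(tiny_grid, np.full(tiny_grid.shape, 100.0))
        assert ct.efield_summary(field, self.roi(tiny_grid), 150.0).pct_above_threshold == 0.0

    def test_two_level_field(self, tiny_grid):
        values = np.zeros(tiny_grid.n_voxels)
        values[:5] = 160.0
        values[5:10] = 140.0
        field = ScalarVolume(tiny_grid, values.reshape(tiny_grid.shape))
        s = ct.efield_summary(field, self.roi(tiny_grid), 150.0)
        assert s.pct_above_threshold == 50.0
        assert s.mean_vpm == 150.0
        assert s.peak_vpm == 160.0

    def test_empty_roi_rejected(self, tiny_grid):
        field = ScalarVolume(tiny_grid, np.ones(tiny_grid.shape))
        with pytest.raises(EmptyMaskError):
            ct.efield_summary(field, self.roi(tiny_grid, 0), 150.0)

    def test_negative_field_rejected(self, tiny_grid):
        field = ScalarVolume(tiny_grid, np.full(tiny_grid.shape, -1.0))
        with pytest.raises(InvalidParameterError):
            ct.efield_summary(field, self.roi(tiny_grid), 150.0)
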