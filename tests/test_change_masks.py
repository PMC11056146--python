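"""Four-class logic, cluster filtering, NN resampling, volumetrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wmhtraj.change_masks import (
    CLASS_NAMES,
    change_classes,
    class_volumes,
    filter_small_clusters,
    resample_nn,
)
from wmhtraj.grid import Grid


def brute_force_classes(nawm_bl, wmh_bl, nawm_fu, wmh_fu):
    """Per-voxel conditional oracle for the four-class logic."""
    out = {name: np.zeros(nawm_bl.shape, bool) for name in CLASS_NAMES}
    for idx in np.ndindex(*nawm_bl.shape):
        if nawm_bl[idx] and nawm_fu[idx]:
            out["stable_nawm"][idx] = True
        elif wmh_bl[idx] and wmh_fu[idx]:
            out["stable_wmh"][idx] = True
        elif nawm_bl[idx] and wmh_fu[idx]:
            out["progressing_wmh"][idx] = True
        elif wmh_bl[idx] and nawm_fu[idx]:
            out["regressing_wmh"][idx] = True
    return out


def bfs_components(mask, connectivity):
    """Flood-fill component enumeration, independent of scipy labeling."""
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
        and (connectivity == 26 or abs(i) + abs(j) + abs(k) == 1)
    ]
    seen = np.zeros(mask.shape, bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offsets:
                nb = tuple(np.add(v, o))
                if all(0 <= nb[d] < mask.shape[d] for d in range(3)):
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
        comps.append(comp)
    return comps


class TestChangeClasses:
    def test_exhaustive_two_by_two_truth_table(self):
        # voxel 0: NAWM->WMH, 1: WMH->NAWM, 2: WMH->WMH, 3: NAWM->NAWM
        nawm_bl = np.array([1, 0, 0, 1], bool).reshape(2, 2, 1)
        wmh_bl = np.array([0, 1, 1, 0], bool).reshape(2, 2, 1)
        nawm_fu = np.array([0, 1, 0, 1], bool).reshape(2, 2, 1)
        wmh_fu = np.array([1, 0, 1, 0], bool).reshape(2, 2, 1)
        m = change_classes(nawm_bl, wmh_bl, nawm_fu, wmh_fu)
        assert m.progressing_wmh[0, 0, 0] and m.progressing_wmh.sum() == 1
        assert m.regressing_wmh[0, 1, 0] and m.regressing_wmh.sum() == 1
        assert m.stable_wmh[1, 0, 0] and m.stable_wmh.sum() == 1
        assert m.stable_nawm[1, 1, 0] and m.stable_nawm.sum() == 1

    def test_no_change_no_progression(self, rng):
        wmh = rng.random((6, 6, 6)) < 0.3
        nawm = ~wmh & (rng.random((6, 6, 6)) < 0.8)
        m = change_classes(nawm, wmh, nawm, wmh)
        assert not m.progressing_wmh.any() and not m.regressing_wmh.any()

    def test_overlap_rejected(self):
        a = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError):
            change_classes(a, a, a, ~a)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        wmh_bl = rng.random((5, 5, 5)) < 0.35
        nawm_bl = ~wmh_bl & (rng.random((5, 5, 5)) < 0.7)
        wmh_fu = rng.random((5, 5, 5)) < 0.35
        nawm_fu = ~wmh_fu & (rng.random((5, 5, 5)) < 0.7)
        got = change_classes(nawm_bl, wmh_bl, nawm_fu, wmh_fu)
        want = brute_force_classes(nawm_bl, wmh_bl, nawm_fu, wmh_fu)
        for name in CLASS_NAMES:
            np.testing.assert_array_equal(getattr(got, name), want[name])

    def test_partition_of_eligible_voxels(self, rng):
        """Each WM-at-both-timepoints voxel lands in exactly one class."""
        wmh_bl = rng.random((6, 6, 6)) < 0.4
        nawm_bl = ~wmh_bl
        wmh_fu = rng.random((6, 6, 6)) < 0.4
        nawm_fu = ~wmh_fu
        m = change_classes(nawm_bl, wmh_bl, nawm_fu, wmh_fu)
        total = sum(getattr(m, n).astype(int) for n in CLASS_NAMES)
        assert np.all(total == 1)


class TestClusterFilter:
    def test_four_removed_five_kept(self):
        mask = np.zeros((10, 10, 3), bool)
        mask[1, 1:5, 1] = True  # 4-voxel line
        mask[5, 1:6, 1] = True  # 5-voxel line
        out = filter_small_clusters(mask, min_size=5)
        assert not out[1, 1:5, 1].any()
        assert out[5, 1:6, 1].all()

    def test_min_size_one_is_identity(self, rng):
        mask = rng.random((8, 8, 8)) < 0.2
        np.testing.assert_array_equal(filter_small_clusters(mask, 1), mask)

    def test_connectivity_matters_for_diagonal(self):
        mask = np.zeros((6, 6, 6), bool)
        for i in range(5):
            mask[i, i, i] = True  # diagonal chain: one 26-component, five 6-components
        assert filter_small_clusters(mask, 5, connectivity=26).sum() == 5
        assert filter_small_clusters(mask, 5, connectivity=6).sum() == 0

    @pytest.mark.parametrize("connectivity", [6, 26])
    @given(seed=st.integers(0, 2**32 - 1))
    def test_matches_bfs_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.random((7, 7, 7)) < 0.25
        got = filter_small_clusters(mask, 4, connectivity)
        want = np.zeros(mask.shape, bool)
        for comp in bfs_components(mask, connectivity):
            if len(comp) >= 4:
                for v in comp:
                    want[v] = True
        np.testing.assert_array_equal(got, want)


class TestResampleNn:
    def test_identity_on_identical_grids(self, rng):
        g = Grid((8, 8, 8), (1.0, 1.0, 1.0))
        mask = rng.random((8, 8, 8)) < 0.5
        np.testing.assert_array_equal(resample_nn(mask, g, g), mask)

    def test_all_ones_any_resolution(self):
        src = Grid((12, 12, 12), (1.0, 1.0, 1.0))
        dst = Grid((5, 6, 4), (2.4, 2.0, 3.0))
        out = resample_nn(np.ones((12, 12, 12), bool), src, dst)
        assert out.all() and out.shape == (5, 6, 4)

    def test_against_exhaustive_nearest_center_search(self, rng):
        src = Grid((12, 12, 12), (1.0, 1.0, 1.0))
        dst = Grid((6, 6, 6), (2.0, 2.0, 2.0))
        mask = rng.random((12, 12, 12)) < 0.5
        got = resample_nn(mask, src, dst)
        src_centers = [src.centers_mm(ax) for ax in range(3)]
        for idx in np.ndindex(*dst.shape):
            nearest = tuple(
                int(np.argmin(np.abs(src_centers[ax] - dst.centers_mm(ax)[idx[ax]])))
                for ax in range(3)
            )
            assert got[idx] == mask[nearest], (idx, nearest)

    def test_disjoint_fov_rejected(self):
        src = Grid((4, 4, 4), (1.0, 1.0, 1.0))
        dst = Grid((4, 4, 4), (10.0, 10.0, 10.0))
        with pytest.raises(ValueError):
            resample_nn(np.ones((4, 4, 4), bool), src, dst)


class TestClassVolumes:
    def test_thousand_unit_voxels_is_one_ml(self):
        m = np.zeros((12, 12, 12), bool)
        m.ravel()[:1000] = True
        masks = change_classes(m, np.zeros_like(m), m, np.zeros_like(m))
        vols = class_volumes(masks, (1.0, 1.0, 1.0))
        assert vols["stable_nawm"] == pytest.approx(1.0)
        assert vols["stable_wmh"] == 0.0

    def test_sphere_volume_within_discretization_bound(self):
        """Voxel-count volume of a digital sphere is within one voxel shell
        of the analytic value."""
        r_mm = 5.0
        shape = (24, 24, 24)
        x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
        sphere = (x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2 <= r_mm**2
        vol_ml = sphere.sum() / 1000.0
        analytic = 4.0 / 3.0 * np.pi * r_mm**3 / 1000.0
        shell = 4.0 * np.pi * r_mm**2 * 1.0 / 1000.0  # one-voxel surface shell
        assert abs(vol_ml - analytic) < shell

    def test_volumes_invariant_to_cluster_filter_order(self, rng):
        """Volumetrics are computed pre-filter: filtering changes the masks
        but must not be applied before the volume readout."""
        wmh_bl = rng.random((10, 10, 10)) < 0.1
        m = change_classes(~wmh_bl, wmh_bl, ~wmh_bl, wmh_bl)
        vols = class_volumes(m, (1.0, 1.0, 1.0))
        filtered = m.map_masks(lambda x: filter_small_clusters(x, 5))
        vols_filtered = class_volumes(filtered, (1.0, 1.0, 1.0))
        assert vols["stable_wmh"] >= vols_filtered["stable_wmh"]
        assert vols["stable_wmh"] == pytest.approx(wmh_bl.sum() / 1000.0)
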