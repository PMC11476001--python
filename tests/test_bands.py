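"""Distance maps, band selection, skeleton branches, and feature extraction."""

import numpy as np
import pytest

from vascband.bands import (
    band_metrics,
    band_select,
    extract_features,
    skeletonize_and_branch,
    surface_distance_map,
)
from vascband.grid import VoxelVolume
from vascband.phantom import (
    TubeBranch,
    grow_vessel_tree,
    make_nodule_phantom,
    rasterize_tubes,
)


class TestSurfaceDistanceMap:
    def test_sphere_distance_geometry(self):
        nod = make_nodule_phantom(10.0, (1.0, 1.0, 1.0), margin_mm=6.0)
        dmap = surface_distance_map(nod)
        center = np.array(nod.shape) // 2
        probe = center + np.array([8, 0, 0])  # 8 mm from center, R = 5
        assert dmap.values[tuple(probe)] == pytest.approx(3.0, abs=np.sqrt(3))

    def test_interior_flagged_and_negative(self):
        nod = make_nodule_phantom(10.0, (1.0, 1.0, 1.0), margin_mm=4.0)
        dmap = surface_distance_map(nod)
        center = tuple(np.array(nod.shape) // 2)
        assert dmap.inside[center]
        assert dmap.values[center] < 0

    def test_empty_mask_rejected(self):
        empty = VoxelVolume(np.zeros((8, 8, 8), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(ValueError, match="no nodule"):
            surface_distance_map(empty)

    def test_anisotropic_spacing_matches_brute_force_oracle(self):
        """EDT with (1,1,2) mm spacing equals all-pairs distance on a tiny grid."""
        spacing = (1.0, 1.0, 2.0)
        mask = np.zeros((12, 12, 12), dtype=np.uint8)
        mask[4:8, 4:8, 5:7] = 1
        vol = VoxelVolume(mask, spacing)
        dmap = surface_distance_map(vol)

        fg = np.argwhere(mask) * np.array(spacing)
        for idx in [(0, 0, 0), (11, 6, 3), (2, 9, 10), (6, 6, 0)]:
            p = np.array(idx) * np.array(spacing)
            brute = np.sqrt(((fg - p) ** 2).sum(1)).min()
            assert dmap.values[idx] == pytest.approx(brute, abs=1e-9)


class TestBandSelect:
    @pytest.fixture()
    def setting(self):
        nod = make_nodule_phantom(10.0, (1.0, 1.0, 1.0), margin_mm=10.0)
        dmap = surface_distance_map(nod)
        vessel = np.zeros(nod.shape, dtype=np.uint8)
        return nod, dmap, vessel

    def test_inclusion_by_distance(self, setting):
        nod, dmap, vessel = setting
        center = np.array(nod.shape) // 2
        near = tuple(center + [8, 0, 0])  # ~3 mm from surface
        far = tuple(center + [12, 0, 0])  # ~7 mm
        vessel[near] = vessel[far] = 1
        band5 = band_select(nod.like(vessel), dmap, 5.0)
        assert band5.data[near] == 1 and band5.data[far] == 0
        band10 = band_select(nod.like(vessel), dmap, 10.0)
        assert band10.data[far] == 1

    def test_interior_vessel_excluded_for_any_band(self, setting):
        nod, dmap, vessel = setting
        center = tuple(np.array(nod.shape) // 2)
        vessel[center] = 1
        for d in (5.0, 10.0, 15.0):
            assert band_select(nod.like(vessel), dmap, d).data.sum() == 0

    def test_empty_vessel_mask_and_nesting(self, setting, rng):
        nod, dmap, vessel = setting
        assert band_select(nod.like(vessel), dmap, 5.0).data.sum() == 0
        vessel[rng.integers(0, nod.shape[0], (50, 3)).T.tolist()] = 1
        sel = [band_select(nod.like(vessel), dmap, d).as_bool() for d in (5, 10, 15)]
        assert np.all(sel[0] <= sel[1]) and np.all(sel[1] <= sel[2])

    def test_grid_mismatch_rejected(self, setting):
        nod, dmap, _ = setting
        other = VoxelVolume(np.zeros((5, 5, 5), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(ValueError, match="different grids"):
            band_select(other, dmap, 5.0)


class TestSkeletonBranches:
    def test_straight_tube_is_one_branch_with_unit_tortuosity(self, vessel_grid):
        line = np.array([[25.0, 25.0, 10.0], [25.0, 25.0, 40.0]])
        mask = rasterize_tubes([TubeBranch(line, 1.0)], vessel_grid)
        bs = skeletonize_and_branch(mask)
        assert len(bs) == 1
        m = band_metrics(mask, bs)
        assert m.tortuosity == pytest.approx(1.0, abs=0.02)

    def test_oblique_straight_tube_tortuosity_near_one(self, vessel_grid):
        u = np.array([1.0, 0.55, 0.3])
        u /= np.linalg.norm(u)
        line = np.stack([np.array([12.0, 12.0, 12.0]) + t * u for t in (0.0, 25.0)])
        mask = rasterize_tubes([TubeBranch(line, 1.0)], vessel_grid)
        m = band_metrics(mask, skeletonize_and_branch(mask))
        assert m.count == 1
        assert m.tortuosity == pytest.approx(1.0, abs=0.02)

    def test_straight_tube_metrics_robust_to_halved_spacing(self):
        u = np.array([0.9, 0.4, 0.2])
        u /= np.linalg.norm(u)
        line = np.stack([np.array([12.0, 12.0, 12.0]) + t * u for t in (0.0, 24.0)])
        results = []
        for s in (1.0, 0.5):
            grid = VoxelVolume(np.zeros((int(50 / s),) * 3, dtype=np.uint8), (s,) * 3)
            mask = rasterize_tubes([TubeBranch(line, 1.2)], grid)
            m = band_metrics(mask, skeletonize_and_branch(mask))
            results.append(m)
        assert results[0].count == results[1].count
        assert abs(results[0].tortuosity - results[1].tortuosity) < 0.02

    def test_y_tree_has_three_branches(self, vessel_grid):
        stem = np.array([[25.0, 25.0, 8.0], [25.0, 25.0, 25.0]])
        arm1 = np.array([[25.0, 25.0, 25.0], [35.0, 25.0, 40.0]])
        arm2 = np.array([[25.0, 25.0, 25.0], [15.0, 25.0, 40.0]])
        mask = rasterize_tubes([TubeBranch(c, 1.2) for c in (stem, arm1, arm2)], vessel_grid)
        bs = skeletonize_and_branch(mask)
        assert len(bs) == 3

    def test_semicircle_tortuosity_is_half_pi(self, vessel_grid):
        theta = np.linspace(0, np.pi, 200)
        arc = np.stack(
            [25 + 8 * np.cos(theta), 25 + 8 * np.sin(theta), np.full_like(theta, 25.0)], 1
        )
        mask = rasterize_tubes([TubeBranch(arc, 1.0)], vessel_grid)
        m = band_metrics(mask, skeletonize_and_branch(mask))
        assert m.tortuosity == pytest.approx(np.pi / 2, abs=0.05)

    def test_cylinder_band_volume_in_cm3(self, vessel_grid):
        line = np.array([[25.0, 25.0, 10.0], [25.0, 25.0, 30.0]])
        mask = rasterize_tubes([TubeBranch(line, 1.0)], vessel_grid)
        m = band_metrics(mask, skeletonize_and_branch(mask))
        assert m.volume_cm3 == pytest.approx(np.pi * 20.0 / 1000.0, rel=0.10)

    def test_empty_mask_yields_empty_branchset_and_sentinel(self, vessel_grid):
        bs = skeletonize_and_branch(vessel_grid)
        m = band_metrics(vessel_grid, bs)
        assert (m.count, m.volume_cm3, m.tortuosity, m.empty_band) == (0, 0.0, 1.0, True)

    def test_closed_loop_counts_but_skips_tortuosity(self, vessel_grid):
        theta = np.linspace(0, 2 * np.pi, 300)
        ring = np.stack(
            [25 + 8 * np.cos(theta), 25 + 8 * np.sin(theta), np.full_like(theta, 25.0)], 1
        )
        mask = rasterize_tubes([TubeBranch(ring, 1.0)], vessel_grid)
        bs = skeletonize_and_branch(mask)
        m = band_metrics(mask, bs)
        assert m.count >= 1
        assert m.tortuosity == 1.0  # sentinel: no valid chord


@pytest.fixture(scope="module")
def phantom_set():
    nod = make_nodule_phantom(10.0, (0.5, 0.5, 0.5), margin_mm=21.0)
    arteries, truth = grow_vessel_tree(
        nod, "artery", n_branches=3, tortuosity_amp=0.0, seed=8
    )
    return nod, arteries, truth


class TestExtractFeatures:
    def test_recovers_truth_and_mirrored_symmetry(self, phantom_set):
        nod, arteries, truth = phantom_set
        amask = rasterize_tubes(arteries, nod)
        mirrored = [
            TubeBranch(2 * np.argwhere(nod.as_bool()).mean(0) * 0.5 - b.centerline[::-1], b.radius, "vein")
            for b in arteries
        ]
        vmask = rasterize_tubes(mirrored, nod)
        overlap = amask.as_bool() & vmask.as_bool()
        vmask = nod.like((vmask.as_bool() & ~overlap).astype(np.uint8))
        feats = extract_features(nod, amask, vmask)
        assert feats["artery5_count"] == truth.count[("artery", 5.0)]
        assert feats["artery5_tortuosity"] == pytest.approx(1.0, abs=0.03)
        # point symmetry through the nodule centre preserves every band metric
        for d in (5, 10, 15):
            assert feats[f"vein{d}_count"] == feats[f"artery{d}_count"]

    def test_band_target_counts_recovered(self):
        nod = make_nodule_phantom(9.0, (0.5, 0.5, 0.5), margin_mm=21.0)
        branches, truth = grow_vessel_tree(
            nod, "artery", band_targets={5: 2, 10: 4, 15: 6}, seed=13
        )
        empty = nod.like(np.zeros(nod.shape, dtype=np.uint8))
        feats = extract_features(nod, rasterize_tubes(branches, nod), empty)
        assert [feats[f"artery{d}_count"] for d in (5, 10, 15)] == [2, 4, 6]
        assert all(feats[f"vein{d}_count"] == 0 for d in (5, 10, 15))

    def test_vessels_only_beyond_10mm(self):
        nod = make_nodule_phantom(9.0, (0.5, 0.5, 0.5), margin_mm=21.0)
        branches, _ = grow_vessel_tree(nod, "artery", band_targets={5: 0, 10: 0, 15: 2}, seed=2)
        empty = nod.like(np.zeros(nod.shape, dtype=np.uint8))
        feats = extract_features(nod, rasterize_tubes(branches, nod), empty)
        assert feats["artery5_count"] == 0 and feats["artery10_count"] == 0
        assert feats["artery15_count"] > 0
        assert feats["artery5_empty_band"] == 1.0

    def test_interior_vessel_voxels_change_nothing(self, phantom_set):
        nod, arteries, _ = phantom_set
        amask = rasterize_tubes(arteries, nod)
        empty = nod.like(np.zeros(nod.shape, dtype=np.uint8))
        base = extract_features(nod, amask, empty)
        spiked = amask.data.copy()
        inside = np.argwhere(nod.as_bool())
        spiked[tuple(inside[:: max(1, len(inside) // 40)].T)] = 1
        spiked[nod.as_bool() & ~nod.as_bool()] = 0  # no-op, keeps dtype
        with_interior = extract_features(nod, nod.like(spiked), empty)
        for key in base.index:
            assert base[key] == pytest.approx(with_interior[key], abs=1e-12), key

    def test_overlapping_compartments_rejected(self, phantom_set):
        nod, arteries, _ = phantom_set
        amask = rasterize_tubes(arteries, nod)
        with pytest.raises(ValueError, match="ambiguous compartment"):
            extract_features(nod, amask, amask)
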