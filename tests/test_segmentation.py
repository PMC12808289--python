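"""Segmentation operators against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from clavimetric import (
    Seed,
    SeedSet,
    erase_region,
    grow_from_seeds,
    label_components,
    logical_combine,
    solidify,
    threshold_mask,
)
from clavimetric.errors import GeometryError, LabelError, SeedError
from clavimetric.grids import BinaryMask

from conftest import ball_mask, make_labels, make_volume


def _mask(arr, spacing=1.0):
    return BinaryMask(mask=np.asarray(arr, dtype=bool),
                      spacing=np.full(3, spacing), origin=np.zeros(3),
                      direction=np.eye(3))


def bfs_grow_oracle(mask, seeds):
    """Independent multi-source oracle: per-label chessboard BFS through the
    mask (26-connectivity), then argmin distance with ties to the smaller
    label id."""
    from collections import deque

    shape = mask.shape
    labels = sorted({s.label for s in seeds})
    dist = {l: np.full(shape, np.inf) for l in labels}
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    for l in labels:
        q = deque()
        for s in seeds:
            if s.label == l:
                dist[l][s.index] = 0
                q.append(s.index)
        while q:
            p = q.popleft()
            for o in offsets:
                n = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
                if all(0 <= n[i] < shape[i] for i in range(3)) and mask[n]:
                    if dist[l][n] == np.inf:
                        dist[l][n] = dist[l][p] + 1
                        q.append(n)
    out = np.zeros(shape, dtype=int)
    stack = np.stack([dist[l] for l in labels])
    best = stack.min(axis=0)
    arg = stack.argmin(axis=0)  # first (= smallest label) wins ties
    reached = mask & np.isfinite(best)
    out[reached] = np.asarray(labels)[arg[reached]]
    return out


class TestThreshold:
    def test_boundary_inclusive_at_300(self):
        vol = make_volume(np.array([-100.0, 299.0, 300.0, 1200.0]).reshape(4, 1, 1))
        m = threshold_mask(vol, 300.0)
        assert m.mask.ravel().tolist() == [False, False, True, True]

    def test_all_air_gives_empty_mask(self):
        assert not threshold_mask(make_volume(np.full((4, 4, 4), -1000.0))).mask.any()

    def test_matches_exhaustive_scan_on_random_grid(self):
        rng = np.random.default_rng(21)
        values = rng.uniform(-1000, 2000, size=(16, 16, 16))
        m = threshold_mask(make_volume(values), 300.0)
        oracle = np.zeros_like(values, dtype=bool)
        for i in range(16):
            for j in range(16):
                for k in range(16):
                    oracle[i, j, k] = values[i, j, k] >= 300.0
        assert np.array_equal(m.mask, oracle)

    @given(st.floats(min_value=-500, max_value=1500),
           st.floats(min_value=0, max_value=500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, lo, delta):
        rng = np.random.default_rng(2)
        vol = make_volume(rng.uniform(-1000, 2000, size=(6, 6, 6)))
        m_lo = threshold_mask(vol, lo).mask
        m_hi = threshold_mask(vol, lo + delta).mask
        assert not (m_hi & ~m_lo).any()


class TestGrowFromSeeds:
    def test_single_seed_floods_component(self):
        mask = ball_mask((11, 11, 11), (5, 5, 5), 4.0)
        seg = grow_from_seeds(_mask(mask), SeedSet([Seed((5, 5, 5), 1)]))
        assert np.array_equal(seg.labels > 0, mask)
        assert set(np.unique(seg.labels)) == {0, 1}

    def test_two_disjoint_components_get_their_own_seed_labels(self):
        mask = np.zeros((12, 5, 5), dtype=bool)
        mask[:4], mask[8:] = True, True
        seg = grow_from_seeds(_mask(mask), SeedSet([
            Seed((1, 1, 1), 1), Seed((10, 1, 1), 2, role="epiphysis_center")]))
        comp, _ = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert np.all(seg.labels[comp == comp[1, 1, 1]] == 1)
        assert np.all(seg.labels[comp == comp[10, 1, 1]] == 2)

    def test_rod_tie_goes_to_smaller_label(self):
        mask = np.zeros((9, 1, 1), dtype=bool)
        mask[:] = True
        seg = grow_from_seeds(_mask(mask), SeedSet([
            Seed((0, 0, 0), 1), Seed((8, 0, 0), 2, role="epiphysis_center")]))
        got = seg.labels[:, 0, 0].tolist()
        assert got == [1, 1, 1, 1, 1, 2, 2, 2, 2]  # midpoint voxel tied -> label 1

    def test_matches_bfs_oracle_on_random_masks(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            mask = ndimage.binary_opening(rng.random((14, 14, 14)) < 0.55)
            if not mask.any():
                continue
            pts = np.argwhere(mask)
            picks = pts[rng.choice(len(pts), size=min(3, len(pts)), replace=False)]
            seeds = SeedSet([Seed(tuple(p), l + 1) for l, p in enumerate(picks)])
            seg = grow_from_seeds(_mask(mask), seeds)
            assert np.array_equal(seg.labels, bfs_grow_oracle(mask, list(seeds)))

    def test_support_within_mask_and_labels_partition(self):
        rng = np.random.default_rng(4)
        mask = rng.random((10, 10, 10)) < 0.4
        pts = np.argwhere(mask)
        seeds = SeedSet([Seed(tuple(pts[0]), 1), Seed(tuple(pts[-1]), 2,
                                                      role="epiphysis_center")])
        seg = grow_from_seeds(_mask(mask), seeds)
        assert not (seg.labels[~mask] != 0).any()

    def test_seed_outside_mask_rejected(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(SeedError):
            grow_from_seeds(_mask(mask), SeedSet([Seed((2, 2, 2), 1)]))


class TestSolidify:
    def test_solid_cube_unchanged(self):
        seg = make_labels(np.ones((5, 5, 5), dtype=np.int32), {1: "metaphysis"})
        assert np.array_equal(solidify(seg, 1).labels, seg.labels)

    def test_hollow_sphere_cavity_filled_matches_border_flood_oracle(self):
        shell = ball_mask((15, 15, 15), (7, 7, 7), 6.0) & ~ball_mask((15, 15, 15), (7, 7, 7), 4.0)
        seg = make_labels(shell.astype(np.int32), {1: "metaphysis"})
        out = solidify(seg, 1)
        # oracle: background voxels with no 6-connected path to the border
        bg = ~shell
        comp, n = ndimage.label(bg, structure=ndimage.generate_binary_structure(3, 1))
        border = set()
        for ax in range(3):
            for sl in (0, -1):
                border |= set(np.unique(np.take(comp, sl, axis=ax)))
        cavity = np.isin(comp, [c for c in range(1, n + 1) if c not in border])
        assert int((out.labels == 1).sum()) == int(shell.sum() + cavity.sum())
        assert np.all(out.labels[cavity] == 1)

    def test_open_cup_not_filled(self):
        cup = np.zeros((9, 9, 9), dtype=bool)
        cup[2:7, 2:7, 2:7] = True
        cup[3:6, 3:6, 3:9] = False  # channel to the border: cavity is open
        seg = make_labels(cup.astype(np.int32), {1: "metaphysis"})
        assert np.array_equal(solidify(seg, 1).labels, seg.labels)

    def test_never_removes_labeled_voxels(self):
        rng = np.random.default_rng(9)
        arr = (rng.random((8, 8, 8)) < 0.5).astype(np.int32)
        seg = make_labels(arr, {1: "metaphysis"})
        out = solidify(seg, 1)
        assert np.all(out.labels[arr == 1] == 1)
        assert (out.labels == 1).sum() >= (arr == 1).sum()

    def test_absent_label_rejected(self):
        seg = make_labels(np.ones((3, 3, 3), dtype=np.int32), {1: "metaphysis"})
        with pytest.raises(LabelError):
            solidify(seg, 2)


class TestLogicalCombine:
    def _two_boxes(self):
        a = np.zeros((8, 8, 8), dtype=np.int32)
        b = np.zeros((8, 8, 8), dtype=np.int32)
        a[1:5, 1:5, 1:5] = 1
        b[3:7, 3:7, 3:7] = 2
        return (make_labels(a, {1: "metaphysis"}),
                make_labels(b, {2: "epiphysis_center"}))

    def test_self_subtraction_is_empty(self):
        a, _ = self._two_boxes()
        assert not logical_combine(a, a, "subtract", 1).labels.any()

    def test_union_of_disjoint_is_additive(self):
        a = make_labels(ball_mask((16, 16, 16), (4, 4, 4), 2.5).astype(np.int32),
                        {1: "metaphysis"})
        b = make_labels(ball_mask((16, 16, 16), (11, 11, 11), 3.0).astype(np.int32),
                        {1: "metaphysis"})
        u = logical_combine(a, b, "union", 1)
        assert (u.labels > 0).sum() == (a.labels > 0).sum() + (b.labels > 0).sum()

    def test_intersection_matches_voxelwise_and(self):
        a, b = self._two_boxes()
        inter = logical_combine(a, b, "intersect", 3, out_role="fusion_area")
        assert np.array_equal(inter.labels == 3, (a.labels > 0) & (b.labels > 0))

    def test_lattice_mismatch_rejected(self):
        a, _ = self._two_boxes()
        other = make_labels(np.zeros((8, 8, 8), dtype=np.int32), {}, spacing=2.0)
        with pytest.raises(GeometryError):
            logical_combine(a, other, "union", 1)


class TestEraseAndComponents:
    def test_erase_then_union_restores_original(self):
        rng = np.random.default_rng(13)
        arr = rng.choice([0, 1, 2], size=(9, 9, 9), p=[0.6, 0.25, 0.15]).astype(np.int32)
        seg = make_labels(arr, {1: "metaphysis", 2: "epiphysis_center"})
        region = _mask(arr == 2)
        erased = erase_region(seg, region)
        assert not (erased.labels[region.mask] != 0).any()
        restored = erased.labels.copy()
        restored[region.mask] = arr[region.mask]
        assert np.array_equal(restored, arr)

    def test_total_and_empty_erase(self):
        seg = make_labels(np.ones((4, 4, 4), dtype=np.int32), {1: "metaphysis"})
        assert not erase_region(seg, _mask(np.ones((4, 4, 4)))).labels.any()
        assert np.array_equal(erase_region(seg, _mask(np.zeros((4, 4, 4)))).labels,
                              seg.labels)

    @pytest.mark.parametrize("centers,expected", [
        ([(5, 5, 5)], 1),
        ([(3, 3, 3), (3, 11, 3), (11, 3, 11)], 3),
    ])
    def test_component_count_of_disjoint_balls(self, centers, expected):
        arr = np.zeros((15, 15, 15), dtype=bool)
        for c in centers:
            arr |= ball_mask((15, 15, 15), c, 2.2)
        seg = make_labels(arr.astype(np.int32) * 2, {2: "epiphysis_center"})
        out, n = label_components(seg, "epiphysis_center")
        assert n == expected
        assert len(out.labels_for_role("epiphysis_center")) == expected

    def test_face_touching_balls_are_one_component(self):
        arr = np.zeros((9, 16, 9), dtype=bool)
        arr |= ball_mask((9, 16, 9), (4, 4, 4), 2.0)
        arr |= ball_mask((9, 16, 9), (4, 9, 4), 2.0)  # touching at a face
        assert ndimage.label(arr)[1] == 1  # sanity: oracle agrees they touch
        seg = make_labels(arr.astype(np.int32) * 2, {2: "epiphysis_center"})
        _, n = label_components(seg, "epiphysis_center")
        assert n == 1

    def test_absent_role_rejected(self):
        seg = make_labels(np.ones((3, 3, 3), dtype=np.int32), {1: "metaphysis"})
        with pytest.raises(LabelError):
            label_components(seg, "epiphysis_center")
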