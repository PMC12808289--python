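"""Profiles, the distal-cut rule, volumes and ratios."""

import math

import numpy as np
import pytest

from clavimetric import (
    Centerline,
    CrossSectionProfile,
    area_ratio,
    clip_at_cut,
    cross_section_profile,
    epiphysis_volume_by_subtraction,
    find_distal_cut,
    make_en_face_frame,
    project_silhouette,
    segment_volume,
)
from clavimetric.errors import ConsistencyError, GeometryError, LabelError
from clavimetric.geometry import Silhouette
from clavimetric.metrics import DistalCut

from conftest import ball_mask, make_labels


def _frame(px=0.4):
    # view along -x: distal direction is +x
    return make_en_face_frame(Centerline(proximal=(-30, 0, 0), distal=(0, 0, 0)), px)


def _profile(positions, diameters):
    positions = np.asarray(positions, dtype=float)
    return CrossSectionProfile(positions=positions,
                               areas=np.zeros_like(positions),
                               diameters=np.asarray(diameters, dtype=float),
                               axis_anchor=0.0)


class TestDistalCutRule:
    def test_cut_is_greatest_diameter_plus_one_third_radius(self):
        prof = _profile([0, 5, 10, 15], [4.0, 8.0, 12.0, 6.0])
        cut = find_distal_cut(prof)
        assert cut.s_star == 10.0
        assert cut.d_max == 12.0
        assert cut.cut_position == 12.0  # 10 + (12/2)/3, exact

    def test_constant_diameter_ties_resolve_most_proximal(self):
        prof = _profile([0, 0.5, 1.0, 1.5], [10.0, 10.0, 10.0, 10.0])
        assert find_distal_cut(prof).s_star == 0.0

    def test_tie_tolerance_treats_near_maxima_as_ties(self):
        prof = _profile([0, 0.5, 1.0], [9.8, 10.0, 9.0])
        assert find_distal_cut(prof).s_star == 0.5
        assert find_distal_cut(prof, tie_tolerance=0.3).s_star == 0.0

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ConsistencyError):
            find_distal_cut(_profile([0, 1], [0.0, 0.0]))

    def test_ellipsoid_greatest_diameter_at_equator(self):
        # ellipsoid semi-axes (8, 5, 5) mm along x: equator at x centre
        shape = (45, 30, 30)
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
        c = np.array([22, 15, 15])
        d = (idx - c) * 0.4 / np.array([8.0, 5.0, 5.0])
        seg = make_labels((np.sum(d**2, axis=-1) <= 1).astype(np.int32),
                          {1: "metaphysis"}, spacing=0.4)
        prof = cross_section_profile(seg, [1], _frame(), step=0.5)
        cut = find_distal_cut(prof)
        # proximal extent of the ellipsoid is 8 mm before the equator
        assert cut.s_star == pytest.approx(8.0, abs=0.5)
        assert cut.d_max == pytest.approx(10.0, rel=0.03)


class TestProfile:
    def test_cylinder_diameters_match_2r(self):
        arr = np.zeros((50, 30, 30), dtype=np.int32)
        yy, zz = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        disc = ((yy - 15.0) ** 2 + (zz - 15.0) ** 2) * 0.4**2 <= 5.0**2
        arr[5:45, disc] = 1
        seg = make_labels(arr, {1: "metaphysis"}, spacing=0.4)
        prof = cross_section_profile(seg, [1], _frame(), step=0.5)
        inner = prof.diameters[1:-2]  # skip the half-filled end slabs
        assert np.all(np.abs(inner - 10.0) <= 0.03 * 10.0)

    def test_cone_frustum_diameters_decrease_distally(self):
        # radius 8 mm at the proximal face tapering to 3 mm distally
        shape = (60, 50, 50)
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
        x = idx[..., 0] * 0.4
        rho = np.sqrt(((idx[..., 1] - 25) * 0.4) ** 2 + ((idx[..., 2] - 25) * 0.4) ** 2)
        r = 8.0 - (8.0 - 3.0) * x / (shape[0] * 0.4)
        seg = make_labels((rho <= r).astype(np.int32), {1: "metaphysis"}, spacing=0.4)
        prof = cross_section_profile(seg, [1], _frame(), step=0.5)
        d = prof.diameters[prof.diameters > 0]
        assert np.all(np.diff(d) <= 0.2)  # monotone within raster jitter
        assert d[0] > d[-1] + 4.0

    def test_single_voxel_slab_hits_exactly_one_sample(self):
        arr = np.zeros((20, 10, 10), dtype=np.int32)
        arr[10, 2:8, 2:8] = 1
        seg = make_labels(arr, {1: "metaphysis"}, spacing=0.4)
        prof = cross_section_profile(seg, [1], _frame(), step=0.5)
        assert int((prof.areas > 0).sum()) == 1

    def test_empty_labels_rejected(self):
        seg = make_labels(np.ones((4, 4, 4), dtype=np.int32), {1: "metaphysis"})
        with pytest.raises(LabelError):
            cross_section_profile(seg, [2], _frame())


class TestClip:
    def _rod(self, n=50):
        arr = np.zeros((n, 12, 12), dtype=np.int32)
        arr[:, 3:9, 3:9] = 1  # 20 mm rod along x at 0.4 mm
        return make_labels(arr, {1: "metaphysis"}, spacing=0.4)

    def test_cut_beyond_model_is_identity(self):
        seg = self._rod()
        prof = cross_section_profile(seg, [1], _frame(), step=0.5)
        cut = DistalCut(s_star=0.0, d_max=2.0, cut_position=100.0,
                        axis_anchor=prof.axis_anchor)
        with pytest.warns(UserWarning):
            out = clip_at_cut(seg, _frame(), cut)
        assert np.array_equal(out.labels, seg.labels)

    def test_rod_cut_12mm_from_distal_end_keeps_proximal_8mm(self):
        seg = self._rod()
        prof = cross_section_profile(seg, [1], _frame(), step=0.5)
        # rod is 20 mm; a cut 8 mm from the proximal end is 12 mm from the
        # distal end, so 8/20 of the voxels survive
        cut = DistalCut(s_star=2.0, d_max=36.0, cut_position=8.0,
                        axis_anchor=prof.axis_anchor)
        out = clip_at_cut(seg, _frame(), cut)
        frac = (out.labels == 1).sum() / (seg.labels == 1).sum()
        assert frac == pytest.approx(8.0 / 20.0, rel=0.02)
        # survivors are the proximal (small-x) end
        kept = np.argwhere(out.labels == 1)[:, 0]
        assert kept.max() < 25

    def test_cut_proximal_to_model_empties_grid(self):
        seg = self._rod()
        cut = DistalCut(s_star=0.0, d_max=2.0, cut_position=1e-6,
                        axis_anchor=100.0)  # plane proximal to everything
        out = clip_at_cut(seg, _frame(), cut)
        assert not out.labels.any()


class TestVolumes:
    def test_full_cube_is_exact(self):
        seg = make_labels(np.ones((10, 10, 10), dtype=np.int32), {1: "metaphysis"},
                          spacing=1.0)
        assert segment_volume(seg, [1]) == pytest.approx(1000.0)

    def test_ball_volume_within_2pc_of_analytic(self):
        mask = ball_mask((35, 35, 35), (17, 17, 17), 6.0, spacing=0.4)
        seg = make_labels(mask.astype(np.int32) * 3, {3: "epiphysis_center"}, spacing=0.4)
        assert segment_volume(seg, [3]) == pytest.approx(4 / 3 * math.pi * 216, rel=0.02)

    def test_absent_label_rejected(self):
        seg = make_labels(np.ones((3, 3, 3), dtype=np.int32), {1: "metaphysis"})
        with pytest.raises(LabelError):
            segment_volume(seg, [9])

    @pytest.mark.parametrize("combined,meta,expected", [(1000, 800, 200), (1000, 1000, 0)])
    def test_subtraction(self, combined, meta, expected):
        assert epiphysis_volume_by_subtraction(combined, meta) == expected

    def test_negative_subtraction_is_a_consistency_error(self):
        with pytest.raises(ConsistencyError):
            epiphysis_volume_by_subtraction(800.0, 1000.0)


class TestAreaRatio:
    def _sil(self, pixels, px=0.4):
        return Silhouette(pixels=np.asarray(pixels, dtype=bool), pixel_size=px,
                          frame=_frame(px))

    def test_equal_silhouettes_give_unity(self):
        s = self._sil(np.ones((5, 5)))
        assert area_ratio(s, s) == 1.0

    def test_empty_epiphysis_gives_zero(self):
        assert area_ratio(self._sil(np.zeros((4, 4))), self._sil(np.ones((4, 4)))) == 0.0

    def test_empty_metaphysis_rejected(self):
        with pytest.raises(ConsistencyError):
            area_ratio(self._sil(np.ones((4, 4))), self._sil(np.zeros((4, 4))))

    def test_mismatched_pixel_size_rejected(self):
        with pytest.raises(GeometryError):
            area_ratio(self._sil(np.ones((4, 4)), px=0.4), self._sil(np.ones((4, 4)), px=0.5))

    def test_disc_on_face_recovers_radius_ratio_squared(self):
        # epiphyseal disc radius 4 mm over a metaphyseal face radius 8 mm:
        # expected ratio (4/8)^2 = 0.25
        from clavimetric import EpiphysealCenter, generate_phantom, noise_free_spec

        spec = noise_free_spec(
            face_radius=8.0, shaft_proximal_radius=5.0, shaft_distal_radius=4.5,
            centers=(EpiphysealCenter(offset=(-3.0, 0.0, 0.0), radii=(2.0, 4.0, 4.0)),),
        )
        vol, truth = generate_phantom(spec)
        frame = make_en_face_frame(truth.centerline, 0.4)
        epi = project_silhouette(truth.label_grid, [2], frame)
        meta = project_silhouette(truth.label_grid, [1], frame)
        assert area_ratio(epi, meta) == pytest.approx(0.25, rel=0.05)
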