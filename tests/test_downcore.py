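"""Slice profiles, interval classification, BI banding and log combination."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ichnocore as ic
from ichnocore import downcore as dc
from ichnocore.shape_metrics import parameterise_component


def make_labels(shape, placements, spacing=(0.5, 0.5, 0.5)):
    """Labels from {label: list of (x, y, z)} placements."""
    arr = np.zeros(shape, np.int32)
    for lab, voxels in placements.items():
        for v in voxels:
            arr[v] = lab
    return ic.LabelVolume(labels=arr, spacing_mm=spacing)


def vertical_line(x, y, z0, z1):
    return [(x, y, z) for z in range(z0, z1)]


def horizontal_line(x0, x1, y, z):
    return [(x, y, z) for x in range(x0, x1)]


def components_for(labels):
    from ichnocore.segmentation import _component_coords

    return [
        parameterise_component(cid, coords, labels.spacing_mm)
        for cid, coords in zip(
            range(1, labels.n_components + 1),
            _component_coords(labels.labels, labels.n_components),
        )
    ]


class TestSliceProfiles:
    def test_pure_vertical_slice(self):
        labels = make_labels((8, 8, 12), {1: vertical_line(3, 3, 1, 11)})
        comps = components_for(labels)
        profiles = dc.slice_profiles(labels, comps, np.ones(labels.shape, bool))
        p = profiles[5]
        assert p.pct_vertical == 100.0
        assert p.pct_horizontal == 0.0

    def test_empty_slice_zeroes(self):
        labels = make_labels((8, 8, 12), {1: vertical_line(3, 3, 4, 10)})
        comps = components_for(labels)
        profiles = dc.slice_profiles(labels, comps, np.ones(labels.shape, bool))
        p = profiles[0]
        assert p.pct_vertical == p.pct_horizontal == 0.0
        assert p.fill_voxels == 0 and p.bioturbated_pct == 0.0

    def test_mixed_slice_percentages_match_brute_force(self):
        # slice z=5: 30 voxels of a vertical component, 10 of a horizontal one
        verts = {}
        verts[1] = sum(
            (vertical_line(2 + i, 2 + j, 1, 11) for i in range(6) for j in range(5)), []
        )[0:0]
        placements = {
            1: sum((vertical_line(2 + i, 2 + j, 1, 11) for i in range(6) for j in range(5)), []),
            2: horizontal_line(10, 25, 10, 5) + horizontal_line(10, 25, 11, 5),
        }
        labels = make_labels((32, 16, 12), placements)
        comps = components_for(labels)
        profiles = dc.slice_profiles(labels, comps, np.ones(labels.shape, bool))
        p = profiles[5]
        # brute-force count in that slice
        sl = labels.labels[:, :, 5]
        n1, n2 = (sl == 1).sum(), (sl == 2).sum()
        assert p.fill_voxels == n1 + n2 == 60
        assert p.pct_vertical == pytest.approx(100.0 * n1 / (n1 + n2)) == 50.0
        assert p.pct_vertical + p.pct_horizontal == 100.0

    def test_missing_component_record_errors(self):
        labels = make_labels((8, 8, 12), {1: vertical_line(3, 3, 1, 11)})
        with pytest.raises(ValueError, match=r"\b1\b"):
            dc.slice_profiles(labels, [], np.ones(labels.shape, bool))

    def test_bioturbated_pct_counts_fill_over_retained(self):
        labels = make_labels((10, 10, 4), {1: vertical_line(5, 5, 0, 4)})
        comps = components_for(labels)
        mask = np.zeros(labels.shape, bool)
        mask[0:5, :, :] = True
        mask[5, 5, :] = True  # 51 retained per slice, 1 is fill
        profiles = dc.slice_profiles(labels, comps, mask)
        assert profiles[0].bioturbated_pct == pytest.approx(100.0 / 51)

    def test_conservation_on_simulated_scene(self, three_tube_rendered):
        vol, truth = three_tube_rendered
        comps = components_for(truth.label_volume)
        profiles = dc.slice_profiles(truth.label_volume, comps, np.ones(vol.shape, bool))
        for p in profiles:
            if p.fill_voxels > 0:
                assert p.pct_vertical + p.pct_horizontal == pytest.approx(100.0)


class TestClassifyIntervals:
    def _profiles(self, pv_list, fill=100):
        return [
            dc.SliceProfile(
                slice_index=i, depth_cm=i * 0.05, pct_vertical=pv,
                pct_horizontal=100 - pv, fill_voxels=fill, retained_voxels=1000,
                bioturbated_pct=10.0,
            )
            for i, pv in enumerate(pv_list)
        ]

    def test_all_vertical_single_interval(self):
        iv = dc.classify_intervals(self._profiles([100.0] * 80))
        assert len(iv) == 1 and iv[0].klass == "V"
        assert iv[0].top_cm == 0.0 and iv[0].base_cm == pytest.approx(4.0)

    def test_constant_even_split_is_vh(self):
        iv = dc.classify_intervals(self._profiles([50.0] * 80))
        assert len(iv) == 1 and iv[0].klass == "V/H"

    def test_alternating_bands_recovered(self):
        pv = [95.0] * 60 + [5.0] * 60
        iv = dc.classify_intervals(self._profiles(pv))
        assert [i.klass for i in iv][0] == "V"
        assert [i.klass for i in iv][-1] == "H"

    def test_intervals_tile_section_exactly(self):
        pv = [95.0] * 30 + [50.0] * 30 + [5.0] * 30
        profs = self._profiles(pv)
        iv = dc.classify_intervals(profs)
        assert iv[0].top_cm == profs[0].depth_cm
        assert iv[-1].base_cm == pytest.approx(profs[-1].depth_cm + 0.05)
        for a, b in zip(iv[:-1], iv[1:]):
            assert a.base_cm == b.top_cm

    def test_empty_slices_inherit_class(self):
        profs = self._profiles([95.0] * 40)
        for p in profs[20:]:
            p.fill_voxels = 0
            p.pct_vertical = p.pct_horizontal = 0.0
        iv = dc.classify_intervals(profs)
        assert len(iv) == 1 and iv[0].klass == "V"

    def test_window_finer_than_spacing_errors(self):
        with pytest.raises(ValueError, match="slice spacing"):
            dc.classify_intervals(self._profiles([50.0] * 10), window_cm=0.01)


class TestBioturbationIndex:
    def _uniform_profiles(self, pct, n=40):
        return [
            dc.SliceProfile(
                slice_index=i, depth_cm=i * 0.05, pct_vertical=100.0,
                pct_horizontal=0.0, fill_voxels=int(pct * 10),
                retained_voxels=1000, bioturbated_pct=pct,
            )
            for i in range(n)
        ]

    @pytest.mark.parametrize(
        "pct,grade", [(0.0, 0), (2.0, 1), (4.0, 1), (20.0, 2), (50.0, 3), (75.0, 4), (95.0, 5), (100.0, 6)]
    )
    def test_band_lookup(self, pct, grade):
        assert dc.pct_to_bi(pct) == grade

    def test_zero_and_complete_bins(self):
        assert [r.bi for r in dc.bioturbation_index(self._uniform_profiles(0.0))] == [0]
        assert [r.bi for r in dc.bioturbation_index(self._uniform_profiles(100.0))] == [6]

    def test_half_filled_bin_grade_3(self):
        assert [r.bi for r in dc.bioturbation_index(self._uniform_profiles(50.0))] == [3]

    def test_bins_cover_section(self):
        recs = dc.bioturbation_index(self._uniform_profiles(10.0, n=100), bin_cm=2.0)
        assert recs[0].top_cm == 0.0
        assert recs[-1].base_cm == pytest.approx(5.0)
        assert all(a.base_cm == b.top_cm for a, b in zip(recs[:-1], recs[1:]))

    def test_non_monotone_bands_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            dc.bioturbation_index(self._uniform_profiles(10.0), bands=[(0, 0), (50, 2), (40, 1)])

    def test_bi_monotone_in_fill_pct(self):
        grades = [dc.pct_to_bi(p) for p in np.linspace(0, 100, 400)]
        assert grades == sorted(grades)


class TestCombineBI:
    def _rec(self, top, base, bi, source="ct", flag=False):
        return dc.BIRecord(top_cm=top, base_cm=base, bi=bi, source=source, disjoint_flag=flag)

    def test_ct_dominates_when_image_blind(self):
        out = dc.combine_bi([self._rec(0, 10, 4)], [self._rec(0, 10, 0, "image2d")])
        assert [r.bi for r in out] == [4]

    def test_both_zero(self):
        out = dc.combine_bi([self._rec(0, 10, 0)], [self._rec(0, 10, 0, "image2d")])
        assert [r.bi for r in out] == [0]

    def test_disjoint_bonus_caps_at_six(self):
        out = dc.combine_bi(
            [self._rec(0, 10, 4)], [self._rec(0, 10, 4, "image2d", flag=True)]
        )
        assert [r.bi for r in out] == [5]
        out = dc.combine_bi(
            [self._rec(0, 10, 6)], [self._rec(0, 10, 6, "image2d", flag=True)]
        )
        assert [r.bi for r in out] == [6]

    def test_misaligned_bins_rebinned_on_edge_union(self):
        ct = [self._rec(0, 10, 2), self._rec(10, 20, 4)]
        img = [self._rec(5, 15, 3, "image2d")]
        out = dc.combine_bi(ct, img)
        assert [(r.top_cm, r.base_cm, r.bi) for r in out] == [(5, 10, 3), (10, 15, 4)]

    def test_non_overlapping_coverage_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            dc.combine_bi([self._rec(0, 10, 2)], [self._rec(20, 30, 3, "image2d")])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        ct=st.integers(0, 6),
        img=st.integers(0, 6),
        flag=st.booleans(),
    )
    def test_combined_never_below_inputs_never_above_six(self, ct, img, flag):
        out = dc.combine_bi(
            [self._rec(0, 10, ct)], [self._rec(0, 10, img, "image2d", flag=flag)]
        )
        assert len(out) == 1
        assert out[0].bi >= max(ct, img)
        assert out[0].bi <= 6
        assert out[0].source == "combined"
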