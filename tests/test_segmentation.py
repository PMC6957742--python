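"""Marker generation, watershed, component separation and size filtering."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

import ichnocore as ic
from ichnocore import segmentation as seg
from ichnocore.segmentation import FILL_MARKER, HOST_MARKER


def flood_fill_oracle(mask: np.ndarray) -> np.ndarray:
    """Brute-force BFS 6-connected labelling, independent of scipy."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    nxt = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        queue = deque([start])
        labels[start] = nxt
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                p = (x + dx, y + dy, z + dz)
                if (
                    0 <= p[0] < mask.shape[0]
                    and 0 <= p[1] < mask.shape[1]
                    and 0 <= p[2] < mask.shape[2]
                    and mask[p]
                    and not labels[p]
                ):
                    labels[p] = nxt
                    queue.append(p)
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Label grids equal up to a label permutation."""
    if (a > 0).sum() != (b > 0).sum() or a.max() != b.max():
        return False
    pairs = set(zip(a[a > 0].ravel(), b[a > 0].ravel()))
    return len(pairs) == a.max() and len({p[0] for p in pairs}) == a.max()


class TestGenerateMarkers:
    def test_single_bright_voxel_is_sole_fill_marker(self):
        data = np.full((10, 10, 10), 5.0, np.float32)
        data[4, 4, 4] = 50.0
        vol = ic.CoreVolume(data=data, spacing_mm=(1, 1, 1))
        markers = seg.generate_markers(vol, seg.SegmentationParams(marker_quantile_fg=0.99))
        assert (markers == FILL_MARKER).sum() == 1
        assert markers[4, 4, 4] == FILL_MARKER

    def test_marker_classes_disjoint_and_respect_mask(self, rng):
        data = rng.normal(100, 10, size=(20, 20, 20)).astype(np.float32)
        mask = np.zeros(data.shape, bool)
        mask[5:15, 5:15, :] = True
        vol = ic.CoreVolume(data=data, spacing_mm=(1, 1, 1), mask=mask)
        markers = seg.generate_markers(vol)
        assert not ((markers == FILL_MARKER) & (markers == HOST_MARKER)).any()
        assert not markers[~mask].any()

    def test_constant_volume_errors(self):
        vol = ic.CoreVolume(data=np.full((8, 8, 8), 3.0, np.float32), spacing_mm=(1, 1, 1))
        with pytest.raises(ValueError, match="contrast"):
            seg.generate_markers(vol)

    def test_markers_inside_true_tube_at_high_contrast(self, three_tube_rendered):
        vol, truth = three_tube_rendered
        geom = ic.fit_core_geometry(vol)
        masked = ic.remove_liner_and_rim(vol, geom)
        markers = seg.generate_markers(masked)
        fill_markers = markers == FILL_MARKER
        inside = truth.label_volume.labels > 0
        assert fill_markers.sum() > 0
        assert (fill_markers & ~inside).sum() == 0

    def test_pure_noise_pipeline_yields_no_components(self):
        """Monte-Carlo: noise-only volumes segment to nothing at defaults."""
        survivors = 0
        for s in range(100):
            r = np.random.default_rng(s)
            data = r.normal(100, 10, size=(40, 40, 50)).astype(np.float32)
            vol = ic.CoreVolume(data=data, spacing_mm=(0.351, 0.351, 0.5))
            labels = seg.segment_burrows(vol)
            survivors += labels.n_components > 0
        assert survivors <= 5  # zero surviving components in >= 95% of seeds


class TestWatershed:
    def test_cylinder_jaccard(self, small_tube_rendered):
        vol, truth = small_tube_rendered
        geom = ic.fit_core_geometry(vol)
        masked = ic.remove_liner_and_rim(vol, geom)
        markers = seg.generate_markers(masked)
        fill = seg.watershed_segment(masked, markers)
        tru = truth.label_volume.labels > 0
        jaccard = (fill & tru).sum() / (fill | tru).sum()
        assert jaccard >= 0.8

    def test_fill_mask_contains_fill_markers(self, small_tube_rendered):
        vol, _ = small_tube_rendered
        geom = ic.fit_core_geometry(vol)
        masked = ic.remove_liner_and_rim(vol, geom)
        markers = seg.generate_markers(masked)
        fill = seg.watershed_segment(masked, markers)
        assert fill[markers == FILL_MARKER].all()

    def test_partition_of_retained_voxels(self, small_tube_rendered):
        vol, _ = small_tube_rendered
        geom = ic.fit_core_geometry(vol)
        masked = ic.remove_liner_and_rim(vol, geom)
        markers = seg.generate_markers(masked)
        surface_partition = seg.watershed_segment(masked, markers)
        # fill | host = retained: watershed assigns every retained voxel
        from skimage.segmentation import watershed as skws

        ws = skws(seg._flood_surface(masked, seg.SegmentationParams()), markers=markers,
                  mask=masked.retained(), connectivity=1)
        assert set(np.unique(ws[masked.retained()])) <= {FILL_MARKER, HOST_MARKER}
        assert np.array_equal(surface_partition, ws == FILL_MARKER)

    def test_only_marked_cylinder_segmented(self):
        """Two identical bright cylinders; markers only inside one of them."""
        data = np.full((40, 40, 30), 100.0, np.float32)
        a = (slice(8, 13), slice(8, 13), slice(5, 25))
        b = (slice(26, 31), slice(26, 31), slice(5, 25))
        data[a] = 180.0
        data[b] = 180.0
        vol = ic.CoreVolume(data=data, spacing_mm=(1, 1, 1))
        markers = np.zeros(data.shape, np.int32)
        markers[10, 10, 10:20] = FILL_MARKER
        markers[2, 2, :] = HOST_MARKER
        markers[37, 37, :] = HOST_MARKER
        fill = seg.watershed_segment(vol, markers)
        assert fill[a].mean() > 0.9
        assert fill[b].sum() == 0

    def test_missing_marker_class_errors(self):
        vol = ic.CoreVolume(data=np.zeros((5, 5, 5), np.float32), spacing_mm=(1, 1, 1))
        markers = np.zeros((5, 5, 5), np.int32)
        markers[0, 0, 0] = FILL_MARKER
        with pytest.raises(ValueError, match="host"):
            seg.watershed_segment(vol, markers)
        markers[:] = 0
        markers[0, 0, 0] = HOST_MARKER
        with pytest.raises(ValueError, match="fill"):
            seg.watershed_segment(vol, markers)

    def test_flat_surface_still_partitions(self):
        data = np.zeros((12, 12, 12), np.float32)
        vol = ic.CoreVolume(data=data, spacing_mm=(1, 1, 1))
        markers = np.zeros(data.shape, np.int32)
        markers[2, 2, 2] = FILL_MARKER
        markers[9, 9, 9] = HOST_MARKER
        fill = seg.watershed_segment(vol, markers)
        assert fill.any() and (~fill).any()
        assert fill.sum() + (~fill).sum() == data.size


class TestSeparateComponents:
    def test_two_cubes(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[2:5, 2:5, 2:5] = True
        mask[10:15, 10:15, 10:15] = True
        lab = seg.separate_components(mask, (1, 1, 1))
        assert lab.n_components == 2
        assert lab.labels[12, 12, 12] == 1  # bigger cube labelled first

    def test_empty_mask(self):
        lab = seg.separate_components(np.zeros((5, 5, 5), bool), (1, 1, 1))
        assert lab.n_components == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_flood_fill(self, seed):
        r = np.random.default_rng(seed)
        mask = r.random((20, 20, 20)) < 0.2
        lab = seg.separate_components(mask, (1, 1, 1))
        oracle = flood_fill_oracle(mask)
        assert same_partition(lab.labels, oracle)

    def test_label_conservation(self, rng):
        mask = rng.random((15, 15, 15)) < 0.3
        lab = seg.separate_components(mask, (1, 1, 1))
        assert (lab.labels > 0).sum() == mask.sum()
        counts = lab.voxel_counts()[1:]
        assert (counts > 0).all()
        assert sorted(counts, reverse=True) == counts.tolist()


class TestFilterSmall:
    def _tube_labels(self, n_vox_long, width, spacing=(0.5, 0.5, 0.5)):
        arr = np.zeros((20, 20, 40), np.int32)
        arr[2:2 + width, 2:2 + width, 2:2 + n_vox_long] = 1
        return ic.LabelVolume(labels=arr, spacing_mm=spacing)

    def test_thin_component_removed(self):
        lab = self._tube_labels(n_vox_long=20, width=1)  # equiv diameter ~0.56 mm
        assert seg.filter_small(lab, 1.0).n_components == 0

    def test_thick_component_retained(self):
        lab = self._tube_labels(n_vox_long=20, width=4)  # ~2 mm equivalent
        assert seg.filter_small(lab, 1.0).n_components == 1

    def test_threshold_zero_is_identity(self):
        lab = self._tube_labels(n_vox_long=20, width=1)
        out = seg.filter_small(lab, 0.0)
        assert np.array_equal(out.labels, lab.labels)

    def test_labels_compacted_after_filter(self):
        arr = np.zeros((30, 20, 40), np.int32)
        arr[2:8, 2:8, 2:30] = 1   # big -> kept
        arr[12, 12, 2:22] = 2     # thin line -> dropped
        arr[20:24, 12:16, 2:22] = 3  # kept
        lab = ic.LabelVolume(labels=arr, spacing_mm=(0.5, 0.5, 0.5))
        out = seg.filter_small(lab, 1.0)
        assert set(np.unique(out.labels)) == {0, 1, 2}
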