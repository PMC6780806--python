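"""Watershed instance segmentation of overlapped cells."""

import numpy as np
import pytest

from favf.errors import InvalidParameterError
from favf.imaging_model import make_cluster_scene, render_scene
from favf.instance_segmentation import (
    MarkerImage,
    binarize,
    channel_threshold,
    distance_markers,
    morphology_clean,
    overlap_judgement,
    segment_overlapped,
    watershed_separate,
)
from favf.planar_locating import Detection, make_reference_template, precise_locate


def det(x, y, w, h):
    return Detection(x + (w - 1) / 2, y + (h - 1) / 2, (x, y, w, h), 1.0, 0, "rough")


def disc_mask(shape, cx, cy, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


class TestOverlapJudgement:
    def test_disjoint_boxes_stay_singletons(self):
        groups = overlap_judgement([det(0, 0, 10, 10), det(30, 30, 10, 10)])
        assert groups == [[0], [1]]

    def test_intersecting_boxes_group(self):
        groups = overlap_judgement([det(0, 0, 10, 10), det(5, 5, 10, 10)])
        assert groups == [[0, 1]]

    def test_transitive_closure_chains(self):
        # A meets B, B meets C, A does not meet C
        groups = overlap_judgement(
            [det(0, 0, 10, 10), det(8, 0, 10, 10), det(16, 0, 10, 10)]
        )
        assert groups == [[0, 1, 2]]

    def test_touching_edges_do_not_group(self):
        groups = overlap_judgement([det(0, 0, 10, 10), det(10, 0, 10, 10)])
        assert groups == [[0], [1]]


class TestChannelOps:
    def test_red_channel_of_green_image_is_empty(self):
        img = np.zeros((10, 10, 3))
        img[..., 1] = 200.0
        assert np.all(channel_threshold(img, "red", 10.0) == 0.0)

    def test_zero_threshold_is_identity_on_support(self, rng):
        img = rng.uniform(1, 255, size=(8, 8, 3))
        assert np.array_equal(channel_threshold(img, "red", 0.0), img[..., 0])

    def test_disc_support_recovered(self):
        img = np.zeros((40, 40, 3))
        img[disc_mask((40, 40), 20, 20, 9), 0] = 180.0
        mask = channel_threshold(img, "red", 10.0)
        assert np.array_equal(mask > 0, disc_mask((40, 40), 20, 20, 9))

    def test_grayscale_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            channel_threshold(np.zeros((10, 10)), "red", 5.0)


class TestBinarize:
    def test_bimodal_threshold_between_modes(self):
        img = np.full((20, 20), 10.0)
        img[5:15, 5:15] = 200.0
        binary, degenerate = binarize(img)
        assert not degenerate
        assert np.array_equal(binary, img > 100)

    def test_constant_image_degenerate(self):
        binary, degenerate = binarize(np.full((10, 10), 42.0))
        assert degenerate and not binary.any()


class TestMorphologyClean:
    def test_isolated_pixel_removed(self):
        img = np.zeros((20, 20), dtype=bool)
        img[10, 10] = True
        assert not morphology_clean(img, 1).any()

    def test_large_disc_nearly_preserved(self):
        img = disc_mask((50, 50), 25, 25, 15)
        cleaned = morphology_clean(img, 2)
        assert cleaned.sum() >= disc_mask((50, 50), 25, 25, 13).sum()
        assert not (cleaned & ~img).any()

    def test_thin_bridge_severed(self):
        img = disc_mask((40, 80), 20, 20, 10) | disc_mask((40, 80), 60, 20, 10)
        img[20, 30:50] = True  # 1-px bridge
        cleaned = morphology_clean(img, 2)
        from scipy import ndimage as ndi

        _, n = ndi.label(cleaned)
        assert n == 2


class TestDistanceMarkers:
    def test_single_disc_single_marker(self):
        markers = distance_markers(disc_mask((40, 40), 20, 20, 10))
        assert markers.cell_marker_count == 1

    def test_two_overlapped_discs_two_markers(self):
        img = disc_mask((40, 60), 20, 20, 10) | disc_mask((40, 60), 20, 38, 10)
        markers = distance_markers(img, 0.6)
        assert markers.cell_marker_count == 2

    def test_empty_mask_background_only(self):
        markers = distance_markers(np.zeros((30, 30), dtype=bool))
        assert markers.cell_marker_count == 0
        assert (markers.labels == 1).sum() == 25  # 5x5 corner block

    @pytest.mark.parametrize("thr", [0.0, 1.0, -0.2])
    def test_invalid_threshold_rejected(self, thr):
        with pytest.raises(InvalidParameterError):
            distance_markers(np.zeros((10, 10), dtype=bool), thr)


class TestWatershed:
    def test_single_disc_center(self):
        img = np.full((40, 40), 8.0)
        img[disc_mask((40, 40), 22, 19, 10)] = 180.0
        markers = distance_markers(img > 100)
        seg = watershed_separate(img, markers)
        assert seg.count == 1
        cx, cy = seg.centers[0]
        assert abs(cx - 22) <= 2 and abs(cy - 19) <= 2

    def test_background_only_markers_yield_nothing(self):
        img = np.full((30, 30), 8.0)
        markers = MarkerImage(np.zeros((30, 30), dtype=np.int32))
        markers.labels[:5, :5] = 1
        seg = watershed_separate(img, markers)
        assert seg.count == 0

    def test_labels_partition_frame(self):
        img = np.full((40, 60), 8.0)
        img[disc_mask((40, 60), 20, 20, 10)] = 180.0
        img[disc_mask((40, 60), 20, 42, 10)] = 180.0
        markers = distance_markers(img > 100)
        seg = watershed_separate(img, markers)
        assert seg.count == 2
        assert (seg.labels > 0).all()  # every pixel claimed by some basin
        labels = set(np.unique(seg.labels))
        assert labels == {1, 2, 3}

    def test_centers_stable_under_marker_relabel(self):
        img = np.full((40, 60), 8.0)
        img[disc_mask((40, 60), 20, 20, 10)] = 180.0
        img[disc_mask((40, 60), 20, 42, 10)] = 180.0
        markers = distance_markers(img > 100)
        seg_a = watershed_separate(img, markers)
        # swap the two cell marker labels
        swapped = markers.labels.copy()
        swapped[markers.labels == 2] = 3
        swapped[markers.labels == 3] = 2
        seg_b = watershed_separate(img, MarkerImage(swapped))
        assert sorted(seg_a.centers) == pytest.approx(sorted(seg_b.centers), abs=1e-6)


class TestSegmentOverlapped:
    def _locate(self, img, optics, nms=6.0):
        ref = make_reference_template(optics)
        return precise_locate(img.channel("red"), ref, 0.5, nms_radius=nms)

    def test_two_touching_red_cells(self, optics):
        scene = make_cluster_scene(2, seed=1)
        img = render_scene(scene, 0.0, optics)
        dets = self._locate(img, optics)
        groups = overlap_judgement(dets)
        group = max(groups, key=len)
        assert len(group) >= 2
        seg = segment_overlapped(img.pixels, dets, group)
        assert seg.count == 2
        for cell in scene.cells:
            assert min(
                np.hypot(cx - cell.x, cy - cell.y) for cx, cy in seg.centers
            ) <= 5.0

    def test_green_neighbour_excluded_by_red_channel(self, optics):
        from dataclasses import replace

        scene = make_cluster_scene(3, seed=2)
        scene.cells[2] = replace(scene.cells[2], color="green")
        img = render_scene(scene, 0.0, optics)
        dets = self._locate(img, optics)
        group = list(range(len(dets)))
        seg = segment_overlapped(img.pixels, dets, group)
        assert seg.count == 2

    def test_fewer_regions_than_detections_flagged(self, optics):
        # two detections pointing at one cell: under-segmentation is
        # reported, not retried
        scene = make_cluster_scene(1, seed=0)
        img = render_scene(scene, 0.0, optics)
        d0 = det(56, 56, 16, 16)
        d1 = det(60, 60, 16, 16)
        seg = segment_overlapped(img.pixels, [d0, d1], [0, 1])
        assert seg.count == 1
        assert seg.under_segmented
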