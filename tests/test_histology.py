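"""Slide segmentation, morphological refinement and cylinder-model caliber."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import draw, measure

from vsimetry.histology import (
    HueModel,
    aggregate_rois,
    quantify,
    refine_objects,
    sample_rois,
    segment_vessels,
    vessel_size_index,
)
from vsimetry.synthetic import SlideSpec, render_slide

radii_sets = st.lists(st.floats(1.0, 50.0), min_size=1, max_size=20)


class TestCaliberFormula:
    def test_two_vessel_direct_summation(self):
        # (5^{4/3} + 10^{4/3}) / (25 + 100), then power -3/2
        num = 5.0 ** (4 / 3) + 10.0 ** (4 / 3)
        assert vessel_size_index([5.0, 10.0]) == pytest.approx(
            (num / 125.0) ** -1.5, rel=1e-14)
        assert vessel_size_index([5.0, 10.0]) == pytest.approx(8.4652588, abs=1e-6)

    @given(r=st.floats(0.5, 100.0), n=st.integers(1, 40))
    @settings(max_examples=60, deadline=None)
    def test_monodisperse_identity(self, r, n):
        assert vessel_size_index([r] * n) == pytest.approx(r, rel=1e-12)

    @given(radii=radii_sets, c=st.floats(0.1, 10.0))
    @settings(max_examples=60, deadline=None)
    def test_scale_equivariance(self, radii, c):
        assert vessel_size_index(np.array(radii) * c) == pytest.approx(
            c * vessel_size_index(radii), rel=1e-9)

    @given(radii=radii_sets)
    @settings(max_examples=60, deadline=None)
    def test_bounded_by_extreme_radii(self, radii):
        v = vessel_size_index(radii)
        assert min(radii) * (1 - 1e-12) <= v <= max(radii) * (1 + 1e-12)

    def test_counts_equivalent_to_repetition(self):
        assert vessel_size_index([5.0, 10.0], counts=[2, 3]) == pytest.approx(
            vessel_size_index([5.0, 5.0, 10.0, 10.0, 10.0]), rel=1e-12)

    def test_empty_set_undefined(self):
        assert np.isnan(vessel_size_index([]))

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            vessel_size_index([3.0, 0.0])


class TestSegmentation:
    def test_empty_slide_gives_no_labels(self):
        rgb, truth = render_slide(SlideSpec(image_shape=(256, 256),
                                            vessel_count_target=0, seed=0))
        labels = segment_vessels(rgb)
        assert truth.count == 0
        assert refine_objects(labels, um_per_px=2.0).max() == 0

    def test_well_separated_disks_counted_exactly(self):
        spec = SlideSpec(image_shape=(512, 512), um_per_px=2.0,
                         vessel_radii=(8.0,) * 10, min_gap_px=15, seed=2)
        rgb, truth = render_slide(spec)
        labels = refine_objects(segment_vessels(rgb), um_per_px=2.0)
        assert labels.max() == truth.count == 10

    def test_grayscale_image_is_degenerate(self):
        gray = np.repeat(np.random.default_rng(0).integers(
            0, 255, (64, 64, 1), dtype=np.uint8), 3, axis=2)
        with pytest.raises(ValueError, match="degenerate"):
            segment_vessels(gray)

    def test_overlapping_hue_model_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            HueModel(vessel_hue=(0.4, 0.7), nuclei_hue=(0.5, 0.8))

    def test_oracle_counts_and_radii(self, rendered_slide_50):
        """Non-touching rendered vessels: exact count, tight radius recovery."""
        spec, rgb, truth = rendered_slide_50
        labels = refine_objects(segment_vessels(rgb), um_per_px=spec.um_per_px)
        res = quantify(labels, um_per_px=spec.um_per_px)
        assert res.vessel_count == truth.count
        assert res.density == pytest.approx(truth.density, rel=1e-12)
        # match each recovered object to the nearest true center
        from scipy.spatial import cKDTree
        props = measure.regionprops(labels)
        centers = np.array([p.centroid for p in props])
        _, idx = cKDTree(truth.centers_px).query(centers)
        rec_r = np.array([np.sqrt(p.area / np.pi) for p in props]) * spec.um_per_px
        err = np.abs(rec_r - truth.radii_um[idx])
        tol = np.maximum(spec.um_per_px, 0.05 * truth.radii_um[idx])
        assert np.all(err <= tol)


class TestRefinement:
    def test_solid_disk_is_fixed_point(self):
        img = np.zeros((64, 64), bool)
        rr, cc = draw.disk((32, 32), 12)
        img[rr, cc] = True
        out = refine_objects(measure.label(img), um_per_px=2.0)
        assert out.max() == 1
        np.testing.assert_array_equal(out > 0, img)

    def test_annulus_fills_to_outer_radius(self):
        img = np.zeros((64, 64), bool)
        rr, cc = draw.disk((32, 32), 15)
        img[rr, cc] = True
        rr, cc = draw.disk((32, 32), 9)
        img[rr, cc] = False
        out = refine_objects(measure.label(img), um_per_px=1.0)
        area = (out > 0).sum()
        assert np.sqrt(area / np.pi) == pytest.approx(15.0, abs=1.0)

    def test_double_lumen_object_split_in_two(self):
        # two rings sharing one wall -> one connected object, two lumens
        img = np.zeros((80, 120), bool)
        for cx in (40, 68):
            rr, cc = draw.disk((40, cx), 16)
            img[rr, cc] = True
        for cx in (40, 68):
            rr, cc = draw.disk((40, cx), 10)
            img[rr, cc] = False
        assert measure.label(img).max() == 1
        out = refine_objects(measure.label(img), um_per_px=1.0,
                             join_distance_um=0.0, closing_radius_px=0)
        assert out.max() == 2

    def test_nearby_fragments_joined(self):
        img = np.zeros((60, 60), bool)
        img[20:40, 10:28] = True
        img[20:40, 30:48] = True   # 2-px gap
        out = refine_objects(measure.label(img), um_per_px=1.0,
                             join_distance_um=5.0)
        assert out.max() == 1


class TestQuantifyAndAggregate:
    def test_density_from_field_area(self):
        labels = np.zeros((100, 100), int)
        for i, (y, x) in enumerate([(20, 20), (20, 80), (80, 20), (80, 80)], 1):
            rr, cc = draw.disk((y, x), 5)
            labels[rr, cc] = i
        res = quantify(labels, um_per_px=10.0)  # 1 mm x 1 mm field
        assert res.field_area_mm2 == pytest.approx(1.0)
        assert res.density == pytest.approx(4.0)

    def test_empty_labels_flagged(self):
        res = quantify(np.zeros((50, 50), int), um_per_px=2.0)
        assert res.vessel_count == 0 and res.density == 0.0
        assert not res.vsi_defined

    def test_zero_field_area_rejected(self):
        with pytest.raises(ValueError):
            quantify(np.zeros((10, 10), int), um_per_px=1.0, field_area_mm2=0.0)

    def test_aggregate_means_and_counts(self):
        from vsimetry.histology import MorphometryResult
        rois = [MorphometryResult(vessel_count=c, density=d, vsi_histo=v,
                                  radii_um=np.array([v]), field_area_mm2=1.0)
                for c, d, v in ((5, 10.0, 10.0), (8, 20.0, 12.0), (9, 30.0, 14.0))]
        agg = aggregate_rois(rois)
        assert agg.density == pytest.approx(20.0)
        assert agg.vsi_histo == pytest.approx(12.0)
        assert agg.vessel_count == 22
        with pytest.raises(ValueError):
            aggregate_rois([])

    def test_quadrant_tiling_conserves_density(self):
        """Counts summed over 4 quadrants reproduce whole-field density."""
        rng = np.random.default_rng(5)
        labels = np.zeros((200, 200), int)
        k = 1
        for qy, qx in [(0, 0), (0, 100), (100, 0), (100, 100)]:
            for _ in range(6):  # disks strictly inside each quadrant
                y, x = rng.integers(15, 85, 2)
                pad_rr, pad_cc = draw.disk((qy + y, qx + x), 9)
                if labels[pad_rr, pad_cc].any():  # keep disks non-touching
                    continue
                rr, cc = draw.disk((qy + y, qx + x), 6)
                labels[rr, cc] = k
                k += 1
        whole = quantify(labels, um_per_px=5.0)
        quads = [quantify(measure.label(labels[sy:sy + 100, sx:sx + 100] > 0),
                          um_per_px=5.0)
                 for sy in (0, 100) for sx in (0, 100)]
        total = sum(q.vessel_count for q in quads)
        area = sum(q.field_area_mm2 for q in quads)
        assert total == whole.vessel_count
        assert total / area == pytest.approx(whole.density, rel=1e-12)

    def test_roi_sampling_non_overlapping(self):
        rois = sample_rois((600, 600), n=3, roi_size=200, seed=0)
        assert len(rois) == 3
        boxes = [(s[0].start, s[1].start) for s in rois]
        for i in range(3):
            for j in range(i + 1, 3):
                dy = abs(boxes[i][0] - boxes[j][0])
                dx = abs(boxes[i][1] - boxes[j][1])
                assert dy >= 200 or dx >= 200


class TestRendererTruth:
    def test_truth_vsi_consistent_with_formula(self, rendered_slide_50):
        _, _, truth = rendered_slide_50
        assert truth.vsi_histo == pytest.approx(
            vessel_size_index(truth.radii_um), rel=1e-15)

    def test_monodisperse_field_truth(self):
        spec = SlideSpec(image_shape=(500, 500), um_per_px=2.0,
                         vessel_radii=(5.0,) * 10, seed=3)
        _, truth = render_slide(spec)
        assert truth.density == pytest.approx(10.0 / spec.field_area_mm2)
        assert truth.vsi_histo == pytest.approx(5.0)

    def test_impossible_packing_raises(self):
        from vsimetry.synthetic import PackingError
        spec = SlideSpec(image_shape=(64, 64), um_per_px=1.0,
                         vessel_radii=(30.0,) * 10, seed=0)
        with pytest.raises(PackingError):
            render_slide(spec)
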