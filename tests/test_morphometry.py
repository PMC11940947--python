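import numpy as np
import pytest
from skimage.draw import disk

import histofuse as hf
from histofuse.morphometry import (CellContour, CellFeatures, detect_edges,
                                   find_contours, measure_contour,
                                   measure_detections, polygon_area,
                                   summarize_features, threshold_binary,
                                   to_grayscale)


def square_contour(side=20.0):
    return CellContour(vertices=np.array(
        [[0.0, 0.0], [side, 0.0], [side, side], [0.0, side]]))


class TestThreshold:
    def test_bimodal_image_recovers_disc(self):
        img = np.full((64, 64), 50.0)
        rr, cc = disk((32, 32), 15)
        img[rr, cc] = 200.0
        mask = threshold_binary(img)
        truth = np.zeros((64, 64), bool)
        truth[rr, cc] = True
        # agreement within a 1-px boundary band
        from scipy.ndimage import binary_dilation, binary_erosion
        assert (mask | binary_dilation(truth))[binary_erosion(truth)].all()
        assert not mask[~binary_dilation(truth)].any()

    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = threshold_binary(np.full((16, 16), 7.0))
        assert not mask.any()

    def test_polarity_contract(self):
        img = np.full((64, 64), 40.0)
        rr, cc = disk((32, 32), 12)
        img[rr, cc] = 210.0
        assert np.array_equal(threshold_binary(img),
                              threshold_binary(255 - img, cells_bright=False))


class TestEdges:
    def test_constant_image_has_no_edges(self):
        assert not detect_edges(np.full((32, 32), 99.0)).any()

    def test_disc_edge_is_thin_ring_near_true_circle(self):
        img = np.full((64, 64), 50.0)
        rr, cc = disk((32, 32), 20)
        img[rr, cc] = 200.0
        e = detect_edges(img)
        ys, xs = np.nonzero(e)
        r = np.hypot(ys - 32, xs - 32)
        assert len(ys) > 0
        assert (np.abs(r - 20) <= 1.5).all()

    def test_edges_invariant_to_negation(self):
        img = np.full((64, 64), 50.0)
        rr, cc = disk((32, 32), 12)
        img[rr, cc] = 180.0
        assert np.array_equal(detect_edges(img), detect_edges(255 - img))


class TestContours:
    def test_counts_disjoint_discs(self):
        mask = np.zeros((100, 100), bool)
        for cy, cx in [(20, 20), (20, 70), (70, 45)]:
            rr, cc = disk((cy, cx), 8)
            mask[rr, cc] = True
        assert len(find_contours(mask, min_area=10)) == 3

    def test_min_area_filters_everything(self):
        mask = np.zeros((50, 50), bool)
        rr, cc = disk((25, 25), 5)
        mask[rr, cc] = True
        assert find_contours(mask, min_area=1e4) == []

    def test_annulus_hole_is_filled_and_recorded(self):
        mask = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 15)
        mask[rr, cc] = True
        rr, cc = disk((30, 30), 6)
        mask[rr, cc] = False
        (contour,) = find_contours(mask, min_area=10)
        assert contour.has_holes
        # outer contour: area close to full disc, not the annulus
        area = polygon_area(contour.vertices)
        assert area > np.pi * 14**2

    def test_border_touching_component_flagged(self):
        mask = np.zeros((40, 40), bool)
        mask[0:10, 5:15] = True
        (contour,) = find_contours(mask)
        assert contour.touches_border

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            CellContour(vertices=np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestMeasure:
    def test_square_closed_form(self):
        f = measure_contour(square_contour(20.0), np.full((30, 30), 128.0))
        assert f.area == 400.0
        assert f.perimeter == 80.0
        assert f.compactness == pytest.approx(np.pi / 4)

    def test_rasterized_disc_close_to_analytic(self):
        mask = np.zeros((64, 64), bool)
        rr, cc = disk((32, 32), 20)
        mask[rr, cc] = True
        (contour,) = find_contours(mask)
        f = measure_contour(contour, np.full((64, 64), 100.0))
        assert abs(f.area - np.pi * 400) / (np.pi * 400) < 0.05
        assert f.compactness >= 0.85

    def test_min_intensity_found_inside(self):
        img = np.full((30, 30), 128.0)
        img[10, 10] = 0.0
        f = measure_contour(square_contour(20.0), img)
        assert f.min_intensity == 0.0

    def test_circle_maximizes_compactness_in_shape_set(self):
        shapes = {}
        mask = np.zeros((120, 120), bool)
        rr, cc = disk((30, 30), 20)
        mask[rr, cc] = True
        shapes["circle"] = mask.copy()
        mask[:] = False
        mask[10:50, 70:110] = True
        shapes["square"] = mask.copy()
        mask[:] = False
        yy, xx = np.mgrid[0:120, 0:120]
        mask[((yy - 90) / 10) ** 2 + ((xx - 30) / 30) ** 2 <= 1] = True
        shapes["ellipse_3to1"] = mask.copy()
        mask[:] = False
        mask[80:100, 70:110] = True
        mask[70:110, 85:95] = True
        shapes["cross"] = mask.copy()
        comp = {}
        for name, m in shapes.items():
            (contour,) = find_contours(m)
            comp[name] = measure_contour(contour, np.full((120, 120), 1.0)).compactness
        assert max(comp, key=comp.get) == "circle"
        assert all(c <= 1.1 for c in comp.values())

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_scaling_laws(self, k):
        base_r = 10
        mask = np.zeros((128, 128), bool)
        rr, cc = disk((64, 64), base_r * k)
        mask[rr, cc] = True
        (contour,) = find_contours(mask)
        f = measure_contour(contour, np.full((128, 128), 1.0))
        assert abs(f.area - np.pi * (base_r * k) ** 2) / (np.pi * (base_r * k) ** 2) < 0.05
        assert abs(f.perimeter - 2 * np.pi * base_r * k) / (2 * np.pi * base_r * k) < 0.05


class TestSummaries:
    def test_mean_of_two_cells(self):
        feats = [CellFeatures(100.0, 40.0, 0.785, 10.0),
                 CellFeatures(300.0, 60.0, 0.6, 30.0)]
        s = summarize_features(feats)
        assert s["n"] == 2
        assert s["mean_area"] == 200.0
        assert s["mean_perimeter"] == 50.0
        assert s["mean_min_intensity"] == 20.0

    def test_single_cell_means_equal_features(self):
        f = CellFeatures(123.0, 45.0, 0.7, 9.0)
        s = summarize_features([f])
        assert s["mean_area"] == f.area and s["n"] == 1

    def test_empty_list_reports_n_zero_without_means(self):
        s = summarize_features([])
        assert s == {"n": 0}


def test_pipeline_closure_recovers_planted_round_cells():
    """generate -> threshold -> contours finds exactly the planted count."""
    s = hf.generate_slide(512, 512,
                          {"round_positive": 25, "ramified_positive": 0,
                           "negative": 0}, "Iba1", seed=5)
    mask = threshold_binary(to_grayscale(s.image))
    contours = find_contours(mask, min_area=20)
    assert len(contours) == 25


def test_measure_detections_table_schema():
    s = hf.generate_slide(256, 256,
                          {"round_positive": 8, "ramified_positive": 0,
                           "negative": 0}, "Iba1", seed=6)
    centers = np.array([(c.x, c.y) for c in s.cells])
    table = measure_detections(s.image, centers, slide_id="s", marker="Iba1")
    assert len(table) == 8
    assert {"area_px2", "perimeter_px", "compactness",
            "min_intensity"} <= set(table.columns)
    assert (table.area_px2 > 0).all()
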