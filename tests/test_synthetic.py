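import numpy as np
import pytest

import histofuse as hf
from histofuse.synthetic import (PHENOTYPES, PlacementError, SerialPanelConfig,
                                 StainParams, generate_serial_panel,
                                 generate_slide, ground_truth_heatmap,
                                 realized_coloc_fraction)


def counts(r=0, m=0, n=0):
    return {"round_positive": r, "ramified_positive": m, "negative": n}


class TestGenerateSlide:
    def test_empty_slide_is_background_only(self):
        s = generate_slide(512, 512, counts(), "Iba1", seed=1)
        assert s.cells == []
        # background is pale: every channel bright, blue-ish tint
        mean = s.image.mean(axis=(0, 1))
        assert mean.min() > 200 and mean[2] > mean[0]

    def test_seed_determinism_bit_identical(self):
        a = generate_slide(512, 512, counts(20, 5, 5), "Iba1", seed=7)
        b = generate_slide(512, 512, counts(20, 5, 5), "Iba1", seed=7)
        assert np.array_equal(a.image, b.image)
        assert a.cells == b.cells

    def test_different_seeds_differ(self):
        a = generate_slide(256, 256, counts(10), "Iba1", seed=1)
        b = generate_slide(256, 256, counts(10), "Iba1", seed=2)
        assert not np.array_equal(a.image, b.image)

    def test_ground_truth_conservation_and_invariants(self):
        s = generate_slide(1024, 1024, counts(50, 50, 50), "CD163", seed=3)
        assert len(s.cells) == 150
        by_ph = {ph: sum(c.phenotype == ph for c in s.cells) for ph in PHENOTYPES}
        assert by_ph == counts(50, 50, 50)
        for c in s.cells:
            assert 0 <= c.x < 1024 and 0 <= c.y < 1024
            assert c.radius_px >= 2
            if c.phenotype == "round_positive":
                assert c.n_processes == 0
            if c.phenotype == "ramified_positive":
                assert c.n_processes >= 2

    def test_rendered_disc_area_matches_geometry(self):
        """Mean segmented disc area agrees with pi*r^2 within 10%."""
        from histofuse.morphometry import (find_contours, measure_contour,
                                           threshold_binary, to_grayscale)

        s = generate_slide(1024, 1024, counts(r=50), "CD163", seed=3)
        mask = threshold_binary(to_grayscale(s.image))
        contours = find_contours(mask, min_area=20)
        assert len(contours) == 50
        measured = np.mean([measure_contour(c, to_grayscale(s.image, invert=False)).area
                            for c in contours])
        expected = np.mean([np.pi * c.radius_px**2 for c in s.cells])
        assert abs(measured - expected) / expected < 0.10

    def test_placement_error_reports_achieved_count(self):
        with pytest.raises(PlacementError) as err:
            generate_slide(128, 128, counts(r=500), "Iba1", seed=1)
        assert err.value.achieved < err.value.requested == 500

    def test_rejects_tiny_slide_and_bad_counts(self):
        with pytest.raises(ValueError):
            generate_slide(64, 512, counts(1), "Iba1", seed=1)
        with pytest.raises(ValueError):
            generate_slide(512, 512, {"round_positive": -1}, "Iba1", seed=1)
        with pytest.raises(ValueError):
            generate_slide(512, 512, {"blob": 3}, "Iba1", seed=1)


class TestSerialPanel:
    def test_full_coloc_places_partner_within_radius(self):
        cfg = SerialPanelConfig(markers=("A", "B"), image_size=(512, 512),
                                n_round=30, n_ramified=5, n_negative=5,
                                coloc_fraction=1.0, coloc_radius=12.0)
        slides, manifest = generate_serial_panel(cfg, seed=2)
        assert len(slides) == 2
        frac = realized_coloc_fraction(slides[0], slides[1], cfg.coloc_radius)
        assert frac == 1.0
        assert manifest["markers"]["B"]["realized_coloc_fraction"] == 1.0

    def test_zero_coloc_matches_uniform_null(self):
        """With coloc 0 the realized nearest-neighbor co-occurrence should
        match a Monte-Carlo estimate of uniform placement."""
        rng = np.random.default_rng(0)
        h = w = 1024
        n_pos = 150
        radius = 12.0
        null = []
        for _ in range(40):
            a = rng.uniform(0, [w, h], size=(n_pos, 2))
            b = rng.uniform(0, [w, h], size=(n_pos, 2))
            from scipy.spatial import cKDTree
            d, _ = cKDTree(b).query(a)
            null.append((d <= radius).mean())
        expected = np.mean(null)
        sd = np.std(null)

        fracs = []
        for seed in range(3):
            cfg = SerialPanelConfig(markers=("A", "B"), image_size=(h, w),
                                    n_round=100, n_ramified=50, n_negative=10,
                                    coloc_fraction=0.0, coloc_radius=radius)
            slides, _ = generate_serial_panel(cfg, seed=seed)
            fracs.append(realized_coloc_fraction(slides[0], slides[1], radius))
        assert abs(np.mean(fracs) - expected) < 4 * sd + 0.02

    def test_section_offset_recovered_by_mask_cross_correlation(self):
        """Exhaustive +-32 px shift search on the binarized cell masks must
        peak at the configured section offset."""
        from histofuse.morphometry import threshold_binary, to_grayscale

        cfg = SerialPanelConfig(markers=("A", "B"), image_size=(256, 256),
                                n_round=40, n_ramified=0, n_negative=0,
                                coloc_fraction=1.0, coloc_radius=2.0,
                                section_offsets={"B": (15, -9)})
        slides, _ = generate_serial_panel(cfg, seed=3)
        ma = threshold_binary(to_grayscale(slides[0].image))
        mb = threshold_binary(to_grayscale(slides[1].image))
        best = None
        for dy in range(-32, 33):
            for dx in range(-32, 33):
                score = (np.roll(np.roll(ma, dy, 0), dx, 1) & mb).sum()
                if best is None or score > best[0]:
                    best = (score, dx, dy)
        assert abs(best[1] - 15) <= 3 and abs(best[2] + 9) <= 3

    def test_coloc_fraction_converges_binomially(self):
        cfg = SerialPanelConfig(markers=("A", "B"), image_size=(1024, 1024),
                                n_round=200, n_ramified=0, n_negative=0,
                                coloc_fraction=0.5, coloc_radius=12.0)
        fracs = [generate_serial_panel(cfg, seed=s)[1]["markers"]["B"]
                 ["realized_coloc_fraction"] for s in range(3)]
        se = np.sqrt(0.5 * 0.5 / 200)
        # uniform extras can also land within the radius, so only an upper
        # deviation bound plus chance co-occurrence is asserted
        assert all(0.5 - 3 * se <= f <= 0.5 + 3 * se + 0.15 for f in fracs)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SerialPanelConfig(markers=("A",))
        with pytest.raises(ValueError):
            SerialPanelConfig(markers=("A", "B"), coloc_fraction=1.5)
        with pytest.raises(ValueError):
            SerialPanelConfig(markers=("A", "B"), image_size=(128, 128),
                              coloc_radius=200.0)
        with pytest.raises(ValueError):
            SerialPanelConfig(markers=("A", "B"),
                              section_offsets={"B": (1000, 0)})


class TestGroundTruthHeatmap:
    def test_marks_positive_cells_only(self):
        s = generate_slide(256, 256, counts(5, 0, 5), "A", seed=4)
        hm = ground_truth_heatmap(s, stride=10)
        det = hf.detect_cells(hm)
        from scipy.spatial import cKDTree
        pos = np.array([(c.x, c.y) for c in s.cells
                        if c.phenotype != "negative"])
        d, _ = cKDTree(det).query(pos)
        assert (d <= 10).all()

    def test_empty_slide_gives_zero_grid(self):
        s = generate_slide(128, 128, counts(), "A", seed=4)
        hm = ground_truth_heatmap(s, stride=10)
        assert hm.grid.sum() == 0


def test_write_slide_round_trip(tmp_path):
    import imageio.v3 as iio
    import pandas as pd

    s = generate_slide(128, 128, counts(3, 2, 1), "Iba1", seed=9)
    paths = hf.synthetic.write_slide(s, tmp_path)
    img = iio.imread(paths["image"])
    assert np.array_equal(img, s.image)
    cells = pd.read_csv(paths["cells"])
    assert len(cells) == 6
    assert set(cells.phenotype) <= set(PHENOTYPES)
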