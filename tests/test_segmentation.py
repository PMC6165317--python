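"""Edge-detection segmentation stages on constructed fixtures."""

import numpy as np
import pytest

from shadematch.colorspace import RGBColor, delta_e, lab_to_rgb, rgb_to_lab
from shadematch.errors import SegmentationError
from shadematch.segmentation import (
    GrayscaleMap,
    IntraoralImage,
    binarize,
    emphasize_edges,
    label_regions,
    mean_region_color,
    select_central_region,
    segment_target,
    tooth_grayscale,
)
from shadematch.synthetic_data import render_scene, three_teeth_spec


def _image(pixels):
    return IntraoralImage(pixels=np.asarray(pixels, dtype=np.uint8))


def _rect_image(h=64, w=64, lo=10, hi=100, rect=(20, 20, 24, 24)):
    """Grayscale fixture: bright rectangle on a dark field."""
    gray = np.full((h, w), lo, dtype=np.uint8)
    x0, y0, rw, rh = rect
    gray[y0 : y0 + rh, x0 : x0 + rw] = hi
    return GrayscaleMap(gray), rect


class TestToothGrayscale:
    @pytest.mark.parametrize(
        "pixel, expected",
        [((100, 100, 80), 100), ((200, 100, 80), 0), ((150, 100, 90), 50)],
    )
    def test_formula_on_single_pixels(self, pixel, expected):
        img = _image(np.full((32, 32, 3), pixel, dtype=np.uint8))
        assert tooth_grayscale(img).values[0, 0] == expected

    def test_blue_channel_is_ignored(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        other = base.copy()
        other[..., 2] = rng.integers(0, 256, (32, 32))
        assert np.array_equal(
            tooth_grayscale(_image(base)).values,
            tooth_grayscale(_image(other)).values,
        )


class TestEmphasizeEdges:
    def test_constant_image_has_no_edges(self):
        gray = GrayscaleMap(np.full((48, 48), 77, dtype=np.uint8))
        assert not emphasize_edges(gray).any()

    def test_edges_surround_a_bright_rectangle(self):
        gray, (x0, y0, rw, rh) = _rect_image()
        edges = emphasize_edges(gray)
        # every boundary pixel of the rectangle has an edge pixel within 2 px
        boundary = []
        for x in range(x0, x0 + rw):
            boundary += [(y0, x), (y0 + rh - 1, x)]
        for y in range(y0, y0 + rh):
            boundary += [(y, x0), (y, x0 + rw - 1)]
        ey, ex = np.nonzero(edges)
        covered = sum(
            1
            for (by, bx) in boundary
            if np.min(np.abs(ey - by) + np.abs(ex - bx)) <= 2
        )
        assert covered >= 0.95 * len(boundary)

    def test_morphology_does_not_reduce_coverage(self):
        gray, _ = _rect_image()
        with_m = emphasize_edges(gray, morphology_enabled=True)
        without = emphasize_edges(gray, morphology_enabled=False)
        assert with_m.sum() >= without.sum()
        assert (with_m & without).sum() == without.sum()


class TestBinarize:
    def test_threshold_between_region_and_surround(self):
        gray, (x0, y0, rw, rh) = _rect_image(lo=10, hi=100)
        edges = emphasize_edges(gray)
        binary = binarize(gray, edges)
        interior = binary[y0 + 3 : y0 + rh - 3, x0 + 3 : x0 + rw - 3]
        assert interior.all()
        assert not binary[:10, :10].any()

    def test_constant_edge_gray_gives_that_threshold(self):
        gray = GrayscaleMap(np.full((40, 40), 50, dtype=np.uint8))
        edges = np.zeros((40, 40), dtype=bool)
        edges[20, 10:30] = True
        binary = binarize(gray, edges)  # t = 50, nothing exceeds it
        assert not binary.any()

    def test_empty_edge_map_is_an_error(self):
        gray = GrayscaleMap(np.full((40, 40), 50, dtype=np.uint8))
        with pytest.raises(SegmentationError, match="edge"):
            binarize(gray, np.zeros((40, 40), dtype=bool))


class TestLabelRegions:
    def test_counts_disjoint_rectangles(self):
        binary = np.zeros((40, 40), dtype=bool)
        binary[5:15, 5:15] = True
        binary[25:35, 25:35] = True
        assert label_regions(binary).label_count == 2
        single = np.zeros((40, 40), dtype=bool)
        single[5:15, 5:15] = True
        result = label_regions(single)
        assert result.label_count == 1
        assert np.array_equal(result.mask, single)

    def test_checkerboard_matches_flood_fill_oracle(self):
        yy, xx = np.mgrid[0:12, 0:12]
        board = ((yy + xx) % 2 == 0)
        got = label_regions(board, connectivity=1).label_count

        # brute-force 4-connected flood fill
        seen = np.zeros_like(board)
        count = 0
        for y in range(12):
            for x in range(12):
                if board[y, x] and not seen[y, x]:
                    count += 1
                    stack = [(y, x)]
                    while stack:
                        cy, cx = stack.pop()
                        if not (0 <= cy < 12 and 0 <= cx < 12):
                            continue
                        if not board[cy, cx] or seen[cy, cx]:
                            continue
                        seen[cy, cx] = True
                        stack += [(cy + 1, cx), (cy - 1, cx), (cy, cx + 1), (cy, cx - 1)]
        assert got == count == board.sum()

    def test_no_foreground_is_an_error(self):
        with pytest.raises(SegmentationError):
            label_regions(np.zeros((40, 40), dtype=bool))


class TestSelectCentralRegion:
    def test_prefers_centered_component(self):
        binary = np.zeros((60, 60), dtype=bool)
        binary[25:35, 25:35] = True  # centered
        binary[0:10, 0:10] = True  # corner, equal size
        regions = label_regions(binary)
        chosen = select_central_region(regions, (60, 60))
        assert chosen.mask[30, 30] and not chosen.mask[5, 5]

    def test_single_component_is_itself(self):
        binary = np.zeros((60, 60), dtype=bool)
        binary[10:20, 40:55] = True
        regions = label_regions(binary)
        chosen = select_central_region(regions, (60, 60))
        assert np.array_equal(chosen.mask, binary)

    def test_area_floor_rejects_specks(self):
        binary = np.zeros((60, 60), dtype=bool)
        binary[30, 30] = True
        regions = label_regions(binary)
        with pytest.raises(SegmentationError, match="floor"):
            select_central_region(regions, (60, 60))


class TestMeanRegionColor:
    def test_uniform_region(self):
        img = _image(np.full((32, 32, 3), (120, 130, 140), dtype=np.uint8))
        mask = np.ones((32, 32), dtype=bool)
        from shadematch.segmentation import RegionMask

        got = mean_region_color(img, RegionMask(mask=mask, label_count=1))
        assert got.to_array() == pytest.approx(np.array([120, 130, 140]) / 255)

    def test_half_black_half_white(self):
        px = np.zeros((32, 32, 3), dtype=np.uint8)
        px[:16] = 255
        from shadematch.segmentation import RegionMask

        got = mean_region_color(
            _image(px), RegionMask(mask=np.ones((32, 32), dtype=bool), label_count=1)
        )
        assert got.to_array() == pytest.approx([0.5, 0.5, 0.5])

    def test_noisy_mean_within_statistical_bound(self):
        rng = np.random.default_rng(3)
        painted = np.array([150.0, 140.0, 120.0])
        px = np.clip(rng.normal(painted, 3.0, (64, 64, 3)), 0, 255).astype(np.uint8)
        from shadematch.segmentation import RegionMask

        got = mean_region_color(
            _image(px), RegionMask(mask=np.ones((64, 64), dtype=bool), label_count=1)
        )
        bound = 3 * 3.0 / np.sqrt(64 * 64) / 255 + 0.5 / 255  # 3 sigma + rounding
        assert np.all(np.abs(got.to_array() - painted / 255) < bound)


class TestSegmentTarget:
    def test_recovers_painted_color_on_clean_scene(self, palette):
        tab_rgb = lab_to_rgb(palette["2M2"])
        spec = three_teeth_spec(tab_rgb, noise_sd=2.0)
        img, truth = render_scene(spec, tab_rgb, np.random.default_rng(1))
        region, color = segment_target(img)
        iou = (region.mask & truth).sum() / (region.mask | truth).sum()
        painted = rgb_to_lab(RGBColor(*np.round(tab_rgb.to_array() * 255) / 255))
        assert iou >= 0.9
        assert delta_e(rgb_to_lab(color), painted).delta_e < 2.0

    def test_glare_patch_with_exclusion_stays_close(self, palette):
        tab_rgb = lab_to_rgb(palette["2M2"])
        rng = np.random.default_rng(1)
        clean_spec = three_teeth_spec(tab_rgb, noise_sd=2.0)
        img, _ = render_scene(clean_spec, tab_rgb, rng)
        _, clean = segment_target(img)
        glare_spec = three_teeth_spec(tab_rgb, noise_sd=2.0, glare=True)
        img_g, _ = render_scene(glare_spec, tab_rgb, rng)
        _, glared = segment_target(img_g, glare_exclude=True, glare_percentile=93)
        painted = rgb_to_lab(RGBColor(*np.round(tab_rgb.to_array() * 255) / 255))
        de_clean = delta_e(rgb_to_lab(clean), painted).delta_e
        de_glare = delta_e(rgb_to_lab(glared), painted).delta_e
        assert de_glare <= max(2 * de_clean, 0.5)

    def test_all_black_image_fails_with_stage_name(self):
        img = _image(np.zeros((48, 48, 3), dtype=np.uint8))
        with pytest.raises(SegmentationError, match="stage"):
            segment_target(img)

    def test_pipeline_is_deterministic(self, palette):
        tab_rgb = lab_to_rgb(palette["3M2"])
        spec = three_teeth_spec(tab_rgb, noise_sd=2.0)
        img, _ = render_scene(spec, tab_rgb, np.random.default_rng(9))
        r1, c1 = segment_target(img)
        r2, c2 = segment_target(img)
        assert np.array_equal(r1.mask, r2.mask)
        assert c1 == c2
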