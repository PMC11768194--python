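import numpy as np
import pytest
from hypothesis import given, strategies as st
from PIL import Image

from breadtex.crumb import (
    CrumbImage,
    NoContrastWarning,
    PoreRegion,
    SizeClassConfig,
    classify_sizes,
    extract_regions,
    load_slice,
    render_colourmap,
    segment_pores,
    slice_from_pil,
)
from breadtex.synthetic import CrumbSceneSpec, generate_crumb_image


def _scene_image(spec: CrumbSceneSpec):
    image, truth = generate_crumb_image(spec)
    return CrumbImage(pixels=image, slice_mask=truth.slice_mask), truth


class TestLoadSlice:
    def test_all_white_is_empty_slice(self, tmp_path):
        path = tmp_path / "white.png"
        Image.fromarray(np.full((20, 20), 255, dtype=np.uint8)).save(path)
        with pytest.raises(ValueError, match="empty slice"):
            load_slice(path)

    def test_generated_scene_mask_matches_ellipse(self, tmp_path):
        image, truth = generate_crumb_image(CrumbSceneSpec(n_pores=12, noise_sd=4.0, seed=8))
        path = tmp_path / "crumb.png"
        Image.fromarray(image).save(path)
        loaded = load_slice(path)
        # any disagreement must sit in a 1-px band around the ellipse edge
        from scipy.ndimage import binary_dilation, binary_erosion

        band = binary_dilation(truth.slice_mask) & ~binary_erosion(truth.slice_mask)
        disagree = loaded.slice_mask != truth.slice_mask
        assert not (disagree & ~band).any()

    def test_alpha_passthrough(self):
        rgba = np.zeros((10, 10, 4), dtype=np.uint8)
        rgba[2:8, 2:8] = (100, 100, 100, 255)
        loaded = slice_from_pil(Image.fromarray(rgba, mode="RGBA"), background_mode="alpha")
        assert np.array_equal(loaded.slice_mask, rgba[..., 3] > 0)

    def test_alpha_mode_requires_alpha(self):
        grey = Image.fromarray(np.full((5, 5), 100, dtype=np.uint8))
        with pytest.raises(ValueError, match="alpha"):
            slice_from_pil(grey, background_mode="alpha")

    def test_none_mode_keeps_everything(self):
        grey = Image.fromarray(np.full((5, 5), 255, dtype=np.uint8))
        loaded = slice_from_pil(grey, background_mode="none")
        assert loaded.slice_mask.all()


class TestSegmentation:
    def test_uniform_slice_no_contrast(self):
        image = CrumbImage(pixels=np.full((30, 30), 120.0), slice_mask=np.ones((30, 30), bool))
        with pytest.warns(NoContrastWarning):
            labels = segment_pores(image)
        assert labels.max() == 0

    def test_ground_truth_recovery_exact(self):
        spec = CrumbSceneSpec(
            n_pores=10, pore_radius_median=6.0, pore_radius_sigma=0.0, noise_sd=0.0, seed=21
        )
        image, truth = _scene_image(spec)
        labels = segment_pores(image)
        assert labels.max() == 10
        # every predicted region's pixel set equals one ground-truth disk
        for gt_id in range(1, 11):
            sel = truth.label_mask == gt_id
            pred = np.unique(labels[sel])
            assert pred.size == 1 and pred[0] > 0
            assert np.array_equal(labels == pred[0], sel)

    def test_connectivity_oracle(self):
        # two 2x2 squares touching at exactly one diagonal pixel pair
        pixels = np.full((10, 10), 200.0)
        pixels[2:4, 2:4] = 10.0
        pixels[4:6, 4:6] = 10.0
        image = CrumbImage(pixels=pixels, slice_mask=np.ones((10, 10), bool))
        conn8 = segment_pores(image, SizeClassConfig(connectivity=8))
        conn4 = segment_pores(image, SizeClassConfig(connectivity=4))
        assert conn8.max() == 1
        assert conn4.max() == 2

    def test_no_pores_returns_zero_regions(self):
        # a single dark speck below the min_area noise floor: no regions
        pixels = np.full((20, 20), 200.0)
        pixels[5, 5] = 10.0
        image = CrumbImage(pixels=pixels, slice_mask=np.ones((20, 20), bool))
        labels = segment_pores(image, SizeClassConfig(min_area=2))
        assert labels.max() == 0

    def test_min_area_monotonicity(self):
        image, _ = _scene_image(CrumbSceneSpec(n_pores=40, noise_sd=6.0, seed=13))
        totals = []
        for min_area in (1, 2, 10, 50, 100):
            config = SizeClassConfig(min_area=min_area)
            labels = segment_pores(image, config)
            regions = extract_regions(labels, image)
            totals.append(classify_sizes(regions, image.slice_area, config).n_total)
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_kmeans_variant_matches_on_clean_scene(self):
        spec = CrumbSceneSpec(n_pores=15, noise_sd=0.0, seed=4)
        image, truth = _scene_image(spec)
        labels = segment_pores(image, SizeClassConfig(method="kmeans"))
        assert labels.max() == 15


class TestRegions:
    def test_hand_computed_square(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[0:3, 0:3] = 1
        regions = extract_regions(labels)
        assert len(regions) == 1
        region = regions[0]
        assert region.area == 9
        assert region.centroid == (1.0, 1.0)
        assert region.touches_border

    def test_generator_oracle_areas(self):
        spec = CrumbSceneSpec(n_pores=20, noise_sd=0.0, seed=17)
        image, truth = _scene_image(spec)
        regions = extract_regions(segment_pores(image), image)
        assert sorted(r.area for r in regions) == sorted(truth.region_table.area_px)

    def test_empty_label_map(self):
        assert extract_regions(np.zeros((5, 5), dtype=np.int32)) == []

    def test_mm_scale(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:4, 2:4] = 1
        image = CrumbImage(
            pixels=np.zeros((8, 8)), slice_mask=np.ones((8, 8), bool), scale_px_per_mm=2.0
        )
        (region,) = extract_regions(labels, image)
        assert region.area_mm2 == pytest.approx(4 / 4.0)


def _region(area, rid=1):
    return PoreRegion(region_id=rid, area=area, centroid=(0, 0), bbox=(0, 0, 1, 1), touches_border=False)


class TestClassifySizes:
    def test_no_regions(self):
        stats = classify_sizes([], slice_area=100)
        assert (stats.n_small, stats.n_medium, stats.n_large, stats.n_total) == (0, 0, 0, 0)
        assert stats.porosity == 0.0
        assert stats.mean_pore_area == 0.0

    def test_band_assignment(self):
        regions = [_region(a, i) for i, a in enumerate([5, 50, 500, 5000], 1)]
        config = SizeClassConfig(min_area=2, small_max=100, medium_max=1000)
        stats = classify_sizes(regions, slice_area=10_000, config=config)
        assert (stats.n_small, stats.n_medium, stats.n_large, stats.n_total) == (2, 1, 1, 4)
        assert stats.porosity == pytest.approx(5555 / 10_000)

    @given(st.lists(st.integers(min_value=2, max_value=20_000), max_size=30))
    def test_partition_identity(self, areas):
        regions = [_region(a, i) for i, a in enumerate(areas, 1)]
        stats = classify_sizes(regions, slice_area=10**9)
        assert stats.n_small + stats.n_medium + stats.n_large == stats.n_total

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SizeClassConfig(small_max=1000, medium_max=100)
        with pytest.raises(ValueError):
            SizeClassConfig(min_area=0)
        with pytest.raises(ValueError):
            SizeClassConfig(connectivity=6)

    def test_porosity_rotation_and_mirror_invariant(self):
        image, _ = _scene_image(CrumbSceneSpec(n_pores=25, noise_sd=5.0, seed=31))
        def porosity(img):
            labels = segment_pores(img)
            regions = extract_regions(labels, img)
            return classify_sizes(regions, img.slice_area).porosity

        base = porosity(image)
        for transform in (np.rot90, np.flipud, np.fliplr):
            turned = CrumbImage(
                pixels=transform(image.pixels), slice_mask=transform(image.slice_mask)
            )
            assert porosity(turned) == pytest.approx(base, abs=0)


class TestColourmap:
    def test_equal_areas_same_colour(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[1:3, 1:3] = 1
        labels[6:8, 6:8] = 2
        regions = extract_regions(labels)
        out = render_colourmap(labels, regions)
        assert np.array_equal(out[1, 1], out[6, 6])

    def test_per_image_normalization(self):
        # the same area maps to different colours when the image's area
        # range differs
        labels_a = np.zeros((20, 20), dtype=np.int32)
        labels_a[0:2, 0:2] = 1  # area 4 (the max in image A)
        labels_a[10, 10] = 2
        labels_b = np.zeros((20, 20), dtype=np.int32)
        labels_b[0:2, 0:2] = 1  # area 4 (the min in image B)
        labels_b[5:15, 5:15] = 2
        colour_a = render_colourmap(labels_a, extract_regions(labels_a))[0, 0]
        colour_b = render_colourmap(labels_b, extract_regions(labels_b))[0, 0]
        assert not np.array_equal(colour_a, colour_b)

    def test_zero_regions_neutral(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        out = render_colourmap(labels, [])
        assert (out == 220).all()

    def test_deterministic(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:5, 2:5] = 1
        regions = extract_regions(labels)
        assert np.array_equal(render_colourmap(labels, regions), render_colourmap(labels, regions))
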