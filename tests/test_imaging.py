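import numpy as np
import pytest

from ramanmet.imaging import (
    CellMask,
    ImageChannel,
    detect_lipid_droplets,
    extract_region_spectrum,
    huang_fuzziness,
    huang_threshold_mask,
    label_cells,
    lipid_channel_image,
    ratio_image,
    region_mean,
)
from ramanmet.spectra import normalize_to_anchor, peak_ratio
from ramanmet.synthetic import simulate_srs_field


def brute_force_huang(image, n_bins=256):
    """Independent exhaustive fuzziness minimization (plain loops)."""
    x = np.asarray(image, dtype=float).ravel()
    lo, hi = x.min(), x.max()
    g = np.minimum(((x - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    hist = np.bincount(g, minlength=n_bins).astype(float)
    C = n_bins - 1
    best_t, best_f = None, np.inf
    for t in range(n_bins - 1):
        lowh = hist[: t + 1].sum()
        highh = hist[t + 1 :].sum()
        if lowh == 0 or highh == 0:
            continue
        m0 = (hist[: t + 1] * np.arange(t + 1)).sum() / lowh
        m1 = (hist[t + 1 :] * np.arange(t + 1, n_bins)).sum() / highh
        f = 0.0
        for gg in range(n_bins):
            if hist[gg] == 0:
                continue
            m = m0 if gg <= t else m1
            mu = 1.0 / (1.0 + abs(gg - m) / C)
            mu = min(max(mu, 1e-12), 1 - 1e-12)
            f += hist[gg] * (-mu * np.log(mu) - (1 - mu) * np.log(1 - mu))
        if f < best_f:
            best_f, best_t = f, t
    return best_t


class TestHuang:
    def test_bimodal_image_split_exactly(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.uniform(size=(40, 40)) < 0.3, 200.0, 10.0)
        mask = huang_threshold_mask(ImageChannel(img))
        np.testing.assert_array_equal(mask.pixels == 1, img == 200.0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="separable"):
            huang_threshold_mask(ImageChannel(np.full((16, 16), 3.0)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, (64, 64))
        assert int(np.argmin(huang_fuzziness(img))) == brute_force_huang(img)

    def test_matches_brute_force_oracle_structured(self):
        _, ch3, _, _, _ = simulate_srs_field(2, 0, 128, seed=0)
        img = ch3.pixels
        assert int(np.argmin(huang_fuzziness(img))) == brute_force_huang(img)

    def test_mask_values_are_binary(self, srs_field):
        mask = huang_threshold_mask(srs_field[1])
        assert set(np.unique(mask.pixels)) <= {0, 1}


class TestRatioImage:
    def test_constant_channels(self):
        ch2 = ImageChannel(np.ones((8, 8)))
        ch3 = ImageChannel(2 * np.ones((8, 8)))
        mask = CellMask(np.ones((8, 8)), threshold_value=0.0)
        np.testing.assert_array_equal(ratio_image(ch2, ch3, mask), 0.5)

    def test_scale_invariance(self, srs_field):
        ch2, ch3 = srs_field[0], srs_field[1]
        mask = huang_threshold_mask(ch3)
        r1 = ratio_image(ch2, ch3, mask)
        r2 = ratio_image(
            ImageChannel(3 * ch2.pixels), ImageChannel(3 * ch3.pixels), mask
        )
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_zero_denominator_and_outside_mask_map_to_zero(self):
        ch2 = ImageChannel(np.ones((2, 2)))
        ch3 = ImageChannel(np.array([[1.0, 0.0], [1.0, 1.0]]))
        mask = CellMask(np.array([[1, 1], [0, 1]]), threshold_value=0.0)
        out = ratio_image(ch2, ch3, mask)
        assert out[0, 1] == 0.0 and out[1, 0] == 0.0 and out[0, 0] == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ratio_image(
                ImageChannel(np.ones((2, 2))),
                ImageChannel(np.ones((3, 3))),
                CellMask(np.ones((2, 2)), 0.0),
            )

    def test_per_cell_means_recover_planted_ratios(self):
        ch2, ch3, _, _, truth = simulate_srs_field(4, 0, 256, seed=1)
        mask = huang_threshold_mask(ch3)
        rimg = ratio_image(ch2, ch3, mask)
        labels = truth.extras["cell_labels"]
        for k, planted in truth.extras["cell_ratio"].items():
            region = (labels == int(k)) & (mask.pixels != 0)
            est = rimg[region].mean()
            assert est == pytest.approx(planted, rel=0.02)


class TestLipidChannel:
    @pytest.mark.parametrize(
        "ch2,ch3,expected",
        [(1.0, 0.0, 5.0), (0.4, 5.0, 0.0), (0.0, 1.0, 0.0)],
    )
    def test_linear_combination(self, ch2, ch3, expected):
        out = lipid_channel_image(
            ImageChannel(np.full((2, 2), ch2)), ImageChannel(np.full((2, 2), ch3))
        )
        np.testing.assert_allclose(out.pixels, expected, atol=1e-12)


class TestRegionMean:
    def test_constancy_and_self_normalization(self):
        img = ImageChannel(np.full((4, 4), 0.3))
        region = np.ones((4, 4), dtype=bool)
        assert region_mean(img, region) == pytest.approx(0.3)
        assert region_mean(img, region, reference_group_mean=0.3) == pytest.approx(1.0)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            region_mean(ImageChannel(np.ones((4, 4))), np.zeros((4, 4), dtype=bool))

    def test_relative_means_recover_fold_changes(self):
        # per-cell CH2 level over a shared reference behaves like the
        # relative C-D quantification (reference group maps to 1)
        ch2, ch3, _, _, truth = simulate_srs_field(4, 0, 256, seed=2)
        labels = truth.extras["cell_labels"]
        level = {
            k: truth.extras["cell_ratio"][k] * truth.extras["cell_ch3_level"][k]
            for k in truth.extras["cell_ratio"]
        }
        ref_key = min(level, key=level.get)
        ref = region_mean(ch2, labels == int(ref_key))
        for k, lv in level.items():
            rel = region_mean(ch2, labels == int(k), reference_group_mean=ref)
            assert rel == pytest.approx(lv / level[ref_key], rel=0.05)


class TestDropletDetection:
    def test_planted_droplets_recovered(self, srs_field):
        ch2, ch3, _, _, truth = srs_field
        mask = huang_threshold_mask(ch3)
        ds = detect_lipid_droplets(ch2, mask)
        assert len(ds) == len(truth.droplet_centers)
        for tr, tc, _ in truth.droplet_centers:
            d = np.min(np.hypot(ds.centroids[:, 0] - tr, ds.centroids[:, 1] - tc))
            assert d <= 1.0

    def test_background_only_no_detections(self):
        rng = np.random.default_rng(0)
        img = ImageChannel(np.abs(rng.normal(0, 0.01, (128, 128))))
        mask = CellMask(np.ones((128, 128)), 0.0)
        assert len(detect_lipid_droplets(img, mask)) == 0

    def test_regions_disjoint_and_inside_mask(self, srs_field):
        ch2, ch3 = srs_field[0], srs_field[1]
        mask = huang_threshold_mask(ch3)
        ds = detect_lipid_droplets(ch2, mask)
        total = np.zeros(ch2.shape, dtype=int)
        for r in ds.regions:
            total += r.pixels.astype(int)
            assert np.all(mask.pixels[r.pixels] == 1)
        assert total.max() <= 1

    def test_sensitivity_and_fdr_across_fields(self):
        hits, truths, detections = 0, 0, 0
        for seed in range(3):
            ch2, ch3, _, _, truth = simulate_srs_field(4, 3, 256, seed=seed)
            mask = huang_threshold_mask(ch3)
            ds = detect_lipid_droplets(ch2, mask)
            detections += len(ds)
            truths += len(truth.droplet_centers)
            for tr, tc, trad in truth.droplet_centers:
                if len(ds) and np.min(
                    np.hypot(ds.centroids[:, 0] - tr, ds.centroids[:, 1] - tc)
                ) <= max(2.0, trad):
                    hits += 1
        assert hits / truths >= 0.95
        assert (detections - hits) / detections <= 0.05


class TestSpectrumExtraction:
    def test_uniform_stack(self):
        wns = np.array([2800.0, 2900.0, 3000.0])
        stack = np.stack([np.full((4, 4), v) for v in (1.0, 2.0, 3.0)])
        region = np.zeros((4, 4), dtype=bool)
        region[1:3, 1:3] = True
        spec = extract_region_spectrum(stack, wns, region)
        np.testing.assert_allclose(spec.intensities, [1.0, 2.0, 3.0])

    def test_single_pixel_region(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(1, 2, size=(5, 3, 3))
        region = np.zeros((3, 3), dtype=bool)
        region[2, 1] = True
        spec = extract_region_spectrum(stack, np.arange(5.0) + 2800, region)
        np.testing.assert_array_equal(spec.intensities, stack[:, 2, 1])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_region_spectrum(np.ones((2, 3, 3)), [2800.0, 2900.0], np.zeros((3, 3), bool))

    def test_droplet_ul_ratio_recovered(self):
        ch2, ch3, stack, wns, truth = simulate_srs_field(
            2, 3, 256, seed=0, hyperspectral=True
        )
        mask = huang_threshold_mask(ch3)
        ds = detect_lipid_droplets(ch2, mask)
        assert len(ds) == len(truth.droplet_centers)
        for reg in ds.regions:
            spec = normalize_to_anchor(extract_region_spectrum(stack, wns, reg.pixels))
            ul = peak_ratio(spec, 3022.0, 2908.0, half_window=0)
            assert ul == pytest.approx(truth.extras["ul_ratio"], rel=0.03)


class TestLabelCells:
    def test_counts_connected_cells(self, srs_field):
        mask = huang_threshold_mask(srs_field[1])
        assert label_cells(mask).max() == 4
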