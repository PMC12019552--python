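"""Stack averaging, cluster segmentation/counting, FRET ratio, ROS readout."""

import numpy as np
import pytest

from nanospt.imagequant import (SegmentParams, average_stack, cluster_density,
                                fret_ratio, mean_intensity, segment_clusters)
from nanospt.simulate import render_frames
import pandas as pd


def spot_image(centers_px, photons=400, bg=20, shape=(128, 128), pixel=0.102,
               noise=False, seed=0):
    locs = pd.DataFrame({
        "frame": 0, "x_um": [c[0] * pixel for c in centers_px],
        "y_um": [c[1] * pixel for c in centers_px],
        "intensity": 1.0, "sigma_um": 0.0, "molecule_id": -1})
    return render_frames(locs, 1.5 * pixel, photons, bg, pixel, shape=shape,
                         poisson_noise=noise, seed=seed)[0]


class TestAverageStack:
    def test_constant_stack(self):
        assert np.all(average_stack(np.full((100, 4, 4), 3.5)) == 3.5)

    def test_alternating_frames_average_to_midpoint(self):
        stack = np.zeros((100, 3, 3))
        stack[1::2] = 2.0
        assert np.all(average_stack(stack) == 1.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="60"):
            average_stack(np.zeros((60, 4, 4)), n_frames=100)

    def test_averaging_gains_sqrt_n_in_snr(self):
        rng = np.random.default_rng(0)
        truth = np.full((64, 64), 9.0)
        truth[30:34, 30:34] = 100.0
        stack = rng.poisson(truth, size=(100, 64, 64)).astype(float)
        sig = stack[:, 32, 32]
        noise_single = np.std(sig)
        avg = average_stack(stack, 100)
        # residual noise of the mean is ~sqrt(100) smaller
        gain = noise_single / np.abs(avg[32, 32] - 100.0).clip(1e-3)
        assert gain > 3  # sqrt(100)=10 in expectation; loose one-sample bound


class TestSegmentAndCount:
    def test_flat_image_empty_mask(self):
        assert segment_clusters(np.full((64, 64), 7.0)).max() == 0

    def test_disjoint_spots_one_label_each(self):
        img = spot_image([(20, 20), (60, 20), (40, 60)], noise=False)
        labels = segment_clusters(img)
        assert labels.max() == 3

    def test_25_spots_with_subthreshold_distractors(self):
        gx, gy = np.meshgrid(np.arange(5), np.arange(5))
        centers = [(14 + 20 * x, 14 + 20 * y)
                   for x, y in zip(gx.ravel(), gy.ravel())]
        img = spot_image(centers, photons=1500, noise=True, seed=1)
        faint = spot_image([(104, 10), (10, 104), (104, 104)], photons=15,
                           bg=0, noise=False)
        labels = segment_clusters(img + faint)
        assert labels.max() == 25

    def test_determinism(self):
        img = spot_image([(30, 40), (80, 90)], noise=True, seed=2)
        a = segment_clusters(img)
        b = segment_clusters(img.copy())
        np.testing.assert_array_equal(a, b)

    def test_count_in_roi_by_centroid(self):
        mask = np.zeros((200, 200), dtype=int)
        # 5 inside the 100x100 ROI, 2 outside
        for k, (r, c) in enumerate([(10, 10), (30, 50), (50, 30), (70, 70),
                                    (90, 90), (150, 150), (10, 180)], start=1):
            mask[r:r + 3, c:c + 3] = k
        out = cluster_density(mask, roi=(0, 0, 100, 100))
        assert out.n_clusters == 5

    def test_empty_mask_zero(self):
        out = cluster_density(np.zeros((120, 120), dtype=int))
        assert out.n_clusters == 0

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            cluster_density(np.zeros((50, 50), dtype=int), roi=(0, 0, 100, 100))

    def test_density_invariant_to_roi_translation(self):
        rng = np.random.default_rng(3)
        centers = [(rng.uniform(10, 290), rng.uniform(10, 290))
                   for _ in range(200)]
        mask = np.zeros((300, 300), dtype=int)
        for k, (r, c) in enumerate(centers, start=1):
            mask[int(r):int(r) + 2, int(c):int(c) + 2] = k
        counts = []
        for _ in range(10):
            r0 = int(rng.uniform(0, 200))
            c0 = int(rng.uniform(0, 200))
            counts.append(cluster_density(mask, (r0, c0, 100, 100)).n_clusters)
        expect = 200 * (100 / 300) ** 2
        assert abs(np.mean(counts) - expect) < 3 * np.sqrt(expect)


class TestFretRatio:
    def test_identical_channels_ratio_one(self):
        img = np.full((32, 32), 50.0)
        ratio = fret_ratio(img, img, bg_method=0.0)
        assert np.allclose(ratio, 1.0)

    def test_doubled_numerator_ratio_two(self):
        venus = np.full((16, 16), 80.0)
        ratio = fret_ratio(2 * venus, venus, bg_method=0.0)
        assert np.allclose(ratio, 2.0)

    def test_common_scaling_invariance(self):
        rng = np.random.default_rng(4)
        venus = rng.uniform(50, 200, (24, 24))
        fret = rng.uniform(50, 200, (24, 24))
        r1 = fret_ratio(fret, venus, bg_method=0.0)
        r2 = fret_ratio(3 * fret, 3 * venus, bg_method=0.0)
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_low_denominator_pixels_masked(self):
        venus = np.full((8, 8), 0.5)
        ratio = fret_ratio(np.ones((8, 8)), venus, bg_method=0.0,
                           denom_floor=1.0)
        assert np.all(np.isnan(ratio))

    def test_fully_masked_roi_warns(self):
        venus = np.zeros((8, 8))
        roi = np.ones((8, 8), dtype=int)
        with pytest.warns(UserWarning, match="masked"):
            _, means = fret_ratio(np.ones((8, 8)), venus, bg_method=0.0,
                                  roi_labels=roi)
        assert np.isnan(means[1])

    def test_two_population_cells_recovered(self):
        from nanospt.studies import fret_study
        out = fret_study(seed=5)
        assert out["measured_high"] == pytest.approx(1.5, rel=0.05)
        assert out["measured_low"] == pytest.approx(1.0, rel=0.05)


class TestMeanIntensity:
    def test_uniform_image_zero_background(self):
        img = np.full((20, 20), 42.0)
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        assert mean_intensity(img, mask, bg_method=0.0) == 42.0

    def test_pure_background_measures_zero(self):
        img = np.full((20, 20), 17.0)
        mask = np.ones((20, 20), dtype=bool)
        assert mean_intensity(img, mask, bg_method=17.0) == 0.0

    def test_linearity_in_signal(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(10, 20, (30, 30))
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:20, 10:20] = True
        v1 = mean_intensity(img, mask, bg_method=5.0)
        v2 = mean_intensity(3 * img, mask, bg_method=15.0)
        assert v2 == pytest.approx(3 * v1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_intensity(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))

    def test_stimulation_fold_change_recovered(self):
        from nanospt.studies import dhe_study
        out = dhe_study(seed=7)
        assert out["measured_fold"] == pytest.approx(2.0, rel=0.05)
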