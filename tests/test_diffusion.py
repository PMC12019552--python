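"""MSD computation, D fitting, mobility classification, log-D histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanospt.detect_link import Track
from nanospt.diffusion import (D_FLOOR, D_THRESHOLD, MSDCurve, compute_msd,
                               diffusion_histogram, fit_diffusion,
                               fit_track_array, histogram_modes,
                               immobile_fraction)
from nanospt.oracles import brute_force_msd
from nanospt.simulate import simulate_track_array
from nanospt.studies import trackset_from_array

from conftest import make_locs

DT = 0.03


def track_of(frames, xs, ys):
    return Track(track_id=0, members=make_locs(frames, xs, ys))


class TestComputeMSD:
    def test_stationary_track_msd_is_zero(self):
        t = track_of(np.arange(6), 1.0, 2.0)
        msd = compute_msd(t, DT)
        assert np.all(msd.msd_um2 == 0)

    def test_ballistic_track_closed_form(self):
        v = 1.0
        frames = np.arange(9)
        t = track_of(frames, v * frames * DT, 0.0)
        msd = compute_msd(t, DT)
        for k, expect in zip(range(1, 5), [0.0009, 0.0036, 0.0081, 0.0144]):
            assert msd.msd_um2[k - 1] == pytest.approx(expect)

    def test_zigzag_matches_brute_force_enumeration(self):
        frames = np.arange(9)
        xs = np.array([0.0, 0.1, 0.05, 0.2, 0.1, 0.3, 0.15, 0.4, 0.2])
        ys = np.array([0.0, -0.05, 0.1, 0.0, 0.2, 0.05, 0.3, 0.1, 0.35])
        t = track_of(frames, xs, ys)
        msd = compute_msd(t, DT)
        xy = np.column_stack([xs, ys])
        for k in (1, 2):
            expect, n = brute_force_msd(frames, xy, DT, k)
            assert msd.msd_um2[k - 1] == pytest.approx(expect)
            assert msd.n_pairs[k - 1] == n

    def test_gap_pairs_use_true_frame_difference(self):
        # frames 0,1,3: the (1,3) pair is lag 2, the (0,3) pair lag 3
        t = track_of([0, 1, 3], [0.0, 1.0, 3.0], 0.0)
        msd = compute_msd(t, DT)
        assert list(np.round(msd.lags_s / DT).astype(int)) == [1, 2, 3]
        assert msd.msd_um2[1] == pytest.approx(4.0)   # (3-1)^2
        assert msd.msd_um2[2] == pytest.approx(9.0)   # (3-0)^2

    def test_single_point_track_rejected(self):
        with pytest.raises(ValueError, match="2 localizations"):
            compute_msd(track_of([0], 0.0, 0.0), DT)

    @given(st.integers(min_value=2, max_value=12), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pair_count_bookkeeping_property(self, n, seed):
        rng = np.random.default_rng(seed)
        frames = np.sort(rng.choice(30, size=n, replace=False))
        xy = rng.normal(size=(n, 2))
        t = track_of(frames, xy[:, 0], xy[:, 1])
        msd = compute_msd(t, DT)
        assert msd.n_pairs.sum() == n * (n - 1) // 2
        assert np.all(np.diff(msd.lags_s) > 0)
        assert np.all(msd.msd_um2 >= 0)


class TestFitDiffusion:
    def test_exact_line_recovers_d(self):
        tau = np.arange(1, 6) * DT
        msd = MSDCurve(tau, 4 * 0.05 * tau, np.full(5, 10))
        est = fit_diffusion(msd)
        assert est.d_um2_s == pytest.approx(0.05)
        assert est.intercept_um2 == pytest.approx(0.0, abs=1e-12)
        assert est.mobility == "mobile"

    def test_affine_curve_splits_slope_and_noise_offset(self):
        sigma, d = 0.02, 0.01
        tau = np.arange(1, 5) * DT
        msd = MSDCurve(tau, 4 * d * tau + 4 * sigma ** 2, np.full(4, 10))
        est = fit_diffusion(msd)
        assert est.d_um2_s == pytest.approx(d)
        assert est.intercept_um2 == pytest.approx(4 * sigma ** 2)

    def test_decreasing_msd_floored_and_flagged(self):
        tau = np.arange(1, 5) * DT
        msd = MSDCurve(tau, 0.01 - 0.02 * tau, np.full(4, 10))
        est = fit_diffusion(msd)
        assert est.floored
        assert est.d_um2_s == D_FLOOR
        assert est.mobility == "immobile"

    def test_too_few_lags_names_the_track(self):
        msd = MSDCurve(np.array([DT]), np.array([0.01]), np.array([3]))
        with pytest.raises(ValueError, match="track 42"):
            fit_diffusion(msd, track_id=42)

    def test_vectorized_fit_matches_per_track_path(self):
        rng = np.random.default_rng(0)
        xy = simulate_track_array(40, 15, 0.03, DT, 0.02, rng)
        fast = fit_track_array(xy, DT)
        slow = np.array([fit_diffusion(compute_msd(t, DT)).d_um2_s
                         for t in trackset_from_array(xy)])
        np.testing.assert_allclose(fast, slow, rtol=1e-9)


class TestImmobileFraction:
    def test_all_below_threshold(self):
        est = pd.DataFrame({"d_um2_s": [0.001] * 5})
        assert immobile_fraction(est) == 1.0

    def test_half_split(self):
        est = pd.DataFrame({"d_um2_s": [0.005, 0.02]})
        assert immobile_fraction(est) == 0.5

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        est = pd.DataFrame({"d_um2_s": rng.lognormal(-4, 1.5, size=200)})
        fracs = [immobile_fraction(est, threshold=t)
                 for t in [0.001, 0.01, 0.1, 1.0]]
        assert fracs == sorted(fracs)

    def test_grouped_summary(self):
        est = pd.DataFrame({"d_um2_s": [0.001, 0.02, 0.001, 0.001],
                            "cell_id": ["a", "a", "b", "b"]})
        out = immobile_fraction(est, by=["cell_id"])
        assert dict(zip(out["cell_id"], out["immobile_fraction"])) == {
            "a": 0.5, "b": 1.0}


class TestDiffusionHistogram:
    def test_single_value_occupies_one_bin(self):
        counts, _ = diffusion_histogram(pd.DataFrame({"d_um2_s": [0.02] * 7}),
                                        bins=10, range_log=(-10, 0))
        assert (counts > 0).sum() == 1
        assert counts.sum() == 7

    def test_base_change_rescales_edges_preserves_counts(self):
        est = pd.DataFrame({"d_um2_s": [0.001, 0.01, 0.1, 0.05, 0.002]})
        c2, e2 = diffusion_histogram(est, log_base=2, bins=8)
        c10, e10 = diffusion_histogram(est, log_base=10, bins=8)
        np.testing.assert_array_equal(c2, c10)
        np.testing.assert_allclose(e10, e2 * np.log10(2), rtol=1e-12)

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            diffusion_histogram(pd.DataFrame({"d_um2_s": [0.01, 0.0]}))

    def test_two_population_mixture_is_bimodal(self):
        rng = np.random.default_rng(2)
        xy_imm = simulate_track_array(180, 20, 0.001, DT, 0.02, rng)
        xy_mob = simulate_track_array(420, 20, 0.08, DT, 0.02, rng)
        d = fit_track_array(np.concatenate([xy_imm, xy_mob]), DT)
        counts, _ = diffusion_histogram(pd.DataFrame({"d_um2_s": d}), bins=30)
        assert histogram_modes(counts, smooth=3) >= 2


class TestEstimatorCalibration:
    def test_single_population_median_d_and_intercept(self):
        rng = np.random.default_rng(3)
        sigma = 0.02
        xy = simulate_track_array(500, 20, 0.05, DT, sigma, rng)
        d = fit_track_array(xy, DT)
        assert np.median(d) == pytest.approx(0.05, rel=0.15)
        intercepts = []
        for t in trackset_from_array(xy):
            intercepts.append(fit_diffusion(compute_msd(t, DT)).intercept_um2)
        assert np.median(intercepts) == pytest.approx(4 * sigma ** 2, rel=0.5)
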