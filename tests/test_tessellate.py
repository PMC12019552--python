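"""Blinking-merge, Voronoi densities, nanodomain segmentation and metrics."""

import numpy as np
import pandas as pd
import pytest

from nanospt.oracles import brute_force_components
from nanospt.simulate import PatternSimConfig, simulate_pattern
from nanospt.tessellate import (TessConfig, _adjacency_pairs,
                                merge_blinking_detections,
                                nanodomain_metrics, segment_nanodomains,
                                voronoi_densities)

from conftest import make_locs

REGION = (0.0, 0.0, 10.0, 10.0)


def grid_pattern(n=10, s=1.0, origin=0.5):
    gx, gy = np.meshgrid(np.arange(n) * s + origin, np.arange(n) * s + origin)
    return np.column_stack([gx.ravel(), gy.ravel()])


def blob_pattern(n_blob=60, n_bg=40, sigma=0.04, seed=7):
    rng = np.random.default_rng(seed)
    blob = rng.standard_normal((n_blob, 2)) * sigma + 5.0
    bg = rng.uniform(0.5, 9.5, size=(n_bg, 2))
    return np.vstack([blob, bg])


class TestMergeBlinkingDetections:
    def test_consecutive_detections_collapse_to_one_point(self):
        locs = make_locs(np.arange(5), 1.0 + np.arange(5) * 0.005, 2.0)
        out = merge_blinking_detections(locs, TessConfig())
        assert len(out) == 1
        assert out["x_um"].iloc[0] == pytest.approx(1.01)

    def test_simultaneous_distant_detections_stay_separate(self):
        locs = make_locs([0, 0], [1.0, 1.5], 1.0)  # 10x merge radius apart
        out = merge_blinking_detections(locs, TessConfig())
        assert len(out) == 2

    @pytest.mark.parametrize("dark,expected", [(3, 1), (4, 2)])
    def test_blink_gap_boundary_matches_tracking_convention(self, dark, expected):
        frames = np.concatenate([np.arange(3), np.arange(3 + dark, 6 + dark)])
        locs = make_locs(frames, 2.0, 2.0)
        out = merge_blinking_detections(locs, TessConfig())
        assert len(out) == expected

    def test_intensity_weighted_position(self):
        locs = make_locs([0, 1], [1.0, 1.03], 0.0, intensity=[3.0, 1.0])
        out = merge_blinking_detections(locs, TessConfig())
        assert out["x_um"].iloc[0] == pytest.approx(1.0075)

    def test_output_never_larger_than_input(self, small_spt_run):
        _, locs, truth = small_spt_run
        out = merge_blinking_detections(locs, TessConfig())
        assert len(out) <= len(locs)
        assert len(out) >= 1


class TestVoronoiDensities:
    def test_square_grid_interior_cells_exact(self):
        s = 1.0
        vmap = voronoi_densities(grid_pattern(10, s), REGION)
        interior = ~vmap.border
        assert interior.sum() == 64  # 8x8 inner grid
        np.testing.assert_allclose(vmap.area_um2[interior], s ** 2, rtol=1e-9)
        np.testing.assert_allclose(vmap.density[interior], 1 / s ** 2, rtol=1e-9)
        assert vmap.delta_avg == pytest.approx(100 / 100.0)

    def test_triangle_all_cells_border_flagged(self):
        xy = np.array([[2.0, 2.0], [8.0, 2.0], [5.0, 7.0]])
        vmap = voronoi_densities(xy, REGION)
        assert vmap.border.all()

    def test_area_conservation(self):
        cfg = PatternSimConfig(mode="csr", background_intensity=20.0, seed=1)
        locs, _ = simulate_pattern(cfg)
        vmap = voronoi_densities(locs, REGION)
        assert vmap.area_um2.sum() == pytest.approx(100.0, rel=1e-3)

    def test_poisson_voronoi_mean_cell_area(self):
        lam = 25.0
        cfg = PatternSimConfig(mode="csr", background_intensity=lam, seed=2)
        locs, _ = simulate_pattern(cfg)
        assert len(locs) >= 2000
        vmap = voronoi_densities(locs, REGION)
        mean_area = vmap.area_um2[~vmap.border].mean()
        assert mean_area == pytest.approx(1 / lam, rel=0.05)

    def test_collinear_points_rejected(self):
        xy = np.column_stack([np.arange(5, dtype=float), np.arange(5) * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            voronoi_densities(xy, REGION)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            voronoi_densities(np.array([[1.0, 1.0], [2.0, 2.0]]), REGION)


class TestSegmentNanodomains:
    def test_uniform_grid_has_no_domains(self):
        vmap = voronoi_densities(grid_pattern(10), REGION)
        assert segment_nanodomains(vmap, TessConfig()) == []

    def test_single_dense_blob_yields_one_domain(self):
        vmap = voronoi_densities(blob_pattern(60), REGION)
        # brute-force confirmation that the blob really crosses 50x average
        assert (vmap.density > 50 * vmap.delta_avg).sum() >= 25
        domains = segment_nanodomains(vmap, TessConfig())
        assert len(domains) == 1
        assert domains[0].n_detections >= 25
        assert np.hypot(domains[0].centroid_um[0] - 5.0,
                        domains[0].centroid_um[1] - 5.0) < 0.1

    def test_small_blob_fails_min_detection_rule(self):
        vmap = voronoi_densities(blob_pattern(20), REGION)
        assert segment_nanodomains(vmap, TessConfig()) == []

    def test_threshold_monotonicity(self):
        cfg = PatternSimConfig(seed=3)
        locs, _ = simulate_pattern(cfg)
        vmap = voronoi_densities(locs, REGION)
        n_by_factor = [len(segment_nanodomains(
            vmap, TessConfig(density_factor=f))) for f in (25, 50, 100, 400)]
        assert n_by_factor == sorted(n_by_factor, reverse=True)
        n_by_min = [len(segment_nanodomains(
            vmap, TessConfig(min_detections=m))) for m in (10, 25, 60, 200)]
        assert n_by_min == sorted(n_by_min, reverse=True)

    def test_components_match_brute_force_flood_fill(self):
        xy = blob_pattern(50, 30, seed=12)
        # add a second blob
        rng = np.random.default_rng(13)
        xy = np.vstack([xy, rng.standard_normal((50, 2)) * 0.04 + [2.0, 8.0]])
        vmap = voronoi_densities(xy, REGION)
        cfg = TessConfig()
        domains = segment_nanodomains(vmap, cfg)
        pairs = _adjacency_pairs(vmap.xy)
        seed_mask = vmap.density > cfg.density_factor * vmap.delta_avg
        comps = [c for c in brute_force_components(vmap.xy, pairs, seed_mask)
                 if len(c) >= 1]
        seed_sets = {frozenset(d.seed_ids.tolist()) for d in domains}
        big_comps = {c for c in comps if len(c) >= cfg.min_detections}
        # every segmented domain's seed set is one brute-force component
        assert seed_sets <= set(comps)
        assert len(domains) == 2
        assert len(big_comps) <= len(domains)


class TestNanodomainMetrics:
    def test_zero_domains_reports_missing_size(self):
        vmap = voronoi_densities(grid_pattern(10), REGION)
        summary = nanodomain_metrics([], vmap)
        assert np.isnan(summary.mean_equiv_diameter_um)
        assert summary.relative_molecule_count == 0.0
        assert summary.domain_density_per_um2 == 0.0

    def test_relative_count_is_members_over_total(self):
        vmap = voronoi_densities(blob_pattern(60, 40), REGION)
        domains = segment_nanodomains(vmap, TessConfig())
        summary = nanodomain_metrics(domains, vmap)
        n_members = sum(d.n_detections for d in domains)
        assert summary.relative_molecule_count == pytest.approx(
            n_members / len(vmap))
        assert summary.domain_density_per_um2 == pytest.approx(
            len(domains) / 100.0)

    def test_csr_specificity_below_one_percent(self):
        from nanospt.studies import csr_specificity
        out = csr_specificity(seed=0, n_seeds=5)
        assert out["mean_fraction_in_domains"] < 0.01

    def test_thomas_domain_density_recovers_truth(self):
        from nanospt.studies import thomas_sensitivity
        out = thomas_sensitivity(seed=0, n_seeds=3)
        assert out["mean_n_domains"] == pytest.approx(30, rel=0.2)
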