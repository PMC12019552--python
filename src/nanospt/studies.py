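"""End-to-end validation studies at the analysis' standard conditions.

Each function simulates data with the generator, runs the corresponding
pipeline stage(s), and returns the measured quantities together with the
ground truth.  The numbered scripts under ``analysis/`` and the acceptance
machinery are thin wrappers around these functions, so every reported
number is recomputed from scratch.

Study conditions mirror the acquisitions the pipeline was built for: 30 ms
frame interval, tracks of >=7 steps, 4-point MSD fits, the 0.01 µm²/s
immobility threshold, and Voronoi segmentation at 50x average density with
>=25 detections per domain.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffusion as dfu
from . import tessellate as tess
from .detect_link import LinkConfig, Track, TrackSet, detect_spots, link_tracks
from .imagequant import (SegmentParams, average_stack, cluster_density,
                         fret_ratio, mean_intensity, segment_clusters)
from .report_stats import anova_tukey_letters, two_sample_test
from .simulate import (PatternSimConfig, SptSimConfig, render_frames,
                       simulate_pattern, simulate_track_array, simulate_tracks)

DT_S = 0.03  # frame interval of the emulated acquisitions (30 ms)


def stage_seed(seed: int, label: str) -> int:
    """Derive a stable per-stage sub-seed (< 2^31) from a run seed and label."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def trackset_from_array(xy: np.ndarray, dt_offset_frames: int = 0) -> TrackSet:
    """Wrap an (n_tracks, n_locs, 2) array into a TrackSet (gap-free)."""
    tracks = []
    n_locs = xy.shape[1]
    frames = np.arange(n_locs) + dt_offset_frames
    for tid in range(xy.shape[0]):
        members = pd.DataFrame({
            "frame": frames, "x_um": xy[tid, :, 0], "y_um": xy[tid, :, 1],
            "intensity": 1.0, "sigma_um": 0.0, "molecule_id": tid})
        tracks.append(Track(track_id=tid, members=members))
    return TrackSet(tracks)


# ---------------------------------------------------------------- diffusion

def diffusion_calibration(seed: int, n_tracks: int = 500, n_steps: int = 20,
                          d_true: float = 0.05, loc_sigma: float = 0.02,
                          dt_s: float = DT_S) -> dict:
    """Single-population calibration: median fitted D vs truth.

    Mobile Brownian tracks (>= 20 steps, so they pass the 7-step filter) are
    fitted track-by-track through the MSD path.
    """
    rng = np.random.default_rng(stage_seed(seed, "calibration"))
    xy = simulate_track_array(n_tracks, n_steps, d_true, dt_s, loc_sigma, rng)
    tracks = TrackSet([t for t in trackset_from_array(xy) if t.n_steps >= 7])
    est = dfu.estimate_tracks(tracks, dt_s)
    return {
        "d_true": d_true,
        "median_d": float(est["d_um2_s"].median()),
        "median_intercept": float(est["intercept_um2"].median()),
        "n_tracks": len(est),
    }


def _two_population_d(rng: np.random.Generator, n_tracks: int, n_steps: int,
                      f_immobile: float, d_imm: float, d_mob: float,
                      loc_sigma: float, dt_s: float) -> tuple[np.ndarray, int]:
    """Fitted D for a two-population track sample; returns (d_hat, n_imm_true)."""
    n_imm = int(rng.binomial(n_tracks, f_immobile))
    xy_imm = simulate_track_array(n_imm, n_steps, d_imm, dt_s, loc_sigma, rng)
    xy_mob = simulate_track_array(n_tracks - n_imm, n_steps, d_mob, dt_s,
                                  loc_sigma, rng)
    xy = np.concatenate([xy_imm, xy_mob], axis=0)
    return dfu.fit_track_array(xy, dt_s), n_imm


def mixture_recovery(seed: int, n_tracks: int = 600, n_steps: int = 20,
                     f_immobile: float = 0.30, d_imm: float = 0.001,
                     d_mob: float = 0.08, loc_sigma: float = 0.02,
                     n_bimodal_seeds: int = 10, dt_s: float = DT_S) -> dict:
    """Two-population membrane: immobile-fraction recovery and bimodality.

    The recovered fraction uses one seeded sample; bimodality of the log2-D
    histogram (one mode below the 0.01 µm²/s boundary, one above) is scored
    over ``n_bimodal_seeds`` independent repeats.
    """
    rng = np.random.default_rng(stage_seed(seed, "mixture"))
    d_hat, n_imm = _two_population_d(rng, n_tracks, n_steps, f_immobile,
                                     d_imm, d_mob, loc_sigma, dt_s)
    est = pd.DataFrame({"track_id": np.arange(len(d_hat)), "d_um2_s": d_hat})
    frac = dfu.immobile_fraction(est)

    boundary = np.log2(dfu.D_THRESHOLD)
    n_bimodal = 0
    for k in range(n_bimodal_seeds):
        rng_k = np.random.default_rng(stage_seed(seed, f"mixture-rep{k}"))
        d_k, _ = _two_population_d(rng_k, n_tracks, n_steps, f_immobile,
                                   d_imm, d_mob, loc_sigma, dt_s)
        est_k = pd.DataFrame({"d_um2_s": d_k})
        counts, edges = dfu.diffusion_histogram(est_k, log_base=2, bins=30)
        centers = 0.5 * (edges[:-1] + edges[1:])
        modes = dfu.histogram_mode_indices(counts, smooth=3)
        below = any(centers[m] < boundary for m in modes)
        above = any(centers[m] >= boundary for m in modes)
        if below and above:
            n_bimodal += 1
    return {
        "f_true": f_immobile,
        "true_fraction_in_sample": n_imm / n_tracks,
        "recovered_fraction": frac,
        "n_bimodal": n_bimodal,
        "n_bimodal_seeds": n_bimodal_seeds,
        "n_tracks": n_tracks,
    }


def treatment_effect_power(seed: int, n_reps: int = 100, n_cells: int = 10,
                           tracks_per_cell: int = 100, n_steps: int = 20,
                           f_control: float = 0.15, f_treated: float = 0.35,
                           d_imm: float = 0.001, d_mob: float = 0.08,
                           loc_sigma: float = 0.02, alpha: float = 0.05,
                           dt_s: float = DT_S) -> dict:
    """Power of the per-cell two-sample t-test for an osmotic-like shift.

    Each repetition simulates ``n_cells`` control and treated cells (with
    per-cell immobile fractions binomially sampled around the population
    value), estimates per-cell immobile fractions from fitted D, and applies
    the Student t-test.  Returns the rejection rate at ``alpha``.
    """
    rejections = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(stage_seed(seed, f"treatment-{rep}"))
        cell_fracs = {"control": [], "treated": []}
        for cond, f_pop in (("control", f_control), ("treated", f_treated)):
            for _ in range(n_cells):
                d_hat, _ = _two_population_d(rng, tracks_per_cell, n_steps,
                                             f_pop, d_imm, d_mob, loc_sigma,
                                             dt_s)
                est = pd.DataFrame({"d_um2_s": d_hat})
                cell_fracs[cond].append(dfu.immobile_fraction(est))
        _, p = two_sample_test(cell_fracs["control"], cell_fracs["treated"],
                               kind="student")
        if p < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps,
            "alpha": alpha}


# -------------------------------------------------------------- tessellation

def csr_specificity(seed: int, n_seeds: int = 20, intensity: float = 50.0,
                    region=(0.0, 0.0, 10.0, 10.0)) -> dict:
    """Fraction of CSR localizations falsely assigned to nanodomains.

    Complete-spatial-randomness patterns at the stated intensity are
    segmented at the standard thresholds; reports the mean fraction of
    points inside detected domains over ``n_seeds`` patterns.
    """
    cfg = tess.TessConfig()
    fracs = []
    for k in range(n_seeds):
        pcfg = PatternSimConfig(mode="csr", region_um=region,
                                background_intensity=intensity,
                                seed=stage_seed(seed, f"csr-{k}"))
        locs, _ = simulate_pattern(pcfg)
        vmap = tess.voronoi_densities(locs, region)
        domains = tess.segment_nanodomains(vmap, cfg)
        summary = tess.nanodomain_metrics(domains, vmap)
        fracs.append(summary.relative_molecule_count)
    return {"mean_fraction_in_domains": float(np.mean(fracs)),
            "max_fraction_in_domains": float(np.max(fracs)),
            "n_seeds": n_seeds}


def thomas_sensitivity(seed: int, n_seeds: int = 5, n_clusters: int = 30,
                       points_per_cluster: float = 60.0, sigma: float = 0.04,
                       background: float = 5.0,
                       region=(0.0, 0.0, 10.0, 10.0)) -> dict:
    """Nanodomain recovery on Thomas cluster patterns.

    Reports the mean detected domain count, the detected relative molecule
    count, and the ground-truth relative count (fraction of points generated
    as cluster offspring), averaged over seeds.
    """
    cfg = tess.TessConfig()
    counts, rel_detected, rel_true, diameters = [], [], [], []
    for k in range(n_seeds):
        pcfg = PatternSimConfig(mode="thomas", region_um=region,
                                background_intensity=background,
                                n_clusters=n_clusters,
                                points_per_cluster_mean=points_per_cluster,
                                cluster_sigma_um=sigma,
                                seed=stage_seed(seed, f"thomas-{k}"))
        locs, truth = simulate_pattern(pcfg)
        vmap = tess.voronoi_densities(locs, region)
        domains = tess.segment_nanodomains(vmap, cfg)
        summary = tess.nanodomain_metrics(domains, vmap)
        counts.append(summary.n_domains)
        rel_detected.append(summary.relative_molecule_count)
        rel_true.append(float(np.mean(truth.cluster_id >= 0)))
        if summary.n_domains:
            diameters.append(summary.mean_equiv_diameter_um)
    return {
        "true_n_clusters": n_clusters,
        "mean_n_domains": float(np.mean(counts)),
        "mean_relative_count": float(np.mean(rel_detected)),
        "mean_true_relative_count": float(np.mean(rel_true)),
        "mean_equiv_diameter_um": float(np.mean(diameters)) if diameters
        else float("nan"),
        "n_seeds": n_seeds,
    }


def poisson_voronoi_check(seed: int, intensity: float = 25.0,
                          region=(0.0, 0.0, 10.0, 10.0)) -> dict:
    """Mean interior Voronoi cell area on CSR vs the 1/lambda law."""
    pcfg = PatternSimConfig(mode="csr", region_um=region,
                            background_intensity=intensity,
                            seed=stage_seed(seed, "poisson-voronoi"))
    locs, _ = simulate_pattern(pcfg)
    vmap = tess.voronoi_densities(locs, region)
    interior = ~vmap.border
    mean_area = float(vmap.area_um2[interior].mean())
    area_sum_relerr = abs(vmap.area_um2.sum() - vmap.region.area) / vmap.region.area
    return {"mean_interior_cell_area": mean_area,
            "expected_area": 1.0 / intensity,
            "rel_error": abs(mean_area - 1.0 / intensity) * intensity,
            "area_conservation_rel_error": float(area_sum_relerr),
            "n_points": len(vmap)}


# ----------------------------------------------------------------- tracking

def link_accuracy_study(seed: int, n_molecules: int = 50, n_frames: int = 250,
                        fov_um: float = 6.4, pixel_um: float = 0.16,
                        photons: float = 1000.0, bg: float = 10.0,
                        psf_sigma_um: float = 0.16) -> dict:
    """Detection + linking accuracy on rendered high-SNR stacks.

    Simulates a blinking sptPALM acquisition, renders frames at SNR >~ 10,
    detects and links, then scores every link of every recovered track
    against ground truth.  A link is correct when at least one ground-truth
    molecule is consistent with both of its endpoints (emitted within half
    the linking radius of each); requiring a unique nearest molecule instead
    would mark tracks through sub-resolution molecule coincidences wrong
    even though no tracker could resolve them.
    """
    sim = SptSimConfig(n_frames=n_frames, fov_um=fov_um,
                       n_molecules=n_molecules, f_immobile=0.3,
                       p_activate=0.008, p_bleach=0.05,
                       loc_sigma_um=0.0,  # noise enters via rendering
                       seed=stage_seed(seed, "link-accuracy"))
    locs, _ = simulate_tracks(sim)
    npx = int(round(fov_um / pixel_um))
    stack = render_frames(locs, psf_sigma_um, photons, bg, pixel_um,
                          shape=(npx, npx),
                          seed=stage_seed(seed, "link-render"))
    cfg = LinkConfig(max_disp_um=3 * np.sqrt(4 * sim.d_mobile * DT_S),
                     max_gap=3, psf_sigma_um=psf_sigma_um,
                     min_spot_separation_um=2 * pixel_um)
    detected = detect_spots(stack, cfg, pixel_um)
    tracks = link_tracks(detected, cfg)

    # candidate truth molecules per detection, frame by frame
    from scipy.spatial import cKDTree
    truth_by_frame = {f: (cKDTree(g[["x_um", "y_um"]].to_numpy()),
                          g["molecule_id"].to_numpy())
                      for f, g in locs.groupby("frame")}
    tol = 0.5 * cfg.max_disp_um

    def candidates(frame: int, x: float, y: float) -> set[int]:
        if frame not in truth_by_frame:
            return set()
        tree, ids = truth_by_frame[frame]
        return {int(ids[i]) for i in tree.query_ball_point([x, y], tol)}

    n_links = n_correct = 0
    for t in tracks:
        cands = [candidates(int(f), float(p[0]), float(p[1]))
                 for f, p in zip(t.frames, t.xy)]
        for a in range(len(cands) - 1):
            n_links += 1
            if cands[a] & cands[a + 1]:
                n_correct += 1
    return {"n_links": n_links,
            "link_accuracy": n_correct / n_links if n_links else float("nan"),
            "n_detections": len(detected), "n_truth": len(locs)}


# --------------------------------------------------------------- imagequant

def tirf_cluster_study(seed: int, n_spots: int = 25, img_px: int = 128,
                       roi=(14, 14, 100, 100), pixel_um: float = 0.102,
                       photons: float = 1500.0, bg: float = 20.0,
                       n_frames: int = 100) -> dict:
    """Rendered TIRF field: recover the spot count in the 100 x 100 px ROI.

    ``n_spots`` well-separated spots are placed inside the ROI, imaged for
    ``n_frames`` noisy frames, averaged, segmented and counted.
    """
    rng = np.random.default_rng(stage_seed(seed, "tirf"))
    r0, c0, rh, rw = roi
    margin = 5
    min_sep_px = 12  # spots resolvable by the segmenter
    # rejection-sample well-separated centres inside the ROI
    pts: list[np.ndarray] = []
    while len(pts) < n_spots:
        cand = np.array([rng.uniform(c0 + margin, c0 + rw - margin),
                         rng.uniform(r0 + margin, r0 + rh - margin)])
        if all(np.hypot(*(cand - p)) >= min_sep_px for p in pts):
            pts.append(cand)
    centers_px = np.array(pts)
    frames = np.repeat(np.arange(n_frames), n_spots)
    locs = pd.DataFrame({
        "frame": frames,
        "x_um": np.tile(centers_px[:, 0] * pixel_um, n_frames),
        "y_um": np.tile(centers_px[:, 1] * pixel_um, n_frames),
        "intensity": 1.0, "sigma_um": 0.0, "molecule_id": -1})
    stack = render_frames(locs, psf_sigma_um=1.5 * pixel_um, photons=photons,
                          bg_level=bg, pixel_um=pixel_um,
                          shape=(img_px, img_px),
                          seed=stage_seed(seed, "tirf-render"))
    avg = average_stack(stack, n_frames)
    labels = segment_clusters(avg, SegmentParams())
    count = cluster_density(labels, roi)
    return {"true_spots": n_spots, "counted": count.n_clusters,
            "n_labels": int(labels.max())}


def fret_study(seed: int, ratio_high: float = 1.5, ratio_low: float = 1.0,
               img_px: int = 120, venus_signal: float = 400.0,
               bg: float = 40.0) -> dict:
    """Two-population ratiometric sensor cells: recover true FRET ratios.

    Two disk 'cells' share a donor (Venus) intensity; the acceptor (FRET)
    channel carries ``ratio_high`` / ``ratio_low`` times the donor signal.
    Both channels get Poisson noise; per-ROI ratio means are recovered with
    the known background.
    """
    rng = np.random.default_rng(stage_seed(seed, "fret"))
    yy, xx = np.mgrid[0:img_px, 0:img_px]
    c1 = (img_px * 0.3, img_px * 0.3)
    c2 = (img_px * 0.7, img_px * 0.7)
    r = img_px * 0.18
    roi = np.zeros((img_px, img_px), dtype=np.int32)
    roi[(yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 < r ** 2] = 1
    roi[(yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 < r ** 2] = 2

    venus_true = np.full(roi.shape, bg, dtype=float)
    venus_true[roi > 0] += venus_signal
    fret_true = np.full(roi.shape, bg, dtype=float)
    fret_true[roi == 1] += ratio_high * venus_signal
    fret_true[roi == 2] += ratio_low * venus_signal
    venus = rng.poisson(venus_true).astype(float)
    fret = rng.poisson(fret_true).astype(float)
    _, means = fret_ratio(fret, venus, bg_method=bg, roi_labels=roi,
                          denom_floor=venus_signal * 0.1)
    return {"true_high": ratio_high, "true_low": ratio_low,
            "measured_high": means[1], "measured_low": means[2]}


def dhe_study(seed: int, fold: float = 2.0, baseline: float = 120.0,
              bg: float = 30.0, img_px: int = 100) -> dict:
    """ROS readout: recover a known stimulation fold-change.

    Baseline and 'stimulated' images share the background; the cell mask
    signal is ``baseline`` vs ``fold * baseline``.  Background-subtracted
    mean gray values give the measured fold-change.
    """
    rng = np.random.default_rng(stage_seed(seed, "dhe"))
    yy, xx = np.mgrid[0:img_px, 0:img_px]
    mask = (yy - img_px / 2) ** 2 + (xx - img_px / 2) ** 2 < (img_px * 0.3) ** 2

    def make(signal: float) -> np.ndarray:
        img = np.full((img_px, img_px), bg, dtype=float)
        img[mask] += signal
        return rng.poisson(img).astype(float)

    v0 = mean_intensity(make(baseline), mask, bg_method="outside_percentile")
    v1 = mean_intensity(make(fold * baseline), mask,
                        bg_method="outside_percentile")
    return {"true_fold": fold, "measured_fold": v1 / v0,
            "baseline_value": v0, "stimulated_value": v1}


# ------------------------------------------------------------------- stats

def null_fwer_study(seed: int, n_reps: int = 1000, n_groups: int = 4,
                    n_per_group: int = 10, alpha: float = 0.05) -> dict:
    """Family-wise error of the letter display under the global null.

    All groups drawn from N(0, 1); an error occurs when any two groups fail
    to share a letter.  The rate should sit near ``alpha`` (Tukey HSD
    controls FWER exactly under the null).
    """
    rng = np.random.default_rng(stage_seed(seed, "fwer"))
    errors = 0
    names = [f"g{i}" for i in range(n_groups)]
    for _ in range(n_reps):
        vals = rng.standard_normal((n_groups, n_per_group))
        table = pd.DataFrame({
            "group": np.repeat(names, n_per_group),
            "value": vals.ravel()})
        _, _, letters = anova_tukey_letters(table, alpha=alpha)
        sets = [set(letters[g]) for g in names]
        if any(not (sets[i] & sets[j])
               for i in range(n_groups) for j in range(i + 1, n_groups)):
            errors += 1
    return {"fwer": errors / n_reps, "alpha": alpha, "n_reps": n_reps}
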