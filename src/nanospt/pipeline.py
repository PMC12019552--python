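"""Configuration-driven orchestration of the analysis chain.

A run config (YAML mapping or dict) selects stages and carries per-stage
parameters; :func:`run` executes ``simulate -> link -> diffusion ->
tessellate -> report`` (any prefix/subset whose inputs exist), writing every
output plus a manifest with the config hash and seed, so identical
config + seed reproduces all CSV outputs byte-identically.

The global seed is expanded into per-stage sub-seeds keyed by stage label
(:func:`nanospt.studies.stage_seed`), so toggling one stage never perturbs
another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .detect_link import LinkConfig, filter_tracks, link_tracks
from .diffusion import diffusion_histogram, estimate_tracks, immobile_fraction
from .oracles import brute_force_msd, exhaustive_linking
from .simulate import SptSimConfig, render_frames, simulate_tracks
from .studies import stage_seed
from .tessellate import (TessConfig, domains_to_frame, merge_blinking_detections,
                         nanodomain_metrics, segment_nanodomains,
                         voronoi_densities)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "link", "diffusion", "tessellate", "report")


def _cfg_from(d: dict, cls):
    fields = {f.name for f in dataclasses.fields(cls)}
    return cls(**{k: v for k, v in d.items() if k in fields})


def run(config: dict, out_dir) -> dict:
    """Execute the configured stages; return the manifest (also written).

    ``config`` keys: ``stages`` (list, default all), ``seed``, and optional
    ``simulate`` / ``link`` / ``tessellate`` sections with the corresponding
    dataclass fields.  Outputs land in ``out_dir``; a partial failure leaves
    ``manifest.json`` marked incomplete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", ALL_STAGES))
    manifest = {"config_hash": io.config_hash(config), "seed": seed,
                "stages": stages, "outputs": [], "complete": False}

    def emit(name: str):
        manifest["outputs"].append(name)
        return out / name

    try:
        dt_s = float(config.get("simulate", {}).get("frame_interval_s", 0.03))
        if "simulate" in stages:
            sim_cfg = _cfg_from({**config.get("simulate", {}),
                                 "seed": stage_seed(seed, "simulate")},
                                SptSimConfig)
            locs, truth = simulate_tracks(sim_cfg)
            io.write_localizations(locs, emit("localizations.csv"))
            gt = {"mobility": truth.mobility,
                  "d_true": truth.d_true}
            (emit("ground_truth.json")).write_text(
                json.dumps(gt, indent=1, sort_keys=True))
            fov = sim_cfg.fov_um
        else:
            locs = io.read_localizations(config["inputs"]["localizations"])
            fov = float(config.get("fov_um", max(locs["x_um"].max(),
                                                 locs["y_um"].max())))

        if "link" in stages:
            link_cfg = _cfg_from(config.get("link", {}), LinkConfig)
            tracks = link_tracks(locs, link_cfg)
            kept = filter_tracks(tracks, int(config.get("min_steps", 7)))
            io.write_tracks(kept, emit("tracks.csv"), emit("tracks_meta.json"))
        else:
            kept = None

        est = None
        if "diffusion" in stages and kept is not None:
            est = estimate_tracks(kept, dt_s)
            io.write_csv(est, emit("diffusion_estimates.csv"))
            if len(est):
                counts, edges = diffusion_histogram(est)
                io.write_csv(pd.DataFrame({"bin_left": edges[:-1],
                                           "bin_right": edges[1:],
                                           "count": counts}),
                             emit("diffusion_histogram.csv"))

        summary = None
        if "tessellate" in stages:
            tess_cfg = _cfg_from(config.get("tessellate", {}), TessConfig)
            merged = merge_blinking_detections(locs, tess_cfg)
            region = (0.0, 0.0, fov, fov)
            if len(merged) >= 3:
                vmap = voronoi_densities(merged, region)
                io.write_csv(pd.DataFrame({"x_um": vmap.xy[:, 0],
                                           "y_um": vmap.xy[:, 1],
                                           "area_um2": vmap.area_um2,
                                           "density_per_um2": vmap.density,
                                           "border": vmap.border.astype(int)}),
                             emit("voronoi_densities.csv"))
                domains = segment_nanodomains(vmap, tess_cfg)
                io.write_csv(domains_to_frame(domains), emit("nanodomains.csv"))
                summary = nanodomain_metrics(domains, vmap)

        if "report" in stages:
            report: dict = {"seed": seed}
            if est is not None and len(est):
                report["n_tracks"] = int(len(est))
                report["immobile_fraction"] = immobile_fraction(est)
            if summary is not None:
                nd = dataclasses.asdict(summary)
                # strict JSON: an undefined mean size is null, not NaN
                if not np.isfinite(nd["mean_equiv_diameter_um"]):
                    nd["mean_equiv_diameter_um"] = None
                report["nanodomains"] = nd
            (emit("report.json")).write_text(
                json.dumps(report, indent=1, sort_keys=True))

        manifest["complete"] = True
    finally:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_fixtures(out_dir) -> dict:
    """Write the deterministic toy datasets used throughout the test suite.

    Each fixture comes with an ``expected.json`` computed by the in-repo
    brute-force oracles (pair-enumeration MSD, exhaustive assignment), never
    by the code paths under test.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expected: dict = {}

    # 5x5 unit grid point pattern: interior Voronoi cells are unit squares
    s = 1.0
    gx, gy = np.meshgrid(np.arange(5) * s, np.arange(5) * s)
    grid = pd.DataFrame({"frame": 0, "x_um": gx.ravel(), "y_um": gy.ravel(),
                         "intensity": 1.0, "sigma_um": 0.0,
                         "molecule_id": np.arange(25)})
    io.write_localizations(grid, out / "grid_pattern.csv")
    expected["grid_interior_density"] = 1.0 / s ** 2

    # ballistic track at 1 µm/s sampled every 30 ms
    v, dt = 1.0, 0.03
    frames = np.arange(9)
    ballistic = pd.DataFrame({"frame": frames, "x_um": v * frames * dt,
                              "y_um": 0.0, "intensity": 1.0, "sigma_um": 0.0,
                              "molecule_id": 0})
    io.write_localizations(ballistic, out / "ballistic_track.csv")
    expected["ballistic_msd_lag_1_to_4"] = [
        brute_force_msd(frames, np.column_stack([v * frames * dt,
                                                 np.zeros(9)]), dt, k)[0]
        for k in range(1, 5)]

    # two well-separated molecules over 6 frames
    f6 = np.arange(6)
    two = pd.DataFrame({
        "frame": np.repeat(f6, 2),
        "x_um": np.ravel(np.column_stack([0.02 * f6, 5.0 + 0.02 * f6])),
        "y_um": np.ravel(np.column_stack([0.0 * f6, 0.0 * f6])),
        "intensity": 1.0, "sigma_um": 0.0,
        "molecule_id": np.tile([0, 1], 6)})
    io.write_localizations(two, out / "two_molecules.csv")
    frame_locs = [two[two.frame == f][["x_um", "y_um"]].to_numpy() for f in f6]
    links = exhaustive_linking(frame_locs, max_disp=0.5)
    expected["two_molecule_links_per_transition"] = [len(l) for l in links]

    # dense blob (60 pts, sigma 40 nm) in a sparse 10x10 background
    rng = np.random.default_rng(7)
    blob = rng.standard_normal((60, 2)) * 0.04 + 5.0
    bg = rng.uniform(0, 10, size=(40, 2))
    pts = np.vstack([blob, bg])
    blob_df = pd.DataFrame({"frame": 0, "x_um": pts[:, 0], "y_um": pts[:, 1],
                            "intensity": 1.0, "sigma_um": 0.0,
                            "molecule_id": np.arange(len(pts))})
    io.write_localizations(blob_df, out / "blob_pattern.csv")
    expected["blob_n_domains"] = 1
    expected["blob_min_detections"] = 25

    # 25-spot rendered frame
    yy, xx = np.meshgrid(np.arange(5), np.arange(5))
    centers = np.column_stack([(xx.ravel() * 20 + 14) * 0.102,
                               (yy.ravel() * 20 + 14) * 0.102])
    spot_locs = pd.DataFrame({"frame": 0, "x_um": centers[:, 0],
                              "y_um": centers[:, 1], "intensity": 1.0,
                              "sigma_um": 0.0, "molecule_id": -1})
    stack = render_frames(spot_locs, psf_sigma_um=0.15, photons=400,
                          bg_level=5, pixel_um=0.102, shape=(114, 114),
                          poisson_noise=False)
    io.write_stack(stack, out / "spots_25.tif")
    expected["spots_25_count"] = 25

    (out / "expected.json").write_text(json.dumps(expected, indent=1,
                                                  sort_keys=True))
    return expected
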