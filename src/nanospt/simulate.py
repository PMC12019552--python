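"""Synthetic sptPALM data with known ground truth.

Emulates sparse-photoactivation single-molecule acquisitions of a
photoconvertible tag (mEOS2-like) on the plant plasma membrane: a mixture of
mobile and immobile molecules undergoing 2-D Brownian motion, imaged at a
fixed frame interval with stochastic photoactivation, blinking and bleaching,
and Gaussian localization noise.  Also generates clustered (Thomas) and
completely spatially random point patterns for validating the tessellation
stage, and renders localization tables into camera frames.

All distances are in micrometres, all times in seconds.  Every emitted
localization carries the identity of the ground-truth molecule that produced
it, so downstream tracking, diffusion estimation and segmentation can be
scored against truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

LOC_COLUMNS = ["frame", "x_um", "y_um", "intensity", "sigma_um", "molecule_id"]


def _check_prob(name: str, value: float) -> None:
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_positive(name: str, value: float, *, allow_zero: bool = False) -> None:
    ok = np.isfinite(value) and (value >= 0 if allow_zero else value > 0)
    if not ok:
        kind = "non-negative" if allow_zero else "positive"
        raise ValueError(f"{name} must be a finite {kind} number, got {value!r}")


@dataclass
class SptSimConfig:
    """Acquisition and photophysics parameters for a simulated sptPALM run.

    Defaults mirror the acquisition geometry of the experiments this package
    reanalyses (7000 frames at 30 ms exposure).  The photoactivation,
    blinking and bleaching rates are assumptions — the source experiments do
    not report mEOS2 photophysics — chosen to give sparse, track-able frames.

    Parameters
    ----------
    frame_interval_s
        Time between consecutive frames (s).
    n_frames
        Number of camera frames to simulate.
    fov_um
        Side of the square field of view (µm).
    n_molecules
        Number of ground-truth molecules placed in the field.
    d_mobile, d_immobile
        Diffusion coefficients of the two populations (µm²/s).
    f_immobile
        Fraction of molecules drawn from the immobile population.
    loc_sigma_um
        Isotropic Gaussian localization error SD (µm).
    p_activate
        Per-frame probability that a not-yet-activated molecule converts.
    p_bleach
        Per-frame probability that a fluorescing molecule bleaches.
    p_blink_off, p_blink_on
        Per-frame transition probabilities of the on<->off blinking chain.
    max_true_gap
        Longest dark stretch (frames) after which a molecule is considered
        gone for good (it bleaches instead of returning).
    seed
        RNG seed; identical config + seed reproduces the table exactly.
    """

    frame_interval_s: float = 0.03
    n_frames: int = 7000
    fov_um: float = 10.0
    n_molecules: int = 500
    d_mobile: float = 0.08
    d_immobile: float = 0.001
    f_immobile: float = 0.30
    loc_sigma_um: float = 0.02
    p_activate: float = 0.002
    p_bleach: float = 0.05
    p_blink_off: float = 0.10
    p_blink_on: float = 0.50
    max_true_gap: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive("frame_interval_s", self.frame_interval_s)
        _check_positive("fov_um", self.fov_um)
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.n_molecules < 1:
            raise ValueError(f"n_molecules must be >= 1, got {self.n_molecules}")
        for name in ("p_activate", "p_bleach", "p_blink_off", "p_blink_on",
                     "f_immobile"):
            _check_prob(name, getattr(self, name))
        _check_positive("d_immobile", self.d_immobile, allow_zero=True)
        _check_positive("d_mobile", self.d_mobile, allow_zero=True)
        if self.d_mobile < self.d_immobile:
            raise ValueError(
                f"d_mobile ({self.d_mobile}) must be >= d_immobile "
                f"({self.d_immobile})")
        _check_positive("loc_sigma_um", self.loc_sigma_um, allow_zero=True)
        if self.max_true_gap < 0:
            raise ValueError(f"max_true_gap must be >= 0, got {self.max_true_gap}")


@dataclass
class PatternSimConfig:
    """Spatial point-pattern parameters (CSR null or Thomas cluster process).

    ``mode='csr'`` draws a homogeneous Poisson process of intensity
    ``background_intensity`` over the rectangle.  ``mode='thomas'`` places
    ``n_clusters`` cluster centres uniformly, each with a Poisson number of
    Gaussian-dispersed offspring (SD ``cluster_sigma_um``), on top of a CSR
    background of the given intensity.
    """

    mode: str = "thomas"
    region_um: tuple[float, float, float, float] = (0.0, 0.0, 10.0, 10.0)
    background_intensity: float = 5.0
    n_clusters: int = 30
    points_per_cluster_mean: float = 60.0
    cluster_sigma_um: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("csr", "thomas"):
            raise ValueError(f"mode must be 'csr' or 'thomas', got {self.mode!r}")
        x0, y0, x1, y1 = self.region_um
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"region_um must have positive area, got {self.region_um}")
        _check_positive("background_intensity", self.background_intensity,
                        allow_zero=True)
        if self.mode == "thomas":
            _check_positive("cluster_sigma_um", self.cluster_sigma_um)
            if self.n_clusters < 0:
                raise ValueError(f"n_clusters must be >= 0, got {self.n_clusters}")
            _check_positive("points_per_cluster_mean",
                            self.points_per_cluster_mean, allow_zero=True)

    @property
    def area_um2(self) -> float:
        x0, y0, x1, y1 = self.region_um
        return (x1 - x0) * (y1 - y0)


@dataclass
class GroundTruth:
    """Per-molecule truth for a simulated dataset.

    ``mobility`` maps molecule id -> 'mobile' | 'immobile'; ``d_true`` maps
    id -> diffusion coefficient; ``trajectories`` maps id -> (frames, xy)
    arrays of the true (noise-free) path over the molecule's active life.
    For point patterns, ``cluster_id`` is the per-point cluster membership
    (-1 = background) aligned with the localization table rows.
    """

    mobility: dict[int, str] = field(default_factory=dict)
    d_true: dict[int, float] = field(default_factory=dict)
    trajectories: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    cluster_id: np.ndarray | None = None

    @property
    def n_molecules(self) -> int:
        return len(self.mobility)

    def immobile_ids(self) -> list[int]:
        return [m for m, c in self.mobility.items() if c == "immobile"]


def simulate_tracks(config: SptSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an sptPALM acquisition; return a localization table and truth.

    Molecules diffuse in an unbounded plane (per-axis step variance
    ``2 D dt``); only localizations falling inside the field of view are
    emitted.  Each molecule runs an inactive -> on <-> off -> bleached
    photophysics chain per frame; dark (off) frames emit nothing, and a dark
    stretch longer than ``max_true_gap`` bleaches the molecule.

    Returns
    -------
    (DataFrame, GroundTruth)
        Table with columns ``frame, x_um, y_um, intensity, sigma_um,
        molecule_id``, sorted by frame then molecule id.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_molecules
    dt = cfg.frame_interval_s

    immobile = rng.random(n) < cfg.f_immobile
    d = np.where(immobile, cfg.d_immobile, cfg.d_mobile)
    step_sd = np.sqrt(2.0 * d * dt)

    pos = rng.uniform(0.0, cfg.fov_um, size=(n, 2))
    # states: 0 inactive, 1 on, 2 off, 3 bleached
    state = np.zeros(n, dtype=np.int8)
    dark_run = np.zeros(n, dtype=np.int32)

    frames: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    traj_frames: dict[int, list[int]] = {}
    traj_xy: dict[int, list[np.ndarray]] = {}

    mol_idx = np.arange(n)
    for f in range(cfg.n_frames):
        inactive = state == 0
        if inactive.any():
            act = inactive & (rng.random(n) < cfg.p_activate)
            state[act] = 1

        alive = (state == 1) | (state == 2)
        if alive.any():
            steps = rng.standard_normal((int(alive.sum()), 2)) * step_sd[alive, None]
            pos[alive] += steps
            for m in mol_idx[alive]:
                traj_frames.setdefault(int(m), []).append(f)
                traj_xy.setdefault(int(m), []).append(pos[m].copy())

        on = state == 1
        if on.any():
            obs = pos[on] + rng.standard_normal((int(on.sum()), 2)) * cfg.loc_sigma_um
            in_fov = ((obs[:, 0] >= 0) & (obs[:, 0] <= cfg.fov_um)
                      & (obs[:, 1] >= 0) & (obs[:, 1] <= cfg.fov_um))
            frames.append(np.full(int(in_fov.sum()), f, dtype=np.int64))
            xs.append(obs[in_fov, 0])
            ys.append(obs[in_fov, 1])
            ids.append(mol_idx[on][in_fov])

        # photophysics transitions after emission
        u = rng.random(n)
        bleach = on & (u < cfg.p_bleach)
        goes_off = on & ~bleach & (rng.random(n) < cfg.p_blink_off)
        off = state == 2
        returns = off & (u < cfg.p_blink_on)
        state[bleach] = 3
        state[goes_off] = 2
        dark_run[goes_off] = 0
        state[returns] = 1
        still_off = (state == 2) & ~goes_off
        dark_run[still_off] += 1
        expired = still_off & (dark_run > cfg.max_true_gap)
        state[expired] = 3

    if frames:
        frame_arr = np.concatenate(frames)
        x_arr = np.concatenate(xs)
        y_arr = np.concatenate(ys)
        id_arr = np.concatenate(ids)
    else:
        frame_arr = np.empty(0, dtype=np.int64)
        x_arr = y_arr = np.empty(0)
        id_arr = np.empty(0, dtype=np.int64)

    table = pd.DataFrame({
        "frame": frame_arr,
        "x_um": x_arr,
        "y_um": y_arr,
        "intensity": np.ones_like(x_arr),
        "sigma_um": np.full_like(x_arr, cfg.loc_sigma_um),
        "molecule_id": id_arr.astype(np.int64),
    }).sort_values(["frame", "molecule_id"], kind="stable").reset_index(drop=True)

    truth = GroundTruth(
        mobility={int(m): ("immobile" if immobile[m] else "mobile") for m in mol_idx},
        d_true={int(m): float(d[m]) for m in mol_idx},
        trajectories={m: (np.asarray(fr), np.vstack(xy))
                      for m, fr, xy in ((m, traj_frames[m], traj_xy[m])
                                        for m in traj_frames)},
    )
    return table, truth


def simulate_track_array(n_tracks: int, n_steps: int, d_um2_s: float,
                         dt_s: float, loc_sigma_um: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Directly sample fixed-length Brownian tracks with localization noise.

    Fast path for calibration studies that do not need photophysics: returns
    an array of shape ``(n_tracks, n_steps + 1, 2)`` of observed positions
    (true Brownian path plus iid Gaussian noise), all starting at the origin.
    """
    steps = rng.standard_normal((n_tracks, n_steps, 2)) * np.sqrt(2 * d_um2_s * dt_s)
    true = np.concatenate([np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)],
                          axis=1)
    return true + rng.standard_normal(true.shape) * loc_sigma_um


def simulate_pattern(config: PatternSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a CSR or Thomas point pattern; all points carry frame 0.

    Thomas offspring falling outside the region are discarded (with the
    default geometry this loses a negligible fraction of points).
    ``GroundTruth.cluster_id`` holds per-point cluster membership, -1 for
    background/CSR points.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    x0, y0, x1, y1 = cfg.region_um
    area = cfg.area_um2

    pts: list[np.ndarray] = []
    cid: list[np.ndarray] = []

    n_bg = rng.poisson(cfg.background_intensity * area)
    bg = np.column_stack([rng.uniform(x0, x1, n_bg), rng.uniform(y0, y1, n_bg)])
    pts.append(bg)
    cid.append(np.full(n_bg, -1, dtype=np.int64))

    if cfg.mode == "thomas":
        centers = np.column_stack([rng.uniform(x0, x1, cfg.n_clusters),
                                   rng.uniform(y0, y1, cfg.n_clusters)])
        for k in range(cfg.n_clusters):
            m = rng.poisson(cfg.points_per_cluster_mean)
            off = centers[k] + rng.standard_normal((m, 2)) * cfg.cluster_sigma_um
            keep = ((off[:, 0] >= x0) & (off[:, 0] <= x1)
                    & (off[:, 1] >= y0) & (off[:, 1] <= y1))
            pts.append(off[keep])
            cid.append(np.full(int(keep.sum()), k, dtype=np.int64))

    xy = np.vstack(pts)
    cluster = np.concatenate(cid)
    table = pd.DataFrame({
        "frame": np.zeros(len(xy), dtype=np.int64),
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        "intensity": np.ones(len(xy)),
        "sigma_um": np.zeros(len(xy)),
        "molecule_id": np.arange(len(xy), dtype=np.int64),
    })
    truth = GroundTruth(cluster_id=cluster)
    return table, truth


def render_frames(localizations: pd.DataFrame, psf_sigma_um: float,
                  photons: float, bg_level: float, pixel_um: float,
                  shape: tuple[int, int] | None = None,
                  poisson_noise: bool = True,
                  seed: int | None = 0) -> np.ndarray:
    """Render a localization table into a camera image stack.

    Each localization is drawn as a pixel-integrated 2-D Gaussian PSF of SD
    ``psf_sigma_um`` carrying ``photons`` total counts, on a constant
    background of ``bg_level`` counts/pixel, with optional Poisson shot noise
    on signal + background.  Stack frame count is ``max(frame) + 1``.

    ``shape`` is (height, width) in pixels; by default it is the tight
    bounding box of the localizations.  Localizations outside the field are
    clipped (their in-field PSF tail is still drawn) and counted in a log
    message.
    """
    if pixel_um <= 0:
        raise ValueError(f"pixel_um must be > 0, got {pixel_um}")
    locs = localizations
    n_frames = int(locs["frame"].max()) + 1 if len(locs) else 1
    if shape is None:
        w = int(np.ceil((locs["x_um"].max() if len(locs) else 1.0) / pixel_um)) + 1
        h = int(np.ceil((locs["y_um"].max() if len(locs) else 1.0) / pixel_um)) + 1
        shape = (h, w)
    h, w = shape
    stack = np.full((n_frames, h, w), float(bg_level))

    if len(locs):
        out = ((locs["x_um"] < 0) | (locs["x_um"] > w * pixel_um)
               | (locs["y_um"] < 0) | (locs["y_um"] > h * pixel_um))
        if out.any():
            logger.info("render_frames: %d localizations outside the field were "
                        "clipped", int(out.sum()))

    s = psf_sigma_um / pixel_um  # PSF SD in pixels
    half = max(3, int(np.ceil(4 * s)))
    for frame, x_um, y_um in zip(locs["frame"].to_numpy(dtype=int),
                                 locs["x_um"].to_numpy(),
                                 locs["y_um"].to_numpy()):
        cx = x_um / pixel_um
        cy = y_um / pixel_um
        i0 = max(0, int(np.floor(cy)) - half)
        i1 = min(h, int(np.floor(cy)) + half + 1)
        j0 = max(0, int(np.floor(cx)) - half)
        j1 = min(w, int(np.floor(cx)) + half + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        jj = np.arange(j0, j1)
        ii = np.arange(i0, i1)
        # integral of the Gaussian over each pixel via erf differences
        fx = 0.5 * (special.erf((jj + 1 - cx) / (np.sqrt(2) * s))
                    - special.erf((jj - cx) / (np.sqrt(2) * s)))
        fy = 0.5 * (special.erf((ii + 1 - cy) / (np.sqrt(2) * s))
                    - special.erf((ii - cy) / (np.sqrt(2) * s)))
        stack[frame, i0:i1, j0:j1] += photons * np.outer(fy, fx)

    if poisson_noise:
        rng = np.random.default_rng(seed)
        stack = rng.poisson(stack).astype(float)
    return stack
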