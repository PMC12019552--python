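"""Per-track MSD curves, instantaneous diffusion coefficients and mobility.

The estimator follows the sptPALM convention for membrane proteins: the
time-averaged mean squared displacement of each track is fitted on its first
four lag points by ordinary least squares with a free intercept, and the
instantaneous diffusion coefficient is D = slope / 4 (2-D motion).  The free
intercept absorbs the static localization-error offset (≈ 4σ² for error SD
σ).  Tracks with D below 0.01 µm²/s are classified immobile.

Tracks may contain blink gaps; squared displacements are always binned by
the true frame difference, so a pair spanning a 2-frame gap contributes to
the lag-3 point, never to lag 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect_link import Track, TrackSet

#: immobile/mobile boundary on the instantaneous diffusion coefficient (µm²/s)
D_THRESHOLD = 0.01
#: value assigned to non-positive fitted slopes so log-histograms stay defined
D_FLOOR = 1e-5


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track: lag times (s), MSD (µm²), pair counts."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def __len__(self) -> int:
        return len(self.lags_s)


@dataclass
class DiffusionEstimate:
    track_id: int
    d_um2_s: float
    intercept_um2: float
    mobility: str
    n_fit_points: int
    floored: bool = False


def compute_msd(track: Track, dt_s: float) -> MSDCurve:
    """Time-averaged MSD over all ordered localization pairs of a track.

    For every pair (i, j) with frame_j > frame_i, the squared planar
    displacement is accumulated at lag (frame_j - frame_i) * dt.  Lags with
    no pairs (possible with blink gaps) are omitted.
    """
    frames = track.frames
    xy = track.xy
    if len(frames) < 2:
        raise ValueError(
            f"track {track.track_id}: MSD needs at least 2 localizations")
    # all ordered pairs via upper-triangular index difference
    i, j = np.triu_indices(len(frames), k=1)
    lag_frames = frames[j] - frames[i]
    sq = np.sum((xy[j] - xy[i]) ** 2, axis=1)
    max_lag = int(lag_frames.max())
    counts = np.bincount(lag_frames, minlength=max_lag + 1)
    sums = np.bincount(lag_frames, weights=sq, minlength=max_lag + 1)
    present = np.flatnonzero(counts[1:]) + 1
    return MSDCurve(lags_s=present * dt_s,
                    msd_um2=sums[present] / counts[present],
                    n_pairs=counts[present])


def fit_diffusion(msd: MSDCurve, n_points: int = 4,
                  track_id: int = -1, threshold: float = D_THRESHOLD,
                  fit_intercept: bool = True,
                  msd_dim_factor: float = 4.0,
                  d_floor: float = D_FLOOR) -> DiffusionEstimate:
    """Fit D from the first ``n_points`` lags of an MSD curve.

    OLS line through the ``n_points`` smallest available lags;
    ``D = slope / msd_dim_factor`` (4 for 2-D Brownian motion).  Non-positive
    slopes are floored to ``d_floor`` and flagged; floored tracks classify as
    immobile (they are slower than any threshold of interest).
    """
    if len(msd) < n_points:
        raise ValueError(
            f"track {track_id}: MSD has {len(msd)} lags, need {n_points}")
    tau = msd.lags_s[:n_points]
    y = msd.msd_um2[:n_points]
    if fit_intercept:
        slope, intercept = np.polyfit(tau, y, 1)
    else:
        slope = float(tau @ y / (tau @ tau))
        intercept = 0.0
    floored = slope <= 0
    d = d_floor if floored else float(slope) / msd_dim_factor
    return DiffusionEstimate(
        track_id=track_id, d_um2_s=d, intercept_um2=float(intercept),
        mobility="immobile" if d < threshold else "mobile",
        n_fit_points=n_points, floored=bool(floored))


def estimate_tracks(tracks: TrackSet, dt_s: float, n_points: int = 4,
                    threshold: float = D_THRESHOLD) -> pd.DataFrame:
    """MSD-fit every track; returns a tidy per-track estimate table."""
    rows = []
    for t in tracks:
        est = fit_diffusion(compute_msd(t, dt_s), n_points=n_points,
                            track_id=t.track_id, threshold=threshold)
        rows.append((est.track_id, est.d_um2_s, est.intercept_um2,
                     est.mobility, est.floored))
    return pd.DataFrame(rows, columns=["track_id", "d_um2_s", "intercept_um2",
                                       "mobility", "floored"])


def fit_track_array(xy: np.ndarray, dt_s: float, n_points: int = 4,
                    threshold: float = D_THRESHOLD,
                    d_floor: float = D_FLOOR) -> np.ndarray:
    """Vectorized 4-point MSD fit for equal-length, gap-free tracks.

    ``xy`` has shape (n_tracks, n_locs, 2).  Returns fitted D per track.
    Numerically identical to :func:`compute_msd` + :func:`fit_diffusion` on
    each track (checked in the test suite); used by the repetition-heavy
    calibration studies.
    """
    n_locs = xy.shape[1]
    if n_locs - 1 < n_points:
        raise ValueError(f"tracks of {n_locs} points cannot support "
                         f"{n_points} MSD lags")
    msd = np.empty((xy.shape[0], n_points))
    for k in range(1, n_points + 1):
        disp = xy[:, k:] - xy[:, :-k]
        msd[:, k - 1] = np.mean(np.sum(disp ** 2, axis=2), axis=1)
    tau = np.arange(1, n_points + 1) * dt_s
    tc = tau - tau.mean()
    slope = (msd - msd.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
    d = slope / 4.0
    d[slope <= 0] = d_floor
    return d


def immobile_fraction(estimates: pd.DataFrame, threshold: float = D_THRESHOLD,
                      by: list[str] | None = None):
    """Fraction of tracks with D below the immobility threshold.

    With ``by`` (e.g. ``["cell_id"]`` or ``["genotype", "treatment"]``),
    returns a per-group summary DataFrame with columns
    ``<keys>..., n_tracks, immobile_fraction``; otherwise a float.
    """
    if len(estimates) == 0:
        raise ValueError("immobile_fraction needs at least one estimate")
    imm = estimates["d_um2_s"] < threshold
    if by is None:
        return float(imm.mean())
    df = estimates.assign(_imm=imm)
    out = (df.groupby(by, sort=True)["_imm"]
           .agg(n_tracks="size", immobile_fraction="mean").reset_index())
    out["n_tracks"] = out["n_tracks"].astype(int)
    return out


def diffusion_histogram(estimates: pd.DataFrame, log_base: float = 2.0,
                        bins: int = 30,
                        range_log: tuple[float, float] | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of log(D) at the configured base.

    Returns ``(counts, bin_edges)`` with edges in log-base units.  The
    default range spans the floored minimum to the observed maximum so the
    immobile spike stays in view.  Changing the base rescales edge positions
    by the ratio of logs and leaves counts unchanged.
    """
    d = estimates["d_um2_s"].to_numpy(dtype=float)
    if np.any(d <= 0):
        raise ValueError("diffusion_histogram requires strictly positive D "
                         "(floor non-positive slopes upstream)")
    logd = np.log(d) / np.log(log_base)
    if range_log is None:
        range_log = (float(logd.min()), float(logd.max()))
    counts, edges = np.histogram(logd, bins=bins, range=range_log)
    return counts, edges


def histogram_mode_indices(counts: np.ndarray, smooth: int = 3) -> list[int]:
    """Indices of local maxima of a (lightly box-smoothed) histogram.

    Used to check the bimodality of log-D distributions from two-population
    membranes.  A bin is a mode if it strictly exceeds both neighbours after
    smoothing; plateaus count once (at their first bin).
    """
    c = counts.astype(float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        c = np.convolve(c, kernel, mode="same")
    modes: list[int] = []
    i = 0
    while i < len(c):
        j = i
        while j + 1 < len(c) and c[j + 1] == c[i]:
            j += 1
        left = c[i - 1] if i > 0 else -np.inf
        right = c[j + 1] if j + 1 < len(c) else -np.inf
        if c[i] > left and c[i] > right and c[i] > 0:
            modes.append(i)
        i = j + 1
    return modes


def histogram_modes(counts: np.ndarray, smooth: int = 3) -> int:
    """Number of local maxima of a histogram (see histogram_mode_indices)."""
    return len(histogram_mode_indices(counts, smooth=smooth))
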