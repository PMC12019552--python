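# Methods

This note documents the models, parameters, numerical choices and known
limitations of the nanospt analysis chain. It describes what the code
computes; every number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Simulated sptPALM acquisitions

The generator emulates sparse-photoactivation imaging of a
photoconvertible-tagged membrane protein at 30 ms frame interval and 7000
frames per region — the acquisition geometry of the experiments the
pipeline targets. Each of `n_molecules` molecules:

* is **immobile** with probability `f_immobile` (D = `d_immobile`,
  default 0.001 µm²/s) or mobile (D = `d_mobile`, default 0.08 µm²/s);
* performs 2-D Brownian motion with per-axis step variance 2·D·Δt in an
  **unbounded plane** — only localizations inside the square field of view
  are emitted. This avoids reflecting-boundary artifacts in MSD estimates
  at the cost of molecules drifting out of view;
* runs a per-frame photophysics chain: inactive → (p_activate) → on;
  on → (p_bleach) → bleached, on → (p_blink_off) → off,
  off → (p_blink_on) → on; a dark run longer than `max_true_gap` frames
  bleaches the molecule. The immobile default is strictly positive rather
  than zero so log-D histograms are well defined; exact D = 0 is reserved
  for analytic tests;
* is localized with isotropic Gaussian error of SD `loc_sigma_um`
  (default 20 nm).

The photophysics rates are stated assumptions, not measured values — the
source experiments do not report mEOS2 rate constants. They are chosen so
that a few emitters are on per frame (sparse, trackable) with mean on-times
of a few frames. Because blinking, bleaching and activation are explicit
and parameterizable, the downstream gap-closing and detection-merging
stages can be tested against known molecule counts.

A direct track sampler (`simulate_track_array`) draws fixed-length noisy
Brownian tracks without photophysics; it is the fast path for
repetition-heavy calibration studies and is held to the same fitted-D
results as the full path by an equivalence test.

Point patterns for the tessellation stage are homogeneous Poisson (CSR)
or Thomas processes: `n_clusters` uniform centres, Poisson(`points_per_
cluster_mean`) offspring displaced by an isotropic Gaussian of SD
`cluster_sigma_um`, over a CSR background. Offspring falling outside the
region are discarded (negligible at the default geometry).

Rendering draws each localization as a pixel-integrated 2-D Gaussian PSF
(erf differences) scaled to a photon budget, plus Poisson shot noise on
signal and background. No EMCCD gain model.

## Tracking

Detection: per-frame difference-of-Gaussians band-pass (σ and 2σ of the
PSF), local maxima above median + k·MAD (k = 6 by default) of the filtered
frame, and subpixel intensity-weighted centroids. Coordinates use the
top-left pixel corner as origin, x right, y down, everything in µm.

Linking: candidate (open track end, new localization) pairs within the
search radius are assigned greedily in order of increasing displacement.
Dark gaps up to `max_gap = 3` consecutive frames are bridged — the
blinking convention of the analysis — with search radius growing linearly,
`max_disp·(gap+1)`. Linear growth is more permissive than the √gap scaling
diffusion would suggest; it is a tunable (`grow_radius`) recorded as a
design choice. Greedy shortest-first assignment is a simplification of
full LAP tracking that matches the exhaustive minimal-total-displacement
assignment on sparse instances (tested) and scores ≥ 95% per-link accuracy
on rendered SNR ≥ 10 stacks at sptPALM densities. A link is scored correct
when at least one ground-truth molecule is consistent with both endpoints;
demanding a unique nearest molecule would penalize tracks through
sub-resolution molecule coincidences that no position-only tracker can
resolve. No splitting/merging, no motion-model prediction, no drift
correction.

Only tracks with at least seven steps (eight localizations) enter
diffusion estimation.

## Diffusion estimation

Per-track time-averaged MSD over **all** overlapping ordered pairs, binned
by true frame difference so blink gaps contribute to the correct lag.
The instantaneous D comes from an OLS line through the four smallest
available lags with a free intercept, D = slope/4. Both the intercept and
the dimensionality constant are configurable (`fit_intercept`,
`msd_dim_factor`) since conventions differ across labs. The free intercept
absorbs the static localization-error offset ≈ 4σ² (≈ 0.0016 µm² at
σ = 20 nm); at 4-point fits it is noisy, and the calibration study holds
its median only to within 50%.

Non-positive slopes are floored at D = 10⁻⁵ µm²/s and flagged; floored
tracks count as immobile. The immobile threshold is 0.01 µm²/s. With the
standard conditions (500 tracks of 20 steps, D = 0.05 µm²/s, σ = 20 nm,
Δt = 30 ms) the median fitted D is within ~7% of truth; two-population
mixtures (0.001 / 0.08 µm²/s, 30% immobile) are recovered within ±0.05
and their log2-D histograms are bimodal. Histogram bimodality is scored on
a 3-bin box-smoothed histogram: one local maximum below log(0.01) and one
above. The log base defaults to 2 and only rescales the axis.

## Voronoï nanodomain segmentation

Repeated detections of one blinking emitter are first merged: the linker
is run with a fixed (non-growing) radius `merge_radius_um = 0.05` and gap
tolerance equal to the tracking `max_gap` (3 frames), and each resulting
chain collapses to its intensity-weighted mean position. The defaults
follow common SMLM practice; they are assumptions, not measured values.

The merged molecules are tessellated (shapely Voronoï polygons), cells are
clipped to the analysis region, and the local density is δᵢ = 1/Aᵢ. Border
cells are clipped rather than discarded so edge molecules still contribute
to the average; a flag supports the stricter alternative. The reference
density is δ_avg = N/region area by default (`avg_mode = "global"`); the
mean of δᵢ is available but is strongly biased upward on clustered data
(dense molecules dominate the mean), which would suppress all detections
at high density factors.

Seeds are molecules with δᵢ > 50·δ_avg. Connected components of seeds
under Voronoï adjacency (Delaunay edges) define domains; each domain's
region is the filled outline of the union of its seed cells, its
detections are all molecules covered by that region, and domains with
fewer than 25 detections are discarded. Counting detections inside the
region — rather than seeds only — follows the region-of-interest reading
of the thresholding convention; in practice the two differ little because
a seed cell ends halfway to the nearest sub-threshold molecule.

Metrics per analysis region: mean equivalent circular diameter
2·√(area/π) (the "size" measure; an explicit convention, since none is
standard), fraction of molecules inside domains, and domains per µm².

Validation at the standard thresholds (factor 50, min 25): CSR patterns of
5000 points assign < 1% (measured: 0%) of molecules to domains over 20
seeds; Thomas patterns of 30 clusters × 60 points at σ = 40 nm are
recovered at ~29–30 domains with ~130 nm equivalent diameter.

**Known limitation — molecular share of soft-edged clusters.** For
Gaussian clusters the local intensity falls off continuously, and with 60
points at σ = 40 nm the peak density (~6·10³ µm⁻²) is only ~5× the
segmentation threshold (50·δ_avg ≈ 1.15·10³ µm⁻² at the default
background). Offspring beyond r* = σ·√(2·ln 5) ≈ 1.8σ — about a fifth of
each cluster — sit below threshold *by construction*, so the detected
molecules-in-domain share (~0.57) is structurally below the generated
clustered share (~0.78). This is a property of hard density thresholds on
soft clusters, not an estimator defect; comparisons across conditions at a
fixed threshold (the figure-level use) are unaffected, but the absolute
share should not be read as the true clustered fraction.

## Image quantifications

* **TIRF cluster density.** The first 100 frames are averaged pixelwise;
  clusters are segmented by white top-hat background flattening (disk
  radius 8 px), a global median + 6·MAD threshold, and a 4-px minimum
  area, then counted by centroid inside a 100 × 100 px ROI. This
  deterministic segmenter replaces interactive machine-learning
  segmentation; it is validated on rendered synthetic fields (25/25 spots
  recovered at SNR ≥ 8), not claimed equivalent to a trained classifier.
  The nominal pixel size is treated as 0.102 µm (the "0.102 nm" figure in
  the source description is physically inconsistent with a 100× objective
  and is read as a units typo).
* **FRET/Venus ratio.** Per-pixel (FRET − bg)/(Venus − bg); pixels whose
  background-subtracted donor falls below a floor are masked; per-ROI
  means over unmasked pixels. Backgrounds are configurable (fixed value,
  1st percentile, or outside-ROI median). No spectral bleed-through
  correction — the assay uses a plain ratio.
* **ROS mean gray value.** Background (1st percentile or outside-ROI
  median) subtracted from the mean over the cell mask, clamped at zero.
  A simulated 2× stimulation is recovered within 0.5%.

## Statistics

Group summaries are mean ± t-based 95% CI. Two-sample tests are Student's
t by default (Welch switchable); degenerate all-equal inputs return
p = 1. One-way ANOVA (scipy) is followed by Tukey HSD
(`scipy.stats.tukey_hsd`, cross-checked against statsmodels in the tests)
and a compact letter display computed from the maximal cliques of the
not-significantly-different graph. This guarantees exactly the defining
property — two groups share a letter iff their Tukey-adjusted p ≥ α — and
is verified exhaustively on instances up to six groups; it produces the
same displays as the classical insert-and-absorb procedure. Letters are
ordered by descending group mean. The significance level is a per-analysis
config (α = 0.05 default). Under a global null (4 groups × n = 10, 1000
replicates) the letter display's family-wise error is ≈ 0.04–0.05,
consistent with Tukey's exact control. Units of replication are cells
pooled across biological replicas; the table schema carries replicate ids
so a hierarchical analysis could be added, but none is computed.

## Problem sizes and determinism

The validation studies use deliberately modest sizes — 500–600 tracks for
calibration and mixtures, 100 repetitions × 20 cells for the power study,
20 CSR and 5 Thomas patterns, 250-frame rendered stacks, 1000 null
datasets — chosen so the whole suite and the acceptance script complete in
a few minutes on one CPU while keeping Monte-Carlo error well inside each
tolerance. One global seed is expanded into per-stage sub-seeds by hashing
a stage label, so enabling or disabling one stage never perturbs
another's randomness; all CSV floats are written at 9 significant digits,
making byte-identical reruns achievable and tested.
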