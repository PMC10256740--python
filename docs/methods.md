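# Methods

This note documents the models, conventions, parameter choices and
known limitations of `granulekit`, stage by stage.

## Motion models and trajectory simulation

Trajectories are sampled at the imaging frame rate (default 10
frames/s for 60 s: `frame_interval = 0.1 s`, `n_frames = 600`) under
five regimes:

* **stationary** — constant position.
* **brownian** — per-axis Gaussian steps of variance 2·D·Δt.
* **directed** — constant-velocity run; the per-track speed is drawn
  once per track from a normal truncated at zero (mean `v`, SD `v_sd`),
  matching the track-to-track heterogeneity of per-track velocity
  summaries; optional diffusive jitter on top.
* **confined** — Brownian steps radially reflected inside a disc of
  `corral_radius` about the start point.  This is the simplest model
  that reproduces MSD saturation; the radial-reflection step slightly
  distorts the equilibrium distribution near the wall but leaves the
  short-lag MSD (what the estimator uses) correct.
* **switching** — two-state alternation between a diffusive anchored
  state and a directed run state with per-second exit rates
  (per-frame switch probability 1 − e^(−rate·Δt)); the run heading is
  redrawn at each run start.

Field-of-view handling is **reflecting** by default so rendered movies
never lose particles (no censoring in recovery tests); `boundary="none"`
disables it for estimator tests where reflection would truncate
excursions (a reflected ballistic run no longer satisfies
d_max = v·T).

Two speed-sampling modes exist: `iid` (default) and `stratified`, a
jittered stratified inverse-CDF draw used by the recovery protocols in
`benchmarks.py`.  Both produce the same marginal law and are seeded;
stratification removes the O(SD/√n) wander of the ensemble mean so a
recovery comparison measures estimator bias rather than draw luck.
Where a recovery protocol must reproduce a stated *empirical* mean,
`matched_truncnorm_loc` solves for the truncated-normal location whose
post-truncation mean equals the target (truncation at zero otherwise
biases the realized mean upward — by ~0.8 µm for the distance
protocol, most of its acceptance band).

## Rendering

Spots are isotropic 2-D Gaussians of `psf_sigma` (default 0.18 µm,
near the LoG scale of a 0.5 µm granule) evaluated at pixel centers,
peak `spot_amplitude` = 200 photons on `background` = 10 photons.
Noise: Poisson on signal + background (default), optional additive
Gaussian read noise, or none.  The published movies' SNR is not
stated; these defaults are chosen for estimator testability, not to
mimic a particular instrument.  Pixel centers sit at integer pixel
coordinates, origin top-left, x rightward, y downward; all public
outputs are in µm.

## Tracking

Per frame: rolling-ball background subtraction (radius 3 px, the
classic grayscale-opening-by-a-ball estimate, output clipped ≥ 0),
then scale-normalized LoG response at σ = diameter/(2√2) with
`diameter` = 0.5 µm, local maxima, and sub-pixel refinement by a
1-D quadratic fit per axis (offsets clipped to ±0.5 px).  The quality
threshold defaults to an Otsu split of the pooled per-movie
LoG-response distribution — background responses cluster near zero,
spot responses far above, so the split is robust; a per-movie constant
emulates a single detector "quality" cutoff.

Linking is greedy mutual-nearest-neighbor per consecutive frame pair
within `max_displacement` (default 0.5 µm/frame), no gap closing,
splitting or merging; ties are broken deterministically by lower spot
index after sorting by (frame, y, x), making linking
permutation-invariant.  The track-length filter keeps tracks of ≥ 21
points (strictly more than 20 frames, i.e. > 2 s at 10 frames/s) and
is idempotent.

Noise-free end-to-end fidelity (count exact, positions < 0.5 px RMS)
is asserted in the acceptance suite; measured RMS error is ~0.1 px.

## Dynamics

MSD uses overlapping windows at lags 1…7 (all start points), so
estimates at different lags share data; the per-lag pair counts are
reported.  The diffusion coefficient is the OLS slope of MSD vs lag
time **with a free intercept** (absorbing static localization error;
the intercept is discarded), divided by 4 for the 2-D Brownian
relation MSD = 4Dτ.  A `"slope"` convention (no /4) is selectable for
pipelines that define the coefficient as the slope itself; recovery
tests use the default.  Negative fitted slopes are clamped to zero
with a flag, and log summaries (base 10) are computed only over
positive D, zeros tallied separately.

Velocity is total path length over elapsed time.  (One published
methods sentence states the inverse ratio, "total time by total
distance", but the reported units are µm/s; distance/time is
implemented and the discrepancy noted here.)  Maximum distance is the
farthest Euclidean excursion from the first point, so
velocity ≥ d_max/T always.

Group comparison is a two-tailed Mann–Whitney U: exact enumeration of
all C(n, n_a) assignments with midranks when n_a + n_b ≤ 12 (two
identical groups give p = 1; complete separation of 3 vs 3 gives the
smallest attainable p = 0.1), normal approximation with tie and
continuity correction otherwise.

## Kymographs and co-transport

Kymographs resample each frame along a polyline at `pixel_size` steps
(bilinear interpolation), averaging across an odd `width` of parallel
offsets along the local normal.  Processive runs are maximal monotone
excursions of the positions projected on the track's first principal
component (granule motion in a neurite is effectively 1-D), with net
displacement ≥ 2 µm; zero steps extend the current excursion.  A
reference track with runs counts as co-transported when a single
partner track stays within `max_gap` = 0.5 µm for ≥ 50% of a run's
frames; both thresholds are configurable since the qualitative
criterion ("overlapping in both channels") does not pin them down.

## Recruitment and colocalization

E = log₂(centrosome mean / whole-cell mean); the whole-cell
denominator **includes** the centrosome pixels.  E is invariant to
multiplicative intensity scaling but not to additive offsets (tested).
`make_cell_image` inverts the score analytically — the centrosome
pixel value is solved from the mask sizes so the constructed image
round-trips to the requested E at machine precision; the construction
fails loudly when the requested ratio is unattainable for the given
mask sizes.  Pearson and Manders coefficients operate on masked 2-D or
3-D arrays; Manders thresholds default to 0.

## Fractionation statistics

Counts are negative binomial (gamma–Poisson, shared dispersion 0.05)
over lognormal gene abundances at an expected library size of 10⁶;
per-gene baseline log₂(neurite/soma) ratios are N(0, 0.5); CLIP
densities are a zero-inflated lognormal (40% zeros).  Genes above the
effect threshold (default: top quartile of positive densities) get an
`effect_size` log₂ shift of neurite abundance in perturbed conditions.
One replicate per compartment×condition is the default — statistics
are across genes, not replicates, so no gene-level variance model is
fitted.

Cyclic-loess normalization: log₂(count + 0.5), then for each sample
pair a lowess fit (span 0.7) of M on A subtracted/added symmetrically,
cycled 3 times; pairwise identical samples are left unchanged and
per-gene averages are preserved.  The localization ratio is the mean
normalized neurite log₂ expression minus soma, per condition; the
expression filter (default mean log₂ > 1 in both compartments of every
condition) runs first.  CLIP-density bins default to
{0, (0, q50], (q50, q75], > q75} on positive densities; per-bin median
ΔL with bootstrap SEM (200 resamples) and Wilcoxon rank-sum vs the
zero-density bin.  The mis-localized set uses ΔL ≤ −0.25 by default;
overlap enrichment is observed/expected-under-independence with a
two-tailed Fisher exact p.  With a large induced shift, normalization
recenters the M distribution, so unaffected bins sit slightly above
zero while the top bin sits near the induced −0.5; the bin *contrast*
is the cleaner readout and the rank-sum test captures it.

FISH spot distances: spots project onto the nearest neurite polyline
(shapely); the statistic is arclength from the soma end divided by
that neurite's total length — a per-neurite normalization, since a
cell-wide sum would not bound fractions by 1.  Spots farther than
2 µm from every neurite are flagged and excluded.  Per-cell 95th
percentiles (linear interpolation) require ≥ 150 spots per cell.

qPCR membrane enrichment is 2^(−ΔΔCt) with the cytosolic reference
gene, geometric-mean-aggregated over replicates (equivalent to
averaging ΔΔCt).  The isoform fraction is tpm_α/(tpm_α + tpm_β).

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure each estimator
assumes: Gaussian spots at known positions, NB counts with known
shifts, spots at known arclength fractions, Ct tables with known fold
ratios.  It does not emulate uneven illumination, chromatic offsets
between channels, granule fusion/fission, photobleaching, spot-size
heterogeneity, mapping biases in counts, or segmentation error in
masks.  Passing recovery tests therefore demonstrates correctness of
the estimators under their stated models, not robustness to every
artifact of real data.

## Problem sizes in tests

The default suite uses reduced ensembles (hundreds of tracks,
1–3.4 k genes, 200 null replicates) chosen so the whole suite runs in
well under a minute of compute per module while keeping Monte-Carlo
error far below the asserted tolerances; the acceptance protocols use
the published track counts (36/71/50) where those are part of the
protocol, and 500 tracks / 500 genes-per-bin where the criterion
states them.

## Known limitations

* No gap closing or LAP-style linking: dense fields with blinking
  spots fragment tracks.
* No anomalous-diffusion exponent fitting or hidden-state track
  segmentation.
* Colocalization assumes pre-registered channels.
* 2-D only throughout the imaging synthesis; colocalization accepts
  3-D arrays but no 3-D detection exists.
* No automated anterograde/retrograde polarity (requires soma-position
  metadata assigned manually in practice).
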