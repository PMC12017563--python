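# Methods

`reefscape` turns a duty-cycled passive-acoustic recording campaign into a
set of quantitative soundscape summaries. This note documents the model and
procedure, the parameters that matter, the numerical conventions, what the
synthetic generator does and does not emulate, and the open design choices
the package settles.

## Pipeline

### Preprocessing and segmentation

Each recording is read as mono 16-bit PCM WAV (stereo files and mixed sample
rates are rejected; no down-mixing or resampling is attempted) and high-pass
filtered as a whole file with an 8th-order zero-phase Butterworth filter at
70 Hz (`FilterSpec`). Filtering the whole file before cutting avoids filter
transients at segment boundaries. The filtered waveform is cut into
contiguous, non-overlapping 1-s segments; a trailing remainder is discarded.

### Initial acoustic embedding

Three embeddings project a 1-s segment into the initial acoustic space:

* **mel spectrum** (default, 64-d): natural-log energies of 64 triangular
  mel filters spanning the band of interest (70–2000 Hz by default — the
  range of most fish sounds and boat noise), computed from a single
  Hann-windowed power spectrum of the whole second;
* **mel spectrogram** (6400-d): the same filterbank applied to a short-time
  Fourier transform with a 2048-sample window and a 0.01-s hop (441 samples
  at 44.1 kHz), giving 64 bands × 100 frames = 6400 natural-log values;
* **CNN adapter**: a pluggable external embedding (e.g. a pretrained
  audio CNN). Only an adapter interface ships — no network weights. The
  adapter receives the first 0.96 s of each segment and must declare its
  output dimensionality.

Conventions, declared because published pipelines differ and results depend
on them: HTK mel scale (`2595·log10(1 + f/700)`); triangular unit-peak
filters with edges equally spaced on the mel scale over [fmin, fmax];
periodic Hann window; frames left-aligned starting at sample 0 with the last
windows zero-padded (this framing yields exactly `len // hop` = 100 frames
per second, hence the 6400-value shape); per-bin ("spectrum"-scaled) power
so a stationary tone yields comparable band energies from the whole-segment
and framed analyses; linear band energies floored at 1e-12 (full scale 1)
before the natural log, so digital silence maps to log(1e-12) in every band.
The whole-segment and frame-averaged band energies agree only in the
stationary-signal limit and only approximately (the mel filter weight varies
across a tone's wider spectral spread at the coarser frame resolution); the
test suite checks agreement within a factor ~1.6 on a stationary tone and
does not assert it in general.

### Feature table

Per-second embeddings are averaged over the **integration time** (default
15 s, i.e. 4 samples per one-minute file) in non-overlapping blocks,
trailing partial blocks discarded. Dimensions constant over the whole
dataset (max − min ≤ 1e-12) are pruned; remaining dimensions are
robust-scaled, x → (x − median)/IQR with linearly interpolated (type-7)
quartiles — the IQR value depends on the quantile convention, hence it is
pinned. A non-constant column with degenerate IQR falls back to range
scaling and is flagged. The default order is aggregate → prune → scale;
because the reverse reading (prune and scale per-second vectors, then
aggregate) is also defensible, it is exposed as `pipeline_order =
"scale_first"` and covered by an order-sensitivity regression test rather
than asserted as the single truth.

### Ensemble projection and the averaged distance matrix

UMAP is stochastic; any metric read off a single embedding inherits that
noise. The pipeline therefore repeats the projection N times (default 100;
reduced runs use fewer) with seeds `base_seed + r`, computes each repeat's
pairwise Euclidean distance matrix (the projection space is Euclidean), and
averages the matrices elementwise. All downstream quantification (silhouette,
clustering, trajectories) runs on the averaged matrix; the embeddings
themselves are kept for visualization and per-repeat trajectory statistics.
UMAP hyperparameters other than the dimensionality (default 3) keep the
implementation defaults (`n_neighbors = 15`, clamped to n − 1 on small
datasets and recorded; `min_dist = 0.1`) and are echoed in the results
bundle. PCA is available as a deterministic alternative (N forced to 1),
with a fixed sign convention (largest-magnitude loading positive) so axes
are reproducible.

Diagnostics:

* **Convergence.** For each n, the running-average matrix over the first n
  repeats is compared with the one over n − 1: relative mean and maximum
  absolute elementwise differences, normalized by the mean off-diagonal
  entry of the previous running average (the normalization is a package
  choice; "relative" admits several denominators). For i.i.d. bounded
  repeats the CLT gives ~1/√n decay; the tests assert a negative log-log
  slope rather than the exact exponent.
* **IQM**: interquartile range of the pairwise distances divided by their
  median, over the strict upper triangle — a scale-free distance-contrast
  measure. On clustered data the projected IQM exceeds the raw
  high-dimensional IQM (asserted as a strict inequality on synthetic data,
  not as a specific factor).
* **DLP** (local): mean over samples of the shared fraction between the k
  nearest neighbours in feature space and in the embedding (Euclidean in
  both; k default 100, clamped). **RTA** (global): fraction of uniformly
  sampled anchored triplets (i; j, k) whose distance ordering
  sign(d(i,j) − d(i,k)) agrees between the two spaces, deterministic given
  its seed. Both formulas are package definitions of metrics that are named
  but not written out in the soundscape literature they come from; chance
  levels are k/(n − 1) and 0.5 respectively, and identity embeddings score
  exactly 1.

### Label separation (pairwise silhouette)

For two categories A, B of a categorical label, the averaged distance matrix
is restricted to their samples; each sample gets the classic silhouette
s(i) = (b − a)/max(a, b) with a = mean distance to its own category (self
excluded) and b = mean distance to the other; the index is the mean of s
over the samples of **both** categories (the literature does not pin the
variant; averaging over both is symmetric by construction). Duplicate points
(a = b = 0) contribute 0. Values near 1 mean disjoint occupancy of the
acoustic space, near 0 complete overlap; slightly negative values can occur
for interpenetrating clouds and are reported unclamped even though the index
is usually discussed on the 0–1 range. All unordered category pairs fill a
symmetric matrix (18 categories → 153 pairs), exportable as CSV.

### Unsupervised clustering

HDBSCAN runs directly on the averaged distance matrix
(`sklearn.cluster.HDBSCAN`, metric="precomputed"), with minimum cluster size
100 by default and both selection strategies computed: **EOM** (excess of
mass — coarse) and **leaf** (condensed-tree leaves — fine). `min_samples`
keeps the implementation default (= min cluster size) and is recorded.
Samples too isolated get label −1; ids are remapped to descending cluster
size for stable reporting; when fewer than `min_cluster_size` samples exist
no cluster can form and every sample is −1. Each clustering is compared to
every predefined label by a row-percentage contingency matrix (rows: −1
first, then ascending ids; each row sums to 100). `cluster_purity` maps each
cluster to its majority category and reports the matching fraction over
assigned samples. EOM merges acoustically adjacent sites by construction —
on graded-disturbance designs it typically yields "disturbed vs the rest" —
so planted-structure recovery is assessed on the leaf partition.

### Temporal trajectories

Ordering a group's samples by window start traces a path per (group,
replicate). Because absolute UMAP coordinates are meaningless, the metric is
relative and computed within each repeat: the group's reference is the
centroid of the first point of each replicate's path (a shared per-group
"average starting point", pooled across replicates — the alternative
per-replicate reference is not adopted because cross-replicate comparability
is the point of the display); the scale is the mean distance from the
reference to its k nearest sample points (k default 100, reduced and
recorded when fewer exist; all samples are eligible neighbours); each path
point's value is distance-to-reference divided by the scale. Across repeats
the per-time median and deciles 1 and 9 (linear-interpolation quantiles) are
retained. A stationary soundscape hovers around 1; planted or real
disturbances (rain, boats, dusk) appear as excursions of the median outside
the interdecile band of quiet periods.

## Synthetic campaigns

The generator renders duty-cycled WAV campaigns with known structure so
every stage is testable without field recordings. A scene mixes: Poisson
snap trains (~2 ms exponentially decaying broadband bursts; the rate is
multiplied by a diel night gain of 3 for night files), Poisson fish calls
(3–8 gated 20-ms sinusoid pulses at a base frequency inside a sub-1 kHz
band), boat passages (broadband noise plus an 80–140 Hz engine harmonic
stack, treated as daytime activity), rain intervals (broadband noise), and a
faint ambient floor (3e-3 full scale). Event shapes are package inventions
chosen for spectral plausibility, not measured calls. Per-scene lognormal
jitter on event rates (σ = 0.25) and on the overall level (σ = 0.15)
emulates natural file-to-file variability; without it, 15-s averages of
stationary scenes are so tight that every site separates completely and
silhouette values saturate, which real campaigns do not show. Scenes are
peak-guarded at ≤ 1 and written as 16-bit PCM without dither; generation is
byte-deterministic given (config, seed), with per-file seeds derived as
`seed·1 000 003 + slot index (mod 2³¹)`.

The default campaign: three sites — `quiet` (dense snaps, low fish chorus),
`quiet_variant` (sparser snaps, chorus shifted up in band: a subtle
biophony-level contrast), `boat` (the quiet reef plus continuous daytime
boat traffic: a gross anthropogenic contrast) — recorded 1 min every 10 min
from 12:05 to 12:05 the next day inclusive (145 files per site-day) over 3
non-consecutive days, with day/night labels from fixed 06:00/18:00
sunrise/sunset. That design yields 1305 files and, at 15-s integration,
5220 samples. The reduced campaign used by the tests and the acceptance
script keeps the three sites but simulates 1 h per site-day at a 5-min cycle
(13 files → 52 samples per site), 20 UMAP repeats, minimum cluster size 20,
trajectory k = 20; these sizes keep a full run around a minute on one CPU
while leaving each planted contrast resolvable.

What the generator does **not** emulate: propagation and depth effects,
realistic species call libraries, tide/wind geophony, recorder self-noise
spectra, or clock drift. Passing tests therefore demonstrate that the
pipeline recovers structure of the planted kinds at the planted
signal-to-variability ratios — not that it resolves arbitrary contrasts in
real reef recordings.

## Numerical and degenerate-input conventions

* Quantiles everywhere use linear interpolation (numpy `method="linear"`).
* Energy floor 1e-12 before logs; prune tolerance 1e-12 on max − min;
  robust-scale fallback when IQR ≤ 1e-12.
* IQM requires a positive median pairwise distance (coincident clouds are an
  error); the trajectory scale must be positive (all points at the reference
  is an error).
* Recordings shorter than one segment yield an empty segment list, not an
  error; duty-cycle gaps in the metadata produce warnings, not errors.
* Cluster id numbering: descending cluster size, noise fixed at −1.
* HDF5 bundles are written to a temporary file and renamed, so a failed run
  leaves no partial bundle; CSV exports format floats with `%.12g` and
  round-trip to 1e-9.

## Known limitations

* The averaged distance matrix is kept dense; memory grows as n², which is
  comfortable up to ~10⁴ samples but not beyond.
* UMAP inter-cluster distances are not faithful to feature-space distances;
  once two categories separate completely, their silhouette on the averaged
  matrix saturates and its exact value carries placement noise rather than
  contrast magnitude. Comparisons of silhouette values are meaningful for
  overlapping-to-moderately-separated categories.
* The CNN adapter is an interface only; results with external embeddings
  depend entirely on the adapter supplied.
* `min_samples` and other HDBSCAN hyperparameters beyond the minimum
  cluster size are passed through, not studied.
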