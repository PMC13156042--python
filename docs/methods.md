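# Methods

## Scope and data model

The package operates downstream of motion correction and source
extraction. Its inputs are (i) a neurons × frames matrix of raw
fluorescence traces per session (arbitrary units, 30 frames/s by
default), (ii) per-neuron spatial footprints — non-negative weight
images on the miniscope field of view (600 × 600 px by default) — and
(iii) histology count tables. Traces and footprints for one session live
in a self-describing container directory (`traces.npy`, footprint
patches, `meta.json`), written and validated by `miniens.session`.

## Event detection

A calcium transient is modelled phenomenologically as a steep rise
followed by a slow exponential decay; detection asks only whether a
~100 ms window contains a rise too steep to be noise.

Pipeline per neuron: convolve the raw trace with a unit-area Gaussian
kernel (SDs 50 ms and 100 ms; truncated at ±4 SD, reflect padding so
edges produce no spurious derivatives), decimate by non-overlapping
block means of 3 samples (one point ≈ 100 ms at 30 fps), take first
differences, and threshold them at Q3 + 1.5·IQR of that neuron's own
difference distribution (per kernel). For normally distributed
differences this threshold sits at 0.6745 + 1.5 × 1.3490 ≈ 2.698 SD
above the mean. A decimated point is an event only when it clears the
threshold in *both* kernel pipelines. Design choices:

* **Block-mean decimation** (not keep-every-Nth): averaging after
  smoothing is alias-safe; a `subsample` mode exists for comparison.
* **Derivative after decimation** — the order matters for the noise
  scale of the differences; the implemented order is smoothing →
  decimation → differencing.
* **Per-neuron, per-kernel thresholds**, quartiles by linear
  interpolation between order statistics, so thresholds are exactly
  reproducible.
* **No merging of consecutive suprathreshold points by default** (each
  1 counts); a transient's rise spans about two 100-ms points, so for
  *comparison against ground-truth spike counts* the evaluation
  collapses runs of 1s to their onset (the `merge_consecutive` option).
  Detection scores in the test suite and acceptance script are
  cluster-level recall/precision at ±1 decimated-point tolerance.
* The detector is invariant to positive affine transforms of a trace
  (thresholds scale with the data), verified by property test.

**Quality control.** The upstream "peak-to-noise ratio" criterion has no
universal formula; here PNR = (max − median of the 100 ms-smoothed
trace) / robust noise SD, with noise = raw − smoothed and robust SD =
1.4826 × MAD. The noise-asymmetry statistic is (|Q3| − |Q1|)/|Q1| of the
noise residual. Neurons are flagged when PNR < 20 or asymmetry > 2.0;
both cutoffs are parameters (`QCParams`), since the criteria are
definitional choices rather than derived quantities.

**Rates and ratios.** Event rate = Σ events / n_points (per point) and
/ (n_points · dt) per second. `normalize_to_first` divides each matched
neuron's session rates by its first-session rate, excluding (and
counting) neurons silent in the first session. `activity_ratio` is
(r₁ − r₂)/(r₁ + r₂) in [−1, 1], undefined (NaN) when both are zero.

## Footprint matching

Alignment replaces manual landmark registration with
`skimage.registration.phase_cross_correlation` on the two sessions'
summed footprint images (subpixel, translation only — the upstream
registration is rigid). Patch offsets move by the rounded shift;
centroids by the exact shift. Matching thresholds: spatial correlation
≥ 0.8 (Pearson, computed over the union of the two nonzero supports to
avoid inflation from shared zero background) and centroid distance
≤ 5 px. Candidates come from a KD-tree radius query; conflicts resolve
greedily by descending correlation, ties by smaller distance, then
lower index — deterministic. Matching is validated to be one-to-one and
threshold-respecting on every result, and alignment+matching is
invariant to a global translation of both sessions.

Overlap index = n_matched / mean(n₁, n₂): 1 for identical sessions, 0
for disjoint ones, symmetric in session order.

## Allocation statistics

Top sets take the top q (default 0.10) of cells *active* (rate > 0) in
a session, size max(1, round(q·n_active)) with half-up rounding, rate
ties broken toward lower IDs by a stable sort. The universe U is all
cells detected across the sessions under analysis; separately recorded
sessions are first joined through footprint-matching identities
(unmatched cells remain distinct universe members, inactive in the
session they lack). The joint probability |top_a ∩ top_b| / U is
normalized by chance q_a·q_b; under independent rank assignment its
mean is 1 (Monte-Carlo verified). The four-way composition partitions a
target top set by membership in the prior-context and home-cage top
sets; in the balance ratio (n_prior − n_home)/(n_prior + n_home), cells
belonging to both earlier top sets count in both terms (a documented,
configurable reading).

## Permutation test

Subject level: top-q sets in sessions A, HC and B; cells in all three
top sets are excluded from numerators and denominators
(`exclude_triple`, default on); observed overlap = |top_x ∩ top_b| /
|top_b| after exclusion. The null permutes which cell carries which
B-session rate (uniformly, seeded; default 1,000 shuffles) and
recomputes the overlap with the same exclusion. p = #{null ≥
real}/n_shuffles — deliberately uncorrected, so p = 0 is attainable; a
(k+1)/(n+1) correction is available but off by default. A two-session
form (`rates_hc=None`) computes only the A↔B comparison. Group level:
the across-subject mean observed overlap is compared with the
distribution of across-subject means of shuffle s (shuffles paired
across subjects); this uses exactly the aggregated real and shuffled
distributions, and a pooled-null variant is provided behind
`method="pooled"` since the aggregation scheme is a genuine design
choice.

Calibration conditions: type-I error is estimated on cohorts of one
subject with U = 1,000 cells of independent uniform rates (a realistic
order for cells detected in a concatenated recording), 200 shuffles per
subject, 1,000 replicates — the rejection rate at α = 0.05 must stay
within [0.03, 0.07]. Discreteness of the overlap grid makes the test
slightly conservative at small U; U = 1,000 keeps the grid fine.

## Histology statistics

Chance colocalization = (c-Fos/DAPI)·(marker/DAPI); the enrichment
ratio divides the observed double-positive fraction by it, is invariant
to a common scaling of all counts, and averages the designed enrichment
in simulation (the ratio of binomial proportions carries a small
positive Jensen bias, ~2–4% at the default table sizes — visible in the
calibration values, inside the stated bands). When several slices per
subject are supplied, counts are averaged across slices before the
ratio. Region-pair Pearson correlations use `scipy.stats.pearsonr`
(two-sided p); significance is uncorrected at α = 0.05, matching the
presentation this analysis feeds, with the α parameter exposed.
Gained/lost classification is antisymmetric under group swap by
construction; degenerate (zero-variance) regions are reported and
skipped.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not raw video:

* **Spikes**: homogeneous Poisson per neuron; default 0.1 Hz (sparse
  hippocampal-like firing). A rate range gives each cell a persistent
  base rate reused across sessions, creating the stable activity ranks
  that allocation analyses look for.
* **Transients**: amplitude · (1 − e^(−t/τ_rise)) e^(−t/τ_decay) with
  τ_rise = 50 ms, τ_decay = 500 ms (GCaMP6f-like fast rise / slow
  decay), additive i.i.d. Gaussian noise (SD 1), optional slow
  sinusoidal baseline drift (period ≥ 60 s, off by default). Default
  amplitude is 30 noise SD so that simulated cells clear the PNR ≥ 20
  inclusion applied to accepted extracted neurons; detector-stress
  tests set amplitude/noise explicitly (e.g. 10).
* **Footprints**: truncated (4 SD) 2-D Gaussians, SD 2.5 px, centers
  rejection-sampled with pairwise separation ≥ 15 px (retry cap 10,000
  per cell).
* **Session pairs**: a pool of n cells per session, round(ρ·n) shared;
  session-2 footprints of shared cells are rigidly shifted (default
  (3, 0) px) and jittered per cell, uniform in [−jitter, +jitter] per
  axis (bounded, so matching difficulty is a single knob; shape is
  preserved). Cell order is shuffled per session; the identity map and
  spike times are returned as ground truth. The realized shared count
  is exact by construction.
* **Count tables**: binomial c-Fos and marker counts out of n DAPI
  cells; double positives binomial at enrichment · p_cfos · p_marker,
  clipped to min(cfos, marker); infeasible joint probabilities are
  rejected.

What the generator does *not* emulate: motion artifacts,
photobleaching, extraction cross-talk, non-Gaussian or correlated
noise, footprint shape change across days. Passing tests therefore
demonstrate correctness of the statistics under the stated model, not
robustness to every failure mode of real recordings.

## Numerical and reproducibility notes

* All randomness flows through `numpy.random.Generator` seeds; every
  generator and test statistic is bit-reproducible under a fixed seed,
  and the pipeline writes a manifest with SHA-256 digests of all
  outputs (verified byte-identical across runs).
* Degenerate inputs have defined behaviour: constant derivative series
  → threshold 0; all-zero footprints, empty rasters, zero universes →
  typed errors; both-zero ratios → NaN plus report.
* Problem sizes in the test-suite calibrations (e.g. 200-neuron
  recovery runs, 500-replicate Monte-Carlo, 1,000 × 200-shuffle type-I
  simulation) were chosen to keep Monte-Carlo error well inside the
  asserted bands while the full suite runs in minutes.
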