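# Methods

This note documents the models, estimators, and numerical choices behind
spikekit, in the order a pipeline uses them.

## Data model

Spike times are stored as 0-based integer sample frames; seconds are a
derived view. Exact integer frames make matching deterministic and
format-independent. Frame ranges are half-open `[start, stop)`; channel
subsets preserve request order. A duplicate spike frame within a unit is a
validation error rather than being silently deduplicated — downstream
matching depends on strict ordering — while unsorted input files are
sorted on read with a warning. Zero-spike units survive the NPZ container
but not the row-per-spike CSV, which warns when dropping them.

Every object built from a file, a generator, or a registered transform
carries a provenance record (JSON): the source descriptor (path and
format, or generator name and full parameter set including the seed) plus
the ordered list of applied operations with their parameters. `restore`
re-reads or re-generates the source and replays the operations, so any
recording or sorting in a pipeline can be reconstructed exactly.

## Preprocessing

Trace transforms are lazy views: building a chain reads nothing, and a
trace request propagates up the chain. Filters are zero-phase
forward–backward Butterworth (band-pass, default order 3 before the
forward–backward doubling) or IIR notch designs; zero phase matters
because phase distortion would shift spike times and corrupt matching.
Chunked reads include an overlap margin (default 1024 frames) on each
side before filtering and trim it afterwards, so lazy chunk reads agree
with an eager full-recording filter to well below 1e-6 µV away from the
recording edges. Common referencing subtracts the per-frame median (or
mean) across *all* channels, regardless of which subset is requested.
Removing every channel is an error, not an empty recording.

## Waveforms, templates, and features

Waveforms are cut in a `ms_before`/`ms_after` window (defaults 1 ms / 2 ms;
at 30 kHz, 90 samples). Spikes whose window crosses a recording edge are
skipped and counted; units with more than `max_spikes_per_unit` (default
500) spikes are subsampled without replacement with a seed. Templates are
per-unit means; the best channel maximizes template peak-to-peak. The
waveform trough is the extremum of larger absolute value (ties toward
negative); positive-going spikes are inverted before feature measurement.
Peak-to-valley is trough-to-subsequent-peak time; FWHM is the width at
half the trough depth with linear interpolation between samples. Spike
amplitudes read the trace extremum within ±0.1 ms of the spike frame on
the unit's best channel, with truncated windows at recording edges so
every spike gets a value. Noise sigma per channel is the median absolute
deviation over seeded random chunks divided by 0.6745 (the Gaussian
consistency constant), robust to spikes riding on the noise.

PCA is fit per channel on spikes pooled across units (seeded subsample
above `max_spikes_for_fit`), default 3 components. Pooling is required by
the cross-unit separation metrics, which compare units in one basis; a
per-unit basis would make Mahalanobis distances between clusters
meaningless.

## Agreement and matching

The agreement score between two spike trains is

```
score = n_matches / (n1 + n2 − n_matches)
```

— matched spikes over the size of the union. Two spikes match when they
fall within an inclusive window |Δ| ≤ δ, with δ = round(delta_ms · fs /
1000) frames and delta_ms defaulting to 0.4 ms. "Matched spikes" is made
precise as a maximum one-to-one pairing: a greedy two-pointer sweep over
the sorted trains (pair when within the window, otherwise advance the
earlier spike) attains the bipartite optimum for this interval structure,
which the test suite verifies against a Hopcroft–Karp oracle on random
trains. Two empty trains score 0, not 1: an empty unit carries no
evidence of agreement. The sweep is numba-compiled when numba is present,
with an identical pure-Python fallback.

Unit assignment between two sortings maximizes total agreement with the
Hungarian algorithm; pairs below `min_score` (default 0.5) or at exactly 0
are discarded *after* optimization. The best-match variant instead
returns every partner above threshold per unit, best first, without
injectivity — useful for dissecting splits and merges.

## Ground-truth evaluation

Against ground truth, each matched pair is labeled per spike: tp =
matched spikes, fn = unmatched ground-truth spikes, fp = unmatched tested
spikes, so tp + fn is the ground-truth count and tp + fp the tested
count. The five performance measures are accuracy tp/(tp+fn+fp), recall
tp/(tp+fn), precision tp/(tp+fp), miss rate fn/(tp+fn), and false
discovery rate fp/(tp+fp). Unmatched ground-truth units get recall 0.

Tested units are classified by agreement score with rules applied in
order: *overmerged* (score above 0.2 with two or more ground-truth
units), *well_detected* (assigned partner with score above 0.8),
*redundant* (above 0.2 with exactly one ground-truth unit but not its
assigned partner), *false_positive* (unassigned, or assigned below 0.2),
and *weak_match* for assigned partners scoring between the thresholds.
Checking overmerge first resolves the overlap the rules otherwise leave
open; both thresholds (0.8, 0.2) are parameters.

## Multi-sorter agreement and consensus

All sorter pairs are compared with the Hungarian method; matched pairs at
or above `min_match_score` (default 0.5) become edges of a graph over
(sorter, unit) nodes, weighted by agreement. The agreement count k of a
unit is 1 plus the number of distinct *other* sorters it has a direct
edge to — deliberately not connected-component membership, so transitive
chains (A matches B, B matches C, A does not match C) cannot inflate k.
Two k tallies are reported, because "units on which k sorters agree" is
ambiguous: a group-level table counting each connected agreement group
once (at the maximum k of its members) and a per-sorter table counting
each sorter's own units.

Consensus construction emits one unit per connected group supported by at
least `min_k` sorters (default 2): the union of the spike trains of the
group's two closest matching units (its highest-weight edge), with spikes
matching within the window counted once, keeping the earlier frame.
Consensus curation instead filters each sorter's own output, retaining
units with k ≥ min_k; the exclusion log records the k of every removed
unit. Both modes exist because both are sensible workflows; neither
modifies any retained spike train.

## Quality metrics

All metrics return NaN, never an exception, when undefined for a unit;
curation treats NaN as failing any threshold (overridable). Every
parameter below is surfaced in the metric table's parameter block.

* **firing_rate** — spike count / duration (Hz).
* **presence_ratio** — fraction of 100 equal time bins containing a spike.
* **snr** — template peak magnitude on the best channel over that
  channel's MAD noise sigma.
* **isi_violation_ratio** — with N spikes over T seconds and v intervals
  shorter than `isi_threshold_ms` (default 1.5 ms),
  `(v / (2·N·(t_r − t_min))) / (N/T)`: the inferred contaminant rate over
  the unit's own rate. A clean refractory unit gives 0. Note a property of
  this estimator: a *homogeneous Poisson* train evaluates to about 0.5,
  not 1, since its v ≈ N·λ·t_r while the denominator assumes each
  contaminant can land in either half-window around a true spike. The
  estimator is kept in this standard form; its value on uncontaminated
  and contaminated units, and its monotonicity in contamination, are what
  the tests pin down.
* **amplitude_cutoff** — histogram of amplitude magnitudes (500 bins,
  Gaussian-smoothed with sigma 3 bins); locate the peak, find the first
  bin past the peak whose height returns to that of the lowest-amplitude
  bin, and report the mass beyond it, capped at 0.5. Assumes a symmetric
  amplitude distribution truncated from below by detection misses; NaN
  below 50 spikes. Recovers a planted 1-sigma truncation (15.9% missing)
  to within a few percentage points, with a small positive bias inherent
  to the histogram-peak construction.
* **drift metrics** — per-spike depth is the center of mass of PC1 energy
  over channel y coordinates; the recording is cut into 60 s intervals
  (≥10 spikes each, default), and max drift is the range of interval
  median depths, cumulative drift the summed absolute successive
  differences. NaN below two valid intervals.
* **isolation_distance** — squared Mahalanobis distance (cluster mean and
  covariance) of the N-th closest non-member spike, N = cluster size; NaN
  when non-members are fewer than members or the covariance is singular.
* **l_ratio** — sum over non-members of the chi-squared upper tail of
  their squared Mahalanobis distance (df = feature dimension), divided by
  the cluster size; ≈0.5 when member and non-member clouds coincide.
* **d_prime** — project members vs all other spikes onto the Fisher/LDA
  axis; |μ1 − μ2| / sqrt((σ1² + σ2²)/2).
* **nn_hit_rate / nn_miss_rate** — mean fraction of member neighbors
  among each spike's 4 nearest neighbors (self excluded), averaged over
  member and non-member spikes respectively; fully interleaved equal
  clusters give ≈0.5, well-separated ones ≈1 and ≈0. Seeded subsampling
  above 10,000 spikes.
* **silhouette** — mean silhouette of the unit's spikes against the
  nearest other cluster.

## Synthetic benchmark generator

The generator defines the study conditions the suite runs under, at desk
scale rather than full recording scale.

Ground-truth units fire as independent Poisson processes with a dead
time: after each kept spike the next kept spike is one refractory period
plus an exponential waiting time later, so inter-spike intervals minus
the refractory period are *exactly* exponential (the Kolmogorov–Smirnov
property the tests check), and the realized rate is λ/(1 + λ·t_ref).
Defaults: 5 Hz, 2 ms refractory period, 30 kHz sampling.

Recordings place each unit on a distinct channel of a rectangular probe
(default 4×2, 25 µm pitch), so the planted trough depth at the home
channel equals the unit's amplitude (default 100 µV) and the planted SNR
is amplitude/noise sigma. The template is a parametric biphasic shape (a
sharp negative Gaussian trough with a broader positive rebound, trough
normalized to −1), its amplitude decaying as exp(−distance/30 µm) across
channels; additive Gaussian noise defaults to 10 µV standard deviation.
Spike waveforms superpose linearly. What this deliberately does not
emulate: biophysical waveform diversity, correlated or non-stationary
noise, electrode drift, bursting, or overlapping-spike ambiguity — so
passing tests demonstrate the correctness of the comparison and metric
machinery under controlled conditions, not sorter-grade robustness on
real data.

Corrupted pseudo-sorter outputs model the named failure modes: i.i.d.
spike deletion (`miss_prob`), Gaussian spike-time jitter rounded to
frames, uniform false-positive insertion, pure noise units, splits
(alternating spikes to two new units), and merges (concatenated pairs).
Jitter collisions are nudged +1 frame to preserve strict ordering. The
multi-sorter scenario gives each pseudo-sorter an independent 80%
detection of every true unit plus 10 private noise units, with a truth
table recording each emitted unit's origin and planted agreement count.
The consensus experiments use 6 pseudo-sorters, 40 true units at 5 Hz for
300 s, 10% misses, and 0.1 ms jitter — sizes chosen so the full suite
runs in well under half an hour on one CPU while leaving the statistical
margins wide.

## Determinism

Every stochastic step (generators, subsampling, noise estimation) takes
a seed and is a pure function of its inputs plus that seed. NPZ files
are written with fixed zip timestamps so identical inputs give identical
bytes. CLI runs write a JSON run log holding the complete parameter set;
`spikekit replay` re-executes it, and result tables are byte-identical.

## Known limitations

* The consensus builder follows the two-donor union rule; groups spanning
  many sorters still contribute exactly one two-donor consensus unit.
* The amplitude-cutoff estimator's symmetry assumption breaks on
  multi-modal amplitude distributions (the 0.5 cap is the guard).
* Agreement-graph k is a direct-neighbor count; a sorter that splits a
  unit in two can leave one half at k=1 even when the unit is real.
* CSV sorting files cannot represent zero-spike units.
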