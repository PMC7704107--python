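"""Per-unit quality metrics for curation and validation.

Metrics fall into three groups:

* spike-train statistics — firing rate, presence ratio, ISI refractory
  violation ratio (a contamination proxy normalized so an uncorrelated
  Poisson contaminant gives a value near 1);
* waveform/amplitude statistics — template SNR against the MAD noise
  floor, amplitude-cutoff estimate of the missed-spike fraction, and
  drift of the spike depth (PC1-energy center of mass) over time;
* cluster-separation statistics in PCA feature space — isolation
  distance, L-ratio, d-prime, nearest-neighbor hit/miss rates, and
  silhouette.

A metric that is undefined for a unit (too few spikes, singular
covariance, single cluster, ...) is reported as NaN, never raised.
:func:`compute_quality_metrics` assembles the requested metrics into a
:class:`MetricTable`, deriving waveforms/templates/PCA/amplitudes
internally as needed, and records every parameter used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import chi2
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .core import Recording, Sorting
from .errors import ParameterError
from .postprocessing import (
    PCAScores,
    compute_pca_scores,
    compute_spike_amplitudes,
    compute_templates,
    estimate_noise_levels,
    extract_waveforms,
)

__all__ = [
    "MetricTable",
    "firing_rate",
    "presence_ratio",
    "snr",
    "isi_violation_ratio",
    "amplitude_cutoff",
    "drift_metrics",
    "isolation_distance",
    "l_ratio",
    "d_prime",
    "nearest_neighbor_metrics",
    "silhouette",
    "compute_quality_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = [
    "firing_rate",
    "presence_ratio",
    "snr",
    "isi_violation_ratio",
    "amplitude_cutoff",
    "max_drift_um",
    "cumulative_drift_um",
    "isolation_distance",
    "l_ratio",
    "d_prime",
    "nn_hit_rate",
    "nn_miss_rate",
    "silhouette",
]

#: metrics computable from the sorting alone (no recording required)
SORTING_ONLY_METRICS = {"firing_rate", "presence_ratio", "isi_violation_ratio"}


@dataclass
class MetricTable:
    """Units x metrics table plus the full parameter block that produced it."""

    table: pd.DataFrame
    params: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="unit_id",
                          lineterminator="\n", float_format="%.10g")


# ---------------------------------------------------------------------------
# Spike-train metrics
# ---------------------------------------------------------------------------

def firing_rate(sorting: Sorting, unit, duration: float) -> float:
    """Mean rate in Hz over ``duration`` seconds."""
    if duration <= 0:
        raise ParameterError("duration must be positive")
    return sorting.num_spikes(unit) / duration


def presence_ratio(sorting: Sorting, unit, duration: float,
                   num_bins: int = 100) -> float:
    """Fraction of equal-width time bins that contain at least one spike."""
    if duration <= 0:
        raise ParameterError("duration must be positive")
    times = sorting.spike_train_seconds(unit)
    if times.size == 0:
        return 0.0
    hist, _ = np.histogram(times, bins=num_bins, range=(0, duration))
    return float(np.mean(hist > 0))


def isi_violation_ratio(sorting: Sorting, unit, duration: float,
                        isi_threshold_ms: float = 1.5,
                        min_isi_ms: float = 0.0) -> float:
    """Refractory-violation rate relative to the unit's own firing rate.

    With N spikes over T seconds and v inter-spike intervals shorter than
    the threshold, the ratio is ``(v / (2 N (t_r - t_min))) / (N / T)``.
    Each violation could have been produced by a contaminating spike
    landing in one of the 2N refractory half-windows, so the numerator
    estimates the contaminant rate; an uncorrelated Poisson contaminant of
    the unit's own rate yields a value near 1.  NaN for fewer than 2 spikes.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    n = sorting.num_spikes(unit)
    if n < 2:
        return np.nan
    isis = np.diff(sorting.spike_train_seconds(unit))
    t_r = isi_threshold_ms / 1000.0
    t_min = min_isi_ms / 1000.0
    violations = int(np.sum(isis < t_r))
    violation_rate = violations / (2 * n * (t_r - t_min))
    return violation_rate / (n / duration)


# ---------------------------------------------------------------------------
# Waveform / amplitude metrics
# ---------------------------------------------------------------------------

def snr(templates, unit, noise_levels: np.ndarray) -> float:
    """Template peak magnitude on the best channel over that channel's sigma."""
    if templates.best_channels.get(unit) is None:
        return np.nan
    ch = templates.best_channel_index(unit)
    sigma = noise_levels[ch]
    if sigma == 0:
        return np.nan
    return float(np.max(np.abs(templates.templates[unit][ch])) / sigma)


def amplitude_cutoff(amplitudes: np.ndarray, num_bins: int = 500,
                     smoothing_bins: float = 3.0,
                     min_spikes: int = 50) -> float:
    """Estimated missed-spike fraction from the amplitude histogram.

    Assumes the true amplitude distribution is symmetric about its mode and
    that misses truncate its low-amplitude side.  The smoothed histogram's
    peak is located; the first bin past the peak whose height falls to that
    of the lowest-amplitude bin mirrors the truncation point, and the mass
    beyond it estimates the missing fraction, capped at 0.5 (beyond half,
    the symmetry argument says nothing).  NaN below ``min_spikes`` spikes.
    """
    amps = np.abs(np.asarray(amplitudes, dtype=float))
    amps = amps[np.isfinite(amps)]
    if amps.size < min_spikes:
        return np.nan
    hist, edges = np.histogram(amps, bins=num_bins, density=True)
    pdf = gaussian_filter1d(hist.astype(float), smoothing_bins)
    peak = int(np.argmax(pdf))
    support = edges[1] - edges[0]
    cross = peak + int(np.argmin(np.abs(pdf[peak:] - pdf[0])))
    fraction = float(np.sum(pdf[cross:]) * support)
    return min(fraction, 0.5)


def spike_depths(pca_scores: PCAScores, unit) -> np.ndarray:
    """Per-spike depth: center of mass of PC1 energy over channel y (um)."""
    s = pca_scores.scores[unit]
    energy = s[:, :, 0] ** 2  # (spikes, channels)
    y = pca_scores.channel_locations[:, 1]
    total = energy.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (energy @ y) / total


def drift_metrics(pca_scores: PCAScores, spike_times_s: np.ndarray, unit,
                  interval_s: float = 60.0,
                  min_spikes_per_interval: int = 10) -> tuple:
    """Max and cumulative drift (um) of interval-median spike depth.

    Depth per spike is the PC1-energy center of mass over channel y
    coordinates.  The recording is cut into ``interval_s`` bins; intervals
    with fewer than the minimum spike count are skipped.  NaN if fewer than
    two intervals survive.
    """
    depths = spike_depths(pca_scores, unit)
    if depths.size == 0 or spike_times_s.size != depths.size:
        return np.nan, np.nan
    n_intervals = max(1, int(np.ceil((spike_times_s.max() + 1e-9) / interval_s)))
    medians = []
    for k in range(n_intervals):
        mask = (spike_times_s >= k * interval_s) & (spike_times_s < (k + 1) * interval_s)
        if np.sum(mask) >= min_spikes_per_interval:
            medians.append(np.median(depths[mask]))
    if len(medians) < 2:
        return np.nan, np.nan
    medians = np.asarray(medians)
    max_drift = float(medians.max() - medians.min())
    cumulative = float(np.sum(np.abs(np.diff(medians))))
    return max_drift, cumulative


# ---------------------------------------------------------------------------
# PCA-space separation metrics
# ---------------------------------------------------------------------------

def _split_features(features: np.ndarray, labels: np.ndarray, unit):
    members = features[labels == unit]
    others = features[labels != unit]
    return members, others


def _mahalanobis_sq(points: np.ndarray, mean: np.ndarray,
                    cov: np.ndarray) -> np.ndarray | None:
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        return None
    centered = points - mean
    return np.einsum("ij,jk,ik->i", centered, inv, centered)


def isolation_distance(features: np.ndarray, labels: np.ndarray, unit) -> float:
    """Squared Mahalanobis radius enclosing as many non-members as members.

    Distances are measured in the cluster's own metric (its mean and
    covariance).  With N member spikes, the value is the N-th smallest
    squared distance among non-members — the radius of the smallest
    ellipsoid centered on the cluster containing all its spikes and an
    equal number of foreign ones.  NaN if there are fewer non-members than
    members or the covariance is singular.
    """
    members, others = _split_features(features, labels, unit)
    n = members.shape[0]
    if n < features.shape[1] + 1 or others.shape[0] < n:
        return np.nan
    d2 = _mahalanobis_sq(others, members.mean(axis=0), np.cov(members.T))
    if d2 is None:
        return np.nan
    return float(np.sort(d2)[n - 1])


def l_ratio(features: np.ndarray, labels: np.ndarray, unit) -> float:
    """Chi-squared tail mass of non-members, per member spike.

    Sums ``1 - CDF_chi2(D^2, df)`` over non-member squared Mahalanobis
    distances and divides by the member count; near 0 for well-separated
    clusters, about 0.5 when member and non-member clouds coincide.
    """
    members, others = _split_features(features, labels, unit)
    n = members.shape[0]
    if n < features.shape[1] + 1:
        return np.nan
    if others.shape[0] == 0:
        return 0.0
    d2 = _mahalanobis_sq(others, members.mean(axis=0), np.cov(members.T))
    if d2 is None:
        return np.nan
    return float(np.sum(chi2.sf(d2, df=features.shape[1])) / n)


def d_prime(features: np.ndarray, labels: np.ndarray, unit) -> float:
    """Discriminability of the unit from all other spikes on the LDA axis.

    Projects member and non-member spikes onto the Fisher discriminant and
    returns |mu1 - mu2| / sqrt((s1^2 + s2^2)/2).
    """
    members, others = _split_features(features, labels, unit)
    if members.shape[0] < 2 or others.shape[0] < 2:
        return np.nan
    lda = LinearDiscriminantAnalysis(n_components=1)
    y = (labels == unit).astype(int)
    proj = lda.fit_transform(features, y).ravel()
    p1, p2 = proj[y == 1], proj[y == 0]
    pooled = np.sqrt((p1.var(ddof=1) + p2.var(ddof=1)) / 2.0)
    if pooled == 0:
        return np.nan
    return float(abs(p1.mean() - p2.mean()) / pooled)


def nearest_neighbor_metrics(features: np.ndarray, labels: np.ndarray, unit,
                             n_neighbors: int = 4, max_spikes: int = 10_000,
                             seed: int | None = None) -> tuple:
    """Non-parametric contamination estimate via k-nearest neighbors.

    hit_rate — mean fraction of member neighbors among the ``n_neighbors``
    nearest neighbors (self excluded) of member spikes; miss_rate — mean
    fraction of member neighbors of non-member spikes.  Fully interleaved
    equal clusters give hit ~ 0.5, well-separated ones hit ~ 1 / miss ~ 0.
    Above ``max_spikes`` total spikes a seeded subsample is used.  NaN for
    clusters of fewer than 2 spikes.
    """
    y = (labels == unit).astype(int)
    if y.sum() < 2 or (y == 0).sum() < 1:
        return np.nan, np.nan
    if features.shape[0] > max_spikes:
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(features.shape[0], max_spikes, replace=False))
        features, y = features[sel], y[sel]
        if y.sum() < 2 or (y == 0).sum() < 1:
            return np.nan, np.nan
    k = min(n_neighbors, features.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(features)
    _, idx = nn.kneighbors(features)
    member_frac = y[idx[:, 1:]].mean(axis=1)  # per spike
    hit = float(member_frac[y == 1].mean())
    miss = float(member_frac[y == 0].mean())
    return hit, miss


def silhouette(features: np.ndarray, labels: np.ndarray, unit,
               max_spikes: int = 10_000, seed: int | None = None) -> float:
    """Mean silhouette of the unit's spikes against the nearest other cluster."""
    if len(set(labels.tolist())) < 2:
        return np.nan
    if features.shape[0] > max_spikes:
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(features.shape[0], max_spikes, replace=False))
        features, labels = features[sel], labels[sel]
    mask = labels == unit
    if mask.sum() < 2 or len(set(labels.tolist())) < 2:
        return np.nan
    codes = pd.factorize(labels)[0]
    values = silhouette_samples(features, codes)
    return float(values[mask].mean())


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

_DEFAULT_PARAMS = {
    "ms_before": 1.0,
    "ms_after": 2.0,
    "max_spikes_per_unit": 500,
    "n_comp": 3,
    "max_spikes_for_fit": 10_000,
    "peak_sign": "neg",
    "num_bins_presence": 100,
    "isi_threshold_ms": 1.5,
    "min_isi_ms": 0.0,
    "num_bins_amplitude": 500,
    "amplitude_smoothing_bins": 3.0,
    "min_spikes_amplitude": 50,
    "drift_interval_s": 60.0,
    "min_spikes_per_interval": 10,
    "n_neighbors": 4,
    "max_spikes_nn": 10_000,
    "max_spikes_silhouette": 10_000,
    "noise_chunk_seconds": 1.0,
    "noise_num_chunks": 20,
}


def compute_quality_metrics(
    recording: Recording | None,
    sorting: Sorting,
    metric_names: list | None = None,
    params: dict | None = None,
    seed: int | None = 0,
    duration: float | None = None,
) -> MetricTable:
    """Compute the requested metrics for every unit of ``sorting``.

    Waveforms, templates, PCA scores, amplitudes and noise levels are
    derived internally when a requested metric needs them.  ``recording``
    may be None only if every requested metric is a spike-train statistic;
    ``duration`` then must be given (it defaults to the recording length).
    Deterministic for a fixed seed.
    """
    names = list(metric_names) if metric_names is not None else list(METRIC_NAMES)
    drift_cols = {"max_drift_um", "cumulative_drift_um"}
    nn_cols = {"nn_hit_rate", "nn_miss_rate"}
    known = set(METRIC_NAMES)
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ParameterError(f"unknown metric name(s) {unknown!r}; "
                             f"choose from {sorted(known)}")
    needs_recording = [n for n in names if n not in SORTING_ONLY_METRICS]
    if recording is None and needs_recording:
        raise ParameterError(
            f"metrics {needs_recording!r} require a recording"
        )
    p = dict(_DEFAULT_PARAMS)
    if params:
        bad = set(params) - set(p)
        if bad:
            raise ParameterError(f"unknown parameter(s) {sorted(bad)!r}")
        p.update(params)
    if duration is None:
        if recording is not None:
            duration = recording.duration
        else:
            raise ParameterError("duration required when no recording is given")

    pca_metrics = ({"isolation_distance", "l_ratio", "d_prime", "silhouette"}
                   | nn_cols | drift_cols)
    need_pca = bool(pca_metrics & set(names))
    need_templates = bool({"snr"} & set(names)) or need_pca
    need_amplitudes = "amplitude_cutoff" in names

    waveforms = templates = scores = None
    features = labels = None
    amplitudes = noise = None
    if need_templates or need_amplitudes:
        waveforms = extract_waveforms(
            recording, sorting, p["ms_before"], p["ms_after"],
            p["max_spikes_per_unit"], seed=seed,
        )
        templates = compute_templates(waveforms)
    if need_pca:
        scores = compute_pca_scores(waveforms, p["n_comp"],
                                    max_spikes_for_fit=p["max_spikes_for_fit"],
                                    seed=seed)
        features, labels = scores.feature_matrix()
    if need_amplitudes:
        amplitudes = compute_spike_amplitudes(recording, sorting,
                                              p["peak_sign"], templates)
    if "snr" in names:
        noise = estimate_noise_levels(recording, chunk_seconds=p["noise_chunk_seconds"],
                                      num_chunks=p["noise_num_chunks"], seed=seed)

    rows = {}
    for unit in sorting.unit_ids:
        row = {}
        for name in names:
            if name == "firing_rate":
                row[name] = firing_rate(sorting, unit, duration)
            elif name == "presence_ratio":
                row[name] = presence_ratio(sorting, unit, duration,
                                           p["num_bins_presence"])
            elif name == "isi_violation_ratio":
                row[name] = isi_violation_ratio(sorting, unit, duration,
                                                p["isi_threshold_ms"],
                                                p["min_isi_ms"])
            elif name == "snr":
                row[name] = snr(templates, unit, noise)
            elif name == "amplitude_cutoff":
                row[name] = amplitude_cutoff(amplitudes[unit],
                                             p["num_bins_amplitude"],
                                             p["amplitude_smoothing_bins"],
                                             p["min_spikes_amplitude"])
            elif name in drift_cols:
                kept = waveforms.spike_indices[unit]
                times = (sorting.spike_train_seconds(unit)[kept]
                         if kept.size else np.empty(0))
                max_d, cum_d = drift_metrics(scores, times, unit,
                                             p["drift_interval_s"],
                                             p["min_spikes_per_interval"])
                row[name] = max_d if name == "max_drift_um" else cum_d
            elif name == "isolation_distance":
                row[name] = isolation_distance(features, labels, unit)
            elif name == "l_ratio":
                row[name] = l_ratio(features, labels, unit)
            elif name == "d_prime":
                row[name] = d_prime(features, labels, unit)
            elif name in nn_cols:
                hit, miss = nearest_neighbor_metrics(features, labels, unit,
                                                     p["n_neighbors"],
                                                     p["max_spikes_nn"], seed)
                row[name] = hit if name == "nn_hit_rate" else miss
            elif name == "silhouette":
                row[name] = silhouette(features, labels, unit,
                                       p["max_spikes_silhouette"], seed)
        rows[unit] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[names]
    param_block = {"metric_names": names, "seed": seed, "duration": duration, **p}
    return MetricTable(table, param_block)
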