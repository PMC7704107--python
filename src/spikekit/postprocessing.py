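"""Waveforms, templates, PCA projections, amplitudes, and noise levels.

These are the intermediate products the quality metrics consume:

* :func:`extract_waveforms` cuts seeded, subsampled spike snippets;
* :func:`compute_templates` averages them into per-unit templates;
* :func:`compute_pca_scores` fits a per-channel PCA basis pooled across
  units and projects every retained spike;
* :func:`compute_template_features` measures peak-to-valley duration and
  full-width half maximum on the best channel;
* :func:`compute_spike_amplitudes` reads the trace extremum around each
  spike on the unit's best channel;
* :func:`estimate_noise_levels` gives a robust (MAD-based) per-channel
  noise sigma.

All durations are in milliseconds and all voltages in microvolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .core import Recording, Sorting
from .errors import ParameterError

__all__ = [
    "WaveformSet",
    "Templates",
    "PCAScores",
    "extract_waveforms",
    "compute_templates",
    "compute_pca_scores",
    "compute_template_features",
    "compute_spike_amplitudes",
    "estimate_noise_levels",
]

#: Gaussian consistency constant: MAD / 0.6745 estimates sigma
MAD_SCALE = 0.6745


@dataclass
class WaveformSet:
    """Per-unit spike snippets, (n_spikes, n_channels, n_samples) in uV."""

    waveforms: dict
    spike_indices: dict  # per unit: indices into the unit's spike train
    sampling_frequency: float
    ms_before: float
    ms_after: float
    channel_ids: list
    channel_locations: np.ndarray
    n_edge_skipped: dict = field(default_factory=dict)

    @property
    def nbefore(self) -> int:
        return int(round(self.ms_before * self.sampling_frequency / 1000.0))

    @property
    def nafter(self) -> int:
        return int(round(self.ms_after * self.sampling_frequency / 1000.0))

    @property
    def n_samples(self) -> int:
        return self.nbefore + self.nafter

    @property
    def unit_ids(self) -> list:
        return list(self.waveforms)


@dataclass
class Templates:
    """Per-unit mean waveform (n_channels, n_samples) and best channel."""

    templates: dict
    best_channels: dict  # unit -> channel id of max peak-to-peak, None if empty
    sampling_frequency: float
    channel_ids: list

    @property
    def unit_ids(self) -> list:
        return list(self.templates)

    def best_channel_index(self, unit) -> int:
        return self.channel_ids.index(self.best_channels[unit])


@dataclass
class PCAScores:
    """Per-spike, per-channel PCA projections with the fitted basis.

    ``scores[unit]`` has shape (n_spikes, n_channels, n_comp); the basis in
    ``components[channel_index]`` has orthonormal rows.
    """

    scores: dict
    components: dict  # channel index -> (n_comp, n_samples)
    mean: dict        # channel index -> (n_samples,)
    explained_variance: dict
    n_comp: int
    channel_ids: list
    channel_locations: np.ndarray

    @property
    def unit_ids(self) -> list:
        return list(self.scores)

    def feature_matrix(self):
        """Flattened (n_total_spikes, n_channels*n_comp) matrix with labels."""
        blocks, labels = [], []
        for unit, s in self.scores.items():
            blocks.append(s.reshape(s.shape[0], -1))
            labels.extend([unit] * s.shape[0])
        features = (np.concatenate(blocks, axis=0) if blocks
                    else np.empty((0, len(self.channel_ids) * self.n_comp)))
        return features, np.asarray(labels, dtype=object)


def extract_waveforms(
    recording: Recording,
    sorting: Sorting,
    ms_before: float = 1.0,
    ms_after: float = 2.0,
    max_spikes_per_unit: int = 500,
    seed: int | None = None,
) -> WaveformSet:
    """Cut spike-centered snippets from the recording.

    Spikes whose window crosses a recording edge are skipped and counted in
    ``n_edge_skipped``.  Units with more than ``max_spikes_per_unit`` spikes
    are subsampled without replacement with the given seed; the retained
    spike indices are kept in time order.
    """
    fs = recording.sampling_frequency
    nbefore = int(round(ms_before * fs / 1000.0))
    nafter = int(round(ms_after * fs / 1000.0))
    rng = np.random.default_rng(seed)
    waveforms, indices, skipped = {}, {}, {}

    # one bulk read keeps per-spike slicing cheap even for lazy chains
    traces = recording.get_traces()

    for unit in sorting.unit_ids:
        train = sorting.spike_train(unit)
        valid = np.flatnonzero(
            (train - nbefore >= 0) & (train + nafter <= recording.num_frames)
        )
        skipped[unit] = int(train.size - valid.size)
        if valid.size > max_spikes_per_unit:
            valid = np.sort(rng.choice(valid, size=max_spikes_per_unit, replace=False))
        if valid.size == 0:
            if train.size:
                warnings.warn(f"unit {unit!r}: all spikes at recording edges; "
                              "empty waveform array", stacklevel=2)
            waveforms[unit] = np.empty((0, recording.num_channels, nbefore + nafter))
            indices[unit] = valid
            continue
        wfs = np.stack([traces[:, f - nbefore:f + nafter] for f in train[valid]])
        waveforms[unit] = wfs
        indices[unit] = valid
    return WaveformSet(
        waveforms, indices, fs, ms_before, ms_after,
        recording.channel_ids, recording.channel_locations, skipped,
    )


def compute_templates(waveforms: WaveformSet) -> Templates:
    """Average waveforms per unit; best channel maximizes peak-to-peak."""
    templates, best = {}, {}
    for unit, wfs in waveforms.waveforms.items():
        if wfs.shape[0] == 0:
            warnings.warn(f"unit {unit!r}: no waveforms; template undefined",
                          stacklevel=2)
            templates[unit] = None
            best[unit] = None
            continue
        mean = wfs.mean(axis=0)
        templates[unit] = mean
        p2p = mean.max(axis=1) - mean.min(axis=1)
        best[unit] = waveforms.channel_ids[int(np.argmax(p2p))]
    return Templates(templates, best, waveforms.sampling_frequency,
                     list(waveforms.channel_ids))


def compute_pca_scores(
    waveforms: WaveformSet,
    n_comp: int = 3,
    mode: str = "by_channel",
    max_spikes_for_fit: int = 10_000,
    seed: int | None = None,
) -> PCAScores:
    """Fit per-channel PCA on spikes pooled across units; project all spikes.

    Pooling across units keeps the projections of different units in a
    common basis, which the cross-unit isolation metrics require.
    """
    if mode != "by_channel":
        raise ParameterError(f"unsupported PCA mode {mode!r}")
    all_wfs = [w for w in waveforms.waveforms.values() if w.shape[0]]
    if not all_wfs:
        raise ParameterError("no waveforms to fit PCA on")
    pooled = np.concatenate(all_wfs, axis=0)  # (spikes, channels, samples)
    if n_comp > pooled.shape[2]:
        raise ParameterError(
            f"n_comp={n_comp} exceeds {pooled.shape[2]} samples per waveform"
        )
    if pooled.shape[0] < n_comp:
        raise ParameterError("fewer pooled spikes than requested components")
    rng = np.random.default_rng(seed)
    if pooled.shape[0] > max_spikes_for_fit:
        sel = np.sort(rng.choice(pooled.shape[0], max_spikes_for_fit, replace=False))
        fit_data = pooled[sel]
    else:
        fit_data = pooled

    components, mean, explained = {}, {}, {}
    for c in range(pooled.shape[1]):
        pca = PCA(n_components=n_comp, svd_solver="full")
        pca.fit(fit_data[:, c, :])
        components[c] = pca.components_
        mean[c] = pca.mean_
        explained[c] = pca.explained_variance_

    scores = {}
    for unit, wfs in waveforms.waveforms.items():
        s = np.empty((wfs.shape[0], pooled.shape[1], n_comp))
        for c in range(pooled.shape[1]):
            s[:, c, :] = (wfs[:, c, :] - mean[c]) @ components[c].T
        scores[unit] = s
    return PCAScores(scores, components, mean, explained, n_comp,
                     list(waveforms.channel_ids), waveforms.channel_locations)


def _half_width_ms(template_ch: np.ndarray, trough_idx: int, fs: float) -> float:
    """FWHM of the trough at half its depth, linear interpolation, in ms."""
    half = template_ch[trough_idx] / 2.0  # trough is negative here
    n = template_ch.size

    def crossing(direction):
        i = trough_idx
        while 0 <= i + direction < n and template_ch[i + direction] <= half:
            i += direction
        j = i + direction
        if j < 0 or j >= n:
            return float(i)  # width truncated at template edge
        y0, y1 = template_ch[i], template_ch[j]
        frac = (half - y0) / (y1 - y0) if y1 != y0 else 0.0
        return i + direction * frac

    left = crossing(-1)
    right = crossing(+1)
    return (right - left) * 1000.0 / fs


def compute_template_features(templates: Templates) -> dict:
    """Per-unit waveform-shape features on the best channel.

    Returns ``{unit: {"peak_to_valley_ms", "fwhm_ms"}}``; flat or undefined
    templates get NaN features with a warning.  For positive-going spikes
    (extremum of larger magnitude above baseline) the template is inverted
    before applying the trough logic; ties break toward negative.
    """
    features = {}
    for unit in templates.unit_ids:
        template = templates.templates[unit]
        if template is None:
            features[unit] = {"peak_to_valley_ms": np.nan, "fwhm_ms": np.nan}
            continue
        ch = templates.best_channel_index(unit)
        w = np.asarray(template[ch], dtype=float)
        if np.ptp(w) == 0:
            warnings.warn(f"unit {unit!r}: flat template; features undefined",
                          stacklevel=2)
            features[unit] = {"peak_to_valley_ms": np.nan, "fwhm_ms": np.nan}
            continue
        if abs(w.max()) > abs(w.min()):
            w = -w
        trough = int(np.argmin(w))
        fs = templates.sampling_frequency
        if trough == w.size - 1:
            ptv = np.nan
        else:
            peak = trough + 1 + int(np.argmax(w[trough + 1:]))
            ptv = (peak - trough) * 1000.0 / fs
        features[unit] = {
            "peak_to_valley_ms": ptv,
            "fwhm_ms": _half_width_ms(w, trough, fs),
        }
    return features


def compute_spike_amplitudes(
    recording: Recording,
    sorting: Sorting,
    peak_sign: str = "neg",
    templates: Templates | None = None,
    search_ms: float = 0.1,
    **waveform_kwargs,
) -> dict:
    """Per-spike amplitude (uV) at the unit's best channel.

    The amplitude is the trace extremum within +/- ``search_ms`` of the
    spike frame, selected by ``peak_sign`` ('neg', 'pos', or 'both' for the
    extremum of larger magnitude).  Windows at recording edges are
    truncated, not skipped, so every spike gets an amplitude.
    """
    if peak_sign not in ("neg", "pos", "both"):
        raise ParameterError(f"peak_sign must be neg/pos/both, got {peak_sign!r}")
    if templates is None:
        wfs = extract_waveforms(recording, sorting, **waveform_kwargs)
        templates = compute_templates(wfs)
    fs = recording.sampling_frequency
    half = int(round(search_ms * fs / 1000.0))
    traces = recording.get_traces()
    amplitudes = {}
    for unit in sorting.unit_ids:
        if templates.best_channels.get(unit) is None:
            amplitudes[unit] = np.full(sorting.num_spikes(unit), np.nan)
            continue
        ch = templates.best_channel_index(unit)
        amps = np.empty(sorting.num_spikes(unit))
        for i, f in enumerate(sorting.spike_train(unit)):
            lo = max(0, f - half)
            hi = min(recording.num_frames, f + half + 1)
            seg = traces[ch, lo:hi]
            if peak_sign == "neg":
                amps[i] = seg.min()
            elif peak_sign == "pos":
                amps[i] = seg.max()
            else:
                amps[i] = seg.min() if abs(seg.min()) >= abs(seg.max()) else seg.max()
        amplitudes[unit] = amps
    return amplitudes


def estimate_noise_levels(
    recording: Recording,
    method: str = "mad",
    chunk_seconds: float = 1.0,
    num_chunks: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """Per-channel noise sigma in uV from seeded random chunks.

    Uses the median absolute deviation scaled by 1/0.6745, which is robust
    to the spikes riding on the noise floor.
    """
    if method != "mad":
        raise ParameterError(f"unknown noise method {method!r}")
    chunk_frames = int(round(chunk_seconds * recording.sampling_frequency))
    chunk_frames = min(chunk_frames, recording.num_frames)
    rng = np.random.default_rng(seed)
    max_start = recording.num_frames - chunk_frames
    if max_start <= 0 or num_chunks * chunk_frames >= recording.num_frames:
        chunks = [recording.get_traces()]
    else:
        starts = np.sort(rng.integers(0, max_start + 1, size=num_chunks))
        chunks = [recording.get_traces(start_frame=s, end_frame=s + chunk_frames)
                  for s in starts]
    data = np.concatenate(chunks, axis=1)
    med = np.median(data, axis=1, keepdims=True)
    return np.median(np.abs(data - med), axis=1) / MAD_SCALE
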