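"""Seeded generators for ground truth, recordings, and corrupted sortings.

The generators emulate, at desk scale, the benchmark conditions the
comparison and metric machinery is meant for:

* :func:`generate_gt_sorting` — independent Poisson units with a
  refractory period enforced by thinning (after a kept spike, the next
  kept spike is the first event at least one refractory period later, so
  ISIs minus the refractory period remain exactly exponential);
* :func:`synthesize_recording` — spatially decaying biphasic templates on
  a rectangular probe plus additive Gaussian noise (default sigma 10 uV);
* :func:`corrupt_sorting` — controlled sorter failure modes: spike-time
  jitter, missed spikes, inserted false-positive spikes, pure noise
  units, unit splits, and unit merges;
* :func:`generate_comparison_scenario` — a planted multi-sorter ensemble
  (each pseudo-sorter detects a random subset of the true units and adds
  private noise units) with a truth table for every emitted unit.

Every generator is a pure function of its spec, seed included.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import NumpyRecording, Sorting
from .errors import ParameterError
from .provenance import (
    chained_record,
    register_generator,
    register_operation,
    synthetic_source_record,
)

__all__ = [
    "GroundTruthSpec",
    "RecordingSpec",
    "CorruptionSpec",
    "generate_gt_sorting",
    "synthesize_recording",
    "corrupt_sorting",
    "generate_comparison_scenario",
]


@dataclass
class GroundTruthSpec:
    """Independent Poisson units with a refractory period."""

    n_units: int = 10
    firing_rate_hz: float | tuple = 5.0   # scalar or (low, high) per-unit range
    duration_s: float = 300.0
    refractory_ms: float = 2.0
    sampling_frequency: float = 30000.0
    seed: int = 0

    def __post_init__(self):
        rates = np.atleast_1d(np.asarray(self.firing_rate_hz, dtype=float))
        if np.any(rates <= 0):
            raise ParameterError("firing rates must be positive")
        if self.refractory_ms < 0:
            raise ParameterError("refractory period must be >= 0")


@dataclass
class RecordingSpec:
    """Probe layout, template model, and noise for trace synthesis."""

    probe_rows: int = 4
    probe_cols: int = 2
    pitch_um: float = 25.0
    amplitude_uv: float | tuple = 100.0   # trough depth at the home channel
    decay_um: float = 30.0                # exponential spatial decay constant
    noise_sd_uv: float = 10.0
    waveform_ms: float = 2.0
    seed: int = 0

    def __post_init__(self):
        amps = np.atleast_1d(np.asarray(self.amplitude_uv, dtype=float))
        if np.any(amps <= 0):
            raise ParameterError("template amplitudes must be positive")
        if self.decay_um <= 0:
            raise ParameterError("spatial decay constant must be positive")
        if self.noise_sd_uv < 0:
            raise ParameterError("noise sigma must be >= 0")


@dataclass
class CorruptionSpec:
    """Controlled sorter failure modes applied to a ground-truth sorting."""

    jitter_sd_ms: float = 0.0
    miss_prob: float = 0.0
    fp_rate_hz: float = 0.0          # uniform spikes inserted per unit
    n_noise_units: int = 0
    noise_unit_rate_hz: float = 5.0
    split_units: list = field(default_factory=list)
    merge_unit_pairs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.miss_prob < 1):
            raise ParameterError("miss_prob must be in [0, 1)")
        if self.jitter_sd_ms < 0 or self.fp_rate_hz < 0:
            raise ParameterError("jitter and fp rate must be >= 0")


def _strictify(frames: np.ndarray) -> np.ndarray:
    """Sort and nudge collisions by +1 frame to keep strict ordering."""
    frames = np.sort(np.asarray(frames, dtype=np.int64))
    for i in range(1, frames.size):
        if frames[i] <= frames[i - 1]:
            frames[i] = frames[i - 1] + 1
    return frames


def _poisson_train(rng, rate_hz, duration_s, refractory_s) -> np.ndarray:
    """Poisson spike times thinned to a dead time, in seconds."""
    times = []
    t = rng.exponential(1.0 / rate_hz)
    while t < duration_s:
        times.append(t)
        # memorylessness: next kept event is refractory + Exp(rate) later
        t += refractory_s + rng.exponential(1.0 / rate_hz)
    return np.asarray(times)


@register_generator("generate_gt_sorting")
def generate_gt_sorting(spec: GroundTruthSpec | None = None, **kwargs) -> Sorting:
    """Seeded ground-truth sorting of independent Poisson units."""
    if spec is None:
        spec = GroundTruthSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    rates = np.asarray(spec.firing_rate_hz, dtype=float)
    if rates.ndim == 0:
        rates = np.full(spec.n_units, float(rates))
    elif rates.size == 2 and spec.n_units != 2:
        rates = rng.uniform(rates[0], rates[1], size=spec.n_units)
    elif rates.size != spec.n_units:
        raise ParameterError("firing_rate_hz must be scalar, (low, high), or per-unit")
    fs = spec.sampling_frequency
    trains = {}
    for u in range(spec.n_units):
        times = _poisson_train(rng, rates[u], spec.duration_s,
                               spec.refractory_ms / 1000.0)
        trains[u] = _strictify(np.round(times * fs).astype(np.int64))
    params = asdict(spec)
    params["firing_rate_hz"] = (list(np.atleast_1d(spec.firing_rate_hz))
                                if np.ndim(spec.firing_rate_hz) else
                                float(spec.firing_rate_hz))
    return Sorting(trains, fs,
                   provenance=synthetic_source_record(
                       "Sorting", "generate_gt_sorting", params))


def _biphasic_waveform(n_samples: int) -> np.ndarray:
    """Canonical biphasic spike shape, trough normalized to -1.

    A sharp negative Gaussian trough followed by a broader positive
    rebound, the trough centered in the window.
    """
    t = np.arange(n_samples) - n_samples // 2
    sigma_trough = max(1.0, n_samples / 16.0)
    sigma_peak = max(1.5, n_samples / 8.0)
    w = (-np.exp(-0.5 * (t / sigma_trough) ** 2)
         + 0.45 * np.exp(-0.5 * ((t - 2.2 * sigma_trough) / sigma_peak) ** 2))
    return w / abs(w.min())


@register_generator("synthesize_recording")
def synthesize_recording(gt: Sorting | None = None,
                         spec: RecordingSpec | None = None,
                         gt_provenance: dict | None = None,
                         **kwargs) -> NumpyRecording:
    """Template-plus-noise traces for a ground-truth sorting.

    Each unit is placed on a distinct probe channel (its "home" channel),
    so the planted trough depth at that channel equals the unit's
    amplitude and the planted SNR is amplitude / noise sigma.  Template
    amplitude decays as exp(-distance/decay) across channels.  Ground
    truth (locations, home channels, templates) is retrievable from
    ``recording.ground_truth``.
    """
    if gt is None:
        from .provenance import restore
        gt = restore(gt_provenance)
    if isinstance(spec, dict):
        spec = RecordingSpec(**spec)
    elif spec is None:
        spec = RecordingSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    fs = gt.sampling_frequency
    n_channels = spec.probe_rows * spec.probe_cols
    cols, rows = np.meshgrid(np.arange(spec.probe_cols), np.arange(spec.probe_rows))
    locations = np.column_stack([cols.ravel() * spec.pitch_um,
                                 rows.ravel() * spec.pitch_um])

    units = gt.unit_ids
    amps = np.atleast_1d(np.asarray(spec.amplitude_uv, dtype=float))
    if amps.size == 1:
        amps = np.full(len(units), amps[0])
    elif amps.size == 2 and len(units) != 2:
        amps = rng.uniform(amps[0], amps[1], size=len(units))
    elif amps.size != len(units):
        raise ParameterError("amplitude_uv must be scalar, (low, high), or per-unit")
    home = rng.choice(n_channels, size=len(units),
                      replace=len(units) > n_channels)

    n_wf = int(round(spec.waveform_ms * fs / 1000.0))
    shape = _biphasic_waveform(n_wf)
    trough_offset = n_wf // 2
    last = max((int(gt.spike_train(u)[-1]) if gt.num_spikes(u) else 0)
               for u in units) if units else 0
    # round the length up to whole seconds past the last waveform window
    num_frames = int(np.ceil((last + n_wf + 1) / fs) * fs)

    if spec.noise_sd_uv > 0:
        traces = rng.normal(0.0, spec.noise_sd_uv,
                            size=(n_channels, num_frames))
    else:
        traces = np.zeros((n_channels, num_frames))

    templates = {}
    for ui, unit in enumerate(units):
        dist = np.linalg.norm(locations - locations[home[ui]], axis=1)
        gains = amps[ui] * np.exp(-dist / spec.decay_um)
        template = gains[:, None] * shape[None, :]
        templates[unit] = template
        for f in gt.spike_train(unit):
            start = f - trough_offset
            end = start + n_wf
            lo, hi = max(0, start), min(num_frames, end)
            traces[:, lo:hi] += template[:, lo - start:n_wf - (end - hi)]

    params = asdict(spec)
    provenance = synthetic_source_record("Recording", "synthesize_recording", {})
    provenance["source"]["params"] = {
        "gt_provenance": gt.provenance or None,
        "spec": params,
    }
    rec = NumpyRecording(traces, fs, channel_locations=locations,
                         provenance=provenance)
    rec.ground_truth = {
        "unit_locations": {u: locations[home[i]] for i, u in enumerate(units)},
        "home_channels": {u: int(home[i]) for i, u in enumerate(units)},
        "amplitudes_uv": {u: float(amps[i]) for i, u in enumerate(units)},
        "templates": templates,
        "noise_sd_uv": spec.noise_sd_uv,
    }
    return rec


@register_operation("corrupt_sorting")
def corrupt_sorting(gt: Sorting, spec: CorruptionSpec | None = None,
                    **kwargs) -> Sorting:
    """Apply controlled sorter failure modes to a ground-truth sorting.

    Order of operations per unit: miss deletion, Gaussian jitter (rounded
    to frames), false-positive insertion; then splits (alternating spikes
    to two new units), merges (concatenated pairs), and appended noise
    units.  Output unit ids: surviving units keep their ids; split halves
    become ``"{u}_split0/1"``, merges ``"{u}+{v}"``, noise units
    ``"noise{i}"``.
    """
    if isinstance(spec, dict):
        spec = CorruptionSpec(**spec)
    elif spec is None:
        spec = CorruptionSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    fs = gt.sampling_frequency
    duration_frames = int(max(
        [gt.spike_train(u)[-1] for u in gt.unit_ids if gt.num_spikes(u)] or [0]
    )) + 1
    jitter_frames = spec.jitter_sd_ms * fs / 1000.0

    corrupted = {}
    for unit in gt.unit_ids:
        frames = gt.spike_train(unit).astype(np.float64)
        if spec.miss_prob > 0 and frames.size:
            frames = frames[rng.random(frames.size) >= spec.miss_prob]
        if jitter_frames > 0 and frames.size:
            frames = frames + np.round(rng.normal(0, jitter_frames, frames.size))
            frames = frames[frames >= 0]
        if spec.fp_rate_hz > 0:
            n_fp = rng.poisson(spec.fp_rate_hz * duration_frames / fs)
            frames = np.concatenate([
                frames, rng.integers(0, duration_frames, size=n_fp)])
        corrupted[unit] = _strictify(frames)

    for unit in spec.split_units:
        frames = corrupted.pop(unit)
        corrupted[f"{unit}_split0"] = frames[0::2]
        corrupted[f"{unit}_split1"] = frames[1::2]
    for u, v in spec.merge_unit_pairs:
        fu, fv = corrupted.pop(u), corrupted.pop(v)
        corrupted[f"{u}+{v}"] = _strictify(np.concatenate([fu, fv]))
    for i in range(spec.n_noise_units):
        n = rng.poisson(spec.noise_unit_rate_hz * duration_frames / fs)
        corrupted[f"noise{i}"] = _strictify(
            rng.integers(0, duration_frames, size=max(n, 1)))

    params = asdict(spec)
    return Sorting(corrupted, fs,
                   provenance=chained_record(gt.provenance, "corrupt_sorting",
                                             params))


def generate_comparison_scenario(
    n_sorters: int,
    gt_spec: GroundTruthSpec,
    corruption: CorruptionSpec | list,
    detection_prob: float = 0.8,
    seed: int = 0,
):
    """Planted multi-sorter ensemble with a per-unit truth table.

    Each pseudo-sorter detects every ground-truth unit independently with
    ``detection_prob``, corrupts the detected trains, and appends private
    noise units.  Returns ``(gt, sortings, labels, truth_table)`` where the
    table has one row per emitted unit: sorter label, unit id, whether it
    derives from a true unit, the source ground-truth unit (or None), and
    its planted agreement count k (the number of sorters that detected
    that ground-truth unit; 1 for noise units).
    """
    if not (0 < detection_prob <= 1):
        raise ParameterError("detection_prob must be in (0, 1]")
    gt = generate_gt_sorting(gt_spec)
    specs = (list(corruption) if isinstance(corruption, (list, tuple))
             else [corruption] * n_sorters)
    if len(specs) != n_sorters:
        raise ParameterError("need one corruption spec per sorter")
    rng = np.random.default_rng(seed)
    detected = rng.random((n_sorters, gt.num_units)) < detection_prob
    planted_k = detected.sum(axis=0)

    sortings, labels, rows = [], [], []
    for s in range(n_sorters):
        label = f"sorter{s}"
        keep = [u for i, u in enumerate(gt.unit_ids) if detected[s, i]]
        sub = gt.select_units(keep, provenance=chained_record(
            gt.provenance, "exclude_units",
            {"unit_ids": [u for u in gt.unit_ids if u not in keep]}))
        spec = specs[s]
        spec_s = CorruptionSpec(**{**asdict(spec),
                                   "seed": int(spec.seed + 1000 * s + 1)})
        sorting = corrupt_sorting(sub, spec_s)
        sortings.append(sorting)
        labels.append(label)
        gt_index = {u: i for i, u in enumerate(gt.unit_ids)}
        for unit in sorting.unit_ids:
            is_noise = isinstance(unit, str) and unit.startswith("noise")
            source = None if is_noise else unit
            rows.append({
                "sorter": label,
                "unit_id": unit,
                "is_true": not is_noise,
                "gt_unit": source,
                "planted_k": 1 if is_noise else int(planted_k[gt_index[unit]]),
            })
    truth_table = pd.DataFrame(rows)
    return gt, sortings, labels, truth_table
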