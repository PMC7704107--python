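import numpy as np
import pytest

from spikekit import NumpyRecording, Sorting
from spikekit import synthetic as syn


@pytest.fixture
def small_sorting():
    return Sorting(
        {1: [100, 200, 300], 2: [150, 400], 3: []},
        sampling_frequency=30000.0,
    )


@pytest.fixture
def gt_sorting():
    spec = syn.GroundTruthSpec(n_units=4, firing_rate_hz=5.0, duration_s=30.0,
                               refractory_ms=2.0, seed=11)
    return syn.generate_gt_sorting(spec)


@pytest.fixture
def gt_recording(gt_sorting):
    spec = syn.RecordingSpec(noise_sd_uv=10.0, amplitude_uv=100.0, seed=11)
    return syn.synthesize_recording(gt_sorting, spec)


@pytest.fixture
def noise_recording():
    rng = np.random.default_rng(5)
    traces = rng.normal(0, 10.0, size=(4, 30000))
    return NumpyRecording(traces, 30000.0)


def random_sorting(rng, n_units=3, min_spikes=0, max_spikes=20,
                   max_frame=100_000, fs=30000.0):
    trains = {}
    for u in range(n_units):
        n = rng.integers(min_spikes, max_spikes + 1)
        frames = np.unique(rng.integers(0, max_frame, size=n))
        while frames.size < min_spikes:
            frames = np.unique(np.concatenate(
                [frames, rng.integers(0, max_frame, size=min_spikes)]))
        trains[u] = frames
    return Sorting(trains, fs)
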