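"""Lazy, chainable trace transforms.

Each function wraps a Recording in a :class:`ProcessedRecording` that
computes transformed traces only when ``get_traces`` is called, so a chain
of stages costs nothing to build.  Filters read an overlap margin around
the requested range from the parent so that chunked reads match an eager
full-recording filter away from recording edges.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal

from .core import Recording
from .errors import ParameterError
from .provenance import chained_record, register_operation

__all__ = [
    "ProcessedRecording",
    "bandpass_filter",
    "notch_filter",
    "common_reference",
    "remove_channels",
]

#: extra frames read on each side of a filtered chunk to suppress edge
#: transients of the forward-backward IIR pass
DEFAULT_MARGIN_FRAMES = 1024


class ProcessedRecording(Recording):
    """A Recording view applying one lazy transform stage to a parent."""

    stage_name = "processed"

    def __init__(self, parent: Recording, params: dict,
                 channel_ids=None, channel_locations=None):
        if channel_ids is None:
            channel_ids = parent.channel_ids
        if channel_locations is None:
            channel_locations = parent.channel_locations
        super().__init__(
            channel_ids, channel_locations, parent.sampling_frequency,
            parent.num_frames,
            provenance=chained_record(parent.provenance, self.stage_name, params),
        )
        self.parent = parent
        self.params = dict(params)

    def stage_chain(self) -> list:
        """Stage descriptors from the root recording to this stage."""
        chain = []
        rec = self
        while isinstance(rec, ProcessedRecording):
            chain.append((rec.stage_name, rec.params))
            rec = rec.parent
        return chain[::-1]


class _FilteredRecording(ProcessedRecording):
    """Zero-phase SOS filter applied per channel with overlap margins."""

    def __init__(self, parent, sos, params, margin=DEFAULT_MARGIN_FRAMES):
        super().__init__(parent, params)
        self._sos = sos
        self._margin = int(margin)

    def _read_traces(self, channel_indices, start, end):
        if end == start:
            return np.empty((len(channel_indices), 0))
        lo = max(0, start - self._margin)
        hi = min(self.num_frames, end + self._margin)
        ids = [self.parent.channel_ids[i] for i in channel_indices]
        block = self.parent.get_traces(ids, lo, hi)
        filtered = signal.sosfiltfilt(self._sos, block, axis=1)
        return filtered[:, start - lo:end - lo]


class _BandpassRecording(_FilteredRecording):
    stage_name = "bandpass_filter"


class _NotchRecording(_FilteredRecording):
    stage_name = "notch_filter"


class _CommonReferenceRecording(ProcessedRecording):
    stage_name = "common_reference"

    def _read_traces(self, channel_indices, start, end):
        # the reference is computed across *all* parent channels per frame,
        # independent of which subset was requested
        block = self.parent.get_traces(None, start, end)
        if self.params["mode"] == "median":
            ref = np.median(block, axis=0)
        else:
            ref = np.mean(block, axis=0)
        return (block - ref[None, :])[channel_indices]


class _ChannelSliceRecording(ProcessedRecording):
    stage_name = "remove_channels"

    def __init__(self, parent, keep_ids, params):
        keep_idx = parent.channel_indices(keep_ids)
        super().__init__(parent, params, channel_ids=keep_ids,
                         channel_locations=parent.channel_locations[keep_idx])

    def _read_traces(self, channel_indices, start, end):
        ids = [self.channel_ids[i] for i in channel_indices]
        return self.parent.get_traces(ids, start, end)


@register_operation("bandpass_filter")
def bandpass_filter(recording: Recording, freq_min: float = 300.0,
                    freq_max: float = 6000.0, order: int = 3,
                    margin: int = DEFAULT_MARGIN_FRAMES) -> ProcessedRecording:
    """Zero-phase Butterworth band-pass (forward-backward, 2x order)."""
    nyquist = recording.sampling_frequency / 2.0
    if not (0 < freq_min < freq_max < nyquist):
        raise ParameterError(
            f"band [{freq_min}, {freq_max}] Hz must satisfy "
            f"0 < fmin < fmax < Nyquist ({nyquist:g} Hz)"
        )
    sos = signal.butter(order, [freq_min, freq_max], btype="bandpass",
                        fs=recording.sampling_frequency, output="sos")
    return _BandpassRecording(
        recording, sos,
        {"freq_min": freq_min, "freq_max": freq_max, "order": order,
         "margin": margin},
        margin=margin,
    )


@register_operation("notch_filter")
def notch_filter(recording: Recording, freq: float = 50.0, q: float = 30.0,
                 margin: int = DEFAULT_MARGIN_FRAMES) -> ProcessedRecording:
    """Zero-phase IIR notch rejecting a narrow band around ``freq``."""
    nyquist = recording.sampling_frequency / 2.0
    if not (0 < freq < nyquist):
        raise ParameterError(f"notch frequency {freq} Hz outside (0, {nyquist:g})")
    b, a = signal.iirnotch(freq, q, fs=recording.sampling_frequency)
    sos = signal.tf2sos(b, a)
    return _NotchRecording(recording, sos, {"freq": freq, "q": q, "margin": margin},
                           margin=margin)


@register_operation("common_reference")
def common_reference(recording: Recording, mode: str = "median",
                     reference: str = "global") -> ProcessedRecording:
    """Subtract the per-frame median (or mean) across channels."""
    if mode not in ("median", "average"):
        raise ParameterError(f"mode must be 'median' or 'average', got {mode!r}")
    if reference != "global":
        raise ParameterError("only reference='global' is supported")
    if recording.num_channels < 2:
        raise ParameterError("common reference needs at least 2 channels")
    return _CommonReferenceRecording(recording, {"mode": mode, "reference": reference})


@register_operation("remove_channels")
def remove_channels(recording: Recording,
                    channel_ids_to_remove: Sequence) -> ProcessedRecording:
    """Drop channels; remaining traces and probe locations are unchanged."""
    remove = list(channel_ids_to_remove)
    recording.channel_indices(remove)  # validates ids
    keep = [cid for cid in recording.channel_ids if cid not in set(remove)]
    if not keep:
        raise ParameterError("removing all channels would leave an empty recording")
    return _ChannelSliceRecording(recording, keep,
                                  {"channel_ids_to_remove": remove})
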