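"""Core data model: recordings, sortings, and their native file formats.

A :class:`Recording` is a lazy channels x frames trace source in microvolts
with a sampling frequency and per-channel probe coordinates.  A
:class:`Sorting` holds one spike train per unit as strictly increasing
integer sample frames.  Both carry a provenance record (see
:mod:`spikekit.provenance`) describing how they were built, so any object
can be serialized to JSON and reconstructed later.

Native formats are deliberately minimal:

* sorting CSV — header ``unit_id,frame``, UTF-8, LF line endings;
* sorting NPZ — CSR-style arrays ``unit_ids``, ``spike_frames``,
  ``unit_index_ptr`` plus scalar ``sampling_frequency``;
* recording — little-endian flat binary, frame-major (channel-interleaved),
  with a JSON sidecar ``{dtype, num_channels, sampling_frequency,
  gain_to_uV, offset}`` and a probe CSV ``channel_id,x,y`` in micrometers.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

__all__ = [
    "Recording",
    "NumpyRecording",
    "BinaryRecording",
    "Sorting",
    "read_sorting",
    "write_sorting",
    "read_recording",
    "write_recording",
]


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

class Recording:
    """Abstract lazy trace source.

    Subclasses must implement :meth:`_read_traces` returning a float64
    (n_channels, n_frames) matrix in microvolts for a channel-index subset
    and a half-open frame range.  Repeated reads of the same range must be
    identical.
    """

    def __init__(
        self,
        channel_ids: Sequence,
        channel_locations: np.ndarray,
        sampling_frequency: float,
        num_frames: int,
        provenance: dict | None = None,
    ):
        channel_ids = list(channel_ids)
        if len(set(channel_ids)) != len(channel_ids):
            raise ValidationError("channel_ids must be unique")
        locations = np.asarray(channel_locations, dtype=float)
        if locations.ndim != 2 or locations.shape != (len(channel_ids), 2):
            raise ValidationError(
                f"channel_locations must be ({len(channel_ids)}, 2), got {locations.shape}"
            )
        if not sampling_frequency > 0:
            raise ParameterError("sampling_frequency must be positive")
        if num_frames < 0:
            raise ValidationError("num_frames must be non-negative")
        self._channel_ids = channel_ids
        self._channel_locations = locations
        self._sampling_frequency = float(sampling_frequency)
        self._num_frames = int(num_frames)
        self.provenance = provenance or {}

    # -- metadata ----------------------------------------------------------

    @property
    def channel_ids(self) -> list:
        return list(self._channel_ids)

    @property
    def channel_locations(self) -> np.ndarray:
        return self._channel_locations.copy()

    @property
    def num_channels(self) -> int:
        return len(self._channel_ids)

    @property
    def num_frames(self) -> int:
        return self._num_frames

    @property
    def sampling_frequency(self) -> float:
        return self._sampling_frequency

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self._num_frames / self._sampling_frequency

    def channel_indices(self, channel_ids: Sequence | None) -> np.ndarray:
        """Map channel ids to integer indices, preserving request order."""
        if channel_ids is None:
            return np.arange(self.num_channels)
        lookup = {cid: i for i, cid in enumerate(self._channel_ids)}
        try:
            return np.array([lookup[cid] for cid in channel_ids], dtype=int)
        except KeyError as exc:
            raise ParameterError(f"unknown channel id {exc.args[0]!r}") from None

    # -- traces ------------------------------------------------------------

    def get_traces(
        self,
        channel_ids: Sequence | None = None,
        start_frame: int | None = None,
        end_frame: int | None = None,
    ) -> np.ndarray:
        """Return traces for a channel subset over [start_frame, end_frame)."""
        start = 0 if start_frame is None else int(start_frame)
        end = self._num_frames if end_frame is None else int(end_frame)
        if not (0 <= start <= end <= self._num_frames):
            raise ParameterError(
                f"frame range [{start}, {end}) outside [0, {self._num_frames})"
            )
        indices = self.channel_indices(channel_ids)
        traces = self._read_traces(indices, start, end)
        return np.asarray(traces, dtype=np.float64)

    def _read_traces(self, channel_indices: np.ndarray, start: int, end: int) -> np.ndarray:
        raise NotImplementedError


class NumpyRecording(Recording):
    """In-memory recording backed by a (n_channels, n_frames) array in uV."""

    def __init__(
        self,
        traces: np.ndarray,
        sampling_frequency: float,
        channel_ids: Sequence | None = None,
        channel_locations: np.ndarray | None = None,
        provenance: dict | None = None,
    ):
        traces = np.asarray(traces, dtype=np.float64)
        if traces.ndim != 2:
            raise ValidationError("traces must be 2-D (channels, frames)")
        n_channels, n_frames = traces.shape
        if channel_ids is None:
            channel_ids = list(range(n_channels))
        if channel_locations is None:
            # default linear probe, 20 um pitch along y
            channel_locations = np.column_stack(
                [np.zeros(n_channels), 20.0 * np.arange(n_channels)]
            )
        super().__init__(channel_ids, channel_locations, sampling_frequency,
                         n_frames, provenance)
        self._traces = traces

    def _read_traces(self, channel_indices, start, end):
        return self._traces[np.ix_(channel_indices, np.arange(start, end))]


class BinaryRecording(Recording):
    """Flat-binary recording with JSON header sidecar and probe CSV.

    The binary file is frame-major (all channels of frame 0, then frame 1,
    ...).  Construction reads only the sidecar files; trace bytes are
    memory-mapped on first access.
    """

    def __init__(self, path, probe_path, provenance: dict | None = None):
        path = Path(path)
        header_path = path.with_suffix(path.suffix + ".json")
        if not path.exists():
            raise FileNotFoundError(f"binary file not found: {path}")
        if not header_path.exists():
            raise FileNotFoundError(f"header sidecar not found: {header_path}")
        header = json.loads(header_path.read_text())
        for key in ("dtype", "num_channels", "sampling_frequency"):
            if key not in header:
                raise FormatError(f"header missing required key {key!r}")
        try:
            dtype = np.dtype(header["dtype"])
        except TypeError:
            raise FormatError(f"unknown dtype token {header['dtype']!r}") from None
        num_channels = int(header["num_channels"])
        itemsize = dtype.itemsize
        nbytes = path.stat().st_size
        if nbytes % (itemsize * num_channels) != 0:
            raise FormatError(
                f"file size {nbytes} not a multiple of frame size "
                f"{itemsize * num_channels}"
            )
        num_frames = nbytes // (itemsize * num_channels)

        channel_ids, locations = _read_probe_csv(probe_path)
        if len(channel_ids) != num_channels:
            raise ValidationError(
                f"probe file lists {len(channel_ids)} channels but header "
                f"declares {num_channels}"
            )
        if provenance is None:
            from .provenance import file_source_record
            provenance = file_source_record(
                "Recording", "binary", str(path), probe_path=str(probe_path)
            )
        super().__init__(channel_ids, locations, float(header["sampling_frequency"]),
                         num_frames, provenance)
        self._path = path
        self._dtype = dtype
        self._gain = float(header.get("gain_to_uV", 1.0))
        self._offset = float(header.get("offset", 0.0))
        self._memmap = None  # opened lazily

    def _read_traces(self, channel_indices, start, end):
        if self._memmap is None:
            self._memmap = np.memmap(
                self._path, dtype=self._dtype, mode="r",
                shape=(self._num_frames, len(self._channel_ids)),
            )
        block = np.asarray(self._memmap[start:end, :], dtype=np.float64)
        return block[:, channel_indices].T * self._gain + self._offset


def _read_probe_csv(probe_path):
    probe_path = Path(probe_path)
    if not probe_path.exists():
        raise FileNotFoundError(f"probe file not found: {probe_path}")
    df = pd.read_csv(probe_path)
    expected = ["channel_id", "x", "y"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"probe CSV must have columns {expected}, got {list(df.columns)}")
    return list(df["channel_id"]), df[["x", "y"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Sorting
# ---------------------------------------------------------------------------

class Sorting:
    """Unit-indexed spike trains in integer sample frames (0-based).

    Parameters
    ----------
    spike_trains
        Mapping of unit id to a strictly increasing array of non-negative
        integer frame indices.  Duplicate frames within a unit are invalid.
    sampling_frequency
        Sampling rate in Hz used to convert frames to seconds.
    unit_properties
        Optional per-unit scalar annotations, ``{property: {unit: value}}``.
    spike_features
        Optional per-unit per-spike arrays, ``{feature: {unit: array}}``;
        each array must have one value per spike.
    """

    def __init__(
        self,
        spike_trains: Mapping,
        sampling_frequency: float,
        unit_properties: dict | None = None,
        spike_features: dict | None = None,
        provenance: dict | None = None,
    ):
        if not sampling_frequency > 0:
            raise ParameterError("sampling_frequency must be positive")
        trains = {}
        for unit, frames in spike_trains.items():
            arr = np.asarray(frames)
            if arr.size and not np.issubdtype(arr.dtype, np.integer):
                as_int = np.asarray(arr, dtype=np.int64)
                if not np.array_equal(as_int, arr):
                    raise ValidationError(f"unit {unit!r}: non-integer spike frame")
                arr = as_int
            arr = arr.astype(np.int64, copy=True)
            if arr.size:
                if arr.min() < 0:
                    raise ValidationError(f"unit {unit!r}: negative spike frame")
                diffs = np.diff(arr)
                if np.any(diffs == 0):
                    raise ValidationError(f"unit {unit!r}: duplicate spike frame")
                if np.any(diffs < 0):
                    raise ValidationError(
                        f"unit {unit!r}: spike frames not strictly increasing"
                    )
            arr.flags.writeable = False
            trains[unit] = arr
        self._trains = trains
        self._sampling_frequency = float(sampling_frequency)
        self.unit_properties = unit_properties or {}
        self.spike_features = {}
        if spike_features:
            for name, per_unit in spike_features.items():
                self.set_spike_feature(name, per_unit)
        self.provenance = provenance or {}

    @property
    def unit_ids(self) -> list:
        return list(self._trains)

    @property
    def num_units(self) -> int:
        return len(self._trains)

    @property
    def sampling_frequency(self) -> float:
        return self._sampling_frequency

    def spike_train(self, unit) -> np.ndarray:
        """Spike train of ``unit`` as integer frames (read-only view)."""
        try:
            return self._trains[unit]
        except KeyError:
            raise ParameterError(f"unknown unit id {unit!r}") from None

    def spike_train_seconds(self, unit) -> np.ndarray:
        """Spike train of ``unit`` in seconds (derived view)."""
        return self.spike_train(unit) / self._sampling_frequency

    def num_spikes(self, unit) -> int:
        return int(self.spike_train(unit).size)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self._trains.values()))

    def set_spike_feature(self, name: str, per_unit: Mapping) -> None:
        checked = {}
        for unit, values in per_unit.items():
            arr = np.asarray(values)
            if arr.shape[0] != self.num_spikes(unit):
                raise ValidationError(
                    f"feature {name!r} for unit {unit!r} has {arr.shape[0]} values "
                    f"for {self.num_spikes(unit)} spikes"
                )
            checked[unit] = arr
        self.spike_features[name] = checked

    def select_units(self, unit_ids: Sequence, provenance: dict | None = None) -> "Sorting":
        """New Sorting restricted to ``unit_ids`` (trains shared, unchanged)."""
        missing = [u for u in unit_ids if u not in self._trains]
        if missing:
            raise ParameterError(f"unknown unit ids {missing!r}")
        trains = {u: self._trains[u] for u in unit_ids}
        props = {
            name: {u: v for u, v in per_unit.items() if u in trains}
            for name, per_unit in self.unit_properties.items()
        }
        feats = {
            name: {u: v for u, v in per_unit.items() if u in trains}
            for name, per_unit in self.spike_features.items()
        }
        return Sorting(trains, self._sampling_frequency, props, feats,
                       provenance=provenance)

    def __eq__(self, other):
        if not isinstance(other, Sorting):
            return NotImplemented
        return (
            self.unit_ids == other.unit_ids
            and self._sampling_frequency == other._sampling_frequency
            and all(np.array_equal(self._trains[u], other._trains[u])
                    for u in self._trains)
        )

    def __repr__(self):
        return (f"Sorting({self.num_units} units, {self.total_spikes()} spikes, "
                f"fs={self._sampling_frequency:g} Hz)")


# ---------------------------------------------------------------------------
# Sorting I/O
# ---------------------------------------------------------------------------

def _infer_format(path, fmt):
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".npz":
        return "npz"
    raise ParameterError(f"cannot infer sorting format from {path!r}; pass format=")


def read_sorting(path, format: str | None = None,
                 sampling_frequency: float | None = None) -> Sorting:
    """Read a Sorting from CSV or NPZ.

    CSV files do not carry a sampling frequency; pass ``sampling_frequency``
    (defaults to 30000 Hz with a warning).  Unsorted trains are sorted with
    a warning; duplicate frames within a unit raise ValidationError.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sorting file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["unit_id", "frame"]:
            raise FormatError(
                f"sorting CSV must have header 'unit_id,frame', got {list(df.columns)}"
            )
        if len(df) and not np.issubdtype(df["frame"].dtype, np.integer):
            frames_float = df["frame"].to_numpy()
            if not np.all(frames_float == np.round(frames_float)):
                raise ValidationError("non-integer frame value in sorting CSV")
            df["frame"] = frames_float.astype(np.int64)
        if sampling_frequency is None:
            warnings.warn(
                "sorting CSV carries no sampling frequency; assuming 30000 Hz",
                stacklevel=2,
            )
            sampling_frequency = 30000.0
        trains = {}
        for unit, group in df.groupby("unit_id", sort=False):
            frames = group["frame"].to_numpy(dtype=np.int64)
            if frames.size > 1 and np.any(np.diff(frames) < 0):
                warnings.warn(f"unit {unit!r}: unsorted spike frames; sorting on read",
                              stacklevel=2)
                frames = np.sort(frames)
            trains[unit] = frames
        sorting = Sorting(trains, sampling_frequency)
    elif fmt == "npz":
        with np.load(path, allow_pickle=False) as data:
            for key in ("unit_ids", "spike_frames", "unit_index_ptr", "sampling_frequency"):
                if key not in data:
                    raise FormatError(f"sorting NPZ missing array {key!r}")
            unit_ids = data["unit_ids"]
            frames = data["spike_frames"]
            ptr = data["unit_index_ptr"]
            fs = float(data["sampling_frequency"])
        if len(ptr) != len(unit_ids) + 1:
            raise FormatError("unit_index_ptr must have len(unit_ids) + 1 entries")
        trains = {}
        for i, unit in enumerate(unit_ids.tolist()):
            seg = frames[ptr[i]:ptr[i + 1]]
            if seg.size > 1 and np.any(np.diff(seg) < 0):
                warnings.warn(f"unit {unit!r}: unsorted spike frames; sorting on read",
                              stacklevel=2)
                seg = np.sort(seg)
            trains[unit] = seg
        sorting = Sorting(trains, fs)
    else:
        raise ParameterError(f"unknown sorting format {fmt!r}")
    from .provenance import file_source_record
    sorting.provenance = file_source_record(
        "Sorting", fmt, str(path), sampling_frequency=sorting.sampling_frequency
    )
    return sorting


def write_sorting(sorting: Sorting, path, format: str | None = None) -> Path:
    """Write a Sorting to CSV or NPZ; byte-stable for fixed input."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        empty = [u for u in sorting.unit_ids if sorting.num_spikes(u) == 0]
        if empty:
            # the row-per-spike format cannot carry a unit with no spikes
            warnings.warn(f"units {empty!r} have no spikes and are dropped by "
                          "the CSV format; use NPZ to preserve them",
                          stacklevel=2)
        lines = ["unit_id,frame"]
        for unit in sorting.unit_ids:
            lines.extend(f"{unit},{frame}" for frame in sorting.spike_train(unit))
        path.write_bytes(("\n".join(lines) + "\n").encode("utf-8"))
    elif fmt == "npz":
        unit_ids = sorting.unit_ids
        counts = [sorting.num_spikes(u) for u in unit_ids]
        ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        frames = (np.concatenate([sorting.spike_train(u) for u in unit_ids])
                  if unit_ids else np.empty(0, dtype=np.int64))
        arrays = {
            "unit_ids": np.asarray(unit_ids),
            "spike_frames": frames,
            "unit_index_ptr": ptr,
            "sampling_frequency": np.float64(sorting.sampling_frequency),
        }
        _write_stable_npz(path, arrays)
    else:
        raise ParameterError(f"unknown sorting format {fmt!r}")
    return path


def _write_stable_npz(path, arrays: dict) -> None:
    # np.savez stamps current time into the zip directory; write the zip
    # by hand with a fixed timestamp so identical inputs give identical bytes
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asanyarray(arrays[name]))
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def read_recording(path, probe_path) -> BinaryRecording:
    """Open a flat-binary recording lazily (no trace bytes read here)."""
    return BinaryRecording(path, probe_path)


def write_recording(recording: Recording, path, probe_path,
                    dtype: str = "float32", chunk_frames: int = 1_000_000) -> Path:
    """Write traces to flat binary + JSON sidecar and the probe to CSV."""
    path = Path(path)
    dt = np.dtype(dtype)
    with open(path, "wb") as fh:
        for start in range(0, recording.num_frames, chunk_frames):
            end = min(start + chunk_frames, recording.num_frames)
            block = recording.get_traces(start_frame=start, end_frame=end)
            fh.write(np.ascontiguousarray(block.T, dtype=dt).tobytes())
    header = {
        "dtype": dt.name,
        "num_channels": recording.num_channels,
        "sampling_frequency": recording.sampling_frequency,
        "gain_to_uV": 1.0,
        "offset": 0.0,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(header, indent=2, sort_keys=True) + "\n"
    )
    locations = recording.channel_locations
    lines = ["channel_id,x,y"]
    for cid, (x, y) in zip(recording.channel_ids, locations):
        lines.append(f"{cid},{x:g},{y:g}")
    Path(probe_path).write_bytes(("\n".join(lines) + "\n").encode("utf-8"))
    return path
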