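"""Provenance capture and replay.

Every Recording/Sorting built from a file, a synthetic generator, or a
registered transformation carries a provenance record::

    {
        "schema_version": "1",
        "class": "Recording" | "Sorting",
        "source": {"kind": "file" | "synthetic", ...},
        "operations": [{"name": ..., "params": {...}}, ...],
    }

``dump_provenance`` serializes the record (JSON-compatible dict);
``restore`` rebuilds the object by re-reading the source (or re-running
the seeded generator) and replaying the operations in order.  Objects
constructed directly from in-memory arrays have an empty record and
cannot be restored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ProvenanceError

SCHEMA_VERSION = "1"

# name -> callable(obj, **params) for replayable transformations
_OPERATION_REGISTRY: dict = {}

# name -> callable(**params) for synthetic sources
_GENERATOR_REGISTRY: dict = {}


def register_operation(name: str):
    def decorator(func):
        _OPERATION_REGISTRY[name] = func
        return func
    return decorator


def register_generator(name: str):
    def decorator(func):
        _GENERATOR_REGISTRY[name] = func
        return func
    return decorator


def _jsonable(value):
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, Path):
        return str(value)
    return value


def file_source_record(cls: str, fmt: str, path: str, **extra) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "class": cls,
        "source": {"kind": "file", "format": fmt, "path": path,
                   **_jsonable(extra)},
        "operations": [],
    }


def synthetic_source_record(cls: str, generator: str, params: dict) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "class": cls,
        "source": {"kind": "synthetic", "generator": generator,
                   "params": _jsonable(params)},
        "operations": [],
    }


def chained_record(parent_record: dict, op_name: str, params: dict) -> dict:
    """Parent record plus one applied operation."""
    if not parent_record:
        return {}
    record = json.loads(json.dumps(parent_record))  # deep copy, JSON-safe
    record["operations"].append({"name": op_name, "params": _jsonable(params)})
    return record


def dump_provenance(obj) -> dict:
    """Return the object's provenance record as a JSON-compatible dict."""
    record = getattr(obj, "provenance", None)
    if not record:
        raise ProvenanceError(
            "object has no provenance record (built directly from memory?)"
        )
    return json.loads(json.dumps(record))


def save_provenance(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dump_provenance(obj), indent=2, sort_keys=True) + "\n")
    return path


def restore(record):
    """Rebuild a Recording or Sorting from a provenance record.

    Accepts a record dict, a JSON string, or a path to a JSON file.
    """
    from . import core

    if isinstance(record, (str, Path)):
        p = Path(record)
        record = json.loads(p.read_text() if p.exists() else str(record))
    if not isinstance(record, dict) or "schema_version" not in record:
        raise ProvenanceError("not a provenance record")
    if record["schema_version"] != SCHEMA_VERSION:
        raise ProvenanceError(
            f"unsupported provenance schema version {record['schema_version']!r} "
            f"(this build supports {SCHEMA_VERSION!r})"
        )
    source = record.get("source", {})
    kind = source.get("kind")
    if kind == "file":
        fmt = source["format"]
        path = Path(source["path"])
        if not path.exists():
            raise ProvenanceError(f"source file missing: {path}")
        if record["class"] == "Sorting":
            obj = core.read_sorting(path, format=fmt,
                                    sampling_frequency=source.get("sampling_frequency"))
        else:
            probe = Path(source["probe_path"])
            if not probe.exists():
                raise ProvenanceError(f"probe file missing: {probe}")
            obj = core.read_recording(path, probe)
    elif kind == "synthetic":
        name = source["generator"]
        if name not in _GENERATOR_REGISTRY:
            raise ProvenanceError(f"unknown synthetic generator {name!r}")
        obj = _GENERATOR_REGISTRY[name](**source["params"])
    else:
        raise ProvenanceError(f"unknown source kind {kind!r}")

    for op in record.get("operations", []):
        name = op["name"]
        if name not in _OPERATION_REGISTRY:
            raise ProvenanceError(f"unknown operation {name!r} in provenance record")
        obj = _OPERATION_REGISTRY[name](obj, **op["params"])
    return obj
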