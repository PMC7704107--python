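"""Unit curation: metric thresholding and consensus-based retention.

Curation is non-destructive: a :class:`CuratedSorting` keeps its parent
and an exclusion log recording, for every removed unit, the metric value
and threshold that excluded it (or the agreement count k for consensus
curation).  Replaying the log on the parent reproduces the curated unit
set exactly.  Retained spike trains are never modified.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comparison import DEFAULT_DELTA_MS, MultiComparisonGraph, compare_multiple
from .core import Recording, Sorting
from .errors import ParameterError
from .provenance import chained_record, register_operation
from .quality_metrics import METRIC_NAMES, MetricTable, compute_quality_metrics

__all__ = ["CuratedSorting", "threshold_curation", "consensus_curation"]

_SIGNS = {
    "less": np.less,
    "greater": np.greater,
    "less_or_equal": np.less_equal,
    "greater_or_equal": np.greater_equal,
}


class CuratedSorting(Sorting):
    """A Sorting restricted to units that survived curation."""

    def __init__(self, parent: Sorting, keep_units: list, exclusion_log: list,
                 provenance: dict | None = None):
        base = parent.select_units(keep_units)
        super().__init__(
            {u: base.spike_train(u) for u in base.unit_ids},
            parent.sampling_frequency,
            unit_properties=base.unit_properties,
            spike_features=base.spike_features,
            provenance=provenance,
        )
        self.parent = parent
        self.exclusion_log = list(exclusion_log)

    def exclusion_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.exclusion_log,
            columns=["unit_id", "metric", "value", "threshold", "sign"],
        )


@register_operation("exclude_units")
def _exclude_units(sorting: Sorting, unit_ids: list) -> Sorting:
    """Replayable primitive behind every curation step."""
    keep = [u for u in sorting.unit_ids if u not in set(unit_ids)]
    return sorting.select_units(
        keep,
        provenance=chained_record(sorting.provenance, "exclude_units",
                                  {"unit_ids": list(unit_ids)}),
    )


def threshold_curation(
    sorting: Sorting,
    recording: Recording | None = None,
    metric: str = "firing_rate",
    threshold: float = 0.0,
    sign: str = "less",
    metrics_table: MetricTable | None = None,
    exclude_nan: bool = True,
    duration: float | None = None,
    seed: int | None = 0,
) -> CuratedSorting:
    """Exclude units whose metric value satisfies the predicate.

    ``sign='less'`` removes units with ``metric < threshold``, and so on.
    Metrics are computed on demand (pass ``metrics_table`` to reuse a
    precomputed table).  A NaN metric value fails every threshold and is
    excluded unless ``exclude_nan=False``.  Output is a valid Sorting, so
    curation steps chain.
    """
    if sign not in _SIGNS:
        raise ParameterError(f"sign must be one of {sorted(_SIGNS)}, got {sign!r}")
    if metric not in METRIC_NAMES:
        raise ParameterError(f"unknown metric {metric!r}")
    if metrics_table is None:
        metrics_table = compute_quality_metrics(
            recording, sorting, metric_names=[metric], seed=seed, duration=duration,
        )
    values = metrics_table.table[metric]
    predicate = _SIGNS[sign]
    log, keep = [], []
    for unit in sorting.unit_ids:
        value = float(values.loc[unit])
        excluded = exclude_nan if np.isnan(value) else bool(predicate(value, threshold))
        if excluded:
            log.append({"unit_id": unit, "metric": metric, "value": value,
                        "threshold": threshold, "sign": sign})
        else:
            keep.append(unit)
    removed = [entry["unit_id"] for entry in log]
    provenance = chained_record(sorting.provenance, "exclude_units",
                                {"unit_ids": removed})
    return CuratedSorting(sorting, keep, log, provenance=provenance)


def consensus_curation(
    sortings: list,
    labels: list | None = None,
    min_k: int = 2,
    delta_time: float = DEFAULT_DELTA_MS,
    min_match_score: float = 0.5,
    graph: MultiComparisonGraph | None = None,
) -> dict:
    """Per-sorter curation keeping units at least ``min_k`` sorters agree on.

    Builds (or reuses) the multi-sorter agreement graph and, for each
    sorter, retains the units whose agreement count k reaches ``min_k``.
    Returns ``{label: CuratedSorting}``; each exclusion log cites the k
    value under the metric name ``"agreement_count_k"``.
    """
    if labels is None:
        labels = [f"sorter{i}" for i in range(len(sortings))]
    if min_k < 1 or min_k > len(sortings):
        raise ParameterError(
            f"min_k must be in [1, {len(sortings)}], got {min_k}"
        )
    if graph is None:
        graph = compare_multiple(sortings, labels, delta_time, min_match_score)
    curated = {}
    for label, sorting in zip(labels, sortings):
        log, keep = [], []
        for unit in sorting.unit_ids:
            k = graph.agreement_count((label, unit))
            if k >= min_k:
                keep.append(unit)
            else:
                log.append({"unit_id": unit, "metric": "agreement_count_k",
                            "value": k, "threshold": min_k, "sign": "less"})
        removed = [entry["unit_id"] for entry in log]
        provenance = chained_record(sorting.provenance, "exclude_units",
                                    {"unit_ids": removed})
        curated[label] = CuratedSorting(sorting, keep, log, provenance=provenance)
    return curated
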