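"""Spike-train and unit-level comparison.

The central quantity is the agreement score between two spike trains,

    score = n_matches / (n1 + n2 - n_matches),

the matched-spike count over the size of the union of the two trains.
Two spikes match when they fall within a time window of each other
(0.4 ms by default, window inclusive); "matched spikes" is made precise
as a maximum one-to-one pairing, which for sorted trains a two-pointer
sweep computes exactly.

On top of agreement scores the module provides:

* Hungarian (optimal injective) and best-match (thresholded many-to-one)
  unit assignment between two sortings;
* tp/fn/fp spike labeling against ground truth and the five derived
  performance measures (accuracy, recall, precision, miss rate, false
  discovery rate);
* classification of tested units as well-detected / false-positive /
  redundant / overmerged (default thresholds 0.8 and 0.2 on agreement);
* the multi-sorter agreement graph, per-unit agreement counts k, and
  consensus sorting construction (union of the two closest matching
  units, matched spikes counted once).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import Sorting
from .errors import ParameterError, ValidationError
from .provenance import SCHEMA_VERSION

__all__ = [
    "DEFAULT_DELTA_MS",
    "MatchCounts",
    "AgreementMatrix",
    "UNMATCHED",
    "SpikeLabelCounts",
    "count_matched_spikes",
    "agreement_score",
    "compute_agreement_matrix",
    "hungarian_match",
    "best_match",
    "label_spikes",
    "performance_measures",
    "compare_two_sorters",
    "compare_with_ground_truth",
    "classify_units",
    "compare_multiple",
    "agreement_counts",
    "build_consensus_sorting",
]

#: default matching window in milliseconds
DEFAULT_DELTA_MS = 0.4

#: sentinel for "no partner survived the score threshold"
UNMATCHED = None


@dataclass(frozen=True)
class MatchCounts:
    n1: int
    n2: int
    n_matches: int
    delta_frames: int

    def __post_init__(self):
        if not (0 <= self.n_matches <= min(self.n1, self.n2)):
            raise ValidationError("n_matches must lie in [0, min(n1, n2)]")


def _sweep_matches(t1, t2, delta):
    i = j = matches = 0
    n1, n2 = t1.shape[0], t2.shape[0]
    while i < n1 and j < n2:
        d = t1[i] - t2[j]
        if -delta <= d <= delta:
            matches += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return matches


try:  # compiled sweep keeps all-pairs agreement matrices cheap
    from numba import njit

    _sweep_matches = njit(cache=False)(_sweep_matches)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def count_matched_spikes(train1, train2, delta_frames: int) -> MatchCounts:
    """Maximum one-to-one pairing of spikes within ``delta_frames``.

    The window is inclusive (|t1 - t2| <= delta).  For sorted trains a
    greedy two-pointer sweep — advance whichever current spike is earlier,
    pair when within the window — attains the bipartite optimum: skipping a
    feasible earliest pair can never enable more than one extra later pair.
    Ties (a spike equidistant from two candidates) resolve to the earlier
    candidate automatically since the sweep runs left to right.
    """
    t1 = np.ascontiguousarray(train1, dtype=np.int64)
    t2 = np.ascontiguousarray(train2, dtype=np.int64)
    if delta_frames < 0:
        raise ParameterError("delta_frames must be >= 0")
    for name, t in (("train1", t1), ("train2", t2)):
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError(f"{name} must be strictly increasing")
    matches = int(_sweep_matches(t1, t2, int(delta_frames)))
    return MatchCounts(int(t1.size), int(t2.size), matches, int(delta_frames))


def agreement_score(counts: MatchCounts) -> float:
    """Matched spikes over union size; 0 when both trains are empty."""
    denom = counts.n1 + counts.n2 - counts.n_matches
    if denom == 0:
        return 0.0  # an empty pair of units carries no evidence of agreement
    return counts.n_matches / denom


def delta_ms_to_frames(delta_ms: float, sampling_frequency: float) -> int:
    return int(round(delta_ms * sampling_frequency / 1000.0))


@dataclass
class AgreementMatrix:
    """units(A) x units(B) matrix of agreement scores in [0, 1]."""

    row_ids: list
    col_ids: list
    scores: np.ndarray
    match_counts: dict = field(default_factory=dict)  # (row, col) -> MatchCounts
    delta_frames: int = 0

    def score(self, row_unit, col_unit) -> float:
        return float(self.scores[self.row_ids.index(row_unit),
                                 self.col_ids.index(col_unit)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.row_ids, columns=self.col_ids)


def compute_agreement_matrix(
    sorting_a: Sorting,
    sorting_b: Sorting,
    delta_time: float = DEFAULT_DELTA_MS,
) -> AgreementMatrix:
    """All-pairs agreement between the units of two sortings."""
    if sorting_a.sampling_frequency != sorting_b.sampling_frequency:
        raise ValidationError(
            f"sampling frequencies differ: {sorting_a.sampling_frequency} "
            f"vs {sorting_b.sampling_frequency}"
        )
    delta_frames = delta_ms_to_frames(delta_time, sorting_a.sampling_frequency)
    rows, cols = sorting_a.unit_ids, sorting_b.unit_ids
    scores = np.zeros((len(rows), len(cols)))
    counts = {}
    for i, u in enumerate(rows):
        ta = sorting_a.spike_train(u)
        for j, v in enumerate(cols):
            c = count_matched_spikes(ta, sorting_b.spike_train(v), delta_frames)
            counts[(u, v)] = c
            scores[i, j] = agreement_score(c)
    return AgreementMatrix(rows, cols, scores, counts, delta_frames)


@dataclass
class MatchResult:
    """Injective (hungarian) or filtered (best) unit assignment."""

    matches: dict         # row unit -> col unit or UNMATCHED
    scores: dict          # row unit -> score of the retained match
    method: str
    min_score: float


def hungarian_match(matrix: AgreementMatrix, min_score: float = 0.5):
    """Optimal injective assignment maximizing total agreement.

    Pairs scoring below ``min_score`` (or exactly 0) are discarded *after*
    optimization.  Returns the assignment from both sides; the two results
    are mutually consistent.
    """
    if not (0 <= min_score <= 1):
        raise ParameterError("min_score must be in [0, 1]")
    matches_a = {u: UNMATCHED for u in matrix.row_ids}
    matches_b = {v: UNMATCHED for v in matrix.col_ids}
    scores_a = {u: 0.0 for u in matrix.row_ids}
    scores_b = {v: 0.0 for v in matrix.col_ids}
    if matrix.scores.size:
        row_idx, col_idx = linear_sum_assignment(-matrix.scores)
        for i, j in zip(row_idx, col_idx):
            s = float(matrix.scores[i, j])
            if s >= min_score and s > 0:
                u, v = matrix.row_ids[i], matrix.col_ids[j]
                matches_a[u] = v
                matches_b[v] = u
                scores_a[u] = s
                scores_b[v] = s
    return (MatchResult(matches_a, scores_a, "hungarian", min_score),
            MatchResult(matches_b, scores_b, "hungarian", min_score))


def best_match(matrix: AgreementMatrix, min_score: float = 0.2) -> dict:
    """All partners above threshold per row unit, best first (no injectivity)."""
    if not (0 <= min_score <= 1):
        raise ParameterError("min_score must be in [0, 1]")
    result = {}
    for i, u in enumerate(matrix.row_ids):
        pairs = [(matrix.col_ids[j], float(matrix.scores[i, j]))
                 for j in range(len(matrix.col_ids))
                 if matrix.scores[i, j] >= min_score and matrix.scores[i, j] > 0]
        pairs.sort(key=lambda p: -p[1])
        result[u] = pairs
    return result


# ---------------------------------------------------------------------------
# Ground-truth evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeLabelCounts:
    """tp/fn/fp spike counts for a (ground-truth unit, tested unit) pair."""

    tp: int
    fn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValidationError("spike label counts must be non-negative")


def label_spikes(gt_train, tested_train, delta_frames: int) -> SpikeLabelCounts:
    """tp = matched spikes; fn = unmatched ground truth; fp = unmatched tested."""
    c = count_matched_spikes(gt_train, tested_train, delta_frames)
    return SpikeLabelCounts(tp=c.n_matches, fn=c.n1 - c.n_matches,
                            fp=c.n2 - c.n_matches)


def performance_measures(counts: SpikeLabelCounts) -> dict:
    """Accuracy, recall, precision, miss rate, and false discovery rate."""
    tp, fn, fp = counts.tp, counts.fn, counts.fp
    if tp + fn + fp == 0:
        raise ParameterError("performance undefined for all-zero counts")
    recall = tp / (tp + fn) if tp + fn else np.nan
    precision = tp / (tp + fp) if tp + fp else np.nan
    return {
        "accuracy": tp / (tp + fn + fp),
        "recall": recall,
        "precision": precision,
        "miss_rate": fn / (tp + fn) if tp + fn else np.nan,
        "false_discovery_rate": fp / (tp + fp) if tp + fp else np.nan,
    }


@dataclass
class PairComparison:
    """Result of comparing two sorting outputs (Hungarian assignment)."""

    agreement: AgreementMatrix
    match_12: MatchResult
    match_21: MatchResult


def compare_two_sorters(sorting1: Sorting, sorting2: Sorting,
                        delta_time: float = DEFAULT_DELTA_MS,
                        min_score: float = 0.5) -> PairComparison:
    matrix = compute_agreement_matrix(sorting1, sorting2, delta_time)
    m12, m21 = hungarian_match(matrix, min_score)
    return PairComparison(matrix, m12, m21)


@dataclass
class GroundTruthComparison:
    """Ground-truth evaluation bundle for one tested sorting."""

    agreement: AgreementMatrix          # rows = gt units, cols = tested units
    gt_matches: MatchResult             # gt unit -> tested partner
    tested_matches: MatchResult | dict  # tested unit -> gt partner(s)
    method: str
    label_counts: dict                  # gt unit -> SpikeLabelCounts
    performance: pd.DataFrame           # per gt unit
    classification: "UnitClassification"


@dataclass
class UnitClassification:
    """Category per tested unit with the thresholds that produced it."""

    categories: dict
    well_detected_threshold: float
    false_positive_threshold: float

    def units_in(self, category: str) -> list:
        return [u for u, c in self.categories.items() if c == category]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tested_unit": list(self.categories),
             "category": list(self.categories.values())}
        )


def classify_units(
    agreement: AgreementMatrix,
    gt_matches: MatchResult,
    well_detected_threshold: float = 0.8,
    false_positive_threshold: float = 0.2,
) -> UnitClassification:
    """Classify tested units against ground truth by agreement score.

    Rules, applied in order per tested unit:

    1. *overmerged* — agreement above ``false_positive_threshold`` with two
       or more ground-truth units;
    2. *well_detected* — the Hungarian partner of a ground-truth unit with
       agreement above ``well_detected_threshold``;
    3. *redundant* — above ``false_positive_threshold`` with exactly one
       ground-truth unit but not that unit's assigned partner;
    4. *false_positive* — unassigned and above threshold with no unit;
    5. *weak_match* — the assigned partner of a ground-truth unit whose
       score falls between the two thresholds.
    """
    matched_by = {v: u for u, v in gt_matches.matches.items() if v is not UNMATCHED}
    categories = {}
    for j, tested in enumerate(agreement.col_ids):
        col = agreement.scores[:, j]
        n_above = int(np.sum(col > false_positive_threshold))
        if n_above >= 2:
            categories[tested] = "overmerged"
        elif tested in matched_by:
            score = gt_matches.scores[matched_by[tested]]
            if score > well_detected_threshold:
                categories[tested] = "well_detected"
            elif score > false_positive_threshold:
                categories[tested] = "weak_match"
            else:
                categories[tested] = "false_positive"
        elif n_above == 1:
            categories[tested] = "redundant"
        else:
            categories[tested] = "false_positive"
    return UnitClassification(categories, well_detected_threshold,
                              false_positive_threshold)


def compare_with_ground_truth(
    gt_sorting: Sorting,
    tested_sorting: Sorting,
    method: str = "hungarian",
    delta_time: float = DEFAULT_DELTA_MS,
    min_score: float = 0.5,
    well_detected_threshold: float = 0.8,
    false_positive_threshold: float = 0.2,
) -> GroundTruthComparison:
    """Evaluate a tested sorting against ground truth.

    Per ground-truth unit, tp/fn/fp and the five performance measures are
    computed against its matched partner; an unmatched ground-truth unit
    counts all its spikes as misses (recall 0).
    """
    if method not in ("hungarian", "best"):
        raise ParameterError(f"method must be 'hungarian' or 'best', got {method!r}")
    matrix = compute_agreement_matrix(gt_sorting, tested_sorting, delta_time)
    gt_m, tested_m = hungarian_match(matrix, min_score)
    if method == "best":
        tested_view = best_match(
            AgreementMatrix(matrix.col_ids, matrix.row_ids, matrix.scores.T,
                            delta_frames=matrix.delta_frames),
            min_score,
        )
    else:
        tested_view = tested_m

    label_counts, rows = {}, []
    for gt_unit in gt_sorting.unit_ids:
        partner = gt_m.matches[gt_unit]
        n_gt = gt_sorting.num_spikes(gt_unit)
        if partner is UNMATCHED:
            counts = SpikeLabelCounts(tp=0, fn=n_gt, fp=0)
        else:
            counts = label_spikes(gt_sorting.spike_train(gt_unit),
                                  tested_sorting.spike_train(partner),
                                  matrix.delta_frames)
        label_counts[gt_unit] = counts
        perf = (performance_measures(counts) if counts.tp + counts.fn + counts.fp
                else dict.fromkeys(
                    ["accuracy", "recall", "precision", "miss_rate",
                     "false_discovery_rate"], np.nan))
        rows.append({"gt_unit": gt_unit, "tested_unit": partner,
                     "agreement": gt_m.scores[gt_unit],
                     "tp": counts.tp, "fn": counts.fn, "fp": counts.fp, **perf})
    performance = pd.DataFrame(rows)
    classification = classify_units(matrix, gt_m, well_detected_threshold,
                                    false_positive_threshold)
    return GroundTruthComparison(matrix, gt_m, tested_view, method,
                                 label_counts, performance, classification)


# ---------------------------------------------------------------------------
# Multi-sorter comparison and consensus
# ---------------------------------------------------------------------------

@dataclass
class MultiComparisonGraph:
    """Agreement graph over (sorter_label, unit_id) nodes.

    Edges connect Hungarian-matched unit pairs between sorters with weight
    equal to their agreement score (all >= min_match_score).  The agreement
    count k of a node is 1 plus the number of distinct *other* sorters it
    has an edge to; chains through third sorters do not inflate k.
    """

    graph: nx.Graph
    labels: list
    delta_time: float
    min_match_score: float

    def agreement_count(self, node) -> int:
        sorters = {nbr[0] for nbr in self.graph.neighbors(node)}
        sorters.discard(node[0])
        return 1 + len(sorters)

    def nodes_for(self, label) -> list:
        return [n for n in self.graph.nodes if n[0] == label]

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"sorter_a": a[0], "unit_a": a[1], "sorter_b": b[0], "unit_b": b[1],
             "score": d["weight"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows,
                            columns=["sorter_a", "unit_a", "sorter_b", "unit_b",
                                     "score"])


def compare_multiple(
    sortings: list,
    labels: list | None = None,
    delta_time: float = DEFAULT_DELTA_MS,
    min_match_score: float = 0.5,
) -> MultiComparisonGraph:
    """Pairwise Hungarian comparison of every sorter pair, as a graph."""
    if len(sortings) < 2:
        raise ParameterError("need at least two sortings to compare")
    if labels is None:
        labels = [f"sorter{i}" for i in range(len(sortings))]
    if len(labels) != len(sortings):
        raise ParameterError("labels and sortings must have equal length")
    if len(set(labels)) != len(labels):
        raise ParameterError("duplicate sorter labels")
    fs = {s.sampling_frequency for s in sortings}
    if len(fs) != 1:
        raise ValidationError("all sortings must share one sampling frequency")

    graph = nx.Graph()
    for label, sorting in zip(labels, sortings):
        for unit in sorting.unit_ids:
            graph.add_node((label, unit))
    for i in range(len(sortings)):
        for j in range(i + 1, len(sortings)):
            matrix = compute_agreement_matrix(sortings[i], sortings[j], delta_time)
            m_ij, _ = hungarian_match(matrix, min_match_score)
            for u, v in m_ij.matches.items():
                if v is not UNMATCHED:
                    graph.add_edge((labels[i], u), (labels[j], v),
                                   weight=m_ij.scores[u])
    return MultiComparisonGraph(graph, list(labels), delta_time, min_match_score)


def agreement_counts(mcg: MultiComparisonGraph):
    """Unit-group and per-sorter tallies of the agreement count k.

    Returns ``(group_counts, per_sorter)``: ``group_counts[k]`` counts each
    connected agreement group once (a group of units matched across sorters
    is one entry, at the maximum k of its members, so the Figure-style
    "units on which k sorters agree" is not multiply counted);
    ``per_sorter.loc[label, k]`` counts that sorter's own units at each k.
    """
    max_k = len(mcg.labels)
    per_sorter = pd.DataFrame(0, index=mcg.labels,
                              columns=pd.RangeIndex(1, max_k + 1, name="k"))
    for node in mcg.graph.nodes:
        per_sorter.loc[node[0], mcg.agreement_count(node)] += 1
    group_counts = pd.Series(0, index=pd.RangeIndex(1, max_k + 1, name="k"),
                             name="n_unit_groups")
    for component in nx.connected_components(mcg.graph):
        k = max(mcg.agreement_count(n) for n in component)
        group_counts[k] += 1
    return group_counts, per_sorter


def build_consensus_sorting(
    mcg: MultiComparisonGraph,
    sortings: list,
    labels: list | None = None,
    min_k: int = 2,
    delta_time: float | None = None,
) -> Sorting:
    """Consensus sorting from the agreement graph.

    Each connected unit group supported by at least ``min_k`` sorters
    contributes one consensus unit: the union of the spike trains of the
    two closest matching units (the group's highest-weight edge), with
    spikes matching within the window counted once (the earlier frame is
    kept).  Donor units are recorded in the provenance and in the
    ``consensus_donors`` unit property.
    """
    if labels is None:
        labels = mcg.labels
    if min_k > len(mcg.labels):
        raise ParameterError(
            f"min_k={min_k} exceeds the number of sorters ({len(mcg.labels)})"
        )
    if min_k < 1:
        raise ParameterError("min_k must be >= 1")
    if delta_time is None:
        delta_time = mcg.delta_time
    by_label = dict(zip(labels, sortings))
    fs = sortings[0].sampling_frequency
    delta_frames = delta_ms_to_frames(delta_time, fs)

    trains, donors = {}, {}
    next_id = 0
    components = sorted(nx.connected_components(mcg.graph),
                        key=lambda comp: min((str(a), str(b)) for a, b in comp))
    for component in components:
        if max(mcg.agreement_count(n) for n in component) < min_k:
            continue
        edges = [(a, b, d["weight"])
                 for a, b, d in mcg.graph.edges(component, data=True)]
        if not edges:
            if min_k <= 1:
                (node,) = component
                trains[next_id] = by_label[node[0]].spike_train(node[1])
                donors[next_id] = [node]
                next_id += 1
            continue
        a, b, _ = max(edges, key=lambda e: (e[2], str(e[0]), str(e[1])))
        ta = by_label[a[0]].spike_train(a[1])
        tb = by_label[b[0]].spike_train(b[1])
        trains[next_id] = _union_once(ta, tb, delta_frames)
        donors[next_id] = [list(a), list(b)]
        next_id += 1

    provenance = {
        "schema_version": SCHEMA_VERSION,
        "class": "Sorting",
        "source": {"kind": "consensus", "min_k": min_k, "delta_time": delta_time,
                   "donors": {str(u): d for u, d in donors.items()}},
        "operations": [],
    }
    return Sorting(trains, fs,
                   unit_properties={"consensus_donors": donors},
                   provenance=provenance)


def _union_once(t1: np.ndarray, t2: np.ndarray, delta_frames: int) -> np.ndarray:
    """Sorted union of two trains; spikes matching within the window are
    counted once, keeping the earlier frame."""
    i = j = 0
    out = []
    while i < t1.size and j < t2.size:
        d = t1[i] - t2[j]
        if abs(d) <= delta_frames:
            out.append(min(t1[i], t2[j]))
            i += 1
            j += 1
        elif d < 0:
            out.append(t1[i])
            i += 1
        else:
            out.append(t2[j])
            j += 1
    out.extend(t1[i:])
    out.extend(t2[j:])
    arr = np.asarray(out, dtype=np.int64)
    # pairing may leave equal frames adjacent; keep strict ordering by nudge
    for k in range(1, arr.size):
        if arr[k] <= arr[k - 1]:
            arr[k] = arr[k - 1] + 1
    return arr
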