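"""Agreement scoring, matching, ground-truth evaluation, consensus."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikekit.comparison as cmp
from spikekit import Sorting
from spikekit import synthetic as syn
from spikekit.errors import ParameterError, ValidationError
from tests.oracles import brute_force_assignment, brute_force_max_matching


def random_trains(rng, max_spikes=20, max_frame=2000):
    n1, n2 = rng.integers(0, max_spikes + 1, size=2)
    t1 = np.unique(rng.integers(0, max_frame, size=n1))
    t2 = np.unique(rng.integers(0, max_frame, size=n2))
    return t1, t2


# -- matched-spike counting -------------------------------------------------

class TestCountMatchedSpikes:
    def test_identical_trains_all_match(self):
        t = np.array([10, 50, 90])
        for delta in (0, 5, 100):
            c = cmp.count_matched_spikes(t, t, delta)
            assert c.n_matches == 3

    def test_worked_example(self):
        c = cmp.count_matched_spikes([100, 200, 300], [100, 205, 400], 12)
        assert c.n_matches == 2

    def test_injectivity(self):
        c = cmp.count_matched_spikes([100, 101], [100], 5)
        assert c.n_matches == 1

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            t1, t2 = random_trains(rng)
            delta = int(rng.integers(0, 30))
            got = cmp.count_matched_spikes(t1, t2, delta).n_matches
            assert got == brute_force_max_matching(t1, t2, delta)

    def test_unsorted_train_rejected(self):
        with pytest.raises(ValidationError):
            cmp.count_matched_spikes([100, 50], [10], 5)

    def test_negative_delta_rejected(self):
        with pytest.raises(ParameterError):
            cmp.count_matched_spikes([1], [2], -1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_window_monotonicity(self, data):
        """Widening the window never loses matches."""
        t1 = sorted(data.draw(st.sets(st.integers(0, 500), max_size=15)))
        t2 = sorted(data.draw(st.sets(st.integers(0, 500), max_size=15)))
        d1 = data.draw(st.integers(0, 40))
        d2 = data.draw(st.integers(0, 40))
        lo, hi = min(d1, d2), max(d1, d2)
        assert (cmp.count_matched_spikes(t1, t2, hi).n_matches
                >= cmp.count_matched_spikes(t1, t2, lo).n_matches)


class TestAgreementScore:
    def test_identity(self):
        assert cmp.agreement_score(cmp.MatchCounts(100, 100, 100, 0)) == 1.0

    def test_disjoint(self):
        assert cmp.agreement_score(cmp.MatchCounts(10, 20, 0, 0)) == 0.0

    def test_worked_example(self):
        assert cmp.agreement_score(cmp.MatchCounts(100, 80, 60, 0)) == 0.5

    def test_both_empty_defined_zero(self):
        assert cmp.agreement_score(cmp.MatchCounts(0, 0, 0, 0)) == 0.0

    def test_symmetry_in_counts(self):
        a = cmp.agreement_score(cmp.MatchCounts(30, 70, 20, 0))
        b = cmp.agreement_score(cmp.MatchCounts(70, 30, 20, 0))
        assert a == b

    def test_one_iff_perfect(self):
        assert cmp.agreement_score(cmp.MatchCounts(5, 5, 5, 0)) == 1.0
        assert cmp.agreement_score(cmp.MatchCounts(5, 5, 4, 0)) < 1.0


class TestAgreementMatrix:
    def test_self_comparison_diagonal_ones(self, gt_sorting):
        m = cmp.compute_agreement_matrix(gt_sorting, gt_sorting)
        np.testing.assert_allclose(np.diag(m.scores), 1.0)

    def test_empty_second_sorting(self, gt_sorting):
        empty = Sorting({}, gt_sorting.sampling_frequency)
        m = cmp.compute_agreement_matrix(gt_sorting, empty)
        assert m.scores.shape == (gt_sorting.num_units, 0)

    def test_entries_match_naive_recomputation(self):
        rng = np.random.default_rng(3)
        fs = 30000.0
        s1 = Sorting({u: np.unique(rng.integers(0, 30000, 15))
                      for u in range(3)}, fs)
        s2 = Sorting({u: np.unique(rng.integers(0, 30000, 15))
                      for u in range(2)}, fs)
        m = cmp.compute_agreement_matrix(s1, s2, delta_time=0.4)
        delta = round(0.4 * fs / 1000)
        for i, u in enumerate(s1.unit_ids):
            for j, v in enumerate(s2.unit_ids):
                nm = brute_force_max_matching(s1.spike_train(u),
                                              s2.spike_train(v), delta)
                n1, n2 = s1.num_spikes(u), s2.num_spikes(v)
                expected = nm / (n1 + n2 - nm) if n1 + n2 - nm else 0.0
                assert m.scores[i, j] == pytest.approx(expected)

    def test_transpose_symmetry(self, gt_sorting):
        other = syn.corrupt_sorting(gt_sorting,
                                    syn.CorruptionSpec(miss_prob=0.2, seed=1))
        ab = cmp.compute_agreement_matrix(gt_sorting, other)
        ba = cmp.compute_agreement_matrix(other, gt_sorting)
        np.testing.assert_allclose(ab.scores, ba.scores.T)

    def test_mismatched_fs_rejected(self, gt_sorting):
        other = Sorting({0: [1, 2, 3]}, 20000.0)
        with pytest.raises(ValidationError):
            cmp.compute_agreement_matrix(gt_sorting, other)


class TestHungarianMatch:
    def _matrix(self, scores, row_ids=None, col_ids=None):
        scores = np.asarray(scores, dtype=float)
        rows = row_ids or list(range(scores.shape[0]))
        cols = col_ids or list(range(scores.shape[1]))
        return cmp.AgreementMatrix(rows, cols, scores)

    def test_two_by_two(self):
        m = self._matrix([[0.9, 0.1], [0.2, 0.8]])
        a, b = cmp.hungarian_match(m, min_score=0.0)
        assert a.matches == {0: 0, 1: 1}
        assert a.scores[0] + a.scores[1] == pytest.approx(1.7)
        assert b.matches == {0: 0, 1: 1}

    def test_identity_matrix(self):
        m = self._matrix(np.eye(4))
        a, _ = cmp.hungarian_match(m, min_score=0.0)
        assert a.matches == {i: i for i in range(4)}

    def test_threshold_discards_all(self):
        m = self._matrix(np.full((3, 3), 0.3))
        a, b = cmp.hungarian_match(m, min_score=0.5)
        assert all(v is cmp.UNMATCHED for v in a.matches.values())
        assert all(v is cmp.UNMATCHED for v in b.matches.values())

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            shape = rng.integers(1, 6, size=2)
            scores = rng.random(shape)
            a, _ = cmp.hungarian_match(
                cmp.AgreementMatrix(list(range(shape[0])),
                                    list(range(shape[1])), scores),
                min_score=0.0)
            total = sum(a.scores[u] for u in a.matches)
            assert total == pytest.approx(brute_force_assignment(scores),
                                          abs=1e-9)

    def test_mutual_consistency(self):
        rng = np.random.default_rng(5)
        scores = rng.random((4, 6))
        a, b = cmp.hungarian_match(
            cmp.AgreementMatrix(list("abcd"), list(range(6)), scores), 0.2)
        for u, v in a.matches.items():
            if v is not cmp.UNMATCHED:
                assert b.matches[v] == u


class TestBestMatch:
    def test_threshold_filter_and_order(self):
        m = cmp.AgreementMatrix([0], [1, 2, 3],
                                np.array([[0.6, 0.3, 0.55]]))
        result = cmp.best_match(m, min_score=0.5)
        assert result[0] == [(1, 0.6), (3, 0.55)]

    def test_high_threshold_empty(self):
        m = cmp.AgreementMatrix([0], [1, 2, 3],
                                np.array([[0.6, 0.3, 0.55]]))
        assert cmp.best_match(m, min_score=0.7)[0] == []

    def test_matches_naive_scan(self):
        rng = np.random.default_rng(6)
        scores = rng.random((5, 7))
        m = cmp.AgreementMatrix(list(range(5)), list(range(7)), scores)
        result = cmp.best_match(m, min_score=0.4)
        for i in range(5):
            expected = sorted(
                [(j, scores[i, j]) for j in range(7) if scores[i, j] >= 0.4],
                key=lambda p: -p[1])
            assert result[i] == [(j, pytest.approx(s)) for j, s in expected]


class TestSpikeLabels:
    def test_identical_trains(self):
        c = cmp.label_spikes([1, 2, 3], [1, 2, 3], 0)
        assert (c.tp, c.fn, c.fp) == (3, 0, 0)

    def test_empty_tested(self):
        c = cmp.label_spikes([10, 20, 30], [], 5)
        assert (c.tp, c.fn, c.fp) == (0, 3, 0)

    def test_worked_example(self):
        c = cmp.label_spikes([100, 200, 300, 400], [100, 200, 505], 12)
        assert (c.tp, c.fn, c.fp) == (2, 2, 1)

    def test_conservation(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t1, t2 = random_trains(rng)
            c = cmp.label_spikes(t1, t2, int(rng.integers(0, 20)))
            assert c.tp + c.fn == t1.size
            assert c.tp + c.fp == t2.size


class TestPerformanceMeasures:
    def test_printed_formulas(self):
        p = cmp.performance_measures(cmp.SpikeLabelCounts(8, 1, 1))
        assert p["accuracy"] == pytest.approx(0.8)
        assert p["recall"] == pytest.approx(8 / 9)
        assert p["precision"] == pytest.approx(8 / 9)
        assert p["miss_rate"] == pytest.approx(1 / 9)
        assert p["false_discovery_rate"] == pytest.approx(1 / 9)

    def test_perfect_and_zero(self):
        perfect = cmp.performance_measures(cmp.SpikeLabelCounts(50, 0, 0))
        assert perfect["accuracy"] == 1.0 and perfect["miss_rate"] == 0.0
        zero = cmp.performance_measures(cmp.SpikeLabelCounts(0, 5, 5))
        assert zero["accuracy"] == 0.0

    def test_identities_on_grid(self):
        for tp, fn, fp in itertools.product(range(0, 9, 2), repeat=3):
            if tp + fn + fp == 0:
                continue
            p = cmp.performance_measures(cmp.SpikeLabelCounts(tp, fn, fp))
            if tp + fn:
                assert p["recall"] == pytest.approx(1 - p["miss_rate"])
            if tp + fp:
                assert p["precision"] == pytest.approx(
                    1 - p["false_discovery_rate"])
            if tp + fn and tp + fp:
                assert p["accuracy"] <= min(p["precision"], p["recall"]) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ParameterError):
            cmp.performance_measures(cmp.SpikeLabelCounts(0, 0, 0))


class TestGroundTruthComparison:
    def test_self_comparison_perfect(self, gt_sorting):
        result = cmp.compare_with_ground_truth(gt_sorting, gt_sorting)
        assert np.allclose(result.performance["accuracy"], 1.0)
        assert all(c == "well_detected"
                   for c in result.classification.categories.values())

    def test_extra_unit_is_false_positive(self, gt_sorting):
        rng = np.random.default_rng(8)
        trains = {u: gt_sorting.spike_train(u) for u in gt_sorting.unit_ids}
        trains["extra"] = np.unique(rng.integers(0, 900000, 200))
        tested = Sorting(trains, gt_sorting.sampling_frequency)
        result = cmp.compare_with_ground_truth(gt_sorting, tested)
        assert result.classification.categories["extra"] == "false_positive"

    def test_split_unit_better_half_matched_other_redundant(self, gt_sorting):
        tested = syn.corrupt_sorting(
            gt_sorting, syn.CorruptionSpec(split_units=[0], seed=0))
        result = cmp.compare_with_ground_truth(gt_sorting, tested,
                                               min_score=0.0)
        cats = {u: c for u, c in result.classification.categories.items()
                if str(u).startswith("0_split")}
        assert sorted(cats.values()) == ["redundant", "weak_match"]
        # each half has about a third of the union agreement with gt
        half_scores = [result.agreement.score(0, u) for u in cats]
        assert all(0.2 < s < 0.65 for s in half_scores)

    def test_unmatched_gt_unit_has_zero_recall(self, gt_sorting):
        tested = gt_sorting.select_units(gt_sorting.unit_ids[:-1])
        result = cmp.compare_with_ground_truth(gt_sorting, tested)
        missing = gt_sorting.unit_ids[-1]
        row = result.performance.set_index("gt_unit").loc[missing]
        assert row["recall"] == 0.0

    def test_best_match_method_returns_multimatches(self, gt_sorting):
        tested = syn.corrupt_sorting(
            gt_sorting, syn.CorruptionSpec(merge_unit_pairs=[(0, 1)], seed=0))
        result = cmp.compare_with_ground_truth(gt_sorting, tested,
                                               method="best", min_score=0.2)
        merged = [u for u in tested.unit_ids if "+" in str(u)][0]
        assert len(result.tested_matches[merged]) == 2


class TestClassification:
    def _bundle(self, scores, min_score=0.5):
        matrix = cmp.AgreementMatrix(
            [f"gt{i}" for i in range(scores.shape[0])],
            [f"t{j}" for j in range(scores.shape[1])],
            np.asarray(scores, dtype=float))
        gt_m, _ = cmp.hungarian_match(matrix, min_score)
        return matrix, gt_m

    def test_well_detected(self):
        matrix, gt_m = self._bundle(np.array([[0.85]]))
        cats = cmp.classify_units(matrix, gt_m).categories
        assert cats["t0"] == "well_detected"

    def test_unmatched_is_false_positive(self):
        matrix, gt_m = self._bundle(np.array([[0.9, 0.05]]))
        cats = cmp.classify_units(matrix, gt_m).categories
        assert cats["t1"] == "false_positive"

    def test_overmerged_two_gt_partners(self):
        matrix, gt_m = self._bundle(np.array([[0.45], [0.30]]))
        cats = cmp.classify_units(matrix, gt_m).categories
        assert cats["t0"] == "overmerged"

    def test_redundant_not_best_match(self):
        # t0 is the assigned partner; t1 also agrees with gt0 above 0.2
        matrix, gt_m = self._bundle(np.array([[0.9, 0.4]]))
        cats = cmp.classify_units(matrix, gt_m).categories
        assert cats["t0"] == "well_detected"
        assert cats["t1"] == "redundant"

    def test_weak_match_between_thresholds(self):
        matrix, gt_m = self._bundle(np.array([[0.6]]))
        cats = cmp.classify_units(matrix, gt_m).categories
        assert cats["t0"] == "weak_match"

    def test_thresholds_adjustable(self):
        matrix, gt_m = self._bundle(np.array([[0.6]]))
        cats = cmp.classify_units(matrix, gt_m,
                                  well_detected_threshold=0.5).categories
        assert cats["t0"] == "well_detected"


class TestMultiComparison:
    def test_identical_sortings_all_k2(self, gt_sorting):
        mcg = cmp.compare_multiple([gt_sorting, gt_sorting], ["a", "b"])
        assert all(mcg.agreement_count(n) == 2 for n in mcg.graph.nodes)

    def test_planted_shared_and_private_units(self):
        gt = syn.generate_gt_sorting(
            syn.GroundTruthSpec(n_units=5, duration_s=60, seed=21))
        sortings = [
            syn.corrupt_sorting(gt, syn.CorruptionSpec(miss_prob=0.05,
                                                       n_noise_units=2,
                                                       seed=100 + s))
            for s in range(3)
        ]
        mcg = cmp.compare_multiple(sortings)
        for node in mcg.graph.nodes:
            expected = 1 if str(node[1]).startswith("noise") else 3
            assert mcg.agreement_count(node) == expected

    def test_pairwise_injectivity(self):
        gt = syn.generate_gt_sorting(
            syn.GroundTruthSpec(n_units=6, duration_s=30, seed=22))
        sortings = [syn.corrupt_sorting(gt, syn.CorruptionSpec(
            miss_prob=0.1, seed=s)) for s in range(3)]
        mcg = cmp.compare_multiple(sortings)
        for a, b in itertools.combinations(mcg.labels, 2):
            partners = [nbr for node in mcg.nodes_for(a)
                        for nbr in mcg.graph.neighbors(node) if nbr[0] == b]
            assert len(partners) == len(set(partners))

    def test_duplicate_labels_rejected(self, gt_sorting):
        with pytest.raises(ParameterError):
            cmp.compare_multiple([gt_sorting, gt_sorting], ["x", "x"])


class TestAgreementCounts:
    def test_identical_sortings(self, gt_sorting):
        mcg = cmp.compare_multiple([gt_sorting] * 3, ["a", "b", "c"])
        groups, per_sorter = cmp.agreement_counts(mcg)
        assert groups[3] == gt_sorting.num_units
        assert groups[1] == 0 and groups[2] == 0
        for label in "abc":
            assert per_sorter.loc[label, 3] == gt_sorting.num_units

    def test_disjoint_sortings_all_k1(self):
        fs = 30000.0
        s1 = Sorting({0: np.arange(100, 10000, 500)}, fs)
        s2 = Sorting({0: np.arange(300000, 310000, 500)}, fs)
        mcg = cmp.compare_multiple([s1, s2])
        groups, per_sorter = cmp.agreement_counts(mcg)
        assert groups[1] == 2
        assert per_sorter.to_numpy().sum(axis=1).tolist() == [1, 1]

    def test_per_sorter_rows_sum_to_unit_counts(self):
        gt = syn.generate_gt_sorting(
            syn.GroundTruthSpec(n_units=4, duration_s=30, seed=23))
        sortings = [syn.corrupt_sorting(gt, syn.CorruptionSpec(
            miss_prob=0.2, n_noise_units=1, seed=s)) for s in range(3)]
        mcg = cmp.compare_multiple(sortings)
        _, per_sorter = cmp.agreement_counts(mcg)
        for label, sorting in zip(mcg.labels, sortings):
            assert per_sorter.loc[label].sum() == sorting.num_units


class TestConsensus:
    def test_two_identical_units(self, gt_sorting):
        mcg = cmp.compare_multiple([gt_sorting, gt_sorting], ["a", "b"])
        cons = cmp.build_consensus_sorting(mcg, [gt_sorting, gt_sorting],
                                           ["a", "b"])
        assert cons.num_units == gt_sorting.num_units
        totals = sorted(cons.spike_train(u).size for u in cons.unit_ids)
        assert totals == sorted(gt_sorting.num_spikes(u)
                                for u in gt_sorting.unit_ids)

    def test_complementary_misses_recovered(self):
        """Two sorters missing disjoint 10% subsets cover ~99% together."""
        gt = syn.generate_gt_sorting(
            syn.GroundTruthSpec(n_units=1, firing_rate_hz=10, duration_s=300,
                                seed=31))
        train = gt.spike_train(0)
        rng = np.random.default_rng(31)
        drop_a = rng.choice(train.size, train.size // 10, replace=False)
        remaining = np.setdiff1d(np.arange(train.size), drop_a)
        drop_b = rng.choice(remaining, train.size // 10, replace=False)
        sa = Sorting({0: np.delete(train, drop_a)}, gt.sampling_frequency)
        sb = Sorting({0: np.delete(train, drop_b)}, gt.sampling_frequency)
        mcg = cmp.compare_multiple([sa, sb], ["a", "b"])
        cons = cmp.build_consensus_sorting(mcg, [sa, sb], ["a", "b"])
        delta = cmp.delta_ms_to_frames(0.4, gt.sampling_frequency)
        recovered = cmp.count_matched_spikes(train, cons.spike_train(0),
                                             delta).n_matches
        assert recovered / train.size >= 0.99

    def test_three_sorter_component_emits_one_unit(self, gt_sorting):
        sortings = [gt_sorting] * 3
        mcg = cmp.compare_multiple(sortings, ["a", "b", "c"])
        cons = cmp.build_consensus_sorting(mcg, sortings, ["a", "b", "c"])
        assert cons.num_units == gt_sorting.num_units
        for donors in cons.unit_properties["consensus_donors"].values():
            assert len(donors) == 2

    def test_min_k_excludes_private_units(self):
        gt = syn.generate_gt_sorting(
            syn.GroundTruthSpec(n_units=3, duration_s=60, seed=32))
        sortings = [syn.corrupt_sorting(gt, syn.CorruptionSpec(
            n_noise_units=2, seed=s)) for s in range(2)]
        mcg = cmp.compare_multiple(sortings)
        cons = cmp.build_consensus_sorting(mcg, sortings, min_k=2)
        assert cons.num_units == 3

    def test_min_k_above_sorter_count_rejected(self, gt_sorting):
        mcg = cmp.compare_multiple([gt_sorting, gt_sorting], ["a", "b"])
        with pytest.raises(ParameterError):
            cmp.build_consensus_sorting(mcg, [gt_sorting, gt_sorting],
                                        ["a", "b"], min_k=3)

    def test_matched_duplicates_counted_once_keeping_earlier(self):
        fs = 30000.0
        sa = Sorting({0: [100, 1000, 2000]}, fs)
        sb = Sorting({0: [105, 1000, 3000]}, fs)
        mcg = cmp.compare_multiple([sa, sb], ["a", "b"])
        cons = cmp.build_consensus_sorting(mcg, [sa, sb], ["a", "b"])
        np.testing.assert_array_equal(cons.spike_train(0),
                                      [100, 1000, 2000, 3000])
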