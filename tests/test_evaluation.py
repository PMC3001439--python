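from collections import deque

import pytest

from etadiffuse import (
    LabelTable,
    ablation_negative_labels,
    accuracy_at_coverage,
    accuracy_coverage_curve,
    accuracy_percent,
    competitive_annotate,
    false_positive_fold_change,
    sensitivity_precision_curve,
    shortest_path_function_histogram,
)
from etadiffuse.annotate import Prediction

from conftest import network_from_edges


def pred(node, function, z):
    return Prediction(node=node, function=function, confidence=z, method="diffusion")


@pytest.fixture
def four_predictions():
    """Confidences (3, 2, 1, 0.5), correctness (T, T, F, T) against truth."""
    truth = LabelTable({
        "n1": ["1.1.1.1"], "n2": ["1.1.1.1"], "n3": ["1.1.1.1"], "n4": ["2.1.1.1"],
    })
    preds = [
        pred("n1", "1.1.1.1", 3.0),
        pred("n2", "1.1.1.1", 2.0),
        pred("n3", "9.9.9.9", 1.0),   # false positive
        pred("n4", "2.1.1.1", 0.5),
    ]
    return preds, truth


class TestCurves:
    def test_hand_enumerated_accuracy_coverage(self, four_predictions):
        preds, truth = four_predictions
        curve = accuracy_coverage_curve(preds, truth, level=4, test_size=4)
        assert [p.accuracy for p in curve] == [1.0, 1.0, 2.0 / 3.0, 3.0 / 4.0]
        assert [p.coverage for p in curve] == [0.25, 0.5, 0.75, 1.0]
        assert [(p.tp, p.fp) for p in curve] == [(1, 0), (2, 0), (2, 1), (3, 1)]

    def test_hand_enumerated_sensitivity(self, four_predictions):
        """3 correct in total: fn counts correct predictions below cutoff."""
        preds, truth = four_predictions
        curve = sensitivity_precision_curve(preds, truth, level=4, test_size=4)
        assert [p.fn for p in curve] == [2, 1, 1, 0]
        assert [p.sensitivity for p in curve] == pytest.approx(
            [1 / 3, 2 / 3, 2 / 3, 1.0])
        assert curve[-1].sensitivity == 1.0  # full acceptance: fn = 0
        assert [p.precision for p in curve] == [p.accuracy for p in curve]

    def test_all_correct_gives_unit_accuracy_everywhere(self):
        truth = LabelTable({"n1": ["1.1.1.1"], "n2": ["1.1.1.1"]})
        preds = [pred("n1", "1.1.1.1", 2.0), pred("n2", "1.1.1.1", 1.0)]
        curve = accuracy_coverage_curve(preds, truth, level=4, test_size=2)
        assert all(p.accuracy == 1.0 for p in curve)

    def test_match_any_truth_ec(self):
        """A promiscuous chain is correct if any of its ECs matches."""
        truth = LabelTable({"n1": ["1.1.1.1", "5.4.3.2"]})
        curve = accuracy_coverage_curve(
            [pred("n1", "5.4.3.2", 1.0)], truth, level=4, test_size=1)
        assert curve[0].accuracy == 1.0

    def test_equal_confidences_enter_together(self):
        truth = LabelTable({"n1": ["1.1.1.1"], "n2": ["1.1.1.1"]})
        preds = [pred("n1", "1.1.1.1", 1.0), pred("n2", "9.9.9.9", 1.0)]
        curve = accuracy_coverage_curve(preds, truth, level=4, test_size=2)
        assert len(curve) == 1
        assert curve[0].accuracy == 0.5

    def test_cumulative_count_integrality(self, four_predictions):
        preds, truth = four_predictions
        for point in accuracy_coverage_curve(preds, truth, level=4, test_size=4):
            made = point.tp + point.fp
            assert made == round(point.coverage * 4)
            assert point.accuracy * made == pytest.approx(point.tp)

    def test_test_size_smaller_than_predictions_errors(self, four_predictions):
        preds, truth = four_predictions
        with pytest.raises(ValueError, match="test_size"):
            accuracy_coverage_curve(preds, truth, level=4, test_size=3)

    def test_missing_truth_entry_errors(self):
        with pytest.raises(ValueError, match="no truth entry"):
            accuracy_coverage_curve(
                [pred("ghost", "1.1.1.1", 1.0)], LabelTable(), level=4, test_size=1)

    def test_accuracy_at_coverage_picks_deepest_eligible_point(self, four_predictions):
        preds, truth = four_predictions
        curve = accuracy_coverage_curve(preds, truth, level=4, test_size=4)
        assert accuracy_at_coverage(curve, 0.5) == 1.0
        assert accuracy_at_coverage(curve, 0.8) == pytest.approx(2 / 3)
        assert accuracy_at_coverage(curve, 0.1) == 1.0  # falls back to first point


class TestWorkedArithmetic:
    def test_accuracy_percent(self):
        assert accuracy_percent(3, 4) == 75.0
        with pytest.raises(ValueError):
            accuracy_percent(5, 4)

    def test_fold_change(self):
        assert false_positive_fold_change(48, 12) == 4.0
        with pytest.raises(ValueError):
            false_positive_fold_change(48, 0)


class TestAblation:
    def test_single_function_ablation_is_noop(self, bridge):
        """With one function there are no possible negative labels."""
        dataset, net = bridge
        result = ablation_negative_labels(
            net, dataset.labels, ["q0"], dataset.truth, alpha=1.0, level=4)
        assert result.with_negatives == result.without_negatives

    def test_negative_labels_flip_bridge_query(self, two_cluster_flip):
        """On the frozen 6-node two-cluster fixture, the query's winning
        function differs with vs without negative labels."""
        net, labels = two_cluster_flip
        with_neg = competitive_annotate(net, labels, ["q"], alpha=1.0,
                                        level=4, use_negatives=True)
        without = competitive_annotate(net, labels, ["q"], alpha=1.0,
                                       level=4, use_negatives=False)
        assert with_neg[0].function == "1.1.1.1"
        assert without[0].function == "2.1.1.1"

    def test_accuracy_difference_table(self, two_cluster_flip):
        net, labels = two_cluster_flip
        truth = LabelTable({"q": ["1.1.1.1"]})
        result = ablation_negative_labels(net, labels, ["q"], truth,
                                          alpha=1.0, level=4)
        diff = result.accuracy_difference([1.0])
        assert diff.loc[0, "with_negatives"] == 1.0
        assert diff.loc[0, "without_negatives"] == 0.0
        assert diff.loc[0, "difference"] == 1.0


def bfs_distances(adjacency, start):
    """Independent hop-count oracle (plain queue BFS on a dict graph)."""
    dist = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for neighbor in adjacency[node]:
            if neighbor not in dist:
                dist[neighbor] = dist[node] + 1
                queue.append(neighbor)
    return dist


class TestPathHistogram:
    def test_chain_distance_two_between_same_function(self):
        net = network_from_edges(["A", "B", "C"], {("A", "B"): 0.5, ("B", "C"): 0.5})
        truth = LabelTable({"A": ["1.1.1.1"], "C": ["1.1.1.1"]})
        hist = shortest_path_function_histogram(
            net, truth, [pred("A", "1.1.1.1", 0.5)], level=4)
        same = hist[hist.same_function]
        assert same.distance.tolist() == [2]
        assert same["count"].tolist() == [1]

    def test_disconnected_pairs_excluded(self):
        net = network_from_edges(["A", "B", "C", "D"],
                                 {("A", "B"): 0.5, ("C", "D"): 0.5})
        truth = LabelTable({"A": ["1.1.1.1"], "C": ["1.1.1.1"]})
        hist = shortest_path_function_histogram(
            net, truth, [pred("A", "1.1.1.1", 0.5)], level=4)
        assert hist.empty  # only A-C pair exists and it is unreachable

    def test_against_exhaustive_bfs_oracle(self, planted_small):
        """Totals per (distance, same-function) recomputed by plain BFS."""
        dataset, net = planted_small
        truth = dataset.truth
        # give all labeled+truth nodes to the truth table used for distances
        merged = LabelTable({**{c: [str(e) for e in dataset.labels[c]]
                                for c in dataset.labels},
                             **{c: [str(e) for e in truth[c]] for c in truth}})
        preds = competitive_annotate(net, dataset.labels, dataset.queries,
                                     alpha=1.0, level=4)
        hist = shortest_path_function_histogram(net, merged, preds, level=4)

        adjacency = {n: [] for n in net.nodes}
        for (a, b) in net.edges:
            adjacency[a].append(b)
            adjacency[b].append(a)
        expected: dict[tuple[int, bool], int] = {}
        correct = [p for p in preds
                   if p.function in merged.node_functions(p.node, 4)]
        labeled = [n for n in net.nodes if merged.node_functions(n, 4)]
        for p in correct:
            dist = bfs_distances(adjacency, p.node)
            for other in labeled:
                if other == p.node or other not in dist:
                    continue
                same = p.function in merged.node_functions(other, 4)
                key = (dist[other], same)
                expected[key] = expected.get(key, 0) + 1
        observed = (hist.groupby(["distance", "same_function"])["count"]
                    .sum().to_dict())
        assert observed == expected

    def test_same_function_pairs_are_closer_on_planted_networks(self, planted_small):
        """Functions cluster: mean same-function hop distance is below the
        mean different-function distance when p_in >> p_out."""
        dataset, net = planted_small
        merged = LabelTable({**{c: [str(e) for e in dataset.labels[c]]
                                for c in dataset.labels},
                             **{c: [str(e) for e in dataset.truth[c]]
                                for c in dataset.truth}})
        preds = competitive_annotate(net, dataset.labels, dataset.queries,
                                     alpha=1.0, level=4)
        hist = shortest_path_function_histogram(net, merged, preds, level=4)
        means = hist.groupby("same_function").apply(
            lambda g: (g.distance * g["count"]).sum() / g["count"].sum(),
            include_groups=False)
        assert means[True] <= means[False]
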