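"""Confidence-stratified evaluation: accuracy/coverage and
sensitivity/precision curves, the negative-label ablation, and
shortest-path diagnostics.

Predictions are sorted by descending confidence and a cumulative point is
recorded at every distinct confidence value: accuracy = tp/(tp+fp),
coverage = (tp+fp)/test_size, sensitivity = tp/(tp+fn) where any correct
prediction whose confidence falls below the threshold counts as a false
negative, and precision = tp/(tp+fp). A prediction is correct if its
function matches ANY of the truth ECs truncated to the evaluation level
(promiscuous enzymes carry several ECs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .annotate import Prediction, competitive_annotate
from .labels import LabelTable
from .match_graph import SimilarityNetwork

__all__ = [
    "CurvePoint",
    "is_correct",
    "accuracy_percent",
    "false_positive_fold_change",
    "accuracy_coverage_curve",
    "sensitivity_precision_curve",
    "accuracy_at_coverage",
    "AblationResult",
    "ablation_negative_labels",
    "shortest_path_function_histogram",
]


@dataclass(frozen=True)
class CurvePoint:
    """Cumulative counts and rates at one confidence threshold."""

    threshold: float
    tp: int
    fp: int
    fn: int
    accuracy: float
    coverage: float
    sensitivity: float
    precision: float


def is_correct(prediction: Prediction, truth: LabelTable, level: int) -> bool:
    """Match-any-truth-EC correctness at the evaluation level."""
    return prediction.function in truth.node_functions(prediction.node, level)


def accuracy_percent(n_correct: int, n_predictions: int) -> float:
    """Accuracy as a percentage: 100 * correct / predictions made."""
    if n_predictions <= 0:
        raise ValueError("n_predictions must be positive")
    if not 0 <= n_correct <= n_predictions:
        raise ValueError("n_correct must lie in [0, n_predictions]")
    return 100.0 * n_correct / n_predictions

def false_positive_fold_change(fp_baseline: int, fp_method: int) -> float:
    """How many-fold fewer false positives the method makes than a baseline."""
    if fp_method <= 0 or fp_baseline < 0:
        raise ValueError("false-positive counts must be positive")
    return fp_baseline / fp_method


def _curve(
    predictions: Sequence[Prediction], truth: LabelTable, level: int, test_size: int
) -> list[CurvePoint]:
    if test_size < len(predictions):
        raise ValueError(
            f"test_size {test_size} smaller than {len(predictions)} predictions"
        )
    for p in predictions:
        if p.node not in truth:
            raise ValueError(f"prediction node {p.node!r} has no truth entry")
    ranked = sorted(predictions, key=lambda p: -p.confidence)
    total_correct = sum(is_correct(p, truth, level) for p in ranked)

    points: list[CurvePoint] = []
    tp = fp = 0
    i = 0
    n = len(ranked)
    while i < n:
        threshold = ranked[i].confidence
        # equal-confidence predictions enter the curve together
        while i < n and ranked[i].confidence == threshold:
            if is_correct(ranked[i], truth, level):
                tp += 1
            else:
                fp += 1
            i += 1
        fn = total_correct - tp
        made = tp + fp
        points.append(
            CurvePoint(
                threshold=threshold,
                tp=tp,
                fp=fp,
                fn=fn,
                accuracy=tp / made,
                coverage=made / test_size,
                sensitivity=tp / total_correct if total_correct else 0.0,
                precision=tp / made,
            )
        )
    return points


def accuracy_coverage_curve(
    predictions: Sequence[Prediction], truth: LabelTable, level: int, test_size: int
) -> list[CurvePoint]:
    """Cumulative accuracy vs coverage, one point per distinct confidence."""
    return _curve(predictions, truth, level, test_size)


def sensitivity_precision_curve(
    predictions: Sequence[Prediction], truth: LabelTable, level: int, test_size: int
) -> list[CurvePoint]:
    """Cumulative sensitivity and precision, stepping down thresholds.

    Shares the bookkeeping of :func:`accuracy_coverage_curve`; correct
    predictions below the threshold are false negatives.
    """
    return _curve(predictions, truth, level, test_size)


def accuracy_at_coverage(curve: Sequence[CurvePoint], coverage: float) -> float:
    """Accuracy of the deepest curve point with coverage <= the target.

    Falls back to the first (most confident) point if even it overshoots.
    """
    if not curve:
        raise ValueError("empty curve")
    eligible = [p for p in curve if p.coverage <= coverage + 1e-12]
    return (eligible[-1] if eligible else curve[0]).accuracy


@dataclass
class AblationResult:
    """Paired accuracy/coverage curves with and without negative labels."""

    with_negatives: list[CurvePoint]
    without_negatives: list[CurvePoint]

    def accuracy_difference(self, coverages: Iterable[float]) -> pd.DataFrame:
        rows = []
        for c in coverages:
            a_with = accuracy_at_coverage(self.with_negatives, c)
            a_without = accuracy_at_coverage(self.without_negatives, c)
            rows.append(
                {"coverage": c, "with_negatives": a_with,
                 "without_negatives": a_without, "difference": a_with - a_without}
            )
        return pd.DataFrame(rows)


def ablation_negative_labels(
    network: SimilarityNetwork,
    labels: LabelTable,
    queries,
    truth: LabelTable,
    alpha: float = 1.0,
    level: int = 4,
    test_size: int | None = None,
    holdout: str = "batch",
) -> AblationResult:
    """Run competitive diffusion with and without -1 labels and compare.

    Negative labels state that a protein is known to perform some *other*
    function; ablating them quantifies how much that knowledge contributes.
    """
    queries = list(queries)
    if test_size is None:
        test_size = len(queries)
    curves = {}
    for use_negatives in (True, False):
        preds = competitive_annotate(
            network, labels, queries, alpha=alpha, level=level,
            use_negatives=use_negatives, holdout=holdout,
        )
        curves[use_negatives] = accuracy_coverage_curve(preds, truth, level, test_size)
    return AblationResult(with_negatives=curves[True], without_negatives=curves[False])


def shortest_path_function_histogram(
    network: SimilarityNetwork,
    truth: LabelTable,
    predictions: Sequence[Prediction],
    level: int = 4,
    z_edges: Sequence[float] = (0.0, 1.0, 2.0, 3.0),
) -> pd.DataFrame:
    """Hop distances from correctly predicted nodes to labeled nodes.

    For every correct prediction, unweighted shortest-path lengths to every
    labeled node are recorded, split into same-function vs
    different-function at the evaluation level and binned by the
    prediction's confidence z. Unreachable pairs are dropped. Returns a
    tidy frame with columns ``z_bin, distance, same_function, count``.
    """
    g = network.to_networkx()
    edges = [-math.inf, *z_edges, math.inf]

    def _bin(z: float) -> str:
        for lo, hi in zip(edges, edges[1:]):
            if lo <= z < hi:
                lo_s = f"{lo:g}" if math.isfinite(lo) else "-inf"
                hi_s = f"{hi:g}" if math.isfinite(hi) else "inf"
                return f"[{lo_s},{hi_s})"
        raise AssertionError("unreachable")

    rows: dict[tuple[str, int, bool], int] = {}
    labeled = [n for n in network.nodes if truth.node_functions(n, level)]
    for pred in predictions:
        if not is_correct(pred, truth, level):
            continue
        dist = nx.single_source_shortest_path_length(g, pred.node)
        bin_name = _bin(pred.confidence)
        for other in labeled:
            if other == pred.node:
                continue
            d = dist.get(other)
            if d is None:
                continue  # infinite distances are ignored
            same = pred.function in truth.node_functions(other, level)
            key = (bin_name, d, same)
            rows[key] = rows.get(key, 0) + 1
    frame = pd.DataFrame(
        [
            {"z_bin": b, "distance": d, "same_function": s, "count": c}
            for (b, d, s), c in sorted(rows.items())
        ],
        columns=["z_bin", "distance", "same_function", "count"],
    )
    return frame
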