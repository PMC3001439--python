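"""Replicated planted-partition benchmarks.

Desk-scale stand-ins for the large template-match benchmark networks:
generate a planted benchmark per seed, annotate the withheld half of each
function block with both the diffusion and the nearest-neighbor method,
and return confidence-stratified curves per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotate import competitive_annotate, nearest_neighbor_annotate
from .evaluation import (
    CurvePoint,
    ablation_negative_labels,
    accuracy_at_coverage,
    accuracy_coverage_curve,
)
from .match_graph import build_network
from .synthetic import PlantedConfig, planted_function_network

__all__ = ["ReplicateResult", "run_planted_replicates", "run_ablation_replicates",
           "mean_accuracy_at"]


@dataclass
class ReplicateResult:
    """Curves for one planted replicate (both annotation methods)."""

    seed: int
    diffusion: list[CurvePoint]
    nearest_neighbor: list[CurvePoint]


def run_planted_replicates(
    seeds,
    config: PlantedConfig | None = None,
    alpha: float = 1.0,
    level: int = 4,
) -> list[ReplicateResult]:
    """Diffusion vs nearest-neighbor curves on one planted benchmark per seed."""
    base = config or PlantedConfig()
    out = []
    for seed in seeds:
        dataset = planted_function_network(replace(base, seed=int(seed)))
        net = build_network(dataset.records)
        n = len(dataset.queries)
        diff = competitive_annotate(net, dataset.labels, dataset.queries,
                                    alpha=alpha, level=level)
        nn = nearest_neighbor_annotate(net, dataset.labels, dataset.queries,
                                       level=level)
        out.append(
            ReplicateResult(
                seed=int(seed),
                diffusion=accuracy_coverage_curve(diff, dataset.truth, level, n),
                nearest_neighbor=accuracy_coverage_curve(nn, dataset.truth, level, n),
            )
        )
    return out


def run_ablation_replicates(
    seeds,
    config: PlantedConfig | None = None,
    alpha: float = 1.0,
    level: int = 4,
    coverage: float = 0.5,
) -> "np.ndarray":
    """Per-seed (with-negatives, without-negatives) accuracy at a coverage."""
    base = config or PlantedConfig()
    rows = []
    for seed in seeds:
        dataset = planted_function_network(replace(base, seed=int(seed)))
        net = build_network(dataset.records)
        result = ablation_negative_labels(
            net, dataset.labels, dataset.queries, dataset.truth,
            alpha=alpha, level=level,
        )
        rows.append(
            (accuracy_at_coverage(result.with_negatives, coverage),
             accuracy_at_coverage(result.without_negatives, coverage))
        )
    return np.array(rows)


def mean_accuracy_at(results, coverage: float, method: str = "diffusion") -> float:
    """Mean accuracy over replicates at one coverage for one method."""
    curves = [getattr(r, method) for r in results]
    return float(np.mean([accuracy_at_coverage(c, coverage) for c in curves]))
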