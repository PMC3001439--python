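"""Build a weighted protein-similarity network from template-match records.

Each directional match record reports how well one protein's structural
template (six evolutionarily important surface residues) superposes onto
another protein: the RMSD of the superposition (Å) and an evolutionary
similarity score (ETScore). Smaller values of both indicate a better match.

Edges are created only for *reciprocal* matches (A matched B and B matched
A), the per-pair RMSD and ETScore are averaged over the two directions, and
the averaged quantities are standardized against the full record set and
mapped through a logistic so that every stored weight lies strictly in
(0, 1): better-than-average matches score above 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "MatchRecord",
    "MatchStats",
    "EdgeData",
    "SimilarityNetwork",
    "compute_match_statistics",
    "edge_weight",
    "build_network",
    "filter_by_identity",
]

Pair = tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class MatchRecord:
    """One directional template match (query's template found in target)."""

    query_id: str
    target_id: str
    rmsd: float
    et_score: float

    def __post_init__(self) -> None:
        if self.query_id == self.target_id:
            raise ValueError(f"self-match rejected: {self.query_id!r}")
        if not math.isfinite(self.rmsd) or self.rmsd < 0:
            raise ValueError(f"rmsd must be finite and >= 0, got {self.rmsd}")
        if not math.isfinite(self.et_score):
            raise ValueError(f"et_score must be finite, got {self.et_score}")


@dataclass(frozen=True)
class MatchStats:
    """Mean and population SD of rmsd and ETScore over directional records."""

    mu_rmsd: float
    sigma_rmsd: float
    mu_et: float
    sigma_et: float


def compute_match_statistics(records: Iterable[MatchRecord]) -> MatchStats:
    """Population statistics of rmsd and ETScore over all directional records.

    Statistics are taken over the raw directional records, before any
    reciprocal collapsing, and use the divide-by-n (population) SD.
    """
    records = list(records)
    if not records:
        raise ValueError("no matches")
    rmsd = np.array([r.rmsd for r in records], dtype=float)
    et = np.array([r.et_score for r in records], dtype=float)
    return MatchStats(
        mu_rmsd=float(rmsd.mean()),
        sigma_rmsd=float(rmsd.std()),  # ddof=0
        mu_et=float(et.mean()),
        sigma_et=float(et.std()),
    )


def edge_weight(avg_rmsd: float, avg_et: float, stats: MatchStats) -> float:
    """Logistic-of-standardized-average edge weight in (0, 1).

    ``s = 0.5 * [(mu_rmsd - avg_rmsd)/sigma_rmsd + (mu_et - avg_et)/sigma_et]``
    and ``w = 1 / (1 + exp(-s))``. Both quantities are oriented so smaller
    means a better match, hence better-than-average matches give s > 0 and
    w > 0.5. A zero sigma carries no discriminating information and makes
    its term 0.
    """
    s = 0.0
    if stats.sigma_rmsd > 0:
        s += (stats.mu_rmsd - avg_rmsd) / stats.sigma_rmsd
    if stats.sigma_et > 0:
        s += (stats.mu_et - avg_et) / stats.sigma_et
    s *= 0.5
    # numerically stable logistic
    if s >= 0:
        return 1.0 / (1.0 + math.exp(-s))
    e = math.exp(s)
    return e / (1.0 + e)


WeightFn = Callable[[float, float, MatchStats], float]


@dataclass
class EdgeData:
    """Weight and provenance for one undirected edge."""

    weight: float
    avg_rmsd: float
    avg_et: float
    identity: float | None = None


@dataclass
class SimilarityNetwork:
    """Undirected weighted graph of protein chains.

    ``nodes`` is an ordered list of chain identifiers; ``edges`` maps the
    lexicographically sorted node pair to its :class:`EdgeData`. Absent
    pairs have weight 0; stored weights are strictly positive.
    """

    nodes: list[str]
    edges: dict[Pair, EdgeData] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.nodes)}
        for (a, b), data in self.edges.items():
            if a not in self._index or b not in self._index:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            if not (data.weight > 0 and math.isfinite(data.weight)):
                raise ValueError(f"edge ({a}, {b}) weight must be finite and > 0")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, node: str) -> int:
        return self._index[node]

    def has_node(self, node: str) -> bool:
        return node in self._index

    def weight(self, a: str, b: str) -> float:
        data = self.edges.get(_pair(a, b))
        return data.weight if data is not None else 0.0

    def neighbors(self, node: str) -> list[tuple[str, float]]:
        out = []
        for (a, b), data in self.edges.items():
            if a == node:
                out.append((b, data.weight))
            elif b == node:
                out.append((a, data.weight))
        return sorted(out)

    def adjacency(self) -> sp.csr_array:
        """Symmetric sparse weight matrix W in node order."""
        n = self.n_nodes
        rows, cols, vals = [], [], []
        for (a, b), data in self.edges.items():
            i, j = self._index[a], self._index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [data.weight, data.weight]
        return sp.csr_array((vals, (rows, cols)), shape=(n, n))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), data in self.edges.items():
            g.add_edge(a, b, weight=data.weight, avg_rmsd=data.avg_rmsd,
                       avg_et=data.avg_et)
        return g

    def connected_component_of(self, node: str) -> set[str]:
        return nx.node_connected_component(self.to_networkx(), node)


def build_network(
    records: Iterable[MatchRecord],
    stats: MatchStats | None = None,
    reciprocal_only: bool = True,
    weight_fn: WeightFn = edge_weight,
) -> SimilarityNetwork:
    """Collapse directional match records into an undirected weighted network.

    With ``reciprocal_only`` (the default), an edge {A, B} exists iff both
    A->B and B->A records are present; its rmsd and ETScore are the means of
    the two directions. Without it, any single directional record creates
    the edge. Duplicate records for one direction are averaged with a
    warning. ``stats`` defaults to statistics of ``records`` themselves.
    """
    records = list(records)
    if stats is None and records:
        stats = compute_match_statistics(records)

    # collapse duplicates per direction
    directional: dict[tuple[str, str], list[MatchRecord]] = {}
    nodes: set[str] = set()
    for rec in records:
        nodes.add(rec.query_id)
        nodes.add(rec.target_id)
        directional.setdefault((rec.query_id, rec.target_id), []).append(rec)

    def _mean_record(recs: list[MatchRecord]) -> tuple[float, float]:
        if len(recs) > 1:
            logger.warning(
                "duplicate directional match %s->%s (%d records), averaging",
                recs[0].query_id, recs[0].target_id, len(recs),
            )
        return (
            float(np.mean([r.rmsd for r in recs])),
            float(np.mean([r.et_score for r in recs])),
        )

    edges: dict[Pair, EdgeData] = {}
    seen: set[Pair] = set()
    for (q, t) in directional:
        key = _pair(q, t)
        if key in seen:
            continue
        seen.add(key)
        forward = directional.get((q, t))
        backward = directional.get((t, q))
        if reciprocal_only and (forward is None or backward is None):
            continue
        values = []
        if forward:
            values.append(_mean_record(forward))
        if backward:
            values.append(_mean_record(backward))
        avg_rmsd = float(np.mean([v[0] for v in values]))
        avg_et = float(np.mean([v[1] for v in values]))
        w = weight_fn(avg_rmsd, avg_et, stats)
        edges[key] = EdgeData(weight=w, avg_rmsd=avg_rmsd, avg_et=avg_et)

    net = SimilarityNetwork(nodes=sorted(nodes), edges=edges)
    logger.info("built network: %d nodes, %d edges (reciprocal_only=%s)",
                net.n_nodes, net.n_edges, reciprocal_only)
    return net


def filter_by_identity(
    network: SimilarityNetwork,
    identities: Mapping[Pair, float],
    max_identity: float,
) -> SimilarityNetwork:
    """Remove edges between chains more than ``max_identity`` % identical.

    Emulates the homology-ablation experiment: edges whose sequence identity
    exceeds the cutoff are dropped, nodes are retained. Pairs absent from
    ``identities`` keep their edge (absence of homology evidence does not
    erase structural similarity) with a warning.
    """
    if not 0 < max_identity <= 100:
        raise ValueError(f"max_identity must be in (0, 100], got {max_identity}")
    lookup = {_pair(a, b): v for (a, b), v in identities.items()}
    kept: dict[Pair, EdgeData] = {}
    missing = 0
    for pair, data in network.edges.items():
        ident = lookup.get(pair)
        if ident is None:
            missing += 1
            kept[pair] = EdgeData(data.weight, data.avg_rmsd, data.avg_et, None)
            continue
        if ident <= max_identity:
            kept[pair] = EdgeData(data.weight, data.avg_rmsd, data.avg_et, ident)
    if missing:
        logger.warning("%d edges had no identity entry; retained", missing)
    logger.info("identity filter at %.1f%%: %d -> %d edges",
                max_identity, network.n_edges, len(kept))
    return SimilarityNetwork(nodes=list(network.nodes), edges=kept)
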