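"""Tabular readers/writers for every file surface.

All inputs are tab-separated with a required header and optional
``#``-comment lines; curve outputs are CSV. Readers validate eagerly and
raise :class:`DataError` with file and line context, so malformed rows
never propagate into the numerics.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotate import Prediction
from .ec import ECNumber, MalformedECError
from .evaluation import CurvePoint
from .labels import LabelTable
from .match_graph import EdgeData, MatchRecord, SimilarityNetwork

__all__ = [
    "DataError",
    "read_match_table", "write_match_table",
    "read_label_table", "write_label_table",
    "read_identity_table", "write_identity_table",
    "read_network", "write_network",
    "read_predictions", "write_predictions",
    "read_curve", "write_curve",
    "read_query_list",
]


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 2)."""


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                            skip_blank_lines=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pandas parse failure
        raise DataError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {', '.join(missing)}")
    return frame


def _float(value: str, path: Path, row: int, column: str) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise DataError(f"{path}, row {row}: non-numeric {column} {value!r}") from None
    if not math.isfinite(x):
        raise DataError(f"{path}, row {row}: non-finite {column}")
    return x


# -- match tables ---------------------------------------------------------

def read_match_table(path: str | Path) -> list[MatchRecord]:
    path = Path(path)
    frame = _read_tsv(path, ["query_id", "target_id", "rmsd", "et_score"])
    records = []
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        try:
            records.append(
                MatchRecord(
                    query_id=str(rec.query_id),
                    target_id=str(rec.target_id),
                    rmsd=_float(rec.rmsd, path, row, "rmsd"),
                    et_score=_float(rec.et_score, path, row, "et_score"),
                )
            )
        except ValueError as exc:
            if isinstance(exc, DataError):
                raise
            raise DataError(f"{path}, row {row}: {exc}") from exc
    return records


def write_match_table(records: Sequence[MatchRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\ttarget_id\trmsd\tet_score\n")
        for r in records:
            fh.write(f"{r.query_id}\t{r.target_id}\t{r.rmsd:g}\t{r.et_score:g}\n")


# -- label tables ---------------------------------------------------------

def read_label_table(path: str | Path) -> LabelTable:
    """TSV ``chain_id  ec_number``; repeated chains accumulate into a set."""
    path = Path(path)
    frame = _read_tsv(path, ["chain_id", "ec_number"])
    table = LabelTable()
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        try:
            table.add(str(rec.chain_id), ECNumber.parse(str(rec.ec_number)))
        except MalformedECError as exc:
            raise DataError(f"{path}, row {row}: {exc}") from exc
    return table


def write_label_table(table: LabelTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tec_number\n")
        for chain in sorted(table):
            for ec in sorted(table[chain]):
                fh.write(f"{chain}\t{ec}\n")


# -- identity tables ------------------------------------------------------

def read_identity_table(path: str | Path) -> dict[tuple[str, str], float]:
    """TSV ``id_a  id_b  identity_pct`` over unordered pairs."""
    path = Path(path)
    frame = _read_tsv(path, ["id_a", "id_b", "identity_pct"])
    out: dict[tuple[str, str], float] = {}
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        a, b = str(rec.id_a), str(rec.id_b)
        pair = (a, b) if a <= b else (b, a)
        pct = _float(rec.identity_pct, path, row, "identity_pct")
        if not 0 <= pct <= 100:
            raise DataError(f"{path}, row {row}: identity_pct outside [0, 100]")
        if pair in out and out[pair] != pct:
            raise DataError(f"{path}, row {row}: conflicting identity for {pair}")
        out[pair] = pct
    return out


def write_identity_table(identities: Mapping[tuple[str, str], float],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tidentity_pct\n")
        for (a, b), pct in sorted(identities.items()):
            fh.write(f"{a}\t{b}\t{pct:g}\n")


# -- networks -------------------------------------------------------------

def write_network(network: SimilarityNetwork, prefix: str | Path) -> dict[str, Path]:
    """Edge list ``<prefix>.edges.tsv`` + node list ``<prefix>.nodes.txt``."""
    edge_path = Path(f"{prefix}.edges.tsv")
    node_path = Path(f"{prefix}.nodes.txt")
    with open(edge_path, "w") as fh:
        fh.write("id_a\tid_b\tweight\tavg_rmsd\tavg_et_score\n")
        for (a, b), data in sorted(network.edges.items()):
            fh.write(f"{a}\t{b}\t{data.weight!r}\t{data.avg_rmsd!r}\t{data.avg_et!r}\n")
    node_path.write_text("".join(f"{n}\n" for n in network.nodes))
    return {"edges": edge_path, "nodes": node_path}


def read_network(prefix: str | Path) -> SimilarityNetwork:
    edge_path = Path(f"{prefix}.edges.tsv")
    node_path = Path(f"{prefix}.nodes.txt")
    nodes = [line.strip() for line in node_path.read_text().splitlines() if line.strip()]
    frame = _read_tsv(edge_path, ["id_a", "id_b", "weight", "avg_rmsd", "avg_et_score"])
    edges: dict[tuple[str, str], EdgeData] = {}
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        a, b = str(rec.id_a), str(rec.id_b)
        pair = (a, b) if a <= b else (b, a)
        if pair in edges:
            raise DataError(f"{edge_path}, row {row}: duplicate edge {pair}")
        w = _float(rec.weight, edge_path, row, "weight")
        if w <= 0:
            raise DataError(f"{edge_path}, row {row}: weight must be > 0")
        edges[pair] = EdgeData(
            weight=w,
            avg_rmsd=_float(rec.avg_rmsd, edge_path, row, "avg_rmsd"),
            avg_et=_float(rec.avg_et_score, edge_path, row, "avg_et_score"),
        )
    try:
        return SimilarityNetwork(nodes=nodes, edges=edges)
    except ValueError as exc:
        raise DataError(f"{edge_path}: {exc}") from exc


# -- predictions ----------------------------------------------------------

def write_predictions(predictions: Sequence[Prediction], path: str | Path) -> None:
    """Sorted by descending confidence (ties by node id) for stable output."""
    ranked = sorted(predictions, key=lambda p: (-p.confidence, p.node))
    with open(path, "w") as fh:
        fh.write("node\tfunction\tconfidence\tmethod\tisolated\n")
        for p in ranked:
            fh.write(
                f"{p.node}\t{p.function}\t{p.confidence!r}\t{p.method}"
                f"\t{str(p.isolated).lower()}\n"
            )


def read_predictions(path: str | Path) -> list[Prediction]:
    path = Path(path)
    frame = _read_tsv(path, ["node", "function", "confidence", "method", "isolated"])
    out = []
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        flag = str(rec.isolated).lower()
        if flag not in ("true", "false"):
            raise DataError(f"{path}, row {row}: isolated must be true/false")
        out.append(
            Prediction(
                node=str(rec.node),
                function=str(rec.function),
                confidence=_float(rec.confidence, path, row, "confidence"),
                method=str(rec.method),
                isolated=flag == "true",
            )
        )
    return out


# -- curves ---------------------------------------------------------------

def write_curve(curve: Sequence[CurvePoint], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {"threshold": p.threshold, "tp": p.tp, "fp": p.fp, "fn": p.fn,
             "accuracy": p.accuracy, "coverage": p.coverage,
             "sensitivity": p.sensitivity, "precision": p.precision}
            for p in curve
        ]
    )
    frame.to_csv(path, index=False)


def read_curve(path: str | Path) -> list[CurvePoint]:
    frame = pd.read_csv(path)
    return [
        CurvePoint(
            threshold=float(r.threshold), tp=int(r.tp), fp=int(r.fp), fn=int(r.fn),
            accuracy=float(r.accuracy), coverage=float(r.coverage),
            sensitivity=float(r.sensitivity), precision=float(r.precision),
        )
        for r in frame.itertuples(index=False)
    ]


def read_query_list(path: str | Path) -> list[str]:
    """One chain id per line; blank lines and ``#`` comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
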