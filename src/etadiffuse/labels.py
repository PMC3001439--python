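"""Reference function labels: protein chain -> set of EC codes."""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from typing import Iterator

from .ec import ECNumber

__all__ = ["LabelTable"]


class LabelTable(Mapping):
    """Mapping from chain identifier to a frozenset of :class:`ECNumber`.

    Chain identifiers are opaque case-sensitive strings (typically a PDB id
    plus chain letter, e.g. ``"3h04A"``). A chain may carry several EC codes
    (promiscuous or multi-domain enzymes); repeated assignments collapse
    with set semantics.
    """

    def __init__(self, assignments: Mapping[str, Iterable[str | ECNumber]] | None = None):
        self._data: dict[str, frozenset[ECNumber]] = {}
        if assignments:
            for chain, ecs in assignments.items():
                self._data[chain] = frozenset(
                    e if isinstance(e, ECNumber) else ECNumber.parse(e) for e in ecs
                )

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, chain: str) -> frozenset[ECNumber]:
        return self._data[chain]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    # -- level-aware queries ----------------------------------------------
    def node_functions(self, chain: str, level: int) -> frozenset[str]:
        """Complete-at-level truncated EC strings carried by ``chain``.

        Partial codes (e.g. ``3.1.-.-`` queried at level 3) contribute
        nothing: they cannot establish presence of a specific function.
        """
        return frozenset(
            str(ec.truncate(level))
            for ec in self._data.get(chain, frozenset())
            if ec.complete_at(level)
        )

    def has_complete_label(self, chain: str, level: int) -> bool:
        """True iff ``chain`` carries at least one complete-at-level EC."""
        return bool(self.node_functions(chain, level))

    def functions_at_level(self, level: int, chains: Iterable[str] | None = None) -> list[str]:
        """Sorted distinct complete-at-level functions among ``chains``.

        ``chains=None`` means all chains in the table.
        """
        pool = self._data.keys() if chains is None else chains
        out: set[str] = set()
        for chain in pool:
            out |= self.node_functions(chain, level)
        return sorted(out, key=lambda s: ECNumber.parse(s))

    def restrict(self, chains: Iterable[str]) -> "LabelTable":
        """New table containing only the given chains."""
        keep = set(chains)
        table = LabelTable()
        table._data = {c: ecs for c, ecs in self._data.items() if c in keep}
        return table

    def drop(self, chains: Iterable[str]) -> "LabelTable":
        """New table with the given chains removed (label withholding)."""
        gone = set(chains)
        table = LabelTable()
        table._data = {c: ecs for c, ecs in self._data.items() if c not in gone}
        return table

    def add(self, chain: str, ec: str | ECNumber) -> None:
        value = ec if isinstance(ec, ECNumber) else ECNumber.parse(ec)
        self._data[chain] = self._data.get(chain, frozenset()) | {value}

    def __repr__(self) -> str:  # pragma: no cover
        return f"LabelTable({len(self._data)} chains)"
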