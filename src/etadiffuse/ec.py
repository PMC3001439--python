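"""Enzyme Commission (EC) number utilities.

EC numbers are dot-separated codes ``a.b.c.d`` classifying enzymatic
reactions hierarchically: the first digit is the broad reaction class
(e.g. 3 = hydrolase), the fourth typically pins down the substrate.
Partial annotations replace unknown components with ``-`` (``3.1.-.-``).

Annotation transfer in this package operates at a chosen *level*: level 3
compares the first three components (reaction chemistry), level 4 the full
code (substrate specificity).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

__all__ = ["ECNumber", "MalformedECError", "truncate_ec"]


class MalformedECError(ValueError):
    """Raised when a string is not a valid (possibly partial) EC code."""


@total_ordering
@dataclass(frozen=True)
class ECNumber:
    """An EC code of 1-4 components, each a positive integer or ``-``.

    Instances are immutable, hashable, and ordered by their component
    tuple (integers before ``-``, so "1.1.1.1" < "1.1.1.-" < "2.1.1.1").
    """

    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 4:
            raise MalformedECError(
                f"EC code must have 1-4 components, got {len(self.components)}"
            )
        for c in self.components:
            if c == "-":
                continue
            if not c.isdigit() or int(c) <= 0:
                raise MalformedECError(
                    f"EC component {c!r} is neither a positive integer nor '-'"
                )

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        text = text.strip()
        if not text:
            raise MalformedECError("empty EC string")
        return cls(tuple(text.split(".")))

    def truncate(self, level: int) -> "ECNumber":
        """First ``level`` components, padded with ``-`` if shorter."""
        if level not in (1, 2, 3, 4):
            raise ValueError(f"level must be in 1..4, got {level}")
        parts = self.components[:level]
        if len(parts) < level:
            parts = parts + ("-",) * (level - len(parts))
        return ECNumber(parts)

    def complete_at(self, level: int) -> bool:
        """True iff the first ``level`` components are all integers."""
        if level not in (1, 2, 3, 4):
            raise ValueError(f"level must be in 1..4, got {level}")
        if len(self.components) < level:
            return False
        return all(c != "-" for c in self.components[:level])

    def _sort_key(self) -> tuple:
        # integers sort numerically and before "-"
        return tuple((0, int(c)) if c != "-" else (1, 0) for c in self.components)

    def __lt__(self, other: "ECNumber") -> bool:
        return self._sort_key() < other._sort_key()

    def __str__(self) -> str:
        return ".".join(self.components)


def truncate_ec(ec: str | ECNumber, level: int) -> tuple[str, bool]:
    """Truncate an EC code to ``level`` components.

    Returns ``(truncated_string, complete)`` where ``complete`` is True iff
    all retained components are integers; e.g. ``("3.1.-", False)`` for
    ``"3.1.-.-"`` at level 3.
    """
    if isinstance(ec, str):
        ec = ECNumber.parse(ec)
    return str(ec.truncate(level)), ec.complete_at(level)
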