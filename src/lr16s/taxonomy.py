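"""Taxonomic lineages in the GreenGenes prefix convention.

A lineage is an ordered assignment of labels to the seven canonical ranks
(kingdom through species).  The on-disk form is the familiar prefixed,
semicolon-separated string, e.g.::

    k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__; g__; s__

Empty labels mean "unassigned at this rank".  Parsing and formatting
round-trip losslessly; comparison is case-sensitive exact string match per
rank, because all references handled here are generated internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_PREFIXES: tuple[str, ...] = ("k", "p", "c", "o", "f", "g", "s")

_PREFIX_TO_INDEX = {p: i for i, p in enumerate(RANK_PREFIXES)}


class LineageParseError(ValueError):
    """Raised for lineage strings with unknown or misplaced rank prefixes."""


@dataclass(frozen=True, order=True)
class Lineage:
    """Seven-rank taxonomic lineage; empty strings mark unassigned ranks."""

    labels: tuple[str, str, str, str, str, str, str] = field(
        default=("", "", "", "", "", "", "")
    )

    def __post_init__(self) -> None:
        if len(self.labels) != len(RANKS):
            raise ValueError(f"lineage needs {len(RANKS)} labels, got {len(self.labels)}")

    # -- construction -------------------------------------------------

    @classmethod
    def parse(cls, s: str) -> "Lineage":
        """Parse a GreenGenes-style prefixed lineage string.

        Tokens may be absent from the right; an empty suffix (``s__``)
        yields an empty label.  Unknown prefixes raise
        :class:`LineageParseError`.
        """
        labels = [""] * len(RANKS)
        s = s.strip()
        if not s:
            return cls(tuple(labels))
        for token in s.split(";"):
            token = token.strip()
            if not token:
                continue
            if len(token) < 3 or token[1:3] != "__":
                raise LineageParseError(f"malformed lineage token {token!r}")
            prefix = token[0]
            if prefix not in _PREFIX_TO_INDEX:
                raise LineageParseError(f"unknown rank prefix {token[:3]!r} in {s!r}")
            labels[_PREFIX_TO_INDEX[prefix]] = token[3:].strip()
        return cls(tuple(labels))

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "Lineage":
        return cls(tuple(d.get(r, "") for r in RANKS))

    # -- accessors ----------------------------------------------------

    def __str__(self) -> str:
        return self.format()

    def format(self) -> str:
        """Full 7-token prefixed string (empty ranks emit bare prefixes)."""
        return "; ".join(f"{p}__{l}" for p, l in zip(RANK_PREFIXES, self.labels))

    def label(self, rank: str) -> str:
        return self.labels[RANKS.index(rank)]

    @property
    def depth(self) -> int:
        """Index of the deepest non-empty rank plus one (0 if fully empty)."""
        for i in range(len(RANKS) - 1, -1, -1):
            if self.labels[i]:
                return i + 1
        return 0

    @property
    def is_empty(self) -> bool:
        return self.depth == 0

    def deepest(self) -> tuple[str, str]:
        """(rank name, label) of the deepest assigned rank; ('', '') if empty."""
        d = self.depth
        if d == 0:
            return ("", "")
        return (RANKS[d - 1], self.labels[d - 1])

    # -- transforms ---------------------------------------------------

    def truncate(self, rank: str) -> "Lineage":
        """Clear every rank below `rank` (labels at and above are kept)."""
        idx = RANKS.index(rank)
        return Lineage(tuple(l if i <= idx else "" for i, l in enumerate(self.labels)))

    def prefix_string(self, rank: str) -> str:
        """Prefixed string truncated at `rank` — the grouping key used by
        abundance profiles."""
        idx = RANKS.index(rank)
        return "; ".join(
            f"{p}__{l}" for p, l in zip(RANK_PREFIXES[: idx + 1], self.labels[: idx + 1])
        )


def lowest_common_ancestor(lineages: Iterable[Lineage]) -> Lineage:
    """Deepest lineage shared by all inputs.

    Ranks agree until the first disagreement (an empty label in any input
    counts as disagreement); everything below is cleared.
    """
    lineages = list(lineages)
    if not lineages:
        raise ValueError("LCA of an empty set is undefined")
    labels: list[str] = []
    for i in range(len(RANKS)):
        column = {l.labels[i] for l in lineages}
        if len(column) == 1 and "" not in column:
            labels.append(column.pop())
        else:
            labels.extend([""] * (len(RANKS) - i))
            break
    else:
        pass
    return Lineage(tuple(labels[: len(RANKS)]))
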