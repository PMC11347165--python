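"""Query tiling and anchor collection.

The query is divided into consecutive, non-overlapping patterns of the
derived pattern size k; the trailing ``len(query) mod k`` bases carry no
pattern.  Every exact occurrence of a pattern in a target yields one
anchor (query index, target index) -- an alignment starting point.  This
non-overlapping tiling is what makes the quotient-filter guarantee work:
any alignment satisfying the cutoffs must leave at least one pattern
unbroken, and an unbroken pattern is an exact occurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .params import DerivedConstants
from .reference import Reference

__all__ = ["PatternSet", "Anchor", "divide_into_patterns", "collect_anchors"]

logger = logging.getLogger(__name__)

NEW, EVALUATED, SKIPPED = 0, 1, 2


@dataclass(frozen=True)
class PatternSet:
    """Tiling of a query into consecutive patterns of fixed size."""

    pattern_size: int
    count: int  # floor(len(query) / pattern_size)

    def query_start(self, t: int) -> int:
        return t * self.pattern_size

    def reverse_index(self, t: int) -> int:
        """Index counted from the right end of the query (0 = rightmost)."""
        return self.count - 1 - t


@dataclass
class Anchor:
    """Exact pattern occurrence: the pairing of query and target indices."""

    query_pos: int
    target_pos: int
    reverse_index: int
    state: int = NEW

    @property
    def key(self) -> tuple[int, int]:
        return (self.query_pos, self.target_pos)


def divide_into_patterns(query: bytes, pattern_size: int) -> PatternSet:
    if pattern_size < 1:
        raise ValueError("pattern size must be >= 1")
    q = len(query) // pattern_size
    if q == 0:
        logger.warning(
            "query of length %d is shorter than the pattern size %d; "
            "no anchors can be found",
            len(query),
            pattern_size,
        )
    return PatternSet(pattern_size=pattern_size, count=q)


def collect_anchors(
    query: bytes, reference: Reference, derived: DerivedConstants
) -> dict[str, list[Anchor]]:
    """Anchor table per target, sorted by (query_pos, target_pos).

    An empty table (short query, or no pattern occurs anywhere) simply
    means the query reports no results.
    """
    patterns = divide_into_patterns(query, derived.pattern_size)
    k = patterns.pattern_size
    table: dict[str, list[Anchor]] = {}
    if patterns.count == 0:
        return table
    for t in range(patterns.count):
        start = patterns.query_start(t)
        pat = query[start : start + k]
        j = patterns.reverse_index(t)
        for target_id, pos in reference.locate(pat):
            table.setdefault(target_id, []).append(
                Anchor(query_pos=start, target_pos=pos, reverse_index=j)
            )
    for anchors in table.values():
        anchors.sort(key=lambda a: (a.query_pos, a.target_pos))
    return table
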