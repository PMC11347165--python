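"""Immutable collection of target sequences with exact pattern location.

The reference stores an ordered list of targets (any single-byte alphabet)
and answers "where does this fixed-length pattern occur exactly?" queries.
Anchoring tolerates no false negatives and no false positives, so the
locate contract is: exactly the set of occurrence positions (overlapping
occurrences included), 0-based, sorted.

Two interchangeable backends sit behind that contract:

* a packed-k-mer sorted index (numpy) for A/C/G/T targets and pattern
  lengths up to 31 -- built lazily per pattern length and cached, since the
  pipeline only ever queries one pattern length per parameter set;
* a direct ``bytes.find`` scan for everything else.

Index internals are an engineering detail; results are defined by the
naive-scan semantics and fuzz-tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = ["Target", "Reference", "build_reference"]

_ACGT = frozenset(b"ACGT")
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class Target:
    """One named target sequence (bytes over any single-byte alphabet)."""

    id: str
    sequence: bytes

    def __post_init__(self) -> None:
        if not isinstance(self.sequence, (bytes, bytearray)):
            raise TypeError("target sequence must be bytes")
        object.__setattr__(self, "sequence", bytes(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


class _KmerIndex:
    """Sorted packed-k-mer table over one ACGT sequence (k <= 31)."""

    def __init__(self, seq: bytes, k: int):
        codes = _CODE[np.frombuffer(seq, dtype=np.uint8)].astype(np.uint64)
        n = len(seq) - k + 1
        packed = np.zeros(n, dtype=np.uint64)
        # Horner packing: one vectorised pass per pattern position.
        for i in range(k):
            packed = packed * np.uint64(4) + codes[i : i + n]
        order = np.argsort(packed, kind="stable")
        self._sorted = packed[order]
        self._positions = order.astype(np.int64)
        self._k = k

    def locate(self, pattern: bytes) -> list[int]:
        key = np.uint64(0)
        for b in _CODE[np.frombuffer(pattern, dtype=np.uint8)]:
            key = key * np.uint64(4) + np.uint64(b)
        lo = int(np.searchsorted(self._sorted, key, side="left"))
        hi = int(np.searchsorted(self._sorted, key, side="right"))
        return sorted(int(p) for p in self._positions[lo:hi])


def _scan(seq: bytes, pattern: bytes) -> list[int]:
    """Naive overlapping-occurrence scan (the defining semantics)."""
    out: list[int] = []
    start = seq.find(pattern)
    while start != -1:
        out.append(start)
        start = seq.find(pattern, start + 1)
    return out


class Reference:
    """Immutable, concurrently readable set of targets with exact locate.

    Build once via :func:`build_reference`; no mutation afterwards, so a
    single instance can serve any number of alignment contexts.
    """

    def __init__(self, targets: list[Target]):
        self._targets = tuple(targets)
        self._by_id = {t.id: i for i, t in enumerate(self._targets)}
        self._indexes: dict[tuple[int, int], _KmerIndex] = {}
        self._indexable = [
            len(t.sequence) > 0 and not (set(t.sequence) - _ACGT)
            for t in self._targets
        ]

    @property
    def targets(self) -> tuple[Target, ...]:
        return self._targets

    def __len__(self) -> int:
        return len(self._targets)

    def __iter__(self) -> Iterator[Target]:
        return iter(self._targets)

    def target(self, target_id: str) -> Target:
        return self._targets[self._by_id[target_id]]

    def _index_for(self, ti: int, k: int) -> _KmerIndex | None:
        if k > 31 or not self._indexable[ti]:
            return None
        if len(self._targets[ti].sequence) < k:
            return None
        key = (ti, k)
        idx = self._indexes.get(key)
        if idx is None:
            idx = _KmerIndex(self._targets[ti].sequence, k)
            self._indexes[key] = idx
        return idx

    def locate_in(self, target_id: str, pattern: bytes) -> list[int]:
        """All 0-based occurrence positions of pattern in one target."""
        if len(pattern) == 0:
            raise ValueError("pattern must be non-empty")
        ti = self._by_id[target_id]
        seq = self._targets[ti].sequence
        if len(pattern) > len(seq):
            return []
        idx = self._index_for(ti, len(pattern))
        if idx is not None and not (set(pattern) - _ACGT):
            return idx.locate(pattern)
        return _scan(seq, pattern)

    def locate(self, pattern: bytes) -> list[tuple[str, int]]:
        """All occurrences across targets, sorted by (target order, pos)."""
        out: list[tuple[str, int]] = []
        for t in self._targets:
            out.extend((t.id, p) for p in self.locate_in(t.id, pattern))
        return out


def build_reference(targets: Iterable[Target]) -> Reference:
    """Build a reference from >= 1 non-empty targets with unique ids."""
    tlist = list(targets)
    if not tlist:
        raise ValueError("reference needs at least one target")
    seen: set[str] = set()
    for t in tlist:
        if len(t.sequence) == 0:
            raise ValueError(f"target {t.id!r} has an empty sequence")
        if t.id in seen:
            raise ValueError(f"duplicate target id {t.id!r}")
        seen.add(t.id)
    return Reference(tlist)
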