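"""Penalty-bounded, gap-affine wavefront extension of anchors.

One side of an anchor is extended over a pair of flanks (query flank,
target flank, both oriented away from the anchor) with the non-adaptive
diagonal-transition ("wavefront") method: for every penalty score from 0
up to the side's spare penalty, track the furthest-reaching progress on
each diagonal for the three gap-affine states.  Compared to filling the
full dynamic-programming matrix this touches only O(scores * diagonals)
cells, and the spare penalty caps the score range so extension always
stops once no cutoff-satisfying alignment could still be completed.

Conventions
-----------
* Operations: ``=`` match, ``X`` substitution, ``I`` insertion (consumes
  query only), ``D`` deletion (consumes target only).
* A point is (h, v): h query bases and v target bases consumed from the
  anchor.  Diagonal ``k = v - h``; the stored offset is ``h``.
* A merged-state (M) entry stores both its furthest offset and the start
  of its trailing match run, so substitutions and gap openings may branch
  from any point of the run -- necessary near flank ends, where the
  furthest point itself cannot open a gap.
* M entries are dominance-pruned across scores (an entry whose furthest
  offset does not exceed every lower-score entry on the same diagonal is
  dropped).  Pruning makes every stored M offset minimal-penalty for its
  point, which the backtrace tie-break rules rely on.

Endpoint selection prefers, in order: endpoints that can still belong to
a cutoff-satisfying alignment (penalty delta above the opposite side's
bound); endpoints where the query or target flank is used to its end; the
longer aligned span; the lesser penalty; and the smaller diagonal index
(determinism).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, NamedTuple, Sequence

from .params import Penalties

__all__ = [
    "Endpoint",
    "SideExtension",
    "wavefront_extend",
    "select_endpoint",
    "endpoint_sort_key",
    "max_penalty_delta",
    "extend_side",
    "backtrace",
    "op_spans",
    "op_penalty",
]


class Endpoint(NamedTuple):
    """One candidate stopping point of a side extension."""

    score: int
    diag: int  # v - h
    offset: int  # h, query bases consumed

    @property
    def query_used(self) -> int:
        return self.offset

    @property
    def target_used(self) -> int:
        return self.offset + self.diag

    def reached_end(self, lq: int, lt: int) -> bool:
        return self.offset == lq or self.offset + self.diag == lt

    def sel_len(self) -> int:
        """Length proxy for penalty-delta estimates: max(query used,
        target used), the operation count of any one-sided-gap minimal
        path (paths mixing insertions and deletions are longer, so this
        never overestimates)."""
        return max(self.offset, self.offset + self.diag)

    def span_len(self) -> int:
        """Aligned span used for endpoint ordering: min(query used,
        target used).

        A trailing gap advances only one coordinate, so ranking by this
        span (with penalty as tie-break) never prefers an endpoint padded
        with gap operations over the same endpoint without them, while a
        genuine longer alignment advances both coordinates and still
        wins.
        """
        return min(self.offset, self.offset + self.diag)


def endpoint_sort_key(
    ep: Endpoint, lq: int, lt: int, max_ppl: Fraction, min_delta: Fraction
):
    """Ordering: cutoff-feasible endpoints first, then end-reaching, then
    longer, then lesser penalty, then smaller diagonal.

    An endpoint is cutoff-feasible when its penalty delta (MaxP * length -
    penalty) stays above ``min_delta``, the most the opposite side of the
    anchor can contribute; an endpoint below that bound can never be part
    of an alignment meeting the MaxP cutoff, so preferring "longer" among
    such endpoints would discard reachable sub-alignments (e.g. of reads
    with one dense error burst).  The empty endpoint has delta 0, so a
    feasible candidate always exists whenever min_delta <= 0.
    """
    feasible = max_ppl * ep.sel_len() - ep.score >= min_delta
    return (feasible, ep.reached_end(lq, lt), ep.span_len(), -ep.score, -ep.diag)


def select_endpoint(
    candidates: Sequence[Endpoint],
    lq: int,
    lt: int,
    max_ppl: Fraction,
    min_delta: Fraction,
) -> Endpoint:
    if not candidates:
        raise ValueError("at least the empty endpoint must be present")
    # Integer form of endpoint_sort_key; this runs for every candidate of
    # every extension, so Fraction arithmetic is unrolled.
    dn, dd = max_ppl.numerator, max_ppl.denominator
    mn, md = min_delta.numerator, min_delta.denominator
    best = None
    best_key = None
    for ep in candidates:
        s, k, h = ep
        v = h + k
        sel = v if v > h else h
        key = (
            (dn * sel - s * dd) * md >= mn * dd,
            h == lq or v == lt,
            h if h < v else v,
            -s,
            -k,
        )
        if best_key is None or key > best_key:
            best, best_key = ep, key
    return best


def max_penalty_delta(candidates: Sequence[Endpoint], max_ppl: Fraction) -> Fraction:
    """Largest penalty delta (MaxP * length - penalty) over all endpoint
    candidates; at least 0 because the empty endpoint is always present."""
    best = Fraction(0)
    for ep in candidates:
        delta = max_ppl * ep.sel_len() - ep.score
        if delta > best:
            best = delta
    return best


@dataclass
class SideExtension:
    """Backtraced result of one side's extension.

    ``tracer`` backtraces any other candidate endpoint of the same
    extension (used when an anchor's primary endpoint pair fails the
    cutoffs and a cutoff-satisfying pair is extracted instead).
    """

    ops: str  # origin -> endpoint order, over =XID
    penalty: int
    endpoint: Endpoint
    candidates: list[Endpoint]
    reached_end: bool
    tracer: "Callable[[Endpoint], str] | None" = None

    @property
    def length(self) -> int:
        return len(self.ops)

    @property
    def query_span(self) -> int:
        return len(self.ops) - self.ops.count("D")

    @property
    def target_span(self) -> int:
        return len(self.ops) - self.ops.count("I")


def op_spans(ops: str) -> tuple[int, int]:
    """(query span, target span) consumed by an operation string."""
    return len(ops) - ops.count("D"), len(ops) - ops.count("I")


def op_penalty(ops: str, penalties: Penalties) -> int:
    """Recompute the affine-gap penalty of an operation string."""
    total = 0
    prev = ""
    for op in ops:
        if op == "X":
            total += penalties.mismatch
        elif op in "ID":
            total += penalties.gap_extend
            if op != prev:
                total += penalties.gap_open
        prev = op
    return total


def _lcp(q: bytes, t: bytes, h: int, v: int, lq: int, lt: int) -> int:
    """Advance h through the common run of q[h:] vs t[v:], chunked so long
    match runs compare at memcmp speed."""
    chunk = 128
    while True:
        if h >= lq or v >= lt:
            return h
        n = min(chunk, lq - h, lt - v)
        if q[h : h + n] == t[v : v + n]:
            h += n
            v += n
            continue
        for i in range(n):
            if q[h + i] != t[v + i]:
                return h + i
        return h + n  # pragma: no cover


class _Wavefronts:
    """Per-score wavefront rows.

    ``M[s]`` maps diagonal -> (furthest offset, run start); ``I[s]`` and
    ``D[s]`` map diagonal -> offset.
    """

    __slots__ = ("M", "I", "D", "lq", "lt")

    def __init__(self, spare: int, lq: int, lt: int):
        self.M: list[dict[int, tuple[int, int]] | None] = [None] * (spare + 1)
        self.I: list[dict[int, int] | None] = [None] * (spare + 1)
        self.D: list[dict[int, int] | None] = [None] * (spare + 1)
        self.lq = lq
        self.lt = lt


def wavefront_extend(
    qflank: bytes, tflank: bytes, spare: int, penalties: Penalties
) -> tuple[list[Endpoint], _Wavefronts]:
    """Forward wavefront pass.

    Returns the per-score furthest-reaching endpoint candidates and the
    wavefront structure needed for backtracing.  Scores run 0..spare, with
    an early break once no wavefront can spawn successors; all progress is
    clamped to the flank box.
    """
    if spare < 0:
        raise ValueError("spare penalty must be >= 0")
    lq, lt = len(qflank), len(tflank)
    px, po, pe = penalties.mismatch, penalties.gap_open, penalties.gap_extend
    oe = po + pe

    wf = _Wavefronts(spare, lq, lt)
    hw_m: dict[int, int] = {}
    candidates: list[Endpoint] = []

    h0 = _lcp(qflank, tflank, 0, 0, lq, lt)
    wf.M[0] = {0: (h0, 0)}
    hw_m[0] = h0
    candidates.append(Endpoint(0, 0, h0))
    last_alive = 0
    horizon = max(px, oe, pe)

    for s in range(1, spare + 1):
        if s - last_alive > horizon:
            break
        m_sub = wf.M[s - px] if s >= px else None
        m_open = wf.M[s - oe] if s >= oe else None
        i_ext = wf.I[s - pe] if s >= pe else None
        d_ext = wf.D[s - pe] if s >= pe else None

        new_i: dict[int, int] = {}
        new_d: dict[int, int] = {}

        # Insertions consume query; diagonal k receives from k+1.
        diags: set[int] = set()
        if m_open:
            diags.update(k - 1 for k in m_open)
        if i_ext:
            diags.update(k - 1 for k in i_ext)
        for k in diags:
            best = -1
            if m_open is not None:
                src = m_open.get(k + 1)
                if src is not None:
                    f, rs = src
                    u = min(f, lq - 1)
                    if u >= rs:
                        best = u + 1
            if i_ext is not None:
                g = i_ext.get(k + 1)
                if g is not None and g < lq and g + 1 > best:
                    best = g + 1
            if best >= 0:
                new_i[k] = best

        # Deletions consume target; diagonal k receives from k-1.
        diags = set()
        if m_open:
            diags.update(k + 1 for k in m_open)
        if d_ext:
            diags.update(k + 1 for k in d_ext)
        for k in diags:
            best = -1
            if m_open is not None:
                src = m_open.get(k - 1)
                if src is not None:
                    f, rs = src
                    u = min(f, lt - k)  # need v = u + (k-1) < lt
                    if u >= rs:
                        best = u
            if d_ext is not None:
                g = d_ext.get(k - 1)
                if g is not None and g + (k - 1) < lt and g > best:
                    best = g
            if best >= 0:
                new_d[k] = best

        # Merged M: substitution from any point of a run, or adopt a gap
        # point, then extend through the match run.
        new_m: dict[int, tuple[int, int]] = {}
        diags = set(new_i) | set(new_d)
        if m_sub:
            diags.update(m_sub)
        for k in diags:
            best = -1
            if m_sub is not None:
                src = m_sub.get(k)
                if src is not None:
                    f, rs = src
                    u = min(f, lq - 1, lt - 1 - k)
                    if u >= rs:
                        best = u + 1
            gi = new_i.get(k)
            if gi is not None and gi > best:
                best = gi
            gd = new_d.get(k)
            if gd is not None and gd > best:
                best = gd
            if best < 0:
                continue
            run_start = best
            f = _lcp(qflank, tflank, best, best + k, lq, lt)
            if f > hw_m.get(k, -1):
                new_m[k] = (f, run_start)

        if new_i:
            wf.I[s] = new_i
        if new_d:
            wf.D[s] = new_d
        if new_m:
            wf.M[s] = new_m
            for k, (f, _) in new_m.items():
                hw_m[k] = f
                candidates.append(Endpoint(s, k, f))
        if new_i or new_d or new_m:
            last_alive = s

    return candidates, wf


def backtrace(
    wf: _Wavefronts,
    endpoint: Endpoint,
    qflank: bytes,
    tflank: bytes,
    penalties: Penalties,
) -> str:
    """Extract the canonical operation string for one endpoint.

    Tie-breaks (substitution before entering an insertion before a
    deletion; gaps close as early as possible; a match only where no
    same-score junction exists) mirror the canonical walk of the
    dynamic-programming oracle, so both extension engines emit identical
    operation vectors for the same endpoint.
    """
    px, po, pe = penalties.mismatch, penalties.gap_open, penalties.gap_extend
    oe = po + pe
    s, k, h = endpoint.score, endpoint.diag, endpoint.offset
    ops: list[str] = []
    state = "M"

    def m_covers(score: int, diag: int, offset: int) -> bool:
        if score < 0 or offset < 0:
            return False
        row = wf.M[score]
        if row is None:
            return False
        src = row.get(diag)
        if src is None:
            return False
        f, rs = src
        return rs <= offset <= f

    def iget(score: int, diag: int) -> int | None:
        if score < 0:
            return None
        row = wf.I[score]
        return None if row is None else row.get(diag)

    def dget(score: int, diag: int) -> int | None:
        if score < 0:
            return None
        row = wf.D[score]
        return None if row is None else row.get(diag)

    while True:
        if state == "M":
            if s == 0:
                if k != 0:
                    raise AssertionError("score-0 wavefront off the main diagonal")
                ops.append("=" * h)
                break
            chars_equal = (
                h > 0 and h + k > 0 and qflank[h - 1] == tflank[h - 1 + k]
            )
            if not chars_equal and m_covers(s - px, k, h - 1):
                ops.append("X")
                s -= px
                h -= 1
            elif iget(s, k) == h:
                state = "I"
            elif dget(s, k) == h:
                state = "D"
            elif chars_equal and m_covers(s, k, h - 1):
                ops.append("=")
                h -= 1
            else:
                raise AssertionError("inconsistent wavefront parents")
        elif state == "I":
            ops.append("I")
            if m_covers(s - oe, k + 1, h - 1):
                s -= oe
                k += 1
                h -= 1
                state = "M"
            elif iget(s - pe, k + 1) == h - 1:
                s -= pe
                k += 1
                h -= 1
            else:
                raise AssertionError("inconsistent insertion parents")
        else:  # state == "D"
            ops.append("D")
            if m_covers(s - oe, k - 1, h):
                s -= oe
                k -= 1
                state = "M"
            elif dget(s - pe, k - 1) == h:
                s -= pe
                k -= 1
            else:
                raise AssertionError("inconsistent deletion parents")

    return "".join(reversed(ops))


def extend_side(
    qflank: bytes,
    tflank: bytes,
    spare: int,
    penalties: Penalties,
    max_ppl: Fraction,
    min_delta: Fraction,
) -> SideExtension:
    """Extend one side: forward wavefront pass, endpoint selection,
    canonical backtrace."""
    candidates, wf = wavefront_extend(qflank, tflank, spare, penalties)
    lq, lt = len(qflank), len(tflank)
    chosen = select_endpoint(candidates, lq, lt, max_ppl, min_delta)
    ops = backtrace(wf, chosen, qflank, tflank, penalties)
    return SideExtension(
        ops=ops,
        penalty=chosen.score,
        endpoint=chosen,
        candidates=candidates,
        reached_end=chosen.reached_end(lq, lt),
        tracer=lambda ep: backtrace(wf, ep, qflank, tflank, penalties),
    )
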