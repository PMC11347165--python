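"""Anchor orchestration: extend, assemble, deduplicate, skip, prune.

Anchors are processed per target in ascending (query position, target
position) order.  Each evaluated anchor is extended right (with the
precomputed reverse-index spare penalty) then left (with the budget
derived from the chosen right endpoint's penalty delta), backtraced, and
assembled into one alignment; cutoffs are applied with exact rational
arithmetic.

During backtrace every anchor the alignment path passes through is
recorded.  The set {anchor} | {traversed anchors} -- the alignment's
*symbol* -- drives the skip logic and identifies the result in the common
case; deduplication itself compares the full position+operations
identity, because under extreme cutoffs two anchors sharing a symbol can
pick different endpoints, and two anchors of one gap run can produce one
alignment without mutually traversing each other.

Redundant extensions are skipped through *chain truncation*: when an
evaluated anchor's right path runs through co-diagonal anchors connected
by pure matches, the right extension of each such anchor is exactly the
truncation of the computed one (the candidate sets are translates of one
another and the endpoint ordering is translation-invariant, provided the
downstream anchor's spare penalty still covers the chosen endpoint), and
every chain member shares the same left-extension budget.  Extending the
farthest chain anchor leftward then proves the middle anchors reproduce
the identical alignment, so they are skipped without ever being
extended.  Unlike a heuristic skip, each condition is checked, so output
with skipping enabled is identical to output with it disabled.

Finally, overlapping results are pruned: alignments are ranked by longer
length, then smaller penalty, and a result is dropped when both its query
and target intervals intersect those of a higher-priority result on the
same target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, NamedTuple

from .extend import (
    Endpoint,
    SideExtension,
    extend_side,
    max_penalty_delta,
    op_spans,
)
from .params import Cutoffs, Penalties, derive_constants
from .reference import Reference
from .search import EVALUATED, NEW, SKIPPED, Anchor, collect_anchors

__all__ = ["AlignmentResult", "process_query", "prune_overlaps", "primary_only"]

#: extension engine signature: (query flank, target flank, spare penalty,
#: penalties, MaxP, feasibility floor) -> SideExtension
Extender = Callable[
    [bytes, bytes, int, Penalties, "Fraction", "Fraction"], SideExtension
]


@dataclass(frozen=True)
class AlignmentResult:
    """One alignment: position, penalty, length and operation vector.

    Coordinates are 0-based half-open; ``ops`` runs over ``=XID`` with
    ``I`` consuming query and ``D`` consuming target.
    """

    target_id: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    penalty: int
    length: int
    ops: str
    symbol: frozenset = field(compare=False, repr=False, default=frozenset())

    @property
    def position_key(self) -> tuple[str, int, int, str]:
        return (self.target_id, self.qstart, self.tstart, self.ops)


class Traversal(NamedTuple):
    """An anchor hit by a backtraced path."""

    anchor: Anchor
    op_index: int  # operations consumed when the path reaches the anchor
    pure: bool  # every operation up to the anchor is a match


def _traversed(
    ops: str,
    anchor: Anchor,
    anchor_map: dict[tuple[int, int], Anchor],
    pattern_size: int,
    leftward: bool,
) -> list[Traversal]:
    """Anchors whose position the operation path passes through.

    A traversed anchor must lie strictly on the same side in both
    coordinates (nonzero offsets of equal sign) and sit exactly on the
    path after some operation prefix.  Anchors only start at multiples of
    the pattern size, which keeps the per-operation check cheap.
    """
    q, t = anchor.query_pos, anchor.target_pos
    out: list[Traversal] = []
    step = -1 if leftward else 1
    pure = True
    for idx, op in enumerate(ops):
        if op != "D":
            q += step
        if op != "I":
            t += step
        if op != "=":
            pure = False
        if q != anchor.query_pos and t != anchor.target_pos and q % pattern_size == 0:
            hit = anchor_map.get((q, t))
            if hit is not None:
                out.append(Traversal(hit, idx + 1, pure))
    return out


def prune_overlaps(
    results: list[AlignmentResult], target_order: dict[str, int]
) -> list[AlignmentResult]:
    """Greedy overlap pruning in priority order.

    Priority: longer length, then smaller penalty, then (qstart, tstart,
    target order) ascending for determinism.  Overlap means: same target,
    intersecting query intervals and intersecting target intervals.
    """
    ranked = sorted(
        results,
        key=lambda r: (
            -r.length,
            r.penalty,
            r.qstart,
            r.tstart,
            target_order[r.target_id],
        ),
    )
    kept: list[AlignmentResult] = []
    by_target: dict[str, list[AlignmentResult]] = {}
    for r in ranked:
        clash = False
        for k in by_target.get(r.target_id, ()):
            if (
                r.qstart < k.qend
                and k.qstart < r.qend
                and r.tstart < k.tend
                and k.tstart < r.tend
            ):
                clash = True
                break
        if not clash:
            kept.append(r)
            by_target.setdefault(r.target_id, []).append(r)
    return kept


def primary_only(results: list[AlignmentResult]) -> list[AlignmentResult]:
    """Keep the single alignment covering the longest query span (ties:
    smaller penalty, then position) -- an optional read-mapper-style
    filter, never applied by default."""
    if not results:
        return []
    best = min(
        results,
        key=lambda r: (
            -(r.qend - r.qstart),
            r.penalty,
            r.qstart,
            r.target_id,
            r.tstart,
        ),
    )
    return [best]


class _TargetContext:
    """Evaluation state for one query/target pair."""

    def __init__(self, query, tseq, target_id, derived, extender, results):
        self.query = query
        self.tseq = tseq
        self.target_id = target_id
        self.derived = derived
        self.cutoffs = derived.cutoffs
        self.d = derived.cutoffs.max_penalty_per_length
        self.penalties = derived.penalties
        self.extender = extender
        self.results = results
        self.anchor_map: dict[tuple[int, int], Anchor] = {}
        self.registry: set = set()

    def _target_window(self, spare: int, flank_q: int) -> int:
        # Target progress cannot exceed the query flank length plus the
        # number of affordable deletions, so only that window of the
        # target is materialised; the extra byte keeps "reached the
        # target end" detection exact (an artificial window edge is
        # unreachable, a true end is preserved).
        po, pe = self.penalties.gap_open, self.penalties.gap_extend
        max_gap = (spare - po) // pe if spare >= po + pe else 0
        return flank_q + max_gap + 1

    def right_extension(self, a: Anchor) -> SideExtension:
        # The left side of an anchor without further anchors can
        # contribute at most MaxP * (pattern_size - 1) of penalty delta,
        # which bounds which right endpoints remain cutoff-feasible.
        spare = self.derived.right_spare(a.reverse_index)
        flank_q = len(self.query) - a.query_pos
        window = self._target_window(spare, flank_q)
        return self.extender(
            self.query[a.query_pos :],
            self.tseq[a.target_pos : a.target_pos + window],
            spare,
            self.penalties,
            self.d,
            -self.derived.left_delta_bound,
        )

    def left_extension(self, a: Anchor, rext_endpoint: Endpoint) -> SideExtension:
        delta_r = self.d * rext_endpoint.sel_len() - rext_endpoint.score
        budget = self.derived.left_spare(delta_r, a.query_pos, a.target_pos)
        window = self._target_window(budget, a.query_pos)
        return self.extender(
            self.query[: a.query_pos][::-1],
            self.tseq[max(0, a.target_pos - window) : a.target_pos][::-1],
            budget,
            self.penalties,
            self.d,
            -delta_r,
        )

    def register(
        self, a: Anchor, lext: SideExtension, rext: SideExtension
    ) -> tuple[list[Traversal], list[Traversal], bool]:
        a.state = EVALUATED
        kbar = self.derived.pattern_size
        t_right = _traversed(rext.ops, a, self.anchor_map, kbar, leftward=False)
        t_left = _traversed(lext.ops, a, self.anchor_map, kbar, leftward=True)
        ops = lext.ops[::-1] + rext.ops
        qspan, tspan = op_spans(ops)
        result = AlignmentResult(
            target_id=self.target_id,
            qstart=a.query_pos - lext.query_span,
            qend=a.query_pos - lext.query_span + qspan,
            tstart=a.target_pos - lext.target_span,
            tend=a.target_pos - lext.target_span + tspan,
            penalty=lext.penalty + rext.penalty,
            length=len(ops),
            ops=ops,
            symbol=frozenset(
                {a.key}
                | {t.anchor.key for t in t_left}
                | {t.anchor.key for t in t_right}
            ),
        )
        accepted = self.cutoffs.accepts(result.length, result.penalty)
        if result.position_key not in self.registry:
            self.registry.add(result.position_key)
            if accepted:
                self.results.append(result)
        return t_left, t_right, accepted

    def evaluate_full(
        self, a: Anchor
    ) -> tuple[list[Traversal], list[Traversal], SideExtension]:
        rext = self.right_extension(a)
        lext = self.left_extension(a, rext.endpoint)
        t_left, t_right, accepted = self.register(a, lext, rext)
        if not accepted:
            self.rescue(a, rext)
        return t_left, t_right, rext

    def rescue(self, a: Anchor, rext: SideExtension) -> None:
        """Extract a cutoff-satisfying alignment when the primary endpoint
        pair fails the cutoffs.

        The left side is re-extended with the most generous budget any
        right candidate allows, then all (left, right) endpoint pairs are
        scanned for ones whose exact penalty and length proxy already
        satisfy both cutoffs (the proxy never overestimates length, so a
        qualifying pair is guaranteed to pass after backtrace).  Among
        qualifying pairs the longest aligned span wins, then the lesser
        penalty, then smaller diagonals.  Rare in sensible parameter
        regimes -- it fires mostly when the length cutoff is reachable
        only through gap-heavy endpoint pairs.
        """
        delta_max = max_penalty_delta(rext.candidates, self.d)
        budget = self.derived.left_spare(delta_max, a.query_pos, a.target_pos)
        window = self._target_window(budget, a.query_pos)
        lext_full = self.extender(
            self.query[: a.query_pos][::-1],
            self.tseq[max(0, a.target_pos - window) : a.target_pos][::-1],
            budget,
            self.penalties,
            self.d,
            -delta_max,
        )
        dn = self.d.numerator
        dd = self.d.denominator
        minl = self.cutoffs.min_length
        pe = self.penalties.gap_extend
        best_key = None
        best_pair = None
        near_misses: list[tuple] = []
        for el in lext_full.candidates:
            hl = el.offset
            vl = hl + el.diag
            sel_l = vl if vl > hl else hl
            span_l = hl if hl < vl else vl
            extra_l = max(0, (el.score // pe - abs(el.diag)) // 2)
            for er in rext.candidates:
                hr = er.offset
                vr = hr + er.diag
                sel_r = vr if vr > hr else hr
                span_r = hr if hr < vr else vr
                proxy_len = sel_l + sel_r
                pen = el.score + er.score
                key = (span_l + span_r, -pen, -el.diag, -er.diag)
                if proxy_len >= minl and dn * proxy_len >= pen * dd:
                    if best_key is None or key > best_key:
                        best_key = key
                        best_pair = (el, er)
                elif best_key is None:
                    # The proxy may undercount a path mixing insertions
                    # and deletions by the smaller gap count; keep pairs
                    # that could still qualify within that surplus.
                    extra = extra_l + max(0, (er.score // pe - abs(er.diag)) // 2)
                    opt = proxy_len + extra
                    if opt >= minl and dn * opt >= pen * dd:
                        near_misses.append((key, el, er))
        if best_pair is not None:
            el, er = best_pair
            self._register_pair(a, lext_full, el, rext, er)
            return
        # No pair qualifies on the proxy alone: backtrace the best
        # near-misses and accept the first whose exact length passes.
        near_misses.sort(key=lambda item: item[0], reverse=True)
        for key, el, er in near_misses[:64]:
            lops = lext_full.tracer(el)
            rops = rext.tracer(er)
            if self.cutoffs.accepts(len(lops) + len(rops), el.score + er.score):
                self._register_pair(a, lext_full, el, rext, er, lops, rops)
                return

    def _register_pair(self, a, lext_full, el, rext, er, lops=None, rops=None):
        lops = lops if lops is not None else lext_full.tracer(el)
        rops = rops if rops is not None else rext.tracer(er)
        self.register(
            a,
            SideExtension(
                ops=lops,
                penalty=el.score,
                endpoint=el,
                candidates=[],
                reached_end=False,
            ),
            SideExtension(
                ops=rops,
                penalty=er.score,
                endpoint=er,
                candidates=[],
                reached_end=False,
            ),
        )

    def process_chain(self, a: Anchor, rext: SideExtension, t_right: list[Traversal]):
        """Skip provably redundant anchors on ``a``'s right match chain.

        Chain members are anchors the chosen right path reaches through
        matches only, whose own spare penalty still covers the chosen
        endpoint; their right extensions are truncations of ``a``'s, and
        every member shares ``a``'s left budget.  The farthest member is
        extended leftward once; members its left path reaches back through
        matches provably reproduce the same alignment and are skipped.
        """
        # Conditions per member m at query distance delta: the chosen
        # endpoint must fit m's own spare penalty, and its feasibility
        # margin must survive the delta shift (the feasibility threshold
        # is fixed while the endpoint's delta shrinks by MaxP * delta).
        ep = rext.endpoint
        margin = (
            self.d * ep.sel_len() - ep.score + self.derived.left_delta_bound
        )
        chain = [
            t
            for t in t_right
            if t.pure
            and t.anchor.state == NEW
            and ep.score <= self.derived.right_spare(t.anchor.reverse_index)
            and margin >= self.d * (t.anchor.query_pos - a.query_pos)
        ]
        if not chain:
            return
        far = max(chain, key=lambda t: t.op_index)
        m = far.anchor
        delta = m.query_pos - a.query_pos  # == far.op_index for a pure prefix
        rext_m = SideExtension(
            ops=rext.ops[delta:],
            penalty=ep.score,
            endpoint=Endpoint(ep.score, ep.diag, ep.offset - delta),
            candidates=[],
            reached_end=rext.reached_end,
        )
        lext_m = self.left_extension(m, rext_m.endpoint)
        ops_len = len(lext_m.ops) + len(rext_m.ops)
        if not self.cutoffs.accepts(ops_len, lext_m.penalty + rext_m.penalty):
            # The truncated alignment fails the cutoffs; the far anchor
            # (and the middles) would fall back to pair extraction, whose
            # outcome is not a truncation -- evaluate them individually.
            return
        self.register(m, lext_m, rext_m)
        # Middle anchors the far anchor's left path re-traverses through
        # matches yield this same alignment: skip them.
        back_pure = {
            t.anchor.key for t in _traversed(
                lext_m.ops, m, self.anchor_map, self.derived.pattern_size, True
            ) if t.pure
        }
        for t in chain:
            c = t.anchor
            if c.state == NEW and c.key in back_pure:
                c.state = SKIPPED


def process_query(
    query: bytes,
    reference: Reference,
    penalties: Penalties,
    cutoffs: Cutoffs,
    *,
    extender: Extender = extend_side,
    skipping: bool = True,
    prune: bool = True,
) -> list[AlignmentResult]:
    """Align one query against every target; return the final result list.

    Deterministic for fixed inputs.  ``extender``, ``skipping`` and
    ``prune`` exist so tests can swap the engine and disable each pruning
    mechanism independently; defaults are the production pipeline.
    """
    derived = derive_constants(penalties, cutoffs)
    table = collect_anchors(query, reference, derived)
    target_order = {t.id: i for i, t in enumerate(reference.targets)}

    results: list[AlignmentResult] = []
    for target in reference.targets:
        anchors = table.get(target.id)
        if not anchors:
            continue
        ctx = _TargetContext(
            query, target.sequence, target.id, derived, extender, results
        )
        ctx.anchor_map = {a.key: a for a in anchors}
        for a in anchors:
            if a.state != NEW:
                continue
            _, t_right, rext = ctx.evaluate_full(a)
            if skipping:
                ctx.process_chain(a, rext, t_right)

    if prune:
        results = prune_overlaps(results, target_order)
    else:
        results = sorted(
            results,
            key=lambda r: (
                -r.length,
                r.penalty,
                r.qstart,
                r.tstart,
                target_order[r.target_id],
            ),
        )
    return results
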