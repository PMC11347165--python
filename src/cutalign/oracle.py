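"""Reference semantics by dynamic programming.

The aligner's defining claim is that its output can be reproduced by
ordinary dynamic programming plus cutoff filtering.  This module holds the
machinery that makes the claim testable:

* :func:`gotoh_matrices` / :func:`dp_extend_side` -- full-matrix affine-gap
  (Gotoh) extension of one anchor side, an exhaustive drop-in for the
  wavefront engine with identical endpoint-selection and canonical
  backtrace rules;
* :func:`enumerate_alignments_bruteforce` -- exhaustive enumeration of all
  cutoff-satisfying local alignments of two tiny sequences;
* :func:`feasible_alignment_exists` / :func:`feasible_intervals` --
  length-layered DP formulations of the same question that scale to the
  fuzzing volumes the property tests need;
* :func:`pipeline_unpruned` -- the whole pipeline run with the exhaustive
  engine and anchor skipping disabled.

Everything here trades speed for directness and is meant for testing; the
input-size guards on the brute-force enumerator are deliberate.
"""

from __future__ import annotations

import numpy as np

from .extend import Endpoint, SideExtension, select_endpoint
from .params import Cutoffs, Penalties

__all__ = [
    "gotoh_matrices",
    "gotoh_min_penalty",
    "dp_extend_side",
    "enumerate_alignments_bruteforce",
    "feasible_alignment_exists",
    "feasible_intervals",
    "pipeline_unpruned",
]

INF = 1 << 40


def gotoh_matrices(
    qflank: bytes, tflank: bytes, penalties: Penalties
) -> tuple[list[list[int]], list[list[int]], list[list[int]]]:
    """Minimal penalty to consume (i, j) flank prefixes, per end state.

    Returns (SA, SI, SD): ending in match/substitution, in an insertion
    (query-consuming gap), or in a deletion (target-consuming gap).  Gaps
    may open from any state (full reopen cost applies between abutting
    gaps of different kinds).
    """
    lq, lt = len(qflank), len(tflank)
    px, po, pe = penalties.mismatch, penalties.gap_open, penalties.gap_extend
    oe = po + pe
    SA = [[INF] * (lt + 1) for _ in range(lq + 1)]
    SI = [[INF] * (lt + 1) for _ in range(lq + 1)]
    SD = [[INF] * (lt + 1) for _ in range(lq + 1)]
    best_prev: list[int] = [0] * (lt + 1)  # best of row i-1; row 0 is all-gap
    # Row 0: only deletions possible.
    for j in range(1, lt + 1):
        SD[0][j] = po + j * pe
        best_prev[j] = SD[0][j]
    for i in range(1, lq + 1):
        qc = qflank[i - 1]
        row_a, row_i, row_d = SA[i], SI[i], SD[i]
        prev_i = SI[i - 1]
        best_here = [0] * (lt + 1)
        # j = 0 column: only insertions.
        row_i[0] = min(best_prev[0] + oe, prev_i[0] + pe)
        best_here[0] = row_i[0]
        for j in range(1, lt + 1):
            a = best_prev[j - 1] + (0 if qc == tflank[j - 1] else px)
            gi = min(best_prev[j] + oe, prev_i[j] + pe)
            gd = min(best_here[j - 1] + oe, row_d[j - 1] + pe)
            row_a[j] = a
            row_i[j] = gi
            row_d[j] = gd
            best_here[j] = min(a, gi, gd)
        best_prev = best_here
    return SA, SI, SD


def _best(SA, SI, SD, i: int, j: int) -> int:
    """Minimal penalty at a prefix pair over all end states (0 at the
    origin, which no gap/diagonal state can represent)."""
    if i == 0 and j == 0:
        return 0
    return min(SA[i][j], SI[i][j], SD[i][j])


def gotoh_min_penalty(qflank: bytes, tflank: bytes, penalties: Penalties):
    """Matrix of min penalties to each (i, j) prefix pair (any end state)."""
    SA, SI, SD = gotoh_matrices(qflank, tflank, penalties)
    lq, lt = len(qflank), len(tflank)
    return [
        [_best(SA, SI, SD, i, j) for j in range(lt + 1)]
        for i in range(lq + 1)
    ]


def _canonical_walk(
    SA, SI, SD, qflank: bytes, tflank: bytes, penalties: Penalties, endpoint: Endpoint
) -> str:
    """Canonical minimal-penalty path to an endpoint.

    Walks backward preferring, at each point, substitution, then entering
    an insertion, then a deletion, and a match only when no same-score
    junction exists; inside a gap the gap closes as early as possible.
    These are the same tie-break rules the wavefront backtrace applies, so
    the two engines produce identical operation vectors.
    """
    px, po, pe = penalties.mismatch, penalties.gap_open, penalties.gap_extend
    oe = po + pe
    i, j = endpoint.query_used, endpoint.target_used
    s = _best(SA, SI, SD, i, j)
    ops: list[str] = []
    state = "B"
    while i > 0 or j > 0:
        if s == 0 and state == "B":
            # Only matches can remain.
            while i > 0 and j > 0 and qflank[i - 1] == tflank[j - 1]:
                ops.append("=")
                i -= 1
                j -= 1
            if i or j:
                raise AssertionError("walk ended off the origin")
            break
        if state == "B":
            best_diag = (
                _best(SA, SI, SD, i - 1, j - 1) if i > 0 and j > 0 else INF
            )
            if (
                i > 0
                and j > 0
                and qflank[i - 1] != tflank[j - 1]
                and best_diag + px == s
            ):
                ops.append("X")
                i -= 1
                j -= 1
                s -= px
            elif i > 0 and SI[i][j] == s:
                state = "I"
            elif j > 0 and SD[i][j] == s:
                state = "D"
            elif (
                i > 0
                and j > 0
                and qflank[i - 1] == tflank[j - 1]
                and best_diag == s
            ):
                ops.append("=")
                i -= 1
                j -= 1
            else:
                raise AssertionError("no canonical predecessor")
        elif state == "I":
            ops.append("I")
            prev_best = _best(SA, SI, SD, i - 1, j) if i > 0 else INF
            if prev_best + oe == s:
                i -= 1
                s -= oe
                state = "B"
            elif i > 0 and SI[i - 1][j] + pe == s:
                i -= 1
                s -= pe
            else:
                raise AssertionError("broken insertion chain")
        else:  # "D"
            ops.append("D")
            prev_best = _best(SA, SI, SD, i, j - 1) if j > 0 else INF
            if prev_best + oe == s:
                j -= 1
                s -= oe
                state = "B"
            elif j > 0 and SD[i][j - 1] + pe == s:
                j -= 1
                s -= pe
            else:
                raise AssertionError("broken deletion chain")
    return "".join(reversed(ops))


def dp_extend_side(
    qflank: bytes,
    tflank: bytes,
    spare: int,
    penalties: Penalties,
    max_ppl,
    min_delta,
) -> SideExtension:
    """Exhaustive-DP replacement for the wavefront side extension.

    Enumerates every prefix pair within the spare-penalty budget as an
    endpoint candidate and applies the shared selection and canonical
    backtrace rules.
    """
    lq, lt = len(qflank), len(tflank)
    SA, SI, SD = gotoh_matrices(qflank, tflank, penalties)
    # Candidate reduction mirroring the wavefront: per diagonal, the
    # furthest cell of each minimal score, kept only when it out-reaches
    # every cheaper cell of the diagonal (dominated cells can never win
    # endpoint selection nor improve a cutoff-satisfying pair).
    per_diag: dict[int, dict[int, int]] = {}
    for i in range(lq + 1):
        for j in range(lt + 1):
            s = _best(SA, SI, SD, i, j)
            if s <= spare:
                row = per_diag.setdefault(j - i, {})
                if s not in row or i > row[s]:
                    row[s] = i
    candidates: list[Endpoint] = []
    for k, row in per_diag.items():
        furthest = -1
        for s in sorted(row):
            if row[s] > furthest:
                furthest = row[s]
                candidates.append(Endpoint(score=s, diag=k, offset=furthest))
    chosen = select_endpoint(candidates, lq, lt, max_ppl, min_delta)
    ops = _canonical_walk(SA, SI, SD, qflank, tflank, penalties, chosen)
    return SideExtension(
        ops=ops,
        penalty=chosen.score,
        endpoint=chosen,
        candidates=candidates,
        reached_end=chosen.reached_end(lq, lt),
        tracer=lambda ep: _canonical_walk(
            SA, SI, SD, qflank, tflank, penalties, ep
        ),
    )


def enumerate_alignments_bruteforce(
    query: bytes,
    target: bytes,
    penalties: Penalties,
    cutoffs: Cutoffs,
    max_query: int = 25,
    max_target: int = 40,
) -> set[tuple[int, int, str]]:
    """Every cutoff-satisfying local alignment, as (qstart, tstart, ops).

    Recursively enumerates operation paths from every start pair, pruning
    branches whose penalty already exceeds the cutoff ratio at the maximal
    achievable remaining length.  Exponential: refuses inputs beyond the
    stated size limits.
    """
    if len(query) > max_query or len(target) > max_target:
        raise ValueError("sequences too large for exhaustive enumeration")
    px, po, pe = penalties.mismatch, penalties.gap_open, penalties.gap_extend
    d = cutoffs.max_penalty_per_length
    dn, dd = d.numerator, d.denominator
    minl = cutoffs.min_length
    lq, lt = len(query), len(target)
    out: set[tuple[int, int, str]] = set()

    def walk(qs: int, ts: int, qi: int, tj: int, p: int, ops: list[str], last: str):
        length = len(ops)
        if length >= minl and p * dd <= dn * length:
            out.add((qs, ts, "".join(ops)))
        max_len = length + (lq - qi) + (lt - tj)
        if p * dd > dn * max_len:
            return
        if qi < lq and tj < lt:
            cost = 0 if query[qi] == target[tj] else px
            ops.append("=" if cost == 0 else "X")
            walk(qs, ts, qi + 1, tj + 1, p + cost, ops, "A")
            ops.pop()
        if qi < lq:
            ops.append("I")
            walk(qs, ts, qi + 1, tj, p + pe + (0 if last == "I" else po), ops, "I")
            ops.pop()
        if tj < lt:
            ops.append("D")
            walk(qs, ts, qi, tj + 1, p + pe + (0 if last == "D" else po), ops, "D")
            ops.pop()

    for qs in range(lq):
        for ts in range(lt):
            walk(qs, ts, qs, ts, 0, [], "")
    return out


def _layered_best(
    init: np.ndarray, query: bytes, target: bytes, penalties: Penalties
):
    """Yield (L, best-penalty matrix) over alignment length L = 1, 2, ...

    Layer L holds, per prefix-pair end point and gap state, the minimal
    penalty of an exact-length-L alignment ending there, starting from any
    cell where ``init`` is 0.
    """
    lq, lt = len(query), len(target)
    px, po, pe = penalties.mismatch, penalties.gap_open, penalties.gap_extend
    oe = po + pe
    q = np.frombuffer(query, dtype=np.uint8)
    t = np.frombuffer(target, dtype=np.uint8)
    sub = np.where(q[:, None] == t[None, :], 0, px).astype(np.int64)
    best = init.astype(np.int64)
    gi = np.full_like(best, INF)
    gd = np.full_like(best, INF)
    for L in range(1, lq + lt + 1):
        na = np.full_like(best, INF)
        na[1:, 1:] = best[:-1, :-1] + sub
        ni = np.full_like(best, INF)
        ni[1:, :] = np.minimum(best[:-1, :] + oe, gi[:-1, :] + pe)
        nd = np.full_like(best, INF)
        nd[:, 1:] = np.minimum(best[:, :-1] + oe, gd[:, :-1] + pe)
        gi, gd = ni, nd
        best = np.minimum(na, np.minimum(ni, nd))
        if best.min() >= INF:
            return
        yield L, best


def feasible_alignment_exists(
    query: bytes, target: bytes, penalties: Penalties, cutoffs: Cutoffs
) -> bool:
    """Does any local alignment satisfy the cutoffs?

    Length-layered DP over all start positions at once; equivalent to
    asking the brute-force enumerator whether its result set is non-empty,
    but polynomial.
    """
    lq, lt = len(query), len(target)
    if lq == 0 or lt == 0:
        return False
    d = cutoffs.max_penalty_per_length
    init = np.zeros((lq + 1, lt + 1), dtype=np.int64)
    for L, best in _layered_best(init, query, target, penalties):
        if L < cutoffs.min_length:
            continue
        if int(best.min()) * d.denominator <= d.numerator * L:
            return True
    return False


def feasible_intervals(
    query: bytes,
    target: bytes,
    penalties: Penalties,
    cutoffs: Cutoffs,
    strong: bool = False,
) -> set[tuple[int, int, int, int]]:
    """(qstart, qend, tstart, tend) of every cutoff-satisfying alignment.

    With ``strong=True`` only intervals whose *canonical representative*
    satisfies the cutoffs are reported: for each endpoint pair, the
    shortest alignment among those of minimal penalty.  Operation
    variants that reach the length cutoff only by inflating the operation
    count at equal penalty (extra paired insertions/deletions) exist in
    the weak set but are not produced by any minimal-path backtrace, and
    every backtraced path is at least as long as the canonical
    representative, so the strong set is the completeness contract of a
    seed-and-extend pipeline.

    Exact per-start layered DP; quadratic per start pair, so intended for
    small fuzzing instances only.
    """
    lq, lt = len(query), len(target)
    d = cutoffs.max_penalty_per_length
    out: set[tuple[int, int, int, int]] = set()
    for qs in range(lq):
        for ts in range(lt):
            init = np.full((lq + 1, lt + 1), INF, dtype=np.int64)
            init[qs, ts] = 0
            if strong:
                best_p = np.full((lq + 1, lt + 1), INF, dtype=np.int64)
                best_len = np.zeros((lq + 1, lt + 1), dtype=np.int64)
                for L, best in _layered_best(init, query, target, penalties):
                    improved = best < best_p
                    best_p[improved] = best[improved]
                    best_len[improved] = L
                ok = np.argwhere(
                    (best_p < INF)
                    & (best_len >= cutoffs.min_length)
                    & (best_p * d.denominator <= d.numerator * best_len)
                )
                for qe, te in ok:
                    out.add((qs, int(qe), ts, int(te)))
            else:
                for L, best in _layered_best(init, query, target, penalties):
                    if L < cutoffs.min_length:
                        continue
                    ok = np.argwhere(best * d.denominator <= d.numerator * L)
                    for qe, te in ok:
                        out.add((qs, int(qe), ts, int(te)))
    return out


def pipeline_unpruned(query: bytes, reference, penalties, cutoffs, **kwargs):
    """Full pipeline with the exhaustive DP engine and skipping disabled;
    the arbiter for pruning soundness."""
    from .evaluate import process_query

    return process_query(
        query,
        reference,
        penalties,
        cutoffs,
        extender=dp_extend_side,
        skipping=False,
        **kwargs,
    )
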