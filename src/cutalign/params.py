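"""Alignment parameters and the constants derived from them.

The aligner is controlled by five user-facing numbers: three affine gap
penalties (mismatch ``p_x``, gap-open ``p_o``, gap-extend ``p_e``; matches
cost 0 and a gap of length ``g`` costs ``p_o + g*p_e``) and two similarity
cutoffs (minimum alignment length ``min_length`` and maximum
penalty-per-length ``max_penalty_per_length``).  Everything else the
algorithm needs is a pure function of these five values:

* ``p1``/``p2`` -- the cheapest cost of breaking one (resp. a second,
  gap-sharing) k-mer block of the query;
* the maximal anchoring pattern size ``k`` for which the quotient-filter
  guarantee holds ("if any alignment satisfies the cutoffs, at least one
  length-k pattern of the query occurs exactly in the target");
* the spare (stopping) penalties that bound wavefront extension on each
  side of an anchor without ever truncating a cutoff-satisfying alignment.

All ratio arithmetic is carried out in exact rational numbers
(:class:`fractions.Fraction`) so floors and comparisons are bit-identical
across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Union

__all__ = [
    "Penalties",
    "Cutoffs",
    "DerivedConstants",
    "ParameterError",
    "InfeasibleCutoffError",
    "validate_params",
    "compute_p1_p2",
    "min_total_penalty",
    "min_penalty_per_length",
    "compute_pattern_size",
    "right_spare_penalty",
    "left_spare_penalty",
    "derive_constants",
]

#: how many consecutive failing pattern sizes end the iterative k search
K_SEARCH_WINDOW = 8

RatioLike = Union[int, str, float, Fraction]


class ParameterError(ValueError):
    """A penalty or cutoff violates its type invariant."""


class InfeasibleCutoffError(ParameterError):
    """The cutoffs are outside the range the anchoring guarantee supports."""


def _as_fraction(value: RatioLike) -> Fraction:
    """Parse a user-supplied ratio exactly.

    Decimal strings ("0.08") convert exactly; floats go through their
    shortest decimal repr so that e.g. 0.08 means 8/100, not the nearest
    binary double.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(repr(value))
    return Fraction(str(value))


@dataclass(frozen=True)
class Penalties:
    """Affine gap penalties: mismatch, gap-open, gap-extend."""

    mismatch: int
    gap_open: int
    gap_extend: int

    def __post_init__(self) -> None:
        for name in ("mismatch", "gap_open", "gap_extend"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ParameterError(f"{name} must be an integer, got {v!r}")
        if self.mismatch < 1:
            raise ParameterError("mismatch penalty must be >= 1")
        if self.gap_extend < 1:
            raise ParameterError("gap-extend penalty must be >= 1")
        if self.gap_open < 0:
            raise ParameterError("gap-open penalty must be >= 0")

    def gap_cost(self, length: int) -> int:
        return self.gap_open + length * self.gap_extend if length > 0 else 0


@dataclass(frozen=True)
class Cutoffs:
    """Similarity cutoffs: minimum length and maximum penalty per length."""

    min_length: int
    max_penalty_per_length: Fraction

    def __init__(self, min_length: int, max_penalty_per_length: RatioLike):
        object.__setattr__(self, "min_length", min_length)
        object.__setattr__(
            self, "max_penalty_per_length", _as_fraction(max_penalty_per_length)
        )
        if not isinstance(min_length, int) or isinstance(min_length, bool):
            raise ParameterError("min_length must be an integer")
        if min_length < 1:
            raise ParameterError("min_length must be >= 1")
        if self.max_penalty_per_length <= 0:
            raise InfeasibleCutoffError(
                "max penalty per length must be > 0 "
                f"(got {self.max_penalty_per_length})"
            )

    def accepts(self, length: int, penalty: int) -> bool:
        """Exact rational test: length >= MinL and penalty/length <= MaxP."""
        if length < self.min_length:
            return False
        d = self.max_penalty_per_length
        return penalty * d.denominator <= d.numerator * length


def validate_params(penalties: Penalties, cutoffs: Cutoffs) -> tuple[Penalties, Cutoffs]:
    """Check the joint invariant 0 < MaxP < gap_extend and return the pair.

    The denominator ``p_e - MaxP`` appears in every spare-penalty formula,
    so MaxP at or above the gap-extend penalty makes the stopping bounds
    meaningless (arbitrarily long all-gap tails would satisfy the ratio).
    """
    d = cutoffs.max_penalty_per_length
    if d >= penalties.gap_extend:
        raise InfeasibleCutoffError(
            f"max penalty per length ({d}) must be < gap-extend penalty "
            f"({penalties.gap_extend})"
        )
    return penalties, cutoffs


def compute_p1_p2(penalties: Penalties) -> tuple[int, int]:
    """Cheapest penalties that break one k-mer block (p1) and a second,
    gap-sharing block (p1 + p2)."""
    px, po, pe = penalties.mismatch, penalties.gap_open, penalties.gap_extend
    p1 = min(px, po + pe)
    p2 = min(2 * px, po + 2 * pe) - p1
    return p1, p2


def min_total_penalty(n: int, p1: int, p2: int) -> int:
    """Minimum penalty of an alignment in which none of n consecutive
    k-mer blocks of the query is matched intact: p1*ceil(n/2) + p2*floor(n/2)."""
    if n < 0:
        raise ValueError("block count must be >= 0")
    return p1 * ((n + 1) // 2) + p2 * (n // 2)


def min_penalty_per_length(
    n: int, k: int, penalties: Penalties, p1: int, p2: int
) -> Fraction:
    """Lower bound on penalty-per-length over alignments spanning n broken
    k-mer blocks, at the length-maximising gap allocation.

    Even n = 2m:   m(p1+p2) / ((2m+2)(k+1) - 4 + p1/p_e)
    Odd  n = 2m-1: (m(p1+p2) - p2) / ((2m+1)(k+1) - 4 + p1/p_e)
    """
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    pe = penalties.gap_extend
    slack = Fraction(p1, pe)
    if n % 2 == 0:
        m = n // 2
        num = m * (p1 + p2)
        den = (2 * m + 2) * (k + 1) - 4 + slack
    else:
        m = (n + 1) // 2
        num = m * (p1 + p2) - p2
        den = (2 * m + 1) * (k + 1) - 4 + slack
    return Fraction(num) / den


def _n_hat_exact(k: int, min_length: int, p1: int, pe: int) -> int:
    """Smallest block count whose maximal spanned length reaches MinL:
    floor((MinL + 4 - p1/p_e) / (k+1)) - 2, in exact arithmetic."""
    val = (Fraction(min_length + 4) - Fraction(p1, pe)) / (k + 1)
    return math.floor(val) - 2


def _pattern_ok(
    k: int, penalties: Penalties, cutoffs: Cutoffs, p1: int, p2: int
) -> bool:
    """Quotient-filter predicate for pattern size k.

    True when, for the two relevant block counts at MinL, every alignment
    breaking all its patterns has penalty-per-length strictly above MaxP.
    The derivation presumes at least one broken block, so n_hat < 1 fails.
    """
    n = _n_hat_exact(k, cutoffs.min_length, p1, penalties.gap_extend)
    if n < 1:
        return False
    d = cutoffs.max_penalty_per_length
    return (
        min_penalty_per_length(n, k, penalties, p1, p2) > d
        and min_penalty_per_length(n + 1, k, penalties, p1, p2) > d
    )


def compute_pattern_size(penalties: Penalties, cutoffs: Cutoffs) -> int:
    """Largest pattern size k for which the anchoring guarantee holds.

    The predicate is evaluated iteratively for k = 1, 2, ...; the search
    stops once it has failed for ``K_SEARCH_WINDOW`` consecutive sizes
    (it is not proven monotone in k) and the maximum passing k is returned.
    """
    validate_params(penalties, cutoffs)
    p1, p2 = compute_p1_p2(penalties)
    d = cutoffs.max_penalty_per_length

    best = 0
    k = 1
    fails = 0
    while fails < K_SEARCH_WINDOW:
        if _pattern_ok(k, penalties, cutoffs, p1, p2):
            best = k
            fails = 0
        else:
            fails += 1
        k += 1
    if best == 0:
        raise InfeasibleCutoffError(
            "no pattern size satisfies the anchoring guarantee for cutoffs "
            f"(min_length={cutoffs.min_length}, max_penalty_per_length={d}); "
            "the cutoffs are too lenient for complete anchoring"
        )
    # A broken pattern must always cost more per base than the cutoff,
    # otherwise the fixed left-delta bound below would be unsound.
    if not (Fraction(p1, best) > d and Fraction(p1 + p2, 2 * best) > d):
        raise InfeasibleCutoffError(
            f"pattern size {best} violates the per-pattern penalty bound "
            f"(p1/k or (p1+p2)/2k not above {d})"
        )
    return best


def right_spare_penalty(
    j: int, pattern_size: int, penalties: Penalties, cutoffs: Cutoffs
) -> int:
    """Stopping penalty for rightward extension of an anchor whose pattern
    has reverse index ``j`` (0 = rightmost pattern of the query).

    floor( MaxP * (p_e*(k*(j+3) - 2) - p_o) / (p_e - MaxP) ), never below
    the gap-open penalty: the bound is an upper stopping budget, and
    capping it below gap-open could stop extension before a single gap can
    open, so gap-open serves as the floor of the table.
    """
    if j < 0:
        raise ValueError("reverse pattern index must be >= 0")
    d = cutoffs.max_penalty_per_length
    po, pe = penalties.gap_open, penalties.gap_extend
    k = pattern_size
    val = d * (pe * (k * (j + 3) - 2) - po) / (pe - d)
    return max(math.floor(val), po)


def left_spare_penalty(
    right_delta: Fraction,
    left_query_len: int,
    left_target_len: int,
    penalties: Penalties,
    cutoffs: Cutoffs,
) -> int:
    """Stopping penalty for leftward extension given the right side's
    penalty delta (MaxP * right_length - right_penalty).

    Both branches of the budget formula (the below-gap-open linear form and
    the general rational form) are evaluated exactly and the maximum taken,
    clamped at zero: over-budgeting is safe (slower, never lossy) while a
    negative stopping penalty is meaningless.
    """
    d = cutoffs.max_penalty_per_length
    po, pe = penalties.gap_open, penalties.gap_extend
    reach = min(left_query_len, left_target_len)
    low_branch = math.floor(right_delta + d * reach)
    high_branch = math.floor((pe * right_delta + d * pe * reach - d * po) / (pe - d))
    return max(low_branch, high_branch, 0)


@dataclass(frozen=True)
class DerivedConstants:
    """All algorithm constants derived from one (Penalties, Cutoffs) pair."""

    penalties: Penalties
    cutoffs: Cutoffs
    p1: int
    p2: int
    pattern_size: int
    #: fixed bound on the left penalty delta used while extending right
    #: first: MaxP * (pattern_size - 1), the best a left flank without any
    #: further anchor can contribute.
    left_delta_bound: Fraction = field(repr=False)

    def right_spare(self, j: int) -> int:
        return _right_spare_cached(
            j, self.pattern_size, self.penalties, self.cutoffs
        )

    def left_spare(self, right_delta: Fraction, lq: int, lt: int) -> int:
        return left_spare_penalty(right_delta, lq, lt, self.penalties, self.cutoffs)


@lru_cache(maxsize=None)
def _right_spare_cached(
    j: int, pattern_size: int, penalties: Penalties, cutoffs: Cutoffs
) -> int:
    return right_spare_penalty(j, pattern_size, penalties, cutoffs)


@lru_cache(maxsize=None)
def derive_constants(penalties: Penalties, cutoffs: Cutoffs) -> DerivedConstants:
    """Validate parameters and derive every constant the pipeline needs.

    Pure in its inputs; cached so per-query preset scaling reuses work for
    repeated query lengths.
    """
    validate_params(penalties, cutoffs)
    p1, p2 = compute_p1_p2(penalties)
    k = compute_pattern_size(penalties, cutoffs)
    d = cutoffs.max_penalty_per_length
    return DerivedConstants(
        penalties=penalties,
        cutoffs=cutoffs,
        p1=p1,
        p2=p2,
        pattern_size=k,
        left_delta_bound=d * (k - 1),
    )
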