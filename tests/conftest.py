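"""Shared fixtures and fuzzing helpers.

All randomness is seeded so every run of the suite is identical.
"""

from __future__ import annotations

import random
from fractions import Fraction

import pytest

from cutalign.params import (
    Cutoffs,
    InfeasibleCutoffError,
    Penalties,
    derive_constants,
)

BASES = b"ACGT"


def rand_seq(rng: random.Random, n: int) -> bytes:
    return bytes(rng.choice(BASES) for _ in range(n))


def mutate_seq(rng: random.Random, seq: bytes, n_edits: int) -> bytes:
    """Apply point substitutions and single-base indels."""
    s = bytearray(seq)
    for _ in range(n_edits):
        if not s:
            break
        i = rng.randrange(len(s))
        r = rng.random()
        if r < 0.6:
            s[i] = rng.choice(BASES)
        elif r < 0.8 and len(s) > 5:
            del s[i]
        else:
            s.insert(i, rng.choice(BASES))
    return bytes(s)


def draw_params(rng: random.Random, max_minl: int = 30):
    """One random parameter bundle within the anchoring-feasible regime.

    Draws penalties and cutoffs broadly (any MaxP below the gap-extend
    penalty) and rejects combinations for which no pattern size satisfies
    the quotient-filter guarantee -- those are contract errors, exercised
    separately.
    """
    while True:
        pen = Penalties(
            mismatch=rng.randint(1, 6),
            gap_open=rng.randint(0, 7),
            gap_extend=rng.randint(1, 4),
        )
        d = Fraction(rng.randint(1, 8 * pen.gap_extend - 1), 8)
        if d >= pen.gap_extend:
            continue
        cut = Cutoffs(min_length=rng.randint(1, max_minl), max_penalty_per_length=d)
        try:
            derive_constants(pen, cut)
        except InfeasibleCutoffError:
            continue
        return pen, cut


def fuzz_instance(rng: random.Random, max_q: int = 40, max_t: int = 60):
    """A (query, target) pair, usually with a planted similar region."""
    lt = rng.randint(5, max_t)
    target = rand_seq(rng, lt)
    if rng.random() < 0.6 and lt > 12:
        a = rng.randrange(0, lt // 2)
        b = rng.randint(a + 8, lt)
        query = mutate_seq(rng, target[a:b], rng.randint(0, 3))
        query = (
            rand_seq(rng, rng.randint(0, 4))
            + query
            + rand_seq(rng, rng.randint(0, 4))
        )
        query = query[:max_q]
    else:
        query = rand_seq(rng, rng.randint(1, max_q))
    return query, target


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240716)


@pytest.fixture
def default_penalties() -> Penalties:
    return Penalties(mismatch=4, gap_open=6, gap_extend=2)
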