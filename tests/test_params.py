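"""Parameter validation and derived-constant mathematics."""

from fractions import Fraction

import pytest

from cutalign.params import (
    Cutoffs,
    InfeasibleCutoffError,
    ParameterError,
    Penalties,
    compute_p1_p2,
    compute_pattern_size,
    derive_constants,
    left_spare_penalty,
    min_penalty_per_length,
    min_total_penalty,
    right_spare_penalty,
    validate_params,
)


def min_block_break_penalty(n: int, k: int, penalties: Penalties) -> int:
    """Independent oracle: cheapest way to damage all of n consecutive
    k-mer blocks of a query.

    Enumerates operation sequences over the n*k query positions by depth-
    first search.  A block survives (is "matched") when its k positions
    are consumed by k consecutive matches with no deletion opening inside
    it; every block must be damaged.  Gap runs may span block boundaries
    and then damage two blocks at once.
    """
    px, po, pe = penalties.mismatch, penalties.gap_open, penalties.gap_extend
    total = n * k
    best = [n * (po + k * pe) + n * px]  # loose upper bound

    def walk(pos, cost, last, damaged, dels):
        if cost >= best[0]:
            return
        if pos == total:
            if all(damaged):
                best[0] = cost
            return
        block = pos // k
        # match: no damage
        walk(pos + 1, cost, "M", damaged, 0)
        d = list(damaged)
        d[block] = True
        d = tuple(d)
        # substitution damages the block of this position
        walk(pos + 1, cost + px, "S", d, 0)
        # insertion consumes the query position: damages its block; an
        # insertion run spanning a boundary damages two blocks at once
        walk(pos + 1, cost + pe + (0 if last == "I" else po), "I", d, 0)
        # deletion consumes target only; it damages a block only when it
        # falls strictly inside it; two per site already saturate
        if dels < 2:
            d2 = list(damaged)
            if pos % k != 0:
                d2[block] = True
            walk(pos, cost + pe + (0 if last == "D" else po), "D", tuple(d2), dels + 1)

    walk(0, 0, "", tuple([False] * n), 0)
    return best[0]


class TestValidation:
    def test_reference_parameters_are_valid(self):
        pen = Penalties(4, 6, 2)
        cut = Cutoffs(200, "0.08")
        assert validate_params(pen, cut) == (pen, cut)
        assert cut.max_penalty_per_length == Fraction(2, 25)

    def test_max_ppl_at_gap_extend_rejected(self):
        with pytest.raises(InfeasibleCutoffError, match="gap-extend"):
            validate_params(Penalties(4, 6, 2), Cutoffs(100, "2.0"))

    def test_zero_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            Penalties(0, 6, 2)

    @pytest.mark.parametrize(
        "bad",
        [dict(mismatch=4.0, gap_open=6, gap_extend=2),
         dict(mismatch=4, gap_open=-1, gap_extend=2),
         dict(mismatch=4, gap_open=6, gap_extend=0)],
    )
    def test_bad_penalties_rejected(self, bad):
        with pytest.raises(ParameterError):
            Penalties(**bad)

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ParameterError):
            Cutoffs(0, "0.1")
        with pytest.raises(InfeasibleCutoffError):
            Cutoffs(10, "-0.1")

    def test_exact_decimal_parsing(self):
        assert Cutoffs(10, 0.08).max_penalty_per_length == Fraction(2, 25)
        assert Cutoffs(10, "0.125").max_penalty_per_length == Fraction(1, 8)


class TestBlockPenalties:
    @pytest.mark.parametrize(
        "pen,expected",
        [((4, 6, 2), (4, 4)), ((10, 1, 1), (2, 1)), ((1, 0, 1), (1, 1))],
    )
    def test_p1_p2(self, pen, expected):
        assert compute_p1_p2(Penalties(*pen)) == expected

    def test_min_total_penalty_base_cases(self):
        assert min_total_penalty(0, 4, 4) == 0
        assert min_total_penalty(1, 4, 4) == 4
        assert min_total_penalty(3, 4, 4) == 12

    @pytest.mark.parametrize("pen", [(4, 6, 2), (2, 1, 1), (5, 0, 1), (1, 3, 2)])
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_min_total_penalty_matches_block_break_oracle(self, pen, n):
        """The closed form equals the cheapest enumerated way of damaging
        n consecutive blocks (gap runs shared between adjacent blocks
        included)."""
        penalties = Penalties(*pen)
        p1, p2 = compute_p1_p2(penalties)
        assert min_total_penalty(n, p1, p2) == min_block_break_penalty(
            n, 2, penalties
        )

    def test_min_penalty_per_length_even_case(self):
        pen = Penalties(4, 6, 2)
        assert min_penalty_per_length(2, 5, pen, 4, 4) == Fraction(8, 22)

    def test_min_penalty_per_length_positive(self):
        assert min_penalty_per_length(1, 1, Penalties(1, 0, 1), 1, 1) > 0

    @pytest.mark.parametrize("pen", [(4, 6, 2), (3, 2, 1), (1, 4, 3), (6, 0, 2)])
    def test_per_length_bound_grows_every_two_blocks(self, pen):
        """Two more broken blocks always raise the per-length lower bound,
        which is why only two block counts need checking per pattern
        size."""
        penalties = Penalties(*pen)
        p1, p2 = compute_p1_p2(penalties)
        for k in (1, 3, 8, 20):
            vals = [
                min_penalty_per_length(n, k, penalties, p1, p2)
                for n in range(1, 53)
            ]
            for n in range(len(vals) - 2):
                assert vals[n + 2] > vals[n]


class TestPatternSize:
    def test_reference_configuration_regression(self):
        """Pattern size for the documented configuration (penalties 4/6/2,
        MinL 200, MaxP 0.08), frozen from direct predicate evaluation over
        all candidate sizes."""
        assert compute_pattern_size(Penalties(4, 6, 2), Cutoffs(200, "0.08")) == 32

    def test_monotone_in_min_length(self):
        pen = Penalties(4, 6, 2)
        for d in ("0.04", "0.08", "0.12"):
            sizes = [
                compute_pattern_size(pen, Cutoffs(minl, d))
                for minl in (50, 100, 200, 400)
            ]
            assert sizes == sorted(sizes)

    def test_lenient_cutoffs_without_pattern_error(self):
        # With mismatch penalty 1 even a per-base mismatch rate beats this
        # ratio cutoff, so no pattern size can guarantee anchoring.
        with pytest.raises(InfeasibleCutoffError, match="anchoring"):
            compute_pattern_size(Penalties(1, 3, 2), Cutoffs(3, Fraction(3, 4)))

    def test_derived_constants_are_pure(self):
        a = derive_constants(Penalties(4, 6, 2), Cutoffs(200, "0.08"))
        b = derive_constants(Penalties(4, 6, 2), Cutoffs(200, Fraction(2, 25)))
        assert a is b or a == b
        assert a.left_delta_bound == Fraction(2, 25) * 31


class TestSparePenalties:
    def test_right_spare_reference_value(self):
        """f(0) for penalties 4/6/2, MaxP 1/10, pattern size 32, frozen
        from exact rational evaluation."""
        assert right_spare_penalty(0, 32, Penalties(4, 6, 2), Cutoffs(200, "0.1")) == 9

    def test_right_spare_floor_is_gap_open(self):
        pen = Penalties(4, 60, 2)
        cut = Cutoffs(500, "0.01")
        assert right_spare_penalty(0, 40, pen, cut) >= pen.gap_open

    def test_right_spare_nondecreasing_in_reverse_index(self):
        pen = Penalties(4, 6, 2)
        cut = Cutoffs(200, "0.08")
        vals = [right_spare_penalty(j, 32, pen, cut) for j in range(30)]
        assert vals == sorted(vals)

    def test_left_spare_clamped_at_zero(self):
        pen = Penalties(4, 6, 2)
        cut = Cutoffs(200, "0.08")
        assert left_spare_penalty(Fraction(-1000), 10, 10, pen, cut) == 0

    def test_left_spare_zero_residual(self):
        pen = Penalties(4, 6, 2)
        cut = Cutoffs(200, "0.08")
        # both branches floor to <= 0 when nothing remains on the left
        assert left_spare_penalty(Fraction(0), 0, 0, pen, cut) == 0
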