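# Methods

## The model

cutalign is a seed-and-extend local aligner whose *entire* output contract
is two explicit similarity cutoffs plus three affine gap penalties.  Given
a query Q, a reference of targets T, mismatch / gap-open / gap-extend
penalties (p_x, p_o, p_e; matches cost 0 and a gap of g positions costs
p_o + g·p_e), a minimum alignment length MinL and a maximum penalty per
length MaxP, the tool reports local alignments R = (positions, penalty,
length, operation vector over {=, X, I, D}) with

    length(R) ≥ MinL   and   penalty(R) / length(R) ≤ MaxP,

deduplicated and (by default) pruned so that lower-priority alignments
overlapping a kept one (same target, intersecting query and target
intervals) are dropped; priority is longer length, then smaller penalty,
then position.  Both cutoff comparisons are inclusive and carried out in
exact rational arithmetic (MaxP is stored as an integer ratio parsed from
its decimal form), so every floor and comparison in the pipeline is
bit-identical across platforms.

There is no heuristic score threshold, E-value, chaining bandwidth or
seed-count cap anywhere: every internal constant below is derived from
the five parameters.

## Derived constants

**Cheapest block damage (p1, p2).**  p1 = min(p_x, p_o+p_e) is the
cheapest way to damage one pattern-sized block of the query; p2 =
min(2p_x, p_o+2p_e) − p1 is the marginal cost of damaging a second,
adjacent block (a gap run crossing the boundary can damage two blocks on
one gap-open).  The minimum penalty of an alignment in which none of n
consecutive blocks survives intact is p1·⌈n/2⌉ + p2·⌊n/2⌋; a
depth-first enumeration over damage patterns confirms this closed form in
the tests.

**Pattern size (the anchoring guarantee).**  The query is tiled into
consecutive, non-overlapping patterns of size k; every exact occurrence
of a pattern in a target is an anchor.  The guarantee required of k is
quotient-filter-like: *if any alignment satisfies the cutoffs, at least
one pattern is intact and therefore anchors*.  For an alignment spanning
n broken blocks, the minimal penalty-per-length is bounded below by

    even n = 2m:   m(p1+p2)       / ((2m+2)(k+1) − 4 + p1/p_e)
    odd  n = 2m−1: (m(p1+p2)−p2)  / ((2m+1)(k+1) − 4 + p1/p_e)

where the denominator is the longest span a minimum-penalty n-block
alignment can cover (block residues of k−1 on both ends plus one
affordable gap position per block).  Because this bound rises every two
blocks, it suffices to check it at n̂ = ⌊(MinL+4−p1/p_e)/(k+1)⌋ − 2 (the
smallest block count whose maximal span reaches MinL) and n̂+1.  The
pattern size is the largest k for which both checks exceed MaxP; the
search iterates k upward and stops after 8 consecutive failures (the
predicate is not proven monotone in k; the window is regression-tested
against wide scans).  k where n̂ < 1 fails by definition.  If no k ≥ 1
passes, the cutoffs are rejected as infeasible for complete anchoring —
e.g. mismatch penalty 1 with MaxP 0.75 admits per-base mismatch soups
that no pattern size can guard against.  For the documented configuration
(4/6/2, MinL 200, MaxP 0.08) the derived pattern size is 32.

**Spare (stopping) penalties.**  Extension away from an anchor stops at a
penalty budget chosen so that no cutoff-satisfying alignment is ever
truncated.  The right side is extended first, assuming the best the left
flank could contribute without further anchors is a penalty delta of
MaxP·(k−1) (an anchorless flank costs more than MaxP per base beyond k−1
boundary matches, which is also asserted: p1/k and (p1+p2)/2k must exceed
MaxP).  Substituting that bound and the right residual length cap
k(j+2)−1 (j = the pattern's index counted from the right end of the
query) gives a right budget depending only on j,

    spare_R(j) = max( ⌊ MaxP·(p_e·(k(j+3)−2) − p_o) / (p_e − MaxP) ⌋ , p_o ),

precomputed per reverse index.  The gap-open penalty is the *floor* of
the table: a budget below p_o could stop extension before a single gap
opens, and since the budget is an upper stopping bound, a larger value is
safe (slower, never lossy).  After the right side commits to an endpoint
with penalty delta Δ_R = MaxP·len_R − penalty_R, the left budget
evaluates both branches of the stopping bound

    ⌊ Δ_R + MaxP·min(l_Q, l_T) ⌋      and
    ⌊ (p_e·Δ_R + MaxP·p_e·min(l_Q, l_T) − MaxP·p_o) / (p_e − MaxP) ⌋

and takes their maximum, clamped at 0.  Δ_R is the *chosen* endpoint's
delta: this makes the budget identical for every anchor of a match chain
(see skipping below) and is the reading of the stopping-bound formula in
which the opposite side's penalty and length are the actual extension's.

## Extension: non-adaptive wavefronts

One side of an anchor is a pair of flanks (query, target, both oriented
away from the anchor; the rightward flank includes the anchor's pattern,
which the score-0 match run consumes for free).  For each penalty score
s = 0..spare, the furthest-reaching progress per diagonal is tracked for
the three gap-affine states (diagonal-transition method).  Implementation
points that matter:

* Merged diagonal-state entries store (furthest offset, run start), so
  substitutions and gap openings can branch from *any* point of a match
  run — necessary near flank ends, where the furthest point itself cannot
  open a gap, and required for the backtrace to agree with the
  full-matrix oracle.
* Entries are dominance-pruned across scores per diagonal (an entry not
  out-reaching every cheaper entry is dropped).  This makes every stored
  offset minimal-penalty for its point, which the backtrace's
  equality-based tie checks rely on.
* Only a window of the target sequence is materialised: target progress
  cannot exceed the query flank length plus the number of affordable
  deletions, so alignment against megabase targets never copies them.
* The canonical backtrace resolves ties in a fixed order (substitution,
  then entering an insertion, then a deletion, then match; gaps close as
  early as possible).  The full-matrix Gotoh oracle applies the same
  order over its minimality predicates, and the two engines emit
  identical operation vectors on every fuzzed flank — this is load-bearing
  for the pipeline-equals-DP acceptance property.

**Endpoint selection.**  Candidates are the per-score furthest points.
The chosen endpoint maximises, in order:

1. *cutoff feasibility* — penalty delta (MaxP·max(h,v) − s) at or above
   the most the opposite side can contribute (−MaxP·(k−1) for the right
   side; −Δ_R for the left).  The empty endpoint has delta 0, so a
   feasible candidate always exists.  Without this class, a read with one
   dense error burst extends through the burst, assembles an
   over-budget alignment, and loses its perfectly good sub-alignment;
2. reaching the query or target end;
3. the longer *aligned span* min(h, v).  Ranking by span rather than by
   operation count means an endpoint padded with trailing gap operations
   ties its unpadded counterpart and loses on penalty — otherwise a
   perfect fragment is reported with a gap-padded tail, since padding
   preserves the end flag and inflates length;
4. the lesser penalty; then the smaller diagonal (determinism).

**Pair extraction (rescue).**  When the assembled primary alignment
fails the cutoffs, the anchor's candidate pairs are scanned for one whose
exact penalty and length proxy (max(h,v) per side, which never
overestimates) already satisfy both cutoffs; the best such pair (longest
span, then lesser penalty) is backtraced and is guaranteed to pass.  If
no pair qualifies on the proxy, up to 64 near-miss pairs — those that
could still qualify within the provable mixed-gap surplus
(min(#I,#D) ≤ (s/p_e − |diagonal|)/2 per side) — are backtraced in rank
order and the first that truly passes is kept.  The left side is
re-extended for the scan with the most generous budget any right
candidate allows.  Rescue fires only in regimes where the length cutoff
is reachable solely through gap-heavy endpoint pairs; on preset-like
parameters it is essentially never taken.

## Evaluation, symbols, skipping, pruning

Anchors are processed per target in ascending (query, target) position.
During backtrace every anchor the path crosses (nonzero same-sign offsets
in both coordinates, landing exactly on a pattern start) is recorded; the
set {anchor} ∪ {traversed anchors} is the alignment's *symbol*.

*Deduplication* compares the full (positions, operations) identity —
symbols identify results in the common case, but under extreme cutoffs
two anchors sharing a symbol can commit to different endpoints, and two
anchors on one gap run can produce the same alignment without mutually
traversing each other, so identity is what is actually registered.

*Skipping* is chain truncation, and every condition is checked rather
than assumed: when an evaluated anchor's right path runs through
co-diagonal anchors connected by pure matches, each such anchor's right
extension is exactly the truncation of the computed one, because the
candidate sets are translates and the selection order is
translation-invariant — provided the downstream anchor's spare still
covers the chosen endpoint and the feasibility margin survives the shift,
both of which are tested per member.  All chain members then share one
left budget (the Δ_R shift and the flank growth cancel exactly), so
extending the farthest member leftward once proves the middle anchors
reproduce the identical alignment; they are marked skipped and never
extended.  If the truncated alignment fails the cutoffs the chain is
abandoned and every member is evaluated individually (their rescue
outcomes need not be truncations).  Output with skipping on and off is
asserted identical across the fuzz corpus; on a clean alignment the
extension count drops from one per anchor to three per locus.

*Overlap pruning* ranks results by (length desc, penalty asc, position)
and greedily keeps results not overlapping an already-kept one (same
target, both interval pairs intersect).  Pruning is per-target by
construction, which is why growing a reference can never change the
results on its existing targets (the recall-superset property measured by
the reference-growth benchmark).  Positional coverage of every feasible
alignment is a property of the *pre-pruning* accepted set: greedy
pruning can drop a covering result through a chain of overlaps, which no
greedy scheme avoids.

## Reference and search

Targets are byte strings over any single-byte alphabet.  Exact pattern
location is served by a packed-2-bit sorted k-mer table (numpy argsort /
searchsorted) for A/C/G/T targets and pattern lengths up to 31, built
lazily per pattern length and cached on the immutable reference; other
alphabets or lengths fall back to a direct overlapping `bytes.find`
scan.  Both paths are fuzz-tested against the naive scan that defines
the contract.  Coordinates are 0-based half-open everywhere; writers
convert (SAM POS is 1-based).

## Presets

Cutoffs scale with the square root of each query's length l: strict uses
MinL = ⌊5√l⌋ and MaxP = 0.5/√l, lenient MinL = ⌊2√l⌋ and MaxP = 1.5/√l,
both with penalties 4/6/2.  MinL is computed as isqrt(c²l); MaxP is
rationalised at denominator 10⁶ by exact integer square root, so preset
cutoffs are reproducible ratios (lenient at l = 300: MinL 34, MaxP
86602/10⁶).  Flooring is the non-lossy direction for MinL; the fixed
denominator keeps determinism.

## The DP oracle

The package carries its own normative semantics: a full-matrix affine-gap
(Gotoh) engine with identical selection and canonical-walk rules that
drops in for the wavefront engine, plus an exhaustive recursive
enumerator of all cutoff-satisfying local alignments (for tiny inputs)
and length-layered DP formulations of the same question that scale to
fuzzing volumes.  The layered form also yields the *strong* feasible
set: intervals whose canonical representative (the shortest alignment of
the endpoint pair's minimal-penalty class) passes the cutoffs.  The weak
set additionally contains operation-count-inflated variants (extra
paired indels at equal penalty, useful only to clear MinL) that no
single-backtrace tool emits; completeness is asserted against the strong
set, equivalence against the full pipeline run with the DP engine and
skipping disabled.

## Synthetic data

The generators emulate the study conditions without downloads: uniform
A/C/G/T genomes; strains derived by per-base Bernoulli substitutions and
geometric-length indels (mean length 1.5, insertion/deletion
equiprobable) — an intentional simplification of real mutation spectra
and sequencer profiles; fixed-length reads from uniform positions and
random strands with the same per-base error model and recorded truth
intervals.  All generators are pure functions of their seeds.  Passing
the benchmarks on this data shows the algorithmic guarantees (anchoring
completeness, DP-reproducibility, recall under reference growth) under
controlled error rates; it does not certify performance on real-platform
error profiles, quality-correlated errors, or repetitive genomes, where
only sensitivity-style claims would transfer.

Benchmark problem sizes: the read-mapping reproduction runs at 1 Mb
genome / 10,000 reads of 300 bp (0.5% substitution, 0.05% indel,
lenient preset).  The reference-growth reproduction uses a 100 kb base
genome, 64 strains at 1% substitution / 0.1% indel divergence, and ~250
fragments (stride 400) from a held-out strain under both presets; the
measured false-negative rate across doublings is structural (per-target
independence) and does not depend on these sizes, which were chosen to
keep a pure-Python implementation pleasant to re-run.

## Known limitations

* One alignment per anchor: feasible alignments whose existence depends
  on deliberately length-inflated operation variants are not reported
  (excluded from the completeness contract, see above); beyond the
  64-pair rescue bound, extraction gives up.
* The optional match bonus is not implemented; matches always cost 0.
* RNA splicing and substitution matrices are out of scope.
* Reverse-strand alignment is handled by aligning the reverse-complement
  query; overlap pruning applies within a strand, not across strands.
* Throughput is that of pure Python with numpy indexing — the algorithm's
  complexity behaviour is faithful, absolute speed is not a goal.
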