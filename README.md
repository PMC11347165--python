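# cutalign

A non-heuristic seed-and-extend sequence aligner whose output is defined
by two explicit similarity cutoffs.

## The problem

Fast aligners (read mappers, database search tools) reach their speed
through stacked heuristics — seed filters, chaining bandwidths, score
thresholds, E-values, mapping-quality cuts — so *which* alignments end up
in the output is hard to state, and the parameter space is large and
non-linear.  cutalign keeps the seed-and-extend architecture but replaces
every heuristic with constants derived from five user parameters: three
affine gap penalties (mismatch `p_x`, gap-open `p_o`, gap-extend `p_e`;
a gap of `g` positions costs `p_o + g·p_e`, matches cost 0) and two
cutoffs,

* **MinL** — minimum alignment length, and
* **MaxP** — maximum penalty per alignment length,

and reports the local alignments `R` with `length(R) ≥ MinL` and
`penalty(R)/length(R) ≤ MaxP`, deduplicated and overlap-pruned by
explicit priority rules (longer, then cheaper).  The result set is
reproducible by ordinary dynamic programming plus filtering — the package
ships that oracle and asserts the equivalence in its test suite.

Internally, the query is tiled into non-overlapping patterns of a derived
size `k̄` chosen so that *any* alignment satisfying the cutoffs must
contain an intact pattern (a quotient-filter guarantee); exact pattern
occurrences are anchors, extended bidirectionally with a penalty-bounded
gap-affine wavefront whose stopping budgets are likewise derived from the
five parameters.  `docs/methods.md` derives all of it.

Intended users: anyone who needs alignment output with a declarative
contract — "every alignment of ≥ 200 bp with at most two mismatches (or
equivalent gaps) per 100 bp" (that is `MinL=200, MaxP=0.08` with
`p_x=4`) — rather than whatever a particular tool's heuristics kept.

## Worked example

Simulate a 100 kb genome and three 300 bp reads (0.5% substitution
rate), then map them with the `lenient` preset (per-query-length scaled
cutoffs `MinL=⌊2√l⌋`, `MaxP=1.5/√l`, penalties 4/6/2):

```python
from cutalign.simulate import random_genome, simulate_reads, write_fasta
from cutalign.reference import Target
genome = random_genome(100_000, seed=7, target_id="chr1")
write_fasta([genome], "ref.fa")
reads = simulate_reads(genome, 3, 300, 0.005, 0.0005, seed=8)
write_fasta([Target(r.id, r.sequence) for r in reads], "reads.fa")
```

```
$ cutalign --reference ref.fa --query reads.fa --preset lenient --out out.tsv
[INFO] reference: 1 target(s)
[INFO] queries: 3 sequence(s)
[INFO] aligned 3/3 queries; 3 alignment(s) total
$ cat out.tsv
query_id  target_id  strand  penalty  length  qstart  qend  tstart  tend   operations
read0     chr1       -       0        300     0       300   71739   72039  300=
read1     chr1       +       4        300     0       300   32599   32899  40=1X259=
read2     chr1       -       12       300     0       300   11211   11511  103=1X106=1X40=1X48=
```

Each row is one alignment: `penalty` is the affine-gap penalty (read1
carries one substitution at penalty 4; read2 three), `length` the
operation count, coordinates are 0-based half-open (query coordinates in
the original read frame; `strand -` means the reverse complement
aligned), and `operations` is the run-length vector over `=` match, `X`
substitution, `I` insertion, `D` deletion.  All three reads map back to
exactly their simulated origins.  SAM output (`--format sam`) and
explicit cutoffs (`--minl 200 --maxp 0.08`) are available; see
`cutalign --help`.

The same functionality is a library:

```python
from cutalign import build_reference, process_query, Penalties, Cutoffs
ref = build_reference([genome])
results = process_query(reads[1].sequence, ref, Penalties(4, 6, 2),
                        Cutoffs(200, "0.08"))
```

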