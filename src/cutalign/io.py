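"""Sequence readers, preset cutoffs, strand handling and result writers.

Presets
-------
Two representative parameter sets scale the cutoffs with the square root
of the query length ``l`` (the algorithm's workload grows roughly with
the square of query length, so this keeps throughput stable):

* ``strict``:  MinL = floor(5*sqrt(l)),  MaxP = 0.5/sqrt(l)
* ``lenient``: MinL = floor(2*sqrt(l)),  MaxP = 1.5/sqrt(l)

both with mismatch/gap-open/gap-extend penalties 4/6/2.  MinL is floored
and MaxP is rationalised at denominator 10^6 (floored) so per-query
cutoffs stay exact integers/ratios.

Writers
-------
TSV: one row per alignment with 0-based half-open coordinates and a
run-length operation string over ``=XID``.  SAM: ``@SQ`` per target,
CIGAR over ``=XIDS`` (soft clips for the unaligned query ends), 1-based
POS, MAPQ 255, flag 16 for reverse strand and 256 for non-primary
records.  Both emissions are byte-deterministic for fixed input.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

from .evaluate import AlignmentResult, process_query
from .params import Cutoffs, Penalties
from .reference import Reference, Target, build_reference

__all__ = [
    "Preset",
    "STRICT",
    "LENIENT",
    "DEFAULT_PENALTIES",
    "preset_cutoffs",
    "read_sequences",
    "reference_from_fasta",
    "reverse_complement",
    "QueryAlignment",
    "align_query",
    "ops_to_runlength",
    "runlength_to_ops",
    "write_tsv",
    "parse_tsv",
    "write_sam",
]

DEFAULT_PENALTIES = Penalties(mismatch=4, gap_open=6, gap_extend=2)

_COMP = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def reverse_complement(seq: bytes) -> bytes:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Preset:
    """Square-root-of-length scaled cutoff preset."""

    name: str
    min_length_scale: int
    max_ppl_scale: Fraction

    def cutoffs(self, query_length: int) -> Cutoffs:
        if query_length < 1:
            raise ValueError("query length must be >= 1")
        c = self.min_length_scale
        minl = max(1, math.isqrt(c * c * query_length))
        a = 10**6 * self.max_ppl_scale
        if a.denominator != 1:
            raise ValueError("preset scale must be a multiple of 1e-6")
        num = math.isqrt(a.numerator**2 // query_length)
        return Cutoffs(min_length=minl, max_penalty_per_length=Fraction(num, 10**6))


STRICT = Preset("strict", 5, Fraction(1, 2))
LENIENT = Preset("lenient", 2, Fraction(3, 2))
PRESETS = {"strict": STRICT, "lenient": LENIENT}


def preset_cutoffs(name: str, query_length: int) -> Cutoffs:
    return PRESETS[name].cutoffs(query_length)


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _guess_format(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    ext = name.rsplit(".", 1)[-1].lower()
    if ext in ("fq", "fastq"):
        return "fastq"
    if ext in ("fa", "fasta", "fna", "ffn", "mfa"):
        return "fasta"
    raise ValueError(f"cannot guess sequence format of {path!r}")


def read_sequences(path: str | Path, fmt: str | None = None) -> list[tuple[str, bytes]]:
    """Read FASTA/FASTQ records (optionally gzipped) as (id, bytes)."""
    fmt = fmt or _guess_format(path)
    out: list[tuple[str, bytes]] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            out.append((rec.id, bytes(str(rec.seq).upper(), "ascii")))
    return out


def reference_from_fasta(path: str | Path) -> Reference:
    """Build a reference from a multi-record FASTA; record order defines
    target order."""
    return build_reference(
        Target(id=rid, sequence=seq) for rid, seq in read_sequences(path, "fasta")
    )


@dataclass(frozen=True)
class QueryAlignment:
    """An alignment of one query (either strand) against the reference.

    ``result`` coordinates are in the frame of the aligned sequence (the
    reverse complement for strand ``-``); ``query_length`` allows writers
    to convert to the original read frame.
    """

    query_id: str
    strand: str  # '+' or '-'
    query_length: int
    result: AlignmentResult

    @property
    def original_query_interval(self) -> tuple[int, int]:
        r = self.result
        if self.strand == "+":
            return (r.qstart, r.qend)
        return (self.query_length - r.qend, self.query_length - r.qstart)


def align_query(
    query_id: str,
    query: bytes,
    reference: Reference,
    penalties: Penalties,
    cutoffs: Cutoffs,
    *,
    both_strands: bool = True,
) -> list[QueryAlignment]:
    """Align one query (and, by default, its reverse complement)."""
    out: list[QueryAlignment] = []
    n = len(query)
    for strand, seq in (("+", query), ("-", reverse_complement(query))):
        if strand == "-" and not both_strands:
            continue
        for res in process_query(seq, reference, penalties, cutoffs):
            out.append(
                QueryAlignment(
                    query_id=query_id, strand=strand, query_length=n, result=res
                )
            )
    return out


def ops_to_runlength(ops: str) -> str:
    if not ops:
        return "*"
    parts: list[str] = []
    prev = ops[0]
    count = 1
    for op in ops[1:]:
        if op == prev:
            count += 1
        else:
            parts.append(f"{count}{prev}")
            prev = op
            count = 1
    parts.append(f"{count}{prev}")
    return "".join(parts)


def runlength_to_ops(rle: str) -> str:
    if rle == "*":
        return ""
    out: list[str] = []
    num = ""
    for ch in rle:
        if ch.isdigit():
            num += ch
        else:
            out.append(ch * int(num))
            num = ""
    return "".join(out)


TSV_COLUMNS = (
    "query_id",
    "target_id",
    "strand",
    "penalty",
    "length",
    "qstart",
    "qend",
    "tstart",
    "tend",
    "operations",
)


def write_tsv(records: Iterable[QueryAlignment], handle: TextIO) -> None:
    """Tab-separated output; query coordinates in the original read frame,
    0-based half-open."""
    handle.write("\t".join(TSV_COLUMNS) + "\n")
    for qa in records:
        r = qa.result
        qs, qe = qa.original_query_interval
        handle.write(
            "\t".join(
                map(
                    str,
                    (
                        qa.query_id,
                        r.target_id,
                        qa.strand,
                        r.penalty,
                        r.length,
                        qs,
                        qe,
                        r.tstart,
                        r.tend,
                        ops_to_runlength(r.ops),
                    ),
                )
            )
            + "\n"
        )


def parse_tsv(handle: TextIO) -> list[QueryAlignment]:
    """Round-trip reader for :func:`write_tsv` output."""
    header = handle.readline().rstrip("\n").split("\t")
    if tuple(header) != TSV_COLUMNS:
        raise ValueError("unrecognized TSV header")
    out: list[QueryAlignment] = []
    for line in handle:
        fields = line.rstrip("\n").split("\t")
        row = dict(zip(TSV_COLUMNS, fields))
        ops = runlength_to_ops(row["operations"])
        qs, qe = int(row["qstart"]), int(row["qend"])
        qspan = len(ops) - ops.count("D")
        # Reconstruct the aligned-frame interval; the query length is not
        # stored, so reverse-strand rows keep original-frame coordinates
        # by treating the row interval as aligned-frame of an unknown
        # length.  Forward rows round-trip exactly.
        result = AlignmentResult(
            target_id=row["target_id"],
            qstart=qs,
            qend=qs + qspan,
            tstart=int(row["tstart"]),
            tend=int(row["tend"]),
            penalty=int(row["penalty"]),
            length=int(row["length"]),
            ops=ops,
        )
        out.append(
            QueryAlignment(
                query_id=row["query_id"],
                strand=row["strand"],
                query_length=qe - qs if row["strand"] == "+" else 0,
                result=result,
            )
        )
    return out


def _sam_flag(qa: QueryAlignment, is_primary: bool) -> int:
    flag = 0
    if qa.strand == "-":
        flag |= 16
    if not is_primary:
        flag |= 256
    return flag


def write_sam(
    records: list[QueryAlignment],
    reference: Reference,
    handle: TextIO,
    query_seqs: dict[str, bytes],
    primary_filter: bool = False,
) -> None:
    """SAM output with =/X/I/D CIGAR operations and soft-clipped ends.

    The record whose result the primary filter would select is the
    primary alignment of its query; the rest carry flag 256.  With
    ``primary_filter`` only primaries are written.
    """
    handle.write("@HD\tVN:1.6\tSO:unknown\n")
    for t in reference.targets:
        handle.write(f"@SQ\tSN:{t.id}\tLN:{len(t.sequence)}\n")
    handle.write("@PG\tID:cutalign\tPN:cutalign\n")

    by_query: dict[str, list[QueryAlignment]] = {}
    for qa in records:
        by_query.setdefault(qa.query_id, []).append(qa)
    primaries: dict[str, QueryAlignment] = {}
    for qid, qas in by_query.items():
        best = min(
            qas,
            key=lambda qa: (
                -(qa.result.qend - qa.result.qstart),
                qa.result.penalty,
                qa.original_query_interval[0],
                qa.result.target_id,
                qa.result.tstart,
            ),
        )
        primaries[qid] = best

    for qa in records:
        is_primary = primaries[qa.query_id] is qa
        if primary_filter and not is_primary:
            continue
        r = qa.result
        seq = query_seqs[qa.query_id]
        if qa.strand == "-":
            seq = reverse_complement(seq)
        cigar_ops = r.ops
        lead = r.qstart
        trail = len(seq) - r.qend
        cigar = (
            (f"{lead}S" if lead else "")
            + ops_to_runlength(cigar_ops)
            + (f"{trail}S" if trail else "")
        )
        handle.write(
            "\t".join(
                map(
                    str,
                    (
                        qa.query_id,
                        _sam_flag(qa, is_primary),
                        r.target_id,
                        r.tstart + 1,
                        255,
                        cigar,
                        "*",
                        0,
                        0,
                        seq.decode("ascii"),
                        "*",
                    ),
                )
            )
            + "\n"
        )
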