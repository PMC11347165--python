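"""Seeded generators for synthetic genomes, strains and reads, plus the
evaluation metrics used by the scaled-down benchmark reproductions.

The generators emulate the study conditions of the read-mapping and
database-recall experiments without external downloads: uniform-random
genomes, point-mutated strains (per-base Bernoulli substitutions plus
geometric-length indels with mean length 1.5 -- a deliberate
simplification of real sequencer/evolution profiles), and fixed-length
reads with recorded truth positions.  Every generator is a pure function
of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reference import Target

__all__ = [
    "SimulatedRead",
    "MappingScore",
    "random_genome",
    "mutate_strain",
    "simulate_reads",
    "score_mapping",
    "score_recall",
    "write_fasta",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = bytes.maketrans(b"ACGT", b"TGCA")

#: geometric length parameter giving mean indel length 1.5
_INDEL_LEN_P = 2.0 / 3.0


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read with its recorded truth."""

    id: str
    sequence: bytes
    target_id: str
    start: int  # truth interval on the source target, 0-based half-open
    end: int
    strand: str
    n_sub: int
    n_ins: int
    n_del: int


@dataclass(frozen=True)
class MappingScore:
    sensitivity: float
    precision: float
    n_reads: int
    n_alignments: int
    #: True when precision is undefined (no alignments) and reported as 0
    precision_undefined: bool


def random_genome(length: int, seed: int, target_id: str = "genome") -> Target:
    """Uniform A/C/G/T sequence of the given length, reproducible per seed."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes()
    return Target(id=target_id, sequence=seq)


def _substitute(codes: np.ndarray, positions: np.ndarray, rng) -> None:
    codes[positions] = (
        codes[positions] + rng.integers(1, 4, size=len(positions))
    ) % 4


def mutate_strain(
    genome: Target,
    sub_rate: float,
    indel_rate: float,
    seed: int,
    target_id: str | None = None,
) -> Target:
    """Derive a strain: per-base Bernoulli substitutions and geometric
    indels (insertion or deletion with equal probability)."""
    if not (0 <= sub_rate <= 0.2 and 0 <= indel_rate <= 0.2):
        raise ValueError("rates must be within [0, 0.2]")
    rng = np.random.default_rng(seed)
    n = len(genome.sequence)
    codes = np.searchsorted(_BASES, np.frombuffer(genome.sequence, dtype=np.uint8))
    codes = codes.astype(np.int64)
    if sub_rate > 0:
        pos = np.nonzero(rng.random(n) < sub_rate)[0]
        _substitute(codes, pos, rng)
    pieces: list[np.ndarray] = []
    if indel_rate > 0:
        sites = np.nonzero(rng.random(n) < indel_rate)[0]
    else:
        sites = np.empty(0, dtype=np.int64)
    prev = 0
    for site in sites:
        length = int(rng.geometric(_INDEL_LEN_P))
        if rng.random() < 0.5:  # insertion before `site`
            pieces.append(codes[prev:site])
            pieces.append(rng.integers(0, 4, size=length))
            prev = site
        else:  # deletion starting at `site`
            pieces.append(codes[prev:site])
            prev = min(site + length, n)
    pieces.append(codes[prev:])
    out = np.concatenate(pieces) if len(pieces) > 1 else codes
    return Target(
        id=target_id or f"{genome.id}_strain{seed}",
        sequence=_BASES[out].tobytes(),
    )


def simulate_reads(
    genome: Target,
    n: int,
    read_len: int,
    sub_rate: float,
    indel_rate: float,
    seed: int,
    id_prefix: str = "read",
) -> list[SimulatedRead]:
    """Fixed-length reads from uniform start positions and random strands,
    with per-base substitution/indel errors and recorded truth intervals."""
    if read_len > len(genome.sequence):
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(seed)
    L = len(genome.sequence)
    seq = genome.sequence
    reads: list[SimulatedRead] = []
    for i in range(n):
        start = int(rng.integers(0, L - read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        out = bytearray()
        ref_pos = start
        n_sub = n_ins = n_del = 0
        while len(out) < read_len and ref_pos < L:
            r = rng.random()
            if r < indel_rate:
                length = int(rng.geometric(_INDEL_LEN_P))
                if rng.random() < 0.5:
                    for _ in range(length):
                        if len(out) >= read_len:
                            break
                        out.append(int(_BASES[rng.integers(0, 4)]))
                        n_ins += 1
                else:
                    skip = min(length, L - ref_pos)
                    ref_pos += skip
                    n_del += skip
                continue
            base = seq[ref_pos]
            if r < indel_rate + sub_rate:
                code = (int(np.searchsorted(_BASES, base)) + int(rng.integers(1, 4))) % 4
                base = int(_BASES[code])
                n_sub += 1
            out.append(base)
            ref_pos += 1
        read = bytes(out)
        if strand == "-":
            read = read.translate(_COMP)[::-1]
        reads.append(
            SimulatedRead(
                id=f"{id_prefix}{i}",
                sequence=read,
                target_id=genome.id,
                start=start,
                end=ref_pos,
                strand=strand,
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
            )
        )
    return reads


def score_mapping(
    results: dict[str, Sequence[tuple[str, int, int]]],
    truths: Sequence[SimulatedRead],
) -> MappingScore:
    """Sensitivity and precision of mapped positions against the truth.

    ``results`` maps read id -> reported (target_id, tstart, tend)
    intervals.  An alignment is correct when it lies on the truth target
    and its target interval overlaps the truth interval; a read counts as
    correctly mapped when at least one of its alignments is correct.
    """
    truth_by_id = {t.id: t for t in truths}
    for rid in results:
        if rid not in truth_by_id:
            raise KeyError(f"unknown read id {rid!r}")
    hit_reads = 0
    correct = 0
    total = 0
    for t in truths:
        any_hit = False
        for target_id, ts, te in results.get(t.id, ()):
            total += 1
            if target_id == t.target_id and ts < t.end and t.start < te:
                correct += 1
                any_hit = True
        if any_hit:
            hit_reads += 1
    sensitivity = hit_reads / len(truths) if truths else 0.0
    undefined = total == 0
    precision = 0.0 if undefined else correct / total
    return MappingScore(
        sensitivity=sensitivity,
        precision=precision,
        n_reads=len(truths),
        n_alignments=total,
        precision_undefined=undefined,
    )


def score_recall(
    results_small: Iterable[tuple],
    results_big: Iterable[tuple],
) -> float:
    """False-negative rate of small-reference results in a larger run.

    Each element is an identity tuple (target id, positions, operations);
    the FNR is the fraction of small-reference results with no identical
    counterpart among the big-reference results.  0.0 for an empty small
    set.
    """
    small = list(results_small)
    if not small:
        return 0.0
    big = set(results_big)
    missing = sum(1 for r in small if r not in big)
    return missing / len(small)


def write_fasta(targets: Iterable[Target], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f">{t.id}\n")
            seq = t.sequence.decode("ascii")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_tsv(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttarget_id\tstart\tend\tstrand\tn_sub\tn_ins\tn_del\n")
        for r in reads:
            fh.write(
                f"{r.id}\t{r.target_id}\t{r.start}\t{r.end}\t{r.strand}\t"
                f"{r.n_sub}\t{r.n_ins}\t{r.n_del}\n"
            )
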