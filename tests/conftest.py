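"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (per-base
CIGAR walks, hash-group-and-pick duplicate selection, naive covariate
recounts) so the package implementations are checked against code that
shares none of their arithmetic.
"""

from __future__ import annotations

import re

import numpy as np
import pytest

from shardseq.alignment import (
    FLAG_FIRST,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_REVERSE,
    FLAG_SECOND,
    FLAG_UNMAPPED,
    AlignedRead,
    ReadPair,
)
from shardseq.genome_partition import GenomeIndex

_CIG = re.compile(r"(\d+)([MIDNSHP=X])")


# ---------------------------------------------------------------------------
# record factories


def make_read(
    qname="r1",
    flag=0,
    rname="chr1",
    pos=100,
    mapq=60,
    cigar="100M",
    rnext="*",
    pnext=0,
    tlen=0,
    seq=None,
    qual=None,
    tags=(),
):
    ops = _CIG.findall(cigar) if cigar != "*" else []
    qlen = sum(int(n) for n, op in ops if op in "MIS=X")
    if seq is None:
        seq = "A" * qlen if qlen else "*"
    if qual is None:
        qual = "I" * len(seq) if seq != "*" else "*"
    return AlignedRead(qname, flag, rname, pos, mapq, cigar, rnext, pnext, tlen, seq, qual, tuple(tags))


def make_pair(
    qname="p1",
    chrom1="chr1",
    pos1=100,
    chrom2=None,
    pos2=300,
    cigar1="50M",
    cigar2="50M",
    mapq1=60,
    mapq2=60,
    mate2_unmapped=False,
):
    chrom2 = chrom2 or chrom1
    f1 = FLAG_PAIRED | FLAG_FIRST
    f2 = FLAG_PAIRED | FLAG_SECOND | FLAG_REVERSE
    if mate2_unmapped:
        f1 |= FLAG_MATE_UNMAPPED
        f2 = FLAG_PAIRED | FLAG_SECOND | FLAG_UNMAPPED
        cigar2 = "*"
    r1 = make_read(qname, f1, chrom1, pos1, mapq1, cigar1, rnext=chrom2, pnext=pos2)
    r2 = make_read(
        qname,
        f2,
        chrom2 if not mate2_unmapped else chrom1,
        pos2 if not mate2_unmapped else pos1,
        mapq2,
        cigar2,
        rnext=chrom1,
        pnext=pos1,
    )
    return ReadPair(r1, r2)


@pytest.fixture
def toy_genome():
    return GenomeIndex((("chr1", 100), ("chr2", 50)))


@pytest.fixture
def small_genome():
    return GenomeIndex((("chr1", 30_000), ("chr2", 20_000)))


# ---------------------------------------------------------------------------
# oracle: per-base CIGAR walker for unclipped 5' ends


def oracle_unclipped_five_prime(pos: int, cigar: str, reverse: bool) -> int:
    """Assign a hypothetical reference coordinate to every base of the
    original unclipped read, walking the CIGAR base by base; return the
    coordinate of the 5'-most base."""
    ops = [(int(n), op) for n, op in _CIG.findall(cigar)]
    lead = 0
    for n, op in ops:
        if op in "SH":
            lead += n
        else:
            break
    coords: list[int] = []
    cur = pos - lead
    for n, op in ops:
        if op in "SH" or op in "M=X":
            for _ in range(n):
                coords.append(cur)
                cur += 1
        elif op == "I":
            for _ in range(n):
                coords.append(cur)
        elif op in "DN":
            cur += n
    return coords[-1] if reverse else coords[0]


def random_cigar(rng: np.random.Generator) -> str:
    """Structurally valid CIGAR: optional clips around M-bounded blocks."""
    parts = []
    if rng.random() < 0.4:
        parts.append(f"{rng.integers(1, 20)}{'S' if rng.random() < 0.7 else 'H'}")
    n_blocks = int(rng.integers(1, 4))
    for i in range(n_blocks):
        parts.append(f"{rng.integers(1, 60)}{rng.choice(['M', '=', 'X'])}")
        if i < n_blocks - 1:
            parts.append(f"{rng.integers(1, 10)}{rng.choice(['I', 'D', 'N'])}")
    if rng.random() < 0.4:
        parts.append(f"{rng.integers(1, 20)}{'S' if rng.random() < 0.7 else 'H'}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# oracle: brute-force duplicate selection


def oracle_retained_qnames(records) -> set[str]:
    """Hash-group primary pairs by oracle external coordinates and keep
    the best (mapq sum, then qname) member of each group."""
    by_qname: dict[str, list] = {}
    for r in records:
        if r.is_primary and r.is_paired:
            by_qname.setdefault(r.qname, []).append(r)
    groups: dict[tuple, list[tuple[int, str]]] = {}
    passthrough: set[str] = set()
    for qname, recs in by_qname.items():
        if len(recs) != 2:
            passthrough.add(qname)
            continue
        mapped = [r for r in recs if not r.is_unmapped]
        if not mapped:
            passthrough.add(qname)
            continue
        triples = tuple(
            sorted(
                (
                    r.rname,
                    oracle_unclipped_five_prime(r.pos, r.cigar, r.is_reverse),
                    "-" if r.is_reverse else "+",
                )
                for r in mapped
            )
        )
        key = ("single" if len(mapped) == 1 else "pair", triples)
        groups.setdefault(key, []).append((sum(r.mapq for r in recs), qname))
    retained = set(passthrough)
    for members in groups.values():
        members.sort(key=lambda t: (-t[0], t[1]))
        retained.add(members[0][1])
    return retained


# ---------------------------------------------------------------------------
# oracle: naive per-base covariate recount


def oracle_covariate_counts(records, reference) -> dict:
    counts: dict[tuple[int, int, str], list[int]] = {}
    for read in records:
        if read.is_unmapped or not read.is_primary or read.is_duplicate:
            continue
        if read.seq == "*" or read.qual == "*":
            continue
        q_idx = 0
        r_pos = read.pos  # 1-based
        ref = reference[read.rname]
        for n, op in _CIG.findall(read.cigar):
            n = int(n)
            if op in "M=X":
                for i in range(n):
                    base = read.seq[q_idx + i].upper()
                    ref_base = ref[r_pos + i - 1].upper()
                    if base not in "ACGT" or ref_base not in "ACGT":
                        continue
                    rq = min(60, ord(read.qual[q_idx + i]) - 33)
                    cycle = q_idx + i + 1
                    if read.is_second:
                        cycle = -cycle
                    if q_idx + i == 0:
                        ctx = "--"
                    else:
                        prev = read.seq[q_idx + i - 1].upper()
                        ctx = prev + base if prev in "ACGT" else "--"
                    bin_ = (rq, cycle, ctx)
                    entry = counts.setdefault(bin_, [0, 0])
                    entry[0] += 1
                    if base != ref_base:
                        entry[1] += 1
                q_idx += n
                r_pos += n
            elif op in "IS":
                q_idx += n
            elif op in "DN":
                r_pos += n
    return {k: tuple(v) for k, v in counts.items()}
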