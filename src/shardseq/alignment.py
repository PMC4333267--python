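"""SAM record model, text I/O, and duplicate-key coordinate math.

Plain-text SAM only (v1.6 dialect, 11 mandatory fields plus verbatim
optional tags).  The reader/writer round-trips byte-stably for records
this module wrote, which is what the pipeline's determinism contract is
built on.

The unclipped 5' position of a read — leftmost aligned position minus
leading clips on the forward strand, alignment end plus trailing clips
on the reverse strand — together with chromosome and strand forms the
"external coordinates" used both for duplicate identification and for
routing pairs to subregions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")
_QUERY_CONSUMING = frozenset("MIS=X")


class SamFormatError(ValueError):
    """Malformed SAM line."""


class ContractError(ValueError):
    """An operation was called on a record that violates its precondition."""


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into (op, length) tuples."""
    if cigar == "*":
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{l}{op}" for op, l in ops) != cigar:
        raise SamFormatError(f"invalid CIGAR {cigar!r}")
    return ops


def cigar_query_length(cigar: str) -> int:
    return sum(l for op, l in parse_cigar(cigar) if op in _QUERY_CONSUMING)


def cigar_reference_length(cigar: str) -> int:
    return sum(l for op, l in parse_cigar(cigar) if op in _REF_CONSUMING)


@dataclass
class AlignedRead:
    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: tuple[str, ...] = ()

    # -- flag helpers ------------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_first(self) -> bool:
        return bool(self.flag & FLAG_FIRST)

    @property
    def is_second(self) -> bool:
        return bool(self.flag & FLAG_SECOND)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    # -- coordinate math ---------------------------------------------------
    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        return self.pos + cigar_reference_length(self.cigar) - 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return (
            not self.is_unmapped
            and self.rname == chrom
            and self.pos <= end
            and self.reference_end >= start
        )

    def validate(self) -> None:
        if self.seq != "*" and self.qual != "*" and len(self.seq) != len(self.qual):
            raise SamFormatError(
                f"{self.qname}: SEQ length {len(self.seq)} != QUAL length {len(self.qual)}"
            )
        if self.seq != "*" and self.cigar != "*":
            qlen = cigar_query_length(self.cigar)
            if qlen != len(self.seq):
                raise SamFormatError(
                    f"{self.qname}: CIGAR query length {qlen} != SEQ length {len(self.seq)}"
                )
        if not self.is_unmapped and self.pos < 1:
            raise SamFormatError(f"{self.qname}: mapped read with POS {self.pos}")

    def to_line(self) -> str:
        fields = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(self.mapq),
            self.cigar,
            self.rnext,
            str(self.pnext),
            str(self.tlen),
            self.seq,
            self.qual,
        ]
        fields.extend(self.tags)
        return "\t".join(fields)

    @classmethod
    def from_line(cls, line: str, lineno: int | None = None) -> "AlignedRead":
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 11:
            where = f" at line {lineno}" if lineno is not None else ""
            raise SamFormatError(f"SAM record with {len(parts)} fields{where}")
        try:
            read = cls(
                qname=parts[0],
                flag=int(parts[1]),
                rname=parts[2],
                pos=int(parts[3]),
                mapq=int(parts[4]),
                cigar=parts[5],
                rnext=parts[6],
                pnext=int(parts[7]),
                tlen=int(parts[8]),
                seq=parts[9],
                qual=parts[10],
                tags=tuple(parts[11:]),
            )
        except ValueError as exc:
            where = f" at line {lineno}" if lineno is not None else ""
            raise SamFormatError(f"unparseable SAM record{where}: {exc}") from exc
        return read

    def get_tag(self, name: str) -> str | None:
        prefix = name + ":"
        for tag in self.tags:
            if tag.startswith(prefix):
                return tag.split(":", 2)[2]
        return None


@dataclass(frozen=True)
class ReadPair:
    """Two primary records sharing a qname, first- and second-of-pair."""

    first: AlignedRead
    second: AlignedRead

    def __post_init__(self) -> None:
        if self.first.qname != self.second.qname:
            raise ContractError(
                f"pair qname mismatch: {self.first.qname!r} vs {self.second.qname!r}"
            )
        if not (self.first.is_first and self.second.is_second):
            raise ContractError(f"{self.first.qname}: pair mates mislabeled")

    @property
    def qname(self) -> str:
        return self.first.qname

    @property
    def mapq_sum(self) -> int:
        return self.first.mapq + self.second.mapq

    @property
    def reads(self) -> tuple[AlignedRead, AlignedRead]:
        return (self.first, self.second)


SINGLE_END_SENTINEL = ("~", -1, ".")

DEFAULT_LIBRARY = "-"


@dataclass(frozen=True, order=True)
class DuplicateKey:
    """Canonical external coordinates of a pair (or single-end read).

    The two (chromosome, unclipped 5' position, strand) triples are
    stored in lexicographic order, so the key is independent of mate
    labeling.  Single-end keys carry one triple plus a sentinel.
    """

    library: str
    lo: tuple[str, int, str]
    hi: tuple[str, int, str]

    @property
    def is_single_end(self) -> bool:
        return self.hi == SINGLE_END_SENTINEL


def unclipped_five_prime(read: AlignedRead) -> tuple[str, int, str]:
    """External coordinate triple (chromosome, unclipped 5' pos, strand).

    Forward strand: POS minus leading soft/hard clip lengths.  Reverse
    strand: alignment reference end plus trailing soft/hard clip lengths.
    """
    if read.is_unmapped:
        raise ContractError(f"{read.qname}: unclipped 5' position of unmapped read")
    ops = parse_cigar(read.cigar)
    if not ops:
        raise ContractError(f"{read.qname}: mapped read without CIGAR")
    if read.is_reverse:
        end = read.pos + sum(l for op, l in ops if op in _REF_CONSUMING) - 1
        trailing = 0
        for op, l in reversed(ops):
            if op in "SH":
                trailing += l
            else:
                break
        return (read.rname, end + trailing, "-")
    leading = 0
    for op, l in ops:
        if op in "SH":
            leading += l
        else:
            break
    return (read.rname, read.pos - leading, "+")


def _library_of(read: AlignedRead) -> str:
    lb = read.get_tag("LB")
    return lb if lb is not None else DEFAULT_LIBRARY


def duplicate_key(item: ReadPair | AlignedRead) -> DuplicateKey:
    """Canonical duplicate key for a primary pair or single-end read.

    For a pair with one unmapped mate the key is single-end on the
    mapped mate.  Deterministic and symmetric in mate order.
    """
    if isinstance(item, ReadPair):
        for r in item.reads:
            if not r.is_primary:
                raise ContractError(f"{r.qname}: duplicate key of non-primary record")
        mapped = [r for r in item.reads if not r.is_unmapped]
        if not mapped:
            raise ContractError(f"{item.qname}: duplicate key of fully unmapped pair")
        lib = _library_of(item.first)
        if len(mapped) == 1:
            return DuplicateKey(lib, unclipped_five_prime(mapped[0]), SINGLE_END_SENTINEL)
        t1 = unclipped_five_prime(item.first)
        t2 = unclipped_five_prime(item.second)
        lo, hi = sorted((t1, t2))
        return DuplicateKey(lib, lo, hi)
    read = item
    if not read.is_primary:
        raise ContractError(f"{read.qname}: duplicate key of non-primary record")
    return DuplicateKey(_library_of(read), unclipped_five_prime(read), SINGLE_END_SENTINEL)


# ---------------------------------------------------------------------------
# SAM text I/O


def make_header(genome, extra: Sequence[str] = ()) -> list[str]:
    """Minimal deterministic header: @HD plus @SQ in genome order."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in genome.sequences:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.extend(extra)
    return lines


def read_sam(path: str | Path) -> tuple[list[str], list[AlignedRead]]:
    """Read a plain-text SAM file: (header lines, records)."""
    header: list[str] = []
    records: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("@"):
                header.append(line.rstrip("\n"))
            else:
                records.append(AlignedRead.from_line(line, lineno))
    return header, records


def write_sam(records: Iterable[AlignedRead], path: str | Path, header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for read in records:
            fh.write(read.to_line() + "\n")


# ---------------------------------------------------------------------------
# Record grouping


@dataclass
class RecordGroups:
    """Primary pairs, lone primaries, unmapped pairs, and the rest, by qname."""

    pairs: list[ReadPair]
    orphans: list[AlignedRead]  # lone primary whose flags claim a mapped mate
    unmapped: list[AlignedRead]  # fully unmapped pairs/reads, passed through
    attachments: dict[str, list[AlignedRead]]  # secondary/supplementary by qname


def group_records(records: Iterable[AlignedRead]) -> RecordGroups:
    """Reconstruct primary pairs from a record stream.

    Secondary/supplementary records are set aside per qname; they follow
    their primary pair through routing and deduplication.  Fully
    unmapped templates pass through untouched.
    """
    primaries: dict[str, list[AlignedRead]] = {}
    attachments: dict[str, list[AlignedRead]] = {}
    order: list[str] = []
    for read in records:
        if not read.is_primary:
            attachments.setdefault(read.qname, []).append(read)
            continue
        if read.qname not in primaries:
            order.append(read.qname)
        primaries.setdefault(read.qname, []).append(read)
    pairs: list[ReadPair] = []
    orphans: list[AlignedRead] = []
    unmapped: list[AlignedRead] = []
    for qname in order:
        recs = primaries[qname]
        if len(recs) == 2:
            a, b = recs
            first, second = (a, b) if a.is_first else (b, a)
            pair = ReadPair(first, second)
            if first.is_unmapped and second.is_unmapped:
                unmapped.extend(pair.reads)
            else:
                pairs.append(pair)
        elif len(recs) == 1:
            r = recs[0]
            if r.is_unmapped:
                unmapped.append(r)
            else:
                orphans.append(r)
        else:
            raise SamFormatError(f"{qname}: {len(recs)} primary records")
    return RecordGroups(pairs, orphans, unmapped, attachments)


def sort_key(genome) -> "callable":
    """Canonical record sort key: (chromosome order, pos, qname, flag)."""
    ranks = {name: i for i, (name, _) in enumerate(genome.sequences)}

    def key(read: AlignedRead):
        return (ranks.get(read.rname, len(ranks)), read.pos, read.qname, read.flag)

    return key


def sort_records(records: Iterable[AlignedRead], genome) -> list[AlignedRead]:
    return sorted(records, key=sort_key(genome))
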