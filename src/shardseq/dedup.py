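"""Duplicate-pair identification and removal.

Two forms with an exact-equivalence contract between them:

* :func:`deduplicate_serial` — genome-wide dedup of a single record set,
  the reference semantics;
* :func:`deduplicate_parallel` — the sharded form: the chrI file
  (boundary-spanning and interchromosomal pairs) is deduplicated first
  as a unit, its surviving reads are redistributed to subregions by
  coordinate, and each subregion is then deduplicated independently.

Because routing is a function of the duplicate key, every duplicate
class lands intact in exactly one destination, so the parallel form
retains exactly the records the serial form retains.

The survivor of each duplicate class is the member with the highest
mapping quality (sum of mate MAPQs), ties broken by lexicographically
smallest qname; a ``baseq_sum`` rule (sum of base qualities) is
available for interoperability with the wider ecosystem.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alignment import (
    FLAG_DUPLICATE,
    AlignedRead,
    DuplicateKey,
    ReadPair,
    duplicate_key,
    group_records,
    sort_records,
)
from .genome_partition import PartitionPlan
from .router import CHR_I, dest_name, redistribute_chrI

Member = ReadPair | AlignedRead


class DedupError(RuntimeError):
    pass


@dataclass
class DuplicateGroup:
    key: DuplicateKey
    members: list[Member]


def _member_reads(member: Member) -> tuple[AlignedRead, ...]:
    return member.reads if isinstance(member, ReadPair) else (member,)


def _member_qname(member: Member) -> str:
    return member.qname if isinstance(member, ReadPair) else member.qname


def _score(member: Member, rule: str) -> int:
    reads = _member_reads(member)
    if rule == "mapq":
        return sum(r.mapq for r in reads)
    if rule == "baseq_sum":
        return sum(
            sum(ord(c) - 33 for c in r.qual) if r.qual != "*" else 0 for r in reads
        )
    raise DedupError(f"unknown survivor rule {rule!r}")


def select_survivor(group: DuplicateGroup, rule: str = "mapq") -> Member:
    """Retained member: maximal score, ties to smallest qname."""
    if not group.members:
        raise DedupError("empty duplicate group")
    return min(group.members, key=lambda m: (-_score(m, rule), _member_qname(m)))


@dataclass
class DedupMetrics:
    groups: int = 0
    duplicates_removed: int = 0
    per_destination: dict[str, int] = field(default_factory=dict)

    def merge(self, other: "DedupMetrics") -> None:
        self.groups += other.groups
        self.duplicates_removed += other.duplicates_removed
        for k, v in other.per_destination.items():
            self.per_destination[k] = self.per_destination.get(k, 0) + v


def _dedup_records(
    records: Sequence[AlignedRead], rule: str, mark_only: bool
) -> tuple[list[AlignedRead], DedupMetrics]:
    """Core dedup of one record set, preserving input order.

    Lone mapped primaries whose flags claim a mapped mate pass through
    untouched: they are either genuinely orphaned inputs or chrI reads
    already deduplicated as pairs upstream.
    """
    groups_view = group_records(records)
    by_key: dict[DuplicateKey, list[Member]] = {}
    for pair in groups_view.pairs:
        by_key.setdefault(duplicate_key(pair), []).append(pair)
    doomed: set[str] = set()
    metrics = DedupMetrics(groups=len(by_key))
    for key, members in by_key.items():
        survivor = select_survivor(DuplicateGroup(key, members), rule)
        for m in members:
            if m is not survivor:
                doomed.add(_member_qname(m))
                metrics.duplicates_removed += 1
    out: list[AlignedRead] = []
    for read in records:
        if read.qname in doomed:
            if mark_only:
                marked = AlignedRead(
                    read.qname,
                    read.flag | FLAG_DUPLICATE,
                    read.rname,
                    read.pos,
                    read.mapq,
                    read.cigar,
                    read.rnext,
                    read.pnext,
                    read.tlen,
                    read.seq,
                    read.qual,
                    read.tags,
                )
                out.append(marked)
            continue
        out.append(read)
    return out, metrics


def deduplicate_serial(
    records: Sequence[AlignedRead],
    genome,
    survivor: str = "mapq",
    mark_only: bool = False,
) -> tuple[list[AlignedRead], DedupMetrics]:
    """Genome-wide dedup of a complete record set; canonically sorted output."""
    kept, metrics = _dedup_records(records, survivor, mark_only)
    metrics.per_destination["all"] = len(kept)
    return sort_records(kept, genome), metrics


@dataclass
class ParallelDedupResult:
    per_subregion: dict[str, list[AlignedRead]]
    chrI_retained: list[AlignedRead]  # copy of the deduplicated chrI file
    unplaced: list[AlignedRead]  # unmapped chrI leftovers, not redistributed
    metrics: DedupMetrics

    def final_records(self, genome) -> list[AlignedRead]:
        """All retained records, as one canonically sorted list."""
        combined: list[AlignedRead] = []
        for dest in sorted(self.per_subregion):
            combined.extend(self.per_subregion[dest])
        combined.extend(self.unplaced)
        return sort_records(combined, genome)


def deduplicate_parallel(
    merged: Mapping[str, Sequence[AlignedRead]],
    plan: PartitionPlan,
    workers: int = 1,
    survivor: str = "mapq",
    mark_only: bool = False,
) -> ParallelDedupResult:
    """Sharded dedup: chrI first, redistribute, then per-subregion.

    The multiset of retained primary records equals
    :func:`deduplicate_serial` of the concatenated input — exactly, for
    any subregion count and any worker count.
    """
    if workers < 1:
        raise DedupError(f"workers must be >= 1, got {workers}")
    chrI_in = list(merged.get(CHR_I, ()))
    chrI_dedup, chrI_metrics = _dedup_records(chrI_in, survivor, mark_only)
    chrI_sorted = sort_records(chrI_dedup, plan.genome)
    redistributed = redistribute_chrI(chrI_sorted, plan)
    unplaced = [r for r in chrI_sorted if r.is_unmapped]

    metrics = DedupMetrics()
    metrics.merge(chrI_metrics)
    metrics.per_destination[CHR_I] = len(chrI_sorted)

    dests = [dest_name(sr.index) for sr in plan.subregions]

    def run_one(dest: str) -> tuple[str, list[AlignedRead], DedupMetrics]:
        try:
            records = list(merged.get(dest, ()))
            records.extend(redistributed.get(dest, ()))
            kept, m = _dedup_records(records, survivor, mark_only)
            return dest, sort_records(kept, plan.genome), m
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise DedupError(f"deduplication failed in destination {dest}") from exc

    results: dict[str, list[AlignedRead]] = {}
    if workers == 1:
        outs = [run_one(d) for d in dests]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            outs = list(pool.map(run_one, dests))
    for dest, kept, m in sorted(outs, key=lambda t: t[0]):
        results[dest] = kept
        metrics.merge(m)
        metrics.per_destination[dest] = len(kept)
    return ParallelDedupResult(results, chrI_sorted, unplaced, metrics)
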