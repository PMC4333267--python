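"""Routing of read pairs to subregions and the artificial chromosome.

Implements the split/merge choreography: every primary pair whose two
unclipped 5' coordinates fall inside the same subregion's fixed
boundaries is written to that subregion's file; every other pair —
interchromosomal or straddling a fixed boundary — is diverted to the
reserved ``chrI`` destination, deduplicated there as a unit, and only
afterwards redistributed read-by-read to the subregions.

Because routing uses the same coordinates as the duplicate key, any two
pairs with equal keys land in the same destination (duplicate-class
closure), which is what makes per-destination deduplication exactly
equivalent to genome-wide serial deduplication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .alignment import (
    AlignedRead,
    ReadPair,
    group_records,
    read_sam,
    sort_records,
    unclipped_five_prime,
    write_sam,
)
from .genome_partition import PartitionPlan

CHR_I = "chrI"


class RoutingError(ValueError):
    pass


@dataclass(frozen=True)
class RouteDestination:
    kind: str  # "subregion" | "chrI"
    subregion_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "chrI" and self.subregion_index is not None:
            raise RoutingError("chrI destination carries no subregion index")
        if self.kind == "subregion" and self.subregion_index is None:
            raise RoutingError("subregion destination requires an index")

    @property
    def name(self) -> str:
        if self.kind == "chrI":
            return CHR_I
        return f"s{self.subregion_index:04d}"


def dest_name(subregion_index: int | None) -> str:
    return CHR_I if subregion_index is None else f"s{subregion_index:04d}"


def route_pair(pair: ReadPair, plan: PartitionPlan) -> RouteDestination:
    """Destination of a primary pair.

    Same-subregion pairs go to that subregion; pairs whose mates fall in
    different subregions (inter- or intrachromosomal) go to chrI.  Pairs
    with one unmapped mate route by the mapped mate.
    """
    mapped = [r for r in pair.reads if not r.is_unmapped]
    if not mapped:
        return RouteDestination("chrI")
    homes = []
    for read in mapped:
        chrom, p, _ = unclipped_five_prime(read)
        homes.append(plan.locate(chrom, p).index)
    if len(set(homes)) == 1:
        return RouteDestination("subregion", homes[0])
    return RouteDestination("chrI")


def route_records(
    records: Iterable[AlignedRead], plan: PartitionPlan
) -> dict[str, list[AlignedRead]]:
    """Assign every record to exactly one destination, in memory.

    Secondary/supplementary records follow their primary pair; lone
    primaries route as the one-mate case; fully unmapped templates go to
    chrI (they carry no coordinates and are retained there).
    """
    groups = group_records(records)
    out: dict[str, list[AlignedRead]] = {}

    def emit(name: str, reads: Iterable[AlignedRead]) -> None:
        out.setdefault(name, []).extend(reads)

    for pair in groups.pairs:
        name = route_pair(pair, plan).name
        emit(name, pair.reads)
        emit(name, groups.attachments.pop(pair.qname, ()))
    for orphan in groups.orphans:
        chrom, p, _ = unclipped_five_prime(orphan)
        name = dest_name(plan.locate(chrom, p).index)
        emit(name, [orphan])
        emit(name, groups.attachments.pop(orphan.qname, ()))
    if groups.unmapped:
        emit(CHR_I, groups.unmapped)
        for read in groups.unmapped:
            emit(CHR_I, groups.attachments.pop(read.qname, ()))
    # attachments whose primaries never appeared: keep with chrI for safety
    for qname in sorted(groups.attachments):
        emit(CHR_I, groups.attachments[qname])
    return out


@dataclass
class SplitLayout:
    """File layout of the M x N split stage and the merged destinations."""

    workdir: Path
    fragments: dict[tuple[int, str], Path] = field(default_factory=dict)
    merged: dict[str, Path] = field(default_factory=dict)

    def fragment_path(self, input_ordinal: int, dest: str) -> Path:
        return self.workdir / "split" / f"in{input_ordinal:03d}__{dest}.sam"

    def merged_path(self, dest: str) -> Path:
        return self.workdir / "merged" / f"{dest}.sam"

    def write_manifest(self) -> None:
        path = self.workdir / "layout.jsonl"
        with open(path, "w") as fh:
            for (ordinal, dest), frag in sorted(self.fragments.items()):
                fh.write(
                    json.dumps(
                        {"stage": "split", "input": ordinal, "dest": dest, "path": str(frag)},
                        sort_keys=True,
                    )
                    + "\n"
                )
            for dest, path_ in sorted(self.merged.items()):
                fh.write(
                    json.dumps({"stage": "merged", "dest": dest, "path": str(path_)}, sort_keys=True)
                    + "\n"
                )


def split_alignment_file(
    input_ordinal: int,
    records: Iterable[AlignedRead],
    plan: PartitionPlan,
    layout: SplitLayout,
    header: Sequence[str] = (),
) -> None:
    """Split one input's records into per-destination fragment files.

    Zero-count destinations produce no file.  Record counts are
    conserved across the split.
    """
    routed = route_records(records, plan)
    (layout.workdir / "split").mkdir(parents=True, exist_ok=True)
    for dest in sorted(routed):
        path = layout.fragment_path(input_ordinal, dest)
        write_sam(routed[dest], path, header)
        layout.fragments[(input_ordinal, dest)] = path


def merge_by_destination(
    layout: SplitLayout, plan: PartitionPlan, header: Sequence[str] = ()
) -> None:
    """Merge split fragments into one coordinate-sorted file per destination.

    The canonical sort makes the output bytes independent of fragment
    arrival order.
    """
    (layout.workdir / "merged").mkdir(parents=True, exist_ok=True)
    by_dest: dict[str, list[Path]] = {}
    for (ordinal, dest), path in layout.fragments.items():
        by_dest.setdefault(dest, []).append(path)
    for dest in sorted(by_dest):
        records: list[AlignedRead] = []
        for path in sorted(by_dest[dest]):
            if not path.exists():
                raise RoutingError(f"missing split fragment {path}")
            _, recs = read_sam(path)
            records.extend(recs)
        merged = sort_records(records, plan.genome)
        out = layout.merged_path(dest)
        write_sam(merged, out, header)
        layout.merged[dest] = out


def redistribute_chrI(
    chrI_records: Iterable[AlignedRead], plan: PartitionPlan
) -> dict[str, list[AlignedRead]]:
    """Assign deduplicated chrI reads individually to subregions.

    Each mapped read goes to the subregion whose fixed boundaries
    contain its own unclipped 5' position.  Unmapped records stay out of
    the redistribution (the retained chrI copy keeps them).
    """
    out: dict[str, list[AlignedRead]] = {}
    for read in chrI_records:
        if read.is_unmapped:
            continue
        chrom, p, _ = unclipped_five_prime(read)
        name = dest_name(plan.locate(chrom, p).index)
        out.setdefault(name, []).append(read)
    return out
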