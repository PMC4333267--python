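"""Fixed-boundary genome partitioning with overlap buffers.

A genome index (ordered chromosome names and lengths) is divided into
roughly-equal subregions whose fixed boundaries tile each chromosome
exactly.  Each subregion additionally carries a buffered calling window
extending ``overlap`` bp into its neighbours (clipped at chromosome
ends).  Plans serialize to a GATK-style intervals text file.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path


class PartitionError(ValueError):
    """Invalid partitioning arguments or malformed intervals file."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths.

    The sequence order is stable and defines the global sort order used
    by every downstream stage.
    """

    sequences: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.sequences]
        if len(set(names)) != len(names):
            raise PartitionError("duplicate chromosome names in genome index")
        for name, length in self.sequences:
            if length < 1:
                raise PartitionError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.sequences)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.sequences)

    def length_of(self, name: str) -> int:
        for n, l in self.sequences:
            if n == name:
                return l
        raise KeyError(name)

    def rank(self, name: str) -> int:
        """Position of *name* in the global chromosome order."""
        for i, (n, _) in enumerate(self.sequences):
            if n == name:
                return i
        raise KeyError(name)

    @classmethod
    def from_fai(cls, path: str | Path) -> "GenomeIndex":
        """Read a FASTA-index-style file (first two columns: name, length)."""
        seqs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                seqs.append((parts[0], int(parts[1])))
        return cls(tuple(seqs))


@dataclass(frozen=True)
class Subregion:
    """One fixed-boundary interval plus its buffered calling window."""

    index: int
    chrom: str
    start: int
    end: int
    buffered_start: int
    buffered_end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PartitionError(f"subregion start {self.start} > end {self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def fixed_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PartitionPlan:
    """A complete partitioning of a genome into subregions."""

    genome: GenomeIndex
    subregions: tuple[Subregion, ...]
    overlap: int
    target_length: int
    _chrom_offset: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        # precompute per-chromosome (first global ordinal, piece count)
        offsets: dict[str, tuple[int, int]] = {}
        for sr in self.subregions:
            first, count = offsets.get(sr.chrom, (sr.index, 0))
            offsets[sr.chrom] = (min(first, sr.index), count + 1)
        object.__setattr__(self, "_chrom_offset", offsets)

    def __len__(self) -> int:
        return len(self.subregions)

    def subregions_for(self, chrom: str) -> tuple[Subregion, ...]:
        return tuple(sr for sr in self.subregions if sr.chrom == chrom)

    def locate(self, chrom: str, pos: int) -> Subregion:
        """Subregion whose fixed boundaries contain *pos*.

        Positions outside ``[1, chrom_length]`` (possible for unclipped
        coordinates of reads soft-clipped at chromosome ends) are clamped
        to the chromosome before lookup, so every mapped read has a
        well-defined home subregion.
        """
        if chrom not in self._chrom_offset:
            raise PartitionError(f"chromosome {chrom!r} not in partition plan")
        first, count = self._chrom_offset[chrom]
        length = self.genome.length_of(chrom)
        pos = min(max(pos, 1), length)
        piece = min((pos - 1) // self.target_length, count - 1)
        return self.subregions[first + piece]


def partition_genome(index: GenomeIndex, M: int, overlap: int = 3000) -> PartitionPlan:
    """Divide *index* into ~M equal fixed-boundary subregions.

    ``target_length = ceil(total / M)``; each chromosome is cut into
    ``ceil(len / target_length)`` consecutive pieces of ``target_length``
    (the final piece absorbs the remainder).  Subregions never span
    chromosomes, so the realized count may exceed M by up to
    ``n_chromosomes - 1``.
    """
    if M < 1:
        raise PartitionError(f"subregion count must be >= 1, got {M}")
    if overlap < 0:
        raise PartitionError(f"overlap must be >= 0, got {overlap}")
    if not index.sequences:
        raise PartitionError("empty genome index")
    target = math.ceil(index.total_length / M)
    return PartitionPlan(index, _cut(index, target, overlap), overlap, target)


def _cut(index: GenomeIndex, target: int, overlap: int) -> tuple[Subregion, ...]:
    subregions: list[Subregion] = []
    ordinal = 0
    for chrom, length in index.sequences:
        n_pieces = math.ceil(length / target)
        for k in range(n_pieces):
            start = k * target + 1
            end = min((k + 1) * target, length)
            subregions.append(
                Subregion(
                    index=ordinal,
                    chrom=chrom,
                    start=start,
                    end=end,
                    buffered_start=max(1, start - overlap),
                    buffered_end=min(length, end + overlap),
                )
            )
            ordinal += 1
    return tuple(subregions)


_INTERVAL_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def write_intervals(plan: PartitionPlan, path: str | Path) -> None:
    """Serialize the buffered windows as GATK-style intervals.

    One ``chrom:start-end`` line per subregion (1-based inclusive,
    buffered window).  Fixed boundaries are recoverable from the
    ``#overlap=`` and ``#target_length=`` header comments.
    """
    with open(path, "w") as fh:
        fh.write(f"#overlap={plan.overlap}\n")
        fh.write(f"#target_length={plan.target_length}\n")
        for sr in plan.subregions:
            fh.write(f"{sr.chrom}:{sr.buffered_start}-{sr.buffered_end}\n")


def read_intervals(path: str | Path, index: GenomeIndex) -> PartitionPlan:
    """Reconstruct a plan written by :func:`write_intervals`.

    Validates every interval against the index bounds; errors name the
    offending line number.
    """
    overlap = 0
    target = None
    windows: list[tuple[str, int, int, int]] = []  # chrom, bstart, bend, lineno
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#overlap="):
                    overlap = int(line.split("=", 1)[1])
                elif line.startswith("#target_length="):
                    target = int(line.split("=", 1)[1])
                continue
            m = _INTERVAL_RE.match(line)
            if not m:
                raise PartitionError(f"{path}:{lineno}: malformed interval {line!r}")
            chrom, start, end = m.group("chrom"), int(m.group("start")), int(m.group("end"))
            if chrom not in index.names:
                raise PartitionError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            length = index.length_of(chrom)
            if not (1 <= start <= end <= length):
                raise PartitionError(
                    f"{path}:{lineno}: interval {chrom}:{start}-{end} outside "
                    f"chromosome bounds [1, {length}]"
                )
            windows.append((chrom, start, end, lineno))
    if target is None:
        raise PartitionError(f"{path}: missing #target_length header")
    # Recompute the geometry from the header and check it matches the file.
    plan = PartitionPlan(index, _cut(index, target, overlap), overlap, target)
    if len(plan.subregions) != len(windows):
        raise PartitionError(
            f"{path}: {len(windows)} intervals but header geometry implies "
            f"{len(plan.subregions)}"
        )
    for sr, (chrom, start, end, lineno) in zip(plan.subregions, windows):
        if (sr.chrom, sr.buffered_start, sr.buffered_end) != (chrom, start, end):
            raise PartitionError(
                f"{path}:{lineno}: interval {chrom}:{start}-{end} does not match "
                f"header geometry ({sr.chrom}:{sr.buffered_start}-{sr.buffered_end})"
            )
    return plan
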