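"""Buffered-window pileup calling and boundary-zone reconciliation.

Each subregion is called over its buffered window, so a variant lying
within the overlap of two adjacent subregions may be called twice.
Reconciliation keeps exactly the copy produced by the subregion whose
fixed boundaries contain the variant's anchor position (POS), then
concatenates per-subregion calls into one genome-wide VCF.

The caller itself is deliberately simple, fully specified plumbing — a
depth/allele-fraction threshold caller over pileup counts with
leftmost-anchored indels from CIGAR evidence — deterministic by
construction and pluggable behind the same interface for anyone who
wants to shell out to a production caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .alignment import AlignedRead, parse_cigar
from .genome_partition import GenomeIndex, PartitionPlan, Subregion

#: per-base miscall probability used by the binomial-tail quality proxy
ERROR_PROXY = 0.05
MAX_QUAL = 3000.0

_BASE_CODE = {b: i for i, b in enumerate("ACGT")}
_BASES = "ACGT"


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # 1-based anchor
    ref: str
    alt: str
    qual: float
    genotype: str  # "het" | "hom"
    depth: int
    subregion_index: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise VariantError(f"{self.chrom}:{self.pos}: ref == alt ({self.ref})")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _call_quality(alt_count: int, depth: int) -> float:
    """-10*log10 of the probability of >= alt_count miscalls in depth trials."""
    p = float(binom.sf(alt_count - 1, depth, ERROR_PROXY))
    if p <= 0.0:
        return MAX_QUAL
    return min(MAX_QUAL, round(-10.0 * math.log10(p), 2))


def pileup_call(
    window: Subregion,
    records: Iterable[AlignedRead],
    reference: Mapping[str, str],
    min_depth: int = 8,
    min_alt_frac: float = 0.2,
    hom_frac: float = 0.8,
) -> list[VariantCall]:
    """Threshold caller over the buffered window of one subregion.

    SNP: at each reference position, the most frequent non-reference
    base is emitted when depth >= *min_depth* and its fraction >=
    *min_alt_frac*; genotype is hom when the fraction >= *hom_frac*.
    Indels are taken from CIGAR I/D evidence, leftmost-anchored at the
    base before the event, under the same thresholds against the pileup
    depth at the anchor.
    """
    chrom = window.chrom
    if chrom not in reference:
        raise VariantError(f"no reference sequence for {chrom!r}")
    ref_seq = reference[chrom]
    lo, hi = window.buffered_start, window.buffered_end
    if hi > len(ref_seq):
        raise VariantError(
            f"window {chrom}:{lo}-{hi} extends past reference length {len(ref_seq)}"
        )
    L = hi - lo + 1
    counts = np.zeros((5, L), dtype=np.int64)
    indel_counts: dict[tuple[int, str, str], int] = {}

    for read in records:
        if read.is_unmapped or not read.is_primary or read.is_duplicate:
            continue
        if read.rname != chrom or read.seq == "*":
            continue
        q = 0
        r = read.pos  # 1-based reference cursor
        seq = read.seq.upper()
        for op, length in parse_cigar(read.cigar):
            if op in "M=X":
                a = max(r, lo)
                b = min(r + length - 1, hi)
                if a <= b:
                    frag = seq[q + (a - r) : q + (b - r) + 1]
                    codes = np.fromiter(
                        (_BASE_CODE.get(c, 4) for c in frag), dtype=np.int64, count=len(frag)
                    )
                    np.add.at(counts, (codes, np.arange(a - lo, b - lo + 1)), 1)
                q += length
                r += length
            elif op == "I":
                anchor = r - 1
                if anchor >= 1 and lo <= anchor <= hi:
                    ref_base = ref_seq[anchor - 1].upper()
                    alt = ref_base + seq[q : q + length]
                    key = (anchor, ref_base, alt)
                    indel_counts[key] = indel_counts.get(key, 0) + 1
                q += length
            elif op == "D":
                anchor = r - 1
                if anchor >= 1 and lo <= anchor <= hi:
                    ref_base = ref_seq[anchor - 1].upper()
                    deleted = ref_seq[r - 1 : r - 1 + length].upper()
                    key = (anchor, ref_base + deleted, ref_base)
                    indel_counts[key] = indel_counts.get(key, 0) + 1
                r += length
            elif op == "N":
                r += length
            elif op == "S":
                q += length
            # H, P consume nothing

    depth = counts[:4].sum(axis=0)
    calls: list[VariantCall] = []

    # SNPs
    ref_codes = np.fromiter(
        (_BASE_CODE.get(c, 4) for c in ref_seq[lo - 1 : hi].upper()), dtype=np.int64, count=L
    )
    alt_counts = counts[:4].copy()
    valid_ref = ref_codes < 4
    cols = np.arange(L)
    alt_counts[ref_codes[valid_ref], cols[valid_ref]] = -1
    best_alt = np.argmax(alt_counts, axis=0)
    best_count = alt_counts[best_alt, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, best_count / np.maximum(depth, 1), 0.0)
    snp_mask = valid_ref & (depth >= min_depth) & (best_count > 0) & (frac >= min_alt_frac)
    for i in np.nonzero(snp_mask)[0].tolist():
        pos = lo + i
        calls.append(
            VariantCall(
                chrom=chrom,
                pos=pos,
                ref=_BASES[ref_codes[i]],
                alt=_BASES[best_alt[i]],
                qual=_call_quality(int(best_count[i]), int(depth[i])),
                genotype="hom" if frac[i] >= hom_frac else "het",
                depth=int(depth[i]),
                subregion_index=window.index,
            )
        )

    # Indels
    for (pos, ref_allele, alt_allele), n in sorted(indel_counts.items()):
        d = int(depth[pos - lo])
        if d < min_depth:
            continue
        f = min(1.0, n / d) if d > 0 else 0.0
        if f < min_alt_frac:
            continue
        calls.append(
            VariantCall(
                chrom=chrom,
                pos=pos,
                ref=ref_allele,
                alt=alt_allele,
                qual=_call_quality(min(n, d), d),
                genotype="hom" if f >= hom_frac else "het",
                depth=d,
                subregion_index=window.index,
            )
        )

    calls.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return calls


def assign_subregion(call: VariantCall, plan: PartitionPlan) -> int:
    """Owning subregion: the one whose fixed boundaries contain POS."""
    return plan.locate(call.chrom, call.pos).index


def reconcile_boundary_variants(
    calls_by_subregion: Mapping[int, Sequence[VariantCall]], plan: PartitionPlan
) -> list[VariantCall]:
    """Keep each call iff its provenance subregion owns its position.

    Buffer-zone duplicates (same variant called by the adjacent
    subregion) are thereby removed; the owner's record is kept verbatim.
    Result sorted by (chromosome order, pos, ref, alt).
    """
    kept: list[VariantCall] = []
    for idx in sorted(calls_by_subregion):
        for call in calls_by_subregion[idx]:
            if call.subregion_index != idx:
                raise VariantError(
                    f"call {call.site} provenance {call.subregion_index} filed under {idx}"
                )
            if assign_subregion(call, plan) == idx:
                kept.append(call)
    ranks = {name: i for i, name in enumerate(plan.genome.names)}
    kept.sort(key=lambda c: (ranks[c.chrom], c.pos, c.ref, c.alt))
    return kept


# ---------------------------------------------------------------------------
# VCF 4.2 text I/O (deterministic: fixed header, no timestamps)

_VCF_META = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth at site">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]
_GT = {"het": "0/1", "hom": "1/1"}
_GT_BACK = {"0/1": "het", "1/1": "hom", "1|1": "hom", "0|1": "het"}


def _vcf_header(genome: GenomeIndex, sample: str = "SAMPLE") -> list[str]:
    lines = list(_VCF_META)
    for name, length in genome.sequences:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    return lines


def write_vcf(
    calls: Sequence[VariantCall], genome: GenomeIndex, path: str | Path
) -> None:
    """Write calls as deterministic VCF 4.2 text.  Calls must be sorted."""
    ranks = {name: i for i, name in enumerate(genome.names)}
    last = None
    for call in calls:
        key = (ranks[call.chrom], call.pos, call.ref, call.alt)
        if last is not None and key < last:
            raise VariantError("unsorted calls passed to write_vcf")
        last = key
    with open(path, "w") as fh:
        for line in _vcf_header(genome):
            fh.write(line + "\n")
        for call in calls:
            fh.write(
                f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}\t"
                f"{call.qual:.2f}\tPASS\tDP={call.depth}\tGT\t{_GT[call.genotype]}\n"
            )


def read_vcf(path: str | Path, subregion_index: int = -1) -> list[VariantCall]:
    """Parse a VCF written by :func:`write_vcf` (or a compatible subset)."""
    calls: list[VariantCall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alt, qual = parts[0], int(parts[1]), parts[2], parts[3], parts[4], parts[5]
            depth = 0
            for item in parts[7].split(";"):
                if item.startswith("DP="):
                    depth = int(item[3:])
            genotype = "hom"
            if len(parts) > 9:
                genotype = _GT_BACK.get(parts[9].split(":")[0], "hom")
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    qual=float(qual) if qual != "." else 0.0,
                    genotype=genotype,
                    depth=depth,
                    subregion_index=subregion_index,
                )
            )
    return calls


def concat_vcf(paths: Sequence[str | Path], genome: GenomeIndex, out: str | Path) -> None:
    """Concatenate per-subregion VCF fragments into one genome-wide file.

    Equivalent to :func:`write_vcf` of the merged call list.
    """
    calls: list[VariantCall] = []
    for path in paths:
        calls.extend(read_vcf(path))
    ranks = {name: i for i, name in enumerate(genome.names)}
    calls.sort(key=lambda c: (ranks[c.chrom], c.pos, c.ref, c.alt))
    write_vcf(calls, genome, out)
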