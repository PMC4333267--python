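"""Deterministic synthetic references, aligned read pairs, and truth variants.

Everything is reproducible byte-for-byte from the seed.  Reads are
emitted pre-aligned to their true origin: pairs are sampled from a
mutated haplotype and projected back to reference coordinates, so reads
crossing a spiked indel carry the corresponding I/D CIGAR operations
anchored exactly at the variant position.

Controlled structure for exercising the pipeline:

* ``duplication_rate`` — fraction of emitted pairs that are PCR copies
  of an earlier pair (identical external coordinates, fresh qname,
  fresh errors, fresh soft-clips);
* ``interchrom_rate`` — pairs whose mates map to different chromosomes;
* ``boundary_rate`` — pairs placed to straddle a fixed subregion
  boundary of a supplied partition plan;
* ``softclip_rate`` / ``error_rate`` — per-read soft-clipping and
  per-base substitution errors.

Truth is carried in optional tags: ``ot`` (original external
coordinates), ``od`` (qname of the duplicated original), ``vo`` (count
of spiked variants overlapped).
"""

from __future__ import annotations

import bisect
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignment import (
    FLAG_FIRST,
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_REVERSE,
    FLAG_SECOND,
    AlignedRead,
    make_header,
)
from .genome_partition import GenomeIndex, PartitionPlan
from .variants import VariantCall

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationSpec:
    seed: int = 1
    chrom_lengths: tuple[int, ...] = (100_000, 50_000)
    chrom_names: tuple[str, ...] | None = None
    coverage: float = 30.0
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    duplication_rate: float = 0.0
    interchrom_rate: float = 0.0
    boundary_rate: float = 0.0
    softclip_rate: float = 0.0
    error_rate: float = 0.0
    n_snps: int = 0
    n_indels: int = 0
    base_quality: int = 30
    mapq_range: tuple[int, int] = (60, 60)

    def __post_init__(self) -> None:
        if self.chrom_names is None:
            self.chrom_names = tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise SimulationError("chrom_names and chrom_lengths length mismatch")
        for rate in (
            self.duplication_rate,
            self.interchrom_rate,
            self.boundary_rate,
            self.softclip_rate,
            self.error_rate,
        ):
            if not (0.0 <= rate < 1.0):
                raise SimulationError(f"rate {rate} outside [0, 1)")
        if self.coverage <= 0:
            raise SimulationError("coverage must be positive")
        if self.read_length > min(self.chrom_lengths):
            raise SimulationError("read length exceeds shortest chromosome")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def generate_reference(spec: SimulationSpec) -> tuple[dict[str, str], GenomeIndex]:
    """Uniform-random A/C/G/T sequences, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    reference: dict[str, str] = {}
    for name, length in zip(spec.chrom_names, spec.chrom_lengths):
        codes = rng.integers(0, 4, size=length)
        reference[name] = _BASES[codes].tobytes().decode("ascii")
    genome = GenomeIndex(tuple(zip(spec.chrom_names, spec.chrom_lengths)))
    return reference, genome


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fai(genome: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.sequences:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Variant spiking


@dataclass(frozen=True)
class SpikedVariant:
    kind: str  # "snp" | "ins" | "del"
    chrom: str
    pos: int  # SNP: changed base; indel: 1-based anchor (base before event)
    ref: str
    alt: str


def _placeable(ref: str, kind: str, pos: int, size: int, rng) -> tuple[str, str] | None:
    """ref/alt alleles if a variant fits at pos, else None.

    Indels are constructed so their representation cannot be shifted
    left (anchored form is already normalized).
    """
    if kind == "snp":
        base = ref[pos - 1]
        if base not in "ACGT":
            return None
        alts = [b for b in "ACGT" if b != base]
        return base, alts[int(rng.integers(0, 3))]
    anchor = ref[pos - 1]
    if kind == "ins":
        ins = "".join("ACGT"[int(rng.integers(0, 4))] for _ in range(size))
        if ins[-1] == anchor:  # would left-shift
            return None
        return anchor, anchor + ins
    if kind == "del":
        if pos + size > len(ref):
            return None
        deleted = ref[pos : pos + size]
        if deleted[-1] == anchor:  # would left-shift
            return None
        return anchor + deleted, anchor
    raise SimulationError(f"unknown variant kind {kind!r}")


def spike_variants(
    reference: Mapping[str, str],
    spec: SimulationSpec,
    rng: np.random.Generator,
    plan: PartitionPlan | None = None,
) -> tuple[dict[str, str], list[SpikedVariant]]:
    """Mutate the reference with non-overlapping SNPs and short indels.

    When *plan* is supplied, at least one SNP is placed inside the
    buffer (within ``plan.overlap`` bp) of every internal fixed
    boundary, to exercise boundary-zone reconciliation.
    """
    margin = spec.read_length + 50  # keep full coverage over every variant
    min_gap = 12
    occupied: dict[str, list[int]] = {c: [] for c in reference}
    variants: list[SpikedVariant] = []

    def far_enough(chrom: str, pos: int) -> bool:
        return all(abs(pos - p) >= min_gap for p in occupied[chrom])

    def place(kind: str, chrom: str, lo: int, hi: int, size: int = 0) -> bool:
        for _ in range(200):
            pos = int(rng.integers(lo, hi + 1))
            if not far_enough(chrom, pos):
                continue
            alleles = _placeable(reference[chrom], kind, pos, size, rng)
            if alleles is None:
                continue
            variants.append(SpikedVariant(kind, chrom, pos, *alleles))
            occupied[chrom].append(pos)
            return True
        return False

    wanted_snps = spec.n_snps
    if plan is not None:
        for sr in plan.subregions:
            chrom_len = plan.genome.length_of(sr.chrom)
            if sr.end >= chrom_len:  # no boundary after the last piece
                continue
            half = max(1, plan.overlap)
            lo = max(margin, sr.end - half + 1)
            hi = min(chrom_len - margin, sr.end + half)
            if lo > hi or wanted_snps <= 0:
                continue
            if place("snp", sr.chrom, lo, hi):
                wanted_snps -= 1

    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    def random_chrom() -> str:
        return chroms[int(rng.choice(len(chroms), p=weights))]

    for _ in range(wanted_snps):
        c = random_chrom()
        if not place("snp", c, margin, len(reference[c]) - margin):
            raise SimulationError("could not place SNP; genome too small or too dense")
    for _ in range(spec.n_indels):
        c = random_chrom()
        kind = "ins" if rng.random() < 0.5 else "del"
        size = int(rng.integers(1, 7))
        if not place(kind, c, margin, len(reference[c]) - margin, size):
            raise SimulationError("could not place indel; genome too small or too dense")

    variants.sort(key=lambda v: (list(reference).index(v.chrom), v.pos))

    haplotype: dict[str, str] = {}
    for chrom in reference:
        seq = reference[chrom]
        parts: list[str] = []
        cursor = 0  # 0-based
        for v in variants:
            if v.chrom != chrom:
                continue
            if v.kind == "snp":
                parts.append(seq[cursor : v.pos - 1])
                parts.append(v.alt)
                cursor = v.pos
            elif v.kind == "ins":
                parts.append(seq[cursor : v.pos])
                parts.append(v.alt[1:])
                cursor = v.pos
            else:  # del
                parts.append(seq[cursor : v.pos])
                cursor = v.pos + len(v.ref) - 1
        parts.append(seq[cursor:])
        haplotype[chrom] = "".join(parts)
    return haplotype, variants


def truth_calls(variants: Sequence[SpikedVariant], genome: GenomeIndex) -> list[VariantCall]:
    """Spiked variants as VariantCall records (hom genotype), sorted."""
    ranks = {name: i for i, name in enumerate(genome.names)}
    calls = [
        VariantCall(v.chrom, v.pos, v.ref, v.alt, 100.0, "hom", 0, -1) for v in variants
    ]
    calls.sort(key=lambda c: (ranks[c.chrom], c.pos, c.ref, c.alt))
    return calls


# ---------------------------------------------------------------------------
# Haplotype <-> reference projection


class _ChromMap:
    """Block alignment between one haplotype chromosome and the reference."""

    def __init__(self, ref_len: int, variants: Sequence[SpikedVariant]):
        # blocks: ("M", ref_start, hap_start, len) | ("I", anchor, hap_start, len)
        #       | ("D", ref_start, hap_junction, len)   -- all 1-based starts
        self.blocks: list[tuple[str, int, int, int]] = []
        pr, ph = 1, 1
        for v in variants:
            if v.kind == "snp":
                continue
            span = v.pos - pr + 1  # match up to and including the anchor
            if span > 0:
                self.blocks.append(("M", pr, ph, span))
                pr += span
                ph += span
            if v.kind == "ins":
                k = len(v.alt) - 1
                self.blocks.append(("I", v.pos, ph, k))
                ph += k
            else:  # del
                k = len(v.ref) - 1
                self.blocks.append(("D", pr, ph, k))
                pr += k
        if pr <= ref_len:
            self.blocks.append(("M", pr, ph, ref_len - pr + 1))
            ph += ref_len - pr + 1
        self.hap_len = ph - 1

    def project(self, hstart: int, hlen: int) -> tuple[int, list[tuple[str, int]]] | None:
        """Reference POS and CIGAR ops for haplotype interval [hstart, hstart+hlen-1].

        Leading/trailing insertions become soft clips; returns None when
        the interval contains no aligned base.
        """
        hend = hstart + hlen - 1
        ops: list[tuple[str, int]] = []
        pos: int | None = None
        for kind, rs, hs, length in self.blocks:
            if kind == "D":
                # junction between hap positions hs-1 and hs
                if hstart < hs <= hend + 1 and ops and pos is not None:
                    ops.append(("D", length))
                continue
            he = hs + length - 1
            a, b = max(hstart, hs), min(hend, he)
            if a > b:
                continue
            if kind == "M":
                if pos is None:
                    pos = rs + (a - hs)
                ops.append(("M", b - a + 1))
            else:  # I
                ops.append(("I", b - a + 1))
        if pos is None:
            return None
        # trim dangling D, turn terminal I into S, merge runs
        while ops and ops[0][0] == "D":
            ops.pop(0)
        while ops and ops[-1][0] == "D":
            ops.pop()
        if ops and ops[0][0] == "I":
            ops[0] = ("S", ops[0][1])
        if ops and ops[-1][0] == "I":
            ops[-1] = ("S", ops[-1][1])
        merged: list[tuple[str, int]] = []
        for op, length in ops:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + length)
            else:
                merged.append((op, length))
        return pos, merged

    def to_hap(self, ref_pos: int) -> int:
        """Haplotype position of an aligned reference position (nearest match)."""
        best = 1
        for kind, rs, hs, length in self.blocks:
            if kind == "M":
                if rs <= ref_pos <= rs + length - 1:
                    return hs + (ref_pos - rs)
                if ref_pos >= rs + length:
                    best = hs + length - 1
        return best


def _ops_to_cigar(ops: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{l}{op}" for op, l in ops)


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class _MateTemplate:
    chrom: str
    hstart: int  # 1-based haplotype start of the fragment slice
    reverse: bool


@dataclass
class _PairTemplate:
    mates: tuple[_MateTemplate, _MateTemplate]
    proper: bool


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    genome: GenomeIndex
    reference: dict[str, str]
    haplotype: dict[str, str]
    variants: list[SpikedVariant]
    records: list[AlignedRead]
    header: list[str]

    @property
    def truth(self) -> list[VariantCall]:
        return truth_calls(self.variants, self.genome)


def simulate_reads(
    haplotype: Mapping[str, str],
    variants: Sequence[SpikedVariant],
    spec: SimulationSpec,
    rng: np.random.Generator,
    plan: PartitionPlan | None = None,
    genome: GenomeIndex | None = None,
) -> list[AlignedRead]:
    """Emit aligned pairs at the target coverage with controlled structure."""
    chroms = list(haplotype)
    maps = {
        c: _ChromMap(
            len(haplotype[c])
            - sum(len(v.alt) - len(v.ref) for v in variants if v.chrom == c),
            [v for v in variants if v.chrom == c],
        )
        for c in chroms
    }
    hap_lens = {c: maps[c].hap_len for c in chroms}
    for c in chroms:
        if hap_lens[c] != len(haplotype[c]):
            raise SimulationError(f"haplotype/variant bookkeeping mismatch on {c}")
    lengths = np.array([hap_lens[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    rl = spec.read_length
    total = int(sum(hap_lens.values()))
    n_pairs = max(1, round(spec.coverage * total / (2 * rl)))

    # variant positions per chromosome, for the vo truth tag
    var_pos = {c: sorted(v.pos for v in variants if v.chrom == c) for c in chroms}

    def draw_insert() -> int:
        return max(rl, int(round(rng.normal(spec.insert_mean, spec.insert_sd))))

    def draw_chrom() -> str:
        return chroms[int(rng.choice(len(chroms), p=weights))]

    internal_boundaries: list[tuple[str, int]] = []
    if plan is not None:
        for sr in plan.subregions:
            if sr.end < plan.genome.length_of(sr.chrom):
                internal_boundaries.append((sr.chrom, sr.end))

    templates: list[_PairTemplate] = []
    for _ in range(n_pairs):
        u = rng.random()
        if plan is not None and internal_boundaries and u < spec.boundary_rate:
            chrom, b = internal_boundaries[int(rng.integers(0, len(internal_boundaries)))]
            # straddle: mate1 wholly left of the boundary, mate2 wholly right
            hb = maps[chrom].to_hap(b)
            jitter1 = int(rng.integers(0, 40))
            jitter2 = int(rng.integers(0, 40))
            h1 = max(1, hb - rl - jitter1)
            h2 = min(hap_lens[chrom] - rl + 1, hb + 1 + jitter2)
            templates.append(
                _PairTemplate(
                    (
                        _MateTemplate(chrom, h1, False),
                        _MateTemplate(chrom, h2, True),
                    ),
                    proper=True,
                )
            )
            continue
        if u < spec.boundary_rate + spec.interchrom_rate and len(chroms) > 1:
            c1 = draw_chrom()
            c2 = c1
            while c2 == c1:
                c2 = draw_chrom()
            h1 = int(rng.integers(1, hap_lens[c1] - rl + 2))
            h2 = int(rng.integers(1, hap_lens[c2] - rl + 2))
            templates.append(
                _PairTemplate(
                    (_MateTemplate(c1, h1, False), _MateTemplate(c2, h2, True)),
                    proper=False,
                )
            )
            continue
        chrom = draw_chrom()
        flen = min(draw_insert(), hap_lens[chrom])
        s = int(rng.integers(1, hap_lens[chrom] - flen + 2))
        templates.append(
            _PairTemplate(
                (
                    _MateTemplate(chrom, s, False),
                    _MateTemplate(chrom, s + flen - rl, True),
                ),
                proper=True,
            )
        )

    n_dups = int(rng.binomial(len(templates), spec.duplication_rate))
    # keep n_pairs total emissions: last n_dups templates are replaced by copies
    originals = templates[: len(templates) - n_dups] or templates[:1]

    records: list[AlignedRead] = []

    def materialize(template: _PairTemplate, qname: str, dup_of: str | None) -> None:
        reads: list[AlignedRead] = []
        mate_info: list[tuple[str, int, str]] = []
        for mate_idx, mate in enumerate(template.mates):
            projected = maps[mate.chrom].project(mate.hstart, rl)
            if projected is None:
                raise SimulationError("read fell entirely inside an insertion")
            pos, ops = projected
            seq = list(haplotype[mate.chrom][mate.hstart - 1 : mate.hstart + rl - 1])
            # soft clips at read ends (M ops only), preserving external coordinates
            if rng.random() < spec.softclip_rate:
                clip = int(rng.integers(1, 6))
                if rng.random() < 0.5:
                    if ops[0][0] == "M" and ops[0][1] > clip:
                        ops = [("S", clip), ("M", ops[0][1] - clip)] + list(ops[1:])
                        pos += clip
                else:
                    if ops[-1][0] == "M" and ops[-1][1] > clip:
                        ops = list(ops[:-1]) + [("M", ops[-1][1] - clip), ("S", clip)]
            # sequencing errors: substitutions only
            if spec.error_rate > 0:
                errs = np.nonzero(rng.random(rl) < spec.error_rate)[0]
                for i in errs.tolist():
                    cur = seq[i]
                    choices = [b for b in "ACGT" if b != cur]
                    seq[i] = choices[int(rng.integers(0, 3))]
            flag = FLAG_PAIRED | (FLAG_FIRST if mate_idx == 0 else FLAG_SECOND)
            if template.proper:
                flag |= FLAG_PROPER_PAIR
            if mate.reverse:
                flag |= FLAG_REVERSE
            if template.mates[1 - mate_idx].reverse:
                flag |= FLAG_MATE_REVERSE
            mapq = int(rng.integers(spec.mapq_range[0], spec.mapq_range[1] + 1))
            ref_span = sum(l for op, l in ops if op in "MDN=X")
            nvar = 0
            vp = var_pos[mate.chrom]
            if vp:
                nvar = bisect.bisect_right(vp, pos + ref_span - 1) - bisect.bisect_left(vp, pos)
            tags = [f"ot:Z:{mate.chrom}:{pos}"]
            if dup_of is not None:
                tags.append(f"od:Z:{dup_of}")
            tags.append(f"vo:i:{nvar}")
            reads.append(
                AlignedRead(
                    qname=qname,
                    flag=flag,
                    rname=mate.chrom,
                    pos=pos,
                    mapq=mapq,
                    cigar=_ops_to_cigar(ops),
                    rnext="*",
                    pnext=0,
                    tlen=0,
                    seq="".join(seq),
                    qual=chr(spec.base_quality + 33) * rl,
                    tags=tuple(tags),
                )
            )
            mate_info.append((mate.chrom, pos, "-" if mate.reverse else "+"))
        # cross-link mates
        for i, read in enumerate(reads):
            other_chrom, other_pos, _ = mate_info[1 - i]
            read.rnext = "=" if other_chrom == read.rname else other_chrom
            read.pnext = other_pos
            if template.proper and read.rname == other_chrom:
                span = abs(other_pos - read.pos) + rl
                read.tlen = span if read.pos <= other_pos else -span
        records.extend(reads)

    for i, template in enumerate(originals):
        materialize(template, f"p{i:06d}", None)
    for j in range(n_dups):
        k = int(rng.integers(0, len(originals)))
        materialize(originals[k], f"d{j:06d}", f"p{k:06d}")
    return records


def simulate_dataset(
    spec: SimulationSpec, plan: PartitionPlan | None = None
) -> SimulatedDataset:
    """End-to-end: reference, spiked haplotype, truth, and aligned reads."""
    reference, genome = generate_reference(spec)
    rng = np.random.default_rng(spec.seed + 1)
    haplotype, variants = spike_variants(reference, spec, rng, plan)
    records = simulate_reads(haplotype, variants, spec, rng, plan, genome)
    return SimulatedDataset(
        spec=spec,
        genome=genome,
        reference=reference,
        haplotype=haplotype,
        variants=variants,
        records=records,
        header=make_header(genome),
    )
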