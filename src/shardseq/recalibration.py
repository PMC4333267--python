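"""Base-quality recalibration with mergeable covariate tables.

A covariate table counts, for every (reported quality, machine cycle,
dinucleotide context) bin, how many bases were observed and how many
mismatched the reference over aligned (M/=/X) positions.  Tables merge
by bin-wise addition — the merge of per-subregion tables is exactly the
table built over the whole input — so each parallel recalibration
worker can apply a single sample-wide table, reproducing the serial
whole-genome result bit for bit.

The per-bin transform is a Laplace-smoothed empirical Phred:
``Q = round(-10 * log10((mismatches + 1) / (observations + 2)))``,
clamped to [2, 60].  Bins absent from the table leave the reported
quality unchanged.

Cycle is the 1-based position within the read, negated for
second-of-pair records.  Context is the preceding+current nucleotide;
the first base of a read (and any context containing a non-ACGT base)
falls in the sentinel bin ``--``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .alignment import AlignedRead, parse_cigar

MAX_Q = 60
MIN_RECAL_Q = 2
SENTINEL_CONTEXT = "--"

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_CTX_STRINGS = [a + b for a in "ACGT" for b in "ACGT"] + [SENTINEL_CONTEXT]
_CTX_INDEX = {s: i for i, s in enumerate(_CTX_STRINGS)}
N_CTX = 17
SENTINEL_CODE = 16


class RecalibrationError(ValueError):
    pass


def empirical_quality(observations: int, mismatches: int) -> int:
    """Smoothed empirical Phred score of a bin, clamped to [2, 60]."""
    if observations < 0 or mismatches < 0 or mismatches > observations:
        raise RecalibrationError(
            f"invalid bin counts: observations={observations} mismatches={mismatches}"
        )
    rate = (mismatches + 1) / (observations + 2)
    q = int(round(-10.0 * math.log10(rate)))
    return max(MIN_RECAL_Q, min(MAX_Q, q))


@dataclass
class CovariateTable:
    """Map (reported_q, cycle, context) -> (observations, mismatches)."""

    bins: dict[tuple[int, int, str], tuple[int, int]] = field(default_factory=dict)

    def add(self, reported_q: int, cycle: int, context: str, obs: int, mis: int) -> None:
        if mis > obs:
            raise RecalibrationError("mismatches exceed observations")
        key = (reported_q, cycle, context)
        o, m = self.bins.get(key, (0, 0))
        self.bins[key] = (o + obs, m + mis)

    def update(self, other: "CovariateTable") -> None:
        for key, (obs, mis) in other.bins.items():
            o, m = self.bins.get(key, (0, 0))
            self.bins[key] = (o + obs, m + mis)

    def total_observations(self) -> int:
        return sum(o for o, _ in self.bins.values())

    def total_mismatches(self) -> int:
        return sum(m for _, m in self.bins.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CovariateTable):
            return NotImplemented
        return self.bins == other.bins

    # -- serialization (sorted TSV, byte-comparable) -----------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reported_q\tcycle\tcontext\tobservations\tmismatches\n")
            for (q, cycle, ctx), (obs, mis) in sorted(self.bins.items()):
                fh.write(f"{q}\t{cycle}\t{ctx}\t{obs}\t{mis}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CovariateTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                q, cycle, ctx, obs, mis = line.rstrip("\n").split("\t")
                table.add(int(q), int(cycle), ctx, int(obs), int(mis))
        return table


def merge_covariate_tables(tables: Iterable[CovariateTable]) -> CovariateTable:
    """Bin-wise sum; associative and commutative; empty merge is identity."""
    merged = CovariateTable()
    for table in tables:
        merged.update(table)
    return merged


# ---------------------------------------------------------------------------
# Vectorized per-read covariate extraction


def _read_codes(read: AlignedRead) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(base codes, reported q, cycle, context code) per query position."""
    seq = np.frombuffer(read.seq.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[seq]
    qs = np.frombuffer(read.qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
    np.clip(qs, 0, MAX_Q, out=qs)
    n = len(codes)
    cycles = np.arange(1, n + 1, dtype=np.int64)
    if read.is_second:
        cycles = -cycles
    ctx = np.full(n, SENTINEL_CODE, dtype=np.int64)
    if n > 1:
        prev = codes[:-1]
        cur = codes[1:]
        ok = (prev < 4) & (cur < 4)
        ctx[1:][ok] = prev[ok] * 4 + cur[ok]
    return codes, qs, cycles, ctx


def _aligned_positions(read: AlignedRead) -> tuple[np.ndarray, np.ndarray]:
    """Query indices (0-based) and reference positions (0-based) of M/=/X bases."""
    qpos_parts: list[np.ndarray] = []
    rpos_parts: list[np.ndarray] = []
    q = 0
    r = read.pos - 1
    for op, length in parse_cigar(read.cigar):
        if op in "M=X":
            qpos_parts.append(np.arange(q, q + length, dtype=np.int64))
            rpos_parts.append(np.arange(r, r + length, dtype=np.int64))
            q += length
            r += length
        elif op in "IS":
            q += length
        elif op in "DN":
            r += length
        # H, P consume nothing
    if not qpos_parts:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    return np.concatenate(qpos_parts), np.concatenate(rpos_parts)


class _RefCache:
    def __init__(self, reference: Mapping[str, str]):
        self.reference = reference
        self._encoded: dict[str, np.ndarray] = {}

    def codes(self, chrom: str) -> np.ndarray:
        arr = self._encoded.get(chrom)
        if arr is None:
            if chrom not in self.reference:
                raise RecalibrationError(f"no reference sequence for {chrom!r}")
            raw = np.frombuffer(self.reference[chrom].encode("ascii"), dtype=np.uint8)
            arr = _BASE_CODE[raw]
            self._encoded[chrom] = arr
        return arr


def build_covariate_table(
    records: Iterable[AlignedRead], reference: Mapping[str, str]
) -> CovariateTable:
    """Count observations and mismatches over aligned bases.

    Walks M/=/X positions only; insertions, clips, and positions where
    either the read base or the reference base is not A/C/G/T are
    skipped.  Records must be deduplicated primaries; unmapped,
    secondary/supplementary, and duplicate-flagged records are ignored.
    """
    refs = _RefCache(reference)
    # dense accumulators, grown on demand along the cycle axis
    max_cycle = 160
    obs = np.zeros((MAX_Q + 1, 2 * max_cycle + 1, N_CTX), dtype=np.int64)
    mis = np.zeros_like(obs)
    for read in records:
        if read.is_unmapped or not read.is_primary or read.is_duplicate:
            continue
        if read.seq == "*" or read.qual == "*":
            continue
        n = len(read.seq)
        if n > max_cycle:
            grow = max(n, 2 * max_cycle)
            new_obs = np.zeros((MAX_Q + 1, 2 * grow + 1, N_CTX), dtype=np.int64)
            new_mis = np.zeros_like(new_obs)
            new_obs[:, grow - max_cycle : grow + max_cycle + 1, :] = obs
            new_mis[:, grow - max_cycle : grow + max_cycle + 1, :] = mis
            obs, mis, max_cycle = new_obs, new_mis, grow
        codes, qs, cycles, ctx = _read_codes(read)
        qpos, rpos = _aligned_positions(read)
        if len(qpos) == 0:
            continue
        ref_codes = refs.codes(read.rname)
        if rpos[-1] >= len(ref_codes):
            raise RecalibrationError(
                f"{read.qname}: alignment extends past end of reference {read.rname}"
            )
        rb = ref_codes[rpos]
        sb = codes[qpos]
        valid = (rb < 4) & (sb < 4)
        if not valid.any():
            continue
        qv = qs[qpos][valid]
        cv = cycles[qpos][valid] + max_cycle
        xv = ctx[qpos][valid]
        np.add.at(obs, (qv, cv, xv), 1)
        neq = sb[valid] != rb[valid]
        if neq.any():
            np.add.at(mis, (qv[neq], cv[neq], xv[neq]), 1)
    table = CovariateTable()
    qi, ci, xi = np.nonzero(obs)
    for q, c, x in zip(qi.tolist(), ci.tolist(), xi.tolist()):
        table.bins[(q, c - max_cycle, _CTX_STRINGS[x])] = (
            int(obs[q, c, x]),
            int(mis[q, c, x]),
        )
    return table


def apply_recalibration(
    records: Iterable[AlignedRead], table: CovariateTable
) -> list[AlignedRead]:
    """Replace each base's quality by its bin's empirical quality.

    Bins absent from the table fall back to the reported quality.  The
    output depends only on the records and the table, never on how the
    input was sharded.
    """
    max_cycle = 1
    for (_, cycle, _), _ in table.bins.items():
        max_cycle = max(max_cycle, abs(cycle))
    lut = np.full((MAX_Q + 1, 2 * max_cycle + 1, N_CTX), -1, dtype=np.int64)
    for (q, cycle, ctx), (o, m) in table.bins.items():
        lut[q, cycle + max_cycle, _CTX_INDEX[ctx]] = empirical_quality(o, m)
    out: list[AlignedRead] = []
    for read in records:
        if read.seq == "*" or read.qual == "*":
            out.append(read)
            continue
        codes, qs, cycles, ctx = _read_codes(read)
        in_range = np.abs(cycles) <= max_cycle  # cycles past the table keep reported q
        new_q = np.full(len(qs), -1, dtype=np.int64)
        new_q[in_range] = lut[qs[in_range], cycles[in_range] + max_cycle, ctx[in_range]]
        new_q = np.where(new_q < 0, qs, new_q)
        qual = (new_q + 33).astype(np.uint8).tobytes().decode("ascii")
        out.append(replace(read, qual=qual))
    return out
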