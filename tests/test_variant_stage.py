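import numpy as np
import pytest

from shardseq.genome_partition import GenomeIndex, partition_genome
from shardseq.variants import (
    VariantCall,
    VariantError,
    assign_subregion,
    concat_vcf,
    pileup_call,
    read_vcf,
    reconcile_boundary_variants,
    write_vcf,
)

from conftest import make_read


def _reads_at(pos, n, seq, cigar=None, chrom="chr1"):
    cigar = cigar or f"{len(seq)}M"
    return [
        make_read(f"r{pos}_{i}", 0x1 | 0x40, chrom, pos, 60, cigar, seq=seq,
                  qual="I" * len(seq))
        for i in range(n)
    ]


@pytest.fixture
def ref():
    rng = np.random.default_rng(77)
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 400))}


@pytest.fixture
def window(ref):
    genome = GenomeIndex((("chr1", len(ref["chr1"])),))
    return partition_genome(genome, 1, overlap=0).subregions[0]


class TestPileupCall:
    def test_het_threshold(self, ref, window):
        base = ref["chr1"][199]
        alt = "A" if base != "A" else "C"
        seq_ref = ref["chr1"][190:210]
        seq_alt = seq_ref[:9] + alt + seq_ref[10:]
        reads = _reads_at(191, 15, seq_ref) + _reads_at(191, 15, seq_alt)
        calls = pileup_call(window, reads, ref, min_depth=8, min_alt_frac=0.2, hom_frac=0.8)
        assert len(calls) == 1
        call = calls[0]
        assert (call.pos, call.ref, call.alt, call.genotype) == (200, base, alt, "het")
        assert call.depth == 30

    def test_hom_when_fraction_high(self, ref, window):
        base = ref["chr1"][199]
        alt = "A" if base != "A" else "C"
        seq_alt = ref["chr1"][190:210][:9] + alt + ref["chr1"][190:210][10:]
        calls = pileup_call(window, _reads_at(191, 20, seq_alt), ref)
        assert calls[0].genotype == "hom"

    def test_no_alt_no_calls(self, ref, window):
        reads = _reads_at(1, 30, ref["chr1"][:50])
        assert pileup_call(window, reads, ref) == []

    def test_below_depth_suppressed(self, ref, window):
        base = ref["chr1"][199]
        alt = "A" if base != "A" else "C"
        seq_alt = ref["chr1"][190:210][:9] + alt + ref["chr1"][190:210][10:]
        calls = pileup_call(window, _reads_at(191, 5, seq_alt), ref, min_depth=8)
        assert calls == []

    def test_insertion_called(self, ref, window):
        # 20bp read with a 2bp insertion after read base 10 (ref pos 200)
        left = ref["chr1"][190:200]
        right = ref["chr1"][200:210]
        seq = left + "TT" + right
        reads = _reads_at(191, 20, seq, cigar="10M2I10M")
        calls = pileup_call(window, reads, ref)
        ins = [c for c in calls if len(c.alt) > len(c.ref)]
        assert len(ins) == 1
        assert ins[0].pos == 200
        assert ins[0].ref == ref["chr1"][199]
        assert ins[0].alt == ref["chr1"][199] + "TT"

    def test_deletion_called(self, ref, window):
        seq = ref["chr1"][190:200] + ref["chr1"][203:213]
        reads = _reads_at(191, 20, seq, cigar="10M3D10M")
        calls = pileup_call(window, reads, ref)
        dels = [c for c in calls if len(c.ref) > len(c.alt)]
        assert len(dels) == 1
        assert dels[0].pos == 200
        assert dels[0].ref == ref["chr1"][199:203]
        assert dels[0].alt == ref["chr1"][199]

    def test_duplicate_flagged_reads_ignored(self, ref, window):
        base = ref["chr1"][199]
        alt = "A" if base != "A" else "C"
        seq_alt = ref["chr1"][190:210][:9] + alt + ref["chr1"][190:210][10:]
        reads = _reads_at(191, 20, seq_alt)
        for r in reads:
            r.flag |= 0x400
        assert pileup_call(window, reads, ref) == []

    def test_window_outside_reference(self, ref):
        genome = GenomeIndex((("chr1", 1000),))
        window = partition_genome(genome, 1).subregions[0]
        with pytest.raises(VariantError):
            pileup_call(window, [], ref)

    def test_deterministic(self, ref, window):
        base = ref["chr1"][199]
        alt = "A" if base != "A" else "C"
        seq_alt = ref["chr1"][190:210][:9] + alt + ref["chr1"][190:210][10:]
        reads = _reads_at(191, 12, seq_alt) + _reads_at(191, 12, ref["chr1"][190:210])
        c1 = pileup_call(window, reads, ref)
        c2 = pileup_call(window, list(reversed(reads)), ref)
        assert c1 == c2


class TestAssignSubregion:
    def test_boundary_inclusive(self, toy_genome):
        plan = partition_genome(toy_genome, 3, overlap=10)
        left = VariantCall("chr1", 50, "A", "C", 10.0, "het", 10, 0)
        right = VariantCall("chr1", 51, "A", "C", 10.0, "het", 10, 0)
        assert assign_subregion(left, plan) == 0
        assert assign_subregion(right, plan) == 1

    def test_mid_region(self, toy_genome):
        plan = partition_genome(toy_genome, 3, overlap=10)
        call = VariantCall("chr2", 25, "A", "C", 10.0, "het", 10, 2)
        assert assign_subregion(call, plan) == 2

    def test_indel_anchor_at_region_start(self, toy_genome):
        plan = partition_genome(toy_genome, 3, overlap=10)
        call = VariantCall("chr1", 51, "AT", "A", 10.0, "het", 10, 1)
        assert assign_subregion(call, plan) == 1

    def test_all_toy_boundaries_exhaustive(self):
        genome = GenomeIndex((("chr1", 60),))
        plan = partition_genome(genome, 6, overlap=5)  # boundaries every 10
        for pos in range(1, 61):
            expected = (pos - 1) // 10
            call = VariantCall("chr1", pos, "A", "C", 10.0, "het", 10, 0)
            assert assign_subregion(call, plan) == expected


class TestReconcile:
    def test_buffer_duplicate_removed(self, toy_genome):
        plan = partition_genome(toy_genome, 3, overlap=10)
        owner = VariantCall("chr1", 48, "A", "C", 11.0, "het", 12, 0)
        shadow = VariantCall("chr1", 48, "A", "C", 9.0, "het", 10, 1)
        final = reconcile_boundary_variants({0: [owner], 1: [shadow]}, plan)
        assert final == [owner]  # owner's copy kept verbatim

    def test_non_buffer_call_unchanged(self, toy_genome):
        plan = partition_genome(toy_genome, 3, overlap=10)
        call = VariantCall("chr2", 25, "G", "T", 10.0, "hom", 20, 2)
        assert reconcile_boundary_variants({2: [call]}, plan) == [call]

    def test_distinct_alleles_both_kept(self, toy_genome):
        plan = partition_genome(toy_genome, 3, overlap=10)
        a = VariantCall("chr1", 48, "A", "C", 10.0, "het", 10, 0)
        b = VariantCall("chr1", 48, "A", "G", 10.0, "het", 10, 0)
        final = reconcile_boundary_variants({0: [a, b]}, plan)
        assert final == [a, b]

    def test_no_duplicate_sites_property(self, toy_genome):
        plan = partition_genome(toy_genome, 3, overlap=10)
        rng = np.random.default_rng(12)
        per_region: dict[int, list[VariantCall]] = {0: [], 1: [], 2: []}
        seen_sites: set[tuple[str, int]] = set()
        for _ in range(200):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            limit = 100 if chrom == "chr1" else 50
            pos = int(rng.integers(1, limit + 1))
            if (chrom, pos) in seen_sites:
                continue
            seen_sites.add((chrom, pos))
            call_args = (chrom, pos, "A", "C", 10.0, "het", 10)
            owner = plan.locate(chrom, pos).index
            per_region[owner].append(VariantCall(*call_args, owner))
            # adjacent region also sees it when inside the buffer
            for other in (owner - 1, owner + 1):
                if 0 <= other < 3:
                    sr = plan.subregions[other]
                    if sr.chrom == chrom and sr.buffered_start <= pos <= sr.buffered_end:
                        per_region[other].append(VariantCall(*call_args, other))
        final = reconcile_boundary_variants(per_region, plan)
        sites = [c.site for c in final]
        assert len(sites) == len(set(sites))


class TestVcfIO:
    def _calls(self):
        return [
            VariantCall("chr1", 10, "A", "C", 31.25, "het", 20, 0),
            VariantCall("chr1", 60, "G", "GTT", 99.0, "hom", 25, 1),
            VariantCall("chr2", 5, "TA", "T", 12.5, "het", 9, 2),
        ]

    def test_empty_callset_header_only(self, toy_genome, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf([], toy_genome, path)
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        assert any(l.startswith("##contig=<ID=chr1") for l in lines)

    def test_round_trip(self, toy_genome, tmp_path):
        path = tmp_path / "calls.vcf"
        write_vcf(self._calls(), toy_genome, path)
        back = read_vcf(path)
        assert [(c.chrom, c.pos, c.ref, c.alt, c.qual, c.genotype, c.depth) for c in back] == [
            (c.chrom, c.pos, c.ref, c.alt, c.qual, c.genotype, c.depth) for c in self._calls()
        ]

    def test_unsorted_rejected(self, toy_genome, tmp_path):
        calls = list(reversed(self._calls()))
        with pytest.raises(VariantError):
            write_vcf(calls, toy_genome, tmp_path / "bad.vcf")

    def test_concat_equals_merged_write(self, toy_genome, tmp_path):
        calls = self._calls()
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(calls[:2], toy_genome, p1)
        write_vcf(calls[2:], toy_genome, p2)
        cat = tmp_path / "cat.vcf"
        concat_vcf([p2, p1], toy_genome, cat)
        direct = tmp_path / "direct.vcf"
        write_vcf(calls, toy_genome, direct)
        assert cat.read_bytes() == direct.read_bytes()
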