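# shardseq

Deterministic, fixed-boundary sharded pipeline for NGS secondary analysis
(aligned SAM in, genome-wide VCF out), built so that the degree of
parallelization never changes the result.

The pipeline:

1. **Partition** — divides the genome into ~M equal subregions with fixed
   boundaries that tile each chromosome exactly, plus a configurable overlap
   buffer (default 3 kb) on each side used only at variant-calling time.
2. **Route/split** — every primary read pair whose two unclipped 5′
   coordinates fall inside one subregion's fixed boundaries goes to that
   subregion; pairs whose mates land in different subregions (both
   interchromosomal and boundary-spanning intrachromosomal pairs) are
   diverted to a reserved `chrI` destination.
3. **Deduplicate** — the `chrI` file is deduplicated first as a unit, its
   surviving reads are redistributed to subregions by their own coordinates,
   and each subregion is then deduplicated independently. Because routing is
   a function of the duplicate key (chromosome, unclipped 5′ position,
   strand of both mates), every duplicate class lands intact in exactly one
   destination — the parallel result equals genome-wide serial
   deduplication, record for record. Survivor selection keeps the pair with
   the highest mapping quality (sum of mate MAPQs, ties to smallest qname);
   a `baseq_sum` rule is available for Picard-style parity.
4. **Recalibrate** — per-subregion covariate tables (reported quality,
   machine cycle, dinucleotide context → observations/mismatches) are merged
   by bin-wise addition into one sample-wide table, then applied in parallel.
   The per-bin transform is a smoothed empirical Phred
   `Q = round(-10·log10((mismatches+1)/(observations+2)))`, clamped to [2, 60].
5. **Call & reconcile** — a simple deterministic pileup caller runs over each
   subregion's buffered window; a variant called by two adjacent windows is
   kept only by the subregion whose fixed boundaries contain its POS, so no
   site appears twice in the concatenated genome-wide VCF.

All intermediate and final files are plain text (SAM/VCF/TSV) and written
through canonical sorts, so the final VCF, recalibrated SAMs, and covariate
tables are byte-identical regardless of subregion count or worker count.

## CLI

```sh
# partition a genome index (two-column name/length text, .fai-style)
shardseq partition --reference-index ref.fasta.fai --subregions 1000 --overlap 3000 --out intervals.list

# simulate a synthetic dataset (reference FASTA, aligned SAM, truth VCF)
shardseq simulate --seed 1 --chroms 100000,50000 --coverage 30 \
    --dup-rate 0.15 --interchrom-rate 0.05 --snps 50 --indels 10 --out simdir

# run the pipeline from a YAML config (flags override)
shardseq run --config cfg.yaml --workers 4 [--subregions M] [--mark-only] [--resume]

# write per-task shell scripts instead of executing (cluster hand-off)
shardseq run --config cfg.yaml --emit-scripts scripts_dir/
```

A config file looks like:

```yaml
reference: simdir/reference.fasta
inputs: [simdir/reads.sam]
workdir: work
output: work/final.vcf
subregions: 8        # default: 2 x workers
overlap: 3000
workers: 4
survivor: mapq       # or baseq_sum
min_depth: 8
min_alt_frac: 0.2
hom_frac: 0.8
```

Exit codes: 0 success, 2 invalid configuration, 3 task failure.

## Layout

```
src/shardseq/
  genome_partition.py   fixed-boundary subregions + GATK-style intervals I/O
  alignment.py          SAM model, unclipped-5' math, duplicate keys
  router.py             subregion/chrI routing, split/merge, redistribution
  dedup.py              serial and sharded duplicate removal
  recalibration.py      covariate tables, merge, empirical-Phred application
  variants.py           pileup caller, boundary reconciliation, VCF I/O
  pipeline.py           task graph, bounded-concurrency executor, resume
  simulate.py           seeded synthetic references/reads/truth variants
  cli.py                click entry points
```
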