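"""Pipeline driver: task planning, bounded-concurrency execution, determinism.

Stage order: split -> merge (per destination) -> chrI dedup ->
redistribute -> per-subregion dedup -> covariate build -> covariate
merge -> recalibrate -> call -> reconcile/concat.  Only three points
serialize the per-subregion fan-out: the chrI merge, the covariate
merge, and the final VCF concatenation.

Every stage writes canonically sorted text, so all outputs are
byte-identical regardless of worker count and task completion order.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import yaml

from . import dedup as dedup_mod
from .alignment import AlignedRead, make_header, read_sam, sort_records, write_sam
from .genome_partition import GenomeIndex, partition_genome
from .recalibration import (
    CovariateTable,
    apply_recalibration,
    build_covariate_table,
    merge_covariate_tables,
)
from .router import CHR_I, SplitLayout, dest_name, redistribute_chrI, route_records
from .variants import (
    VariantCall,
    pileup_call,
    read_vcf,
    reconcile_boundary_variants,
    write_vcf,
)


class ConfigError(ValueError):
    """Invalid pipeline configuration; message enumerates all problems."""


class TaskFailure(RuntimeError):
    def __init__(self, task: str, cause: BaseException):
        super().__init__(f"task {task!r} failed: {cause}")
        self.task = task
        self.cause = cause


@dataclass
class PipelineConfig:
    reference: Path
    inputs: tuple[Path, ...]
    workdir: Path
    output: Path
    subregions: int | None = None
    overlap: int = 3000
    workers: int = 1
    survivor: str = "mapq"
    mark_only: bool = False
    skip_recalibration: bool = False
    min_depth: int = 8
    min_alt_frac: float = 0.2
    hom_frac: float = 0.8
    resume: bool = False

    @property
    def effective_subregions(self) -> int:
        # default heuristic: twice the worker count
        return self.subregions if self.subregions is not None else 2 * self.workers

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = Path(path).parent
        def _p(v):  # paths in the file are relative to the file
            p = Path(v)
            return p if p.is_absolute() else base / p
        try:
            return cls(
                reference=_p(raw["reference"]),
                inputs=tuple(_p(v) for v in raw["inputs"]),
                workdir=_p(raw["workdir"]),
                output=_p(raw["output"]),
                subregions=raw.get("subregions"),
                overlap=int(raw.get("overlap", 3000)),
                workers=int(raw.get("workers", 1)),
                survivor=raw.get("survivor", "mapq"),
                mark_only=bool(raw.get("mark_only", False)),
                skip_recalibration=bool(raw.get("skip_recalibration", False)),
                min_depth=int(raw.get("min_depth", 8)),
                min_alt_frac=float(raw.get("min_alt_frac", 0.2)),
                hom_frac=float(raw.get("hom_frac", 0.8)),
                resume=bool(raw.get("resume", False)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc.args[0]}") from exc

    def validate(self) -> None:
        problems: list[str] = []
        if self.workers < 1:
            problems.append(f"workers must be >= 1, got {self.workers}")
        if self.subregions is not None and self.subregions < 1:
            problems.append(f"subregions must be >= 1, got {self.subregions}")
        if self.overlap < 0:
            problems.append(f"overlap must be >= 0, got {self.overlap}")
        if not Path(self.reference).exists():
            problems.append(f"reference not found: {self.reference}")
        if not self.inputs:
            problems.append("no input alignment files")
        for p in self.inputs:
            if not Path(p).exists():
                problems.append(f"input not found: {p}")
        if self.survivor not in ("mapq", "baseq_sum"):
            problems.append(f"unknown survivor rule {self.survivor!r}")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class Task:
    name: str
    deps: tuple[str, ...]
    fn: Callable[[], None]


@dataclass
class TaskGraph:
    tasks: dict[str, Task] = field(default_factory=dict)
    barriers: tuple[str, ...] = ()

    def add(self, name: str, deps: Sequence[str], fn: Callable[[], None]) -> None:
        if name in self.tasks:
            raise ConfigError(f"duplicate task {name!r}")
        for dep in deps:
            if dep not in self.tasks:
                raise ConfigError(f"task {name!r} depends on unknown {dep!r}")
        self.tasks[name] = Task(name, tuple(deps), fn)

    def topological_order(self) -> list[str]:
        order: list[str] = []
        done: set[str] = set()
        # insertion order is deterministic; repeated passes preserve it
        pending = list(self.tasks)
        while pending:
            progressed = False
            rest = []
            for name in pending:
                if all(d in done for d in self.tasks[name].deps):
                    order.append(name)
                    done.add(name)
                    progressed = True
                else:
                    rest.append(name)
            if not progressed:
                raise ConfigError("dependency cycle in task graph")
            pending = rest
        return order

    def serialized(self) -> str:
        return json.dumps(
            {name: list(t.deps) for name, t in self.tasks.items()}, sort_keys=True
        )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader preserving sequence order."""
    sequences: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                sequences[name] = []
            elif name is not None:
                sequences[name].append(line)
    return {k: "".join(v).upper() for k, v in sequences.items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Binds a validated config to concrete stage implementations."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.workdir = Path(config.workdir)
        self.reference = read_fasta(config.reference)
        if not self.reference:
            raise ConfigError(f"no sequences in reference {config.reference}")
        self.genome = GenomeIndex(
            tuple((name, len(seq)) for name, seq in self.reference.items())
        )
        self.plan = partition_genome(
            self.genome, config.effective_subregions, config.overlap
        )
        self.header = make_header(self.genome)
        self.layout = SplitLayout(self.workdir)
        self.counts: dict[str, int] = {}
        self._log_path = self.workdir / "run.log.jsonl"

    # -- paths -------------------------------------------------------------
    def _merged(self, dest: str) -> Path:
        return self.workdir / "merged" / f"{dest}.sam"

    def _redistributed(self, dest: str) -> Path:
        return self.workdir / "redistributed" / f"{dest}.sam"

    def _dedup(self, dest: str) -> Path:
        return self.workdir / "dedup" / f"{dest}.sam"

    def _covar(self, dest: str) -> Path:
        return self.workdir / "covar" / f"{dest}.tsv"

    def _recal(self, dest: str) -> Path:
        return self.workdir / "recal" / f"{dest}.sam"

    def _vcf(self, dest: str) -> Path:
        return self.workdir / "vcf" / f"{dest}.vcf"

    # -- stage implementations --------------------------------------------
    def t_split(self, ordinal: int) -> None:
        _, records = read_sam(self.config.inputs[ordinal])
        self.counts[f"input:{ordinal}"] = len(records)
        routed = route_records(records, self.plan)
        (self.workdir / "split").mkdir(parents=True, exist_ok=True)
        for dest in sorted(routed):
            path = self.layout.fragment_path(ordinal, dest)
            write_sam(routed[dest], path, self.header)
            self.layout.fragments[(ordinal, dest)] = path

    def t_merge(self, dest: str) -> None:
        (self.workdir / "merged").mkdir(parents=True, exist_ok=True)
        records: list[AlignedRead] = []
        for ordinal in range(len(self.config.inputs)):
            frag = self.layout.fragment_path(ordinal, dest)
            if frag.exists():
                _, recs = read_sam(frag)
                records.extend(recs)
        out = self._merged(dest)
        write_sam(sort_records(records, self.genome), out, self.header)
        self.layout.merged[dest] = out
        self.counts[f"merged:{dest}"] = len(records)

    def t_dedup_chrI(self) -> None:
        (self.workdir / "dedup").mkdir(parents=True, exist_ok=True)
        _, records = read_sam(self._merged(CHR_I))
        kept, metrics = dedup_mod._dedup_records(
            records, self.config.survivor, self.config.mark_only
        )
        kept = sort_records(kept, self.genome)
        # retained copy of the deduplicated chrI file (structural-variant aid)
        write_sam(kept, self._dedup(CHR_I), self.header)
        self.counts["dedup_removed:chrI"] = metrics.duplicates_removed

    def t_redistribute(self) -> None:
        _, records = read_sam(self._dedup(CHR_I))
        routed = redistribute_chrI(records, self.plan)
        outdir = self.workdir / "redistributed"
        outdir.mkdir(parents=True, exist_ok=True)
        for dest in sorted(routed):
            write_sam(routed[dest], self._redistributed(dest), self.header)

    def t_dedup_subregion(self, index: int) -> None:
        dest = dest_name(index)
        (self.workdir / "dedup").mkdir(parents=True, exist_ok=True)
        _, records = read_sam(self._merged(dest))
        extra = self._redistributed(dest)
        if extra.exists():
            _, more = read_sam(extra)
            records.extend(more)
        kept, metrics = dedup_mod._dedup_records(
            records, self.config.survivor, self.config.mark_only
        )
        write_sam(sort_records(kept, self.genome), self._dedup(dest), self.header)
        self.counts[f"dedup_removed:{dest}"] = metrics.duplicates_removed

    def t_covariates(self, index: int) -> None:
        dest = dest_name(index)
        (self.workdir / "covar").mkdir(parents=True, exist_ok=True)
        _, records = read_sam(self._dedup(dest))
        table = build_covariate_table(records, self.reference)
        table.to_tsv(self._covar(dest))

    def t_covariate_merge(self) -> None:
        tables = [
            CovariateTable.from_tsv(self._covar(dest_name(sr.index)))
            for sr in self.plan.subregions
        ]
        merge_covariate_tables(tables).to_tsv(self._covar("merged"))

    def t_recalibrate(self, index: int) -> None:
        dest = dest_name(index)
        (self.workdir / "recal").mkdir(parents=True, exist_ok=True)
        if self.config.skip_recalibration:
            shutil.copyfile(self._dedup(dest), self._recal(dest))
            return
        _, records = read_sam(self._dedup(dest))
        table = CovariateTable.from_tsv(self._covar("merged"))
        write_sam(apply_recalibration(records, table), self._recal(dest), self.header)

    def t_call(self, index: int) -> None:
        window = self.plan.subregions[index]
        (self.workdir / "vcf").mkdir(parents=True, exist_ok=True)
        _, records = read_sam(self._recal(dest_name(index)))
        # buffer evidence from same-chromosome neighbours
        for other in (index - 1, index + 1):
            if 0 <= other < len(self.plan.subregions):
                sr = self.plan.subregions[other]
                if sr.chrom != window.chrom:
                    continue
                _, neigh = read_sam(self._recal(dest_name(other)))
                records.extend(
                    r
                    for r in neigh
                    if r.overlaps(window.chrom, window.buffered_start, window.buffered_end)
                )
        calls = pileup_call(
            window,
            records,
            self.reference,
            min_depth=self.config.min_depth,
            min_alt_frac=self.config.min_alt_frac,
            hom_frac=self.config.hom_frac,
        )
        write_vcf(calls, self.genome, self._vcf(dest_name(index)))
        self.counts[f"calls:{dest_name(index)}"] = len(calls)

    def t_concat(self) -> None:
        per_subregion: dict[int, list[VariantCall]] = {}
        for sr in self.plan.subregions:
            per_subregion[sr.index] = read_vcf(
                self._vcf(dest_name(sr.index)), subregion_index=sr.index
            )
        final = reconcile_boundary_variants(per_subregion, self.plan)
        Path(self.config.output).parent.mkdir(parents=True, exist_ok=True)
        write_vcf(final, self.genome, self.config.output)
        self.counts["calls:final"] = len(final)
        metrics_path = self.workdir / "metrics.json"
        with open(metrics_path, "w") as fh:
            json.dump(self.counts, fh, indent=2, sort_keys=True)

    # -- graph -------------------------------------------------------------
    def build_graph(self) -> TaskGraph:
        graph = TaskGraph()
        n_inputs = len(self.config.inputs)
        split_tasks = []
        for n in range(n_inputs):
            name = f"split:in{n:03d}"
            graph.add(name, (), lambda n=n: self.t_split(n))
            split_tasks.append(name)
        dests = [dest_name(sr.index) for sr in self.plan.subregions] + [CHR_I]
        for dest in dests:
            graph.add(f"merge:{dest}", split_tasks, lambda d=dest: self.t_merge(d))
        graph.add("dedup:chrI", (f"merge:{CHR_I}",), self.t_dedup_chrI)
        graph.add("redistribute", ("dedup:chrI",), self.t_redistribute)
        for sr in self.plan.subregions:
            d = dest_name(sr.index)
            graph.add(
                f"dedup:{d}",
                (f"merge:{d}", "redistribute"),
                lambda i=sr.index: self.t_dedup_subregion(i),
            )
            graph.add(f"covar:{d}", (f"dedup:{d}",), lambda i=sr.index: self.t_covariates(i))
        graph.add(
            "covar-merge",
            tuple(f"covar:{dest_name(sr.index)}" for sr in self.plan.subregions),
            self.t_covariate_merge,
        )
        for sr in self.plan.subregions:
            d = dest_name(sr.index)
            graph.add(
                f"recal:{d}",
                (f"dedup:{d}", "covar-merge"),
                lambda i=sr.index: self.t_recalibrate(i),
            )
        for sr in self.plan.subregions:
            deps = []
            for other in (sr.index - 1, sr.index, sr.index + 1):
                if 0 <= other < len(self.plan.subregions):
                    if self.plan.subregions[other].chrom == sr.chrom:
                        deps.append(f"recal:{dest_name(other)}")
            graph.add(
                f"call:{dest_name(sr.index)}", deps, lambda i=sr.index: self.t_call(i)
            )
        graph.add(
            "concat",
            tuple(f"call:{dest_name(sr.index)}" for sr in self.plan.subregions),
            self.t_concat,
        )
        graph.barriers = (f"merge:{CHR_I}", "covar-merge", "concat")
        return graph

    # -- execution ---------------------------------------------------------
    def _log(self, **payload) -> None:
        self.workdir.mkdir(parents=True, exist_ok=True)
        with open(self._log_path, "a") as fh:
            fh.write(json.dumps(payload, sort_keys=True) + "\n")

    def _task_outputs(self, name: str) -> list[Path]:
        """Declared outputs per task, for the resume manifest."""
        kind, _, arg = name.partition(":")
        if kind == "split":
            ordinal = int(arg[2:])
            return sorted((self.workdir / "split").glob(f"in{ordinal:03d}__*.sam"))
        if kind == "merge":
            return [self._merged(arg)]
        if name == "dedup:chrI":
            return [self._dedup(CHR_I)]
        if kind == "dedup":
            return [self._dedup(arg)]
        if name == "redistribute":
            return sorted((self.workdir / "redistributed").glob("*.sam"))
        if name == "covar-merge":
            return [self._covar("merged")]
        if kind == "covar":
            return [self._covar(arg)]
        if kind == "recal":
            return [self._recal(arg)]
        if kind == "call":
            return [self._vcf(arg)]
        if name == "concat":
            return [Path(self.config.output)]
        return []

    def execute(self, graph: TaskGraph | None = None) -> dict[str, int]:
        graph = graph or self.build_graph()
        order = graph.topological_order()
        manifest_path = self.workdir / "manifest.json"
        manifest: dict[str, dict[str, str]] = {}
        if self.config.resume and manifest_path.exists():
            with open(manifest_path) as fh:
                manifest = json.load(fh)

        def is_fresh(name: str) -> bool:
            entry = manifest.get(name)
            if entry is None:
                return False
            for rel, digest in entry.items():
                p = Path(rel)
                if not p.exists() or _sha256(p) != digest:
                    return False
            return True

        done: set[str] = set()
        failed: set[str] = set()
        skipped: set[str] = set()

        def run_task(name: str) -> str:
            self._log(task=name, event="start", time=time.time())
            graph.tasks[name].fn()
            self._log(task=name, event="done", time=time.time())
            return name

        self.workdir.mkdir(parents=True, exist_ok=True)
        pending = [n for n in order]
        first_failure: TaskFailure | None = None
        with ThreadPoolExecutor(max_workers=self.config.workers) as pool:
            futures = {}
            while pending or futures:
                ready = [
                    n
                    for n in pending
                    if all(d in done for d in graph.tasks[n].deps)
                ]
                skipped_this_round = False
                for name in ready:
                    pending.remove(name)
                    if self.config.resume and is_fresh(name):
                        done.add(name)
                        skipped.add(name)
                        skipped_this_round = True
                        self._log(task=name, event="skipped")
                        continue
                    futures[pool.submit(run_task, name)] = name
                if not futures:
                    if skipped_this_round:
                        continue  # newly unblocked tasks may be ready now
                    if pending and first_failure is None:
                        raise ConfigError("stalled task graph")
                    break
                finished, _ = wait(futures, return_when=FIRST_COMPLETED)
                for fut in finished:
                    name = futures.pop(fut)
                    exc = fut.exception()
                    if exc is not None:
                        failed.add(name)
                        self._log(task=name, event="failed", error=str(exc))
                        if first_failure is None:
                            first_failure = TaskFailure(name, exc)
                        # abort: stop scheduling dependents
                        pending = [
                            n
                            for n in pending
                            if not _depends_on(graph, n, failed)
                        ]
                    else:
                        done.add(name)
                        manifest[name] = {
                            str(p): _sha256(p) for p in self._task_outputs(name)
                        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        if first_failure is not None:
            raise first_failure
        return dict(self.counts)

    def emit_scripts(self, config_path: str | Path, outdir: str | Path) -> list[Path]:
        """Write one shell script per task, without executing anything."""
        graph = self.build_graph()
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in graph.topological_order():
            safe = name.replace(":", "_")
            path = outdir / f"task_{safe}.sh"
            deps = " ".join(graph.tasks[name].deps)
            with open(path, "w") as fh:
                fh.write("#!/bin/sh\n")
                fh.write(f"# deps: {deps}\n")
                fh.write(f"exec shardseq run-task --config {config_path} --task '{name}'\n")
            path.chmod(0o755)
            paths.append(path)
        return paths

    def run_single_task(self, name: str) -> None:
        graph = self.build_graph()
        if name not in graph.tasks:
            raise ConfigError(f"unknown task {name!r}")
        graph.tasks[name].fn()


def _depends_on(graph: TaskGraph, name: str, targets: set[str]) -> bool:
    seen = set()
    stack = [name]
    while stack:
        cur = stack.pop()
        for dep in graph.tasks[cur].deps:
            if dep in targets:
                return True
            if dep not in seen:
                seen.add(dep)
                stack.append(dep)
    return False


def run_pipeline(config: PipelineConfig) -> dict[str, int]:
    """Plan and execute the full pipeline; returns stage record counts."""
    pipeline = Pipeline(config)
    return pipeline.execute()
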