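import json
from pathlib import Path

import pytest
import yaml
from click.testing import CliRunner

from shardseq.cli import main
from shardseq.genome_partition import GenomeIndex, partition_genome
from shardseq.pipeline import ConfigError, Pipeline, PipelineConfig, TaskFailure
from shardseq.simulate import SimulationSpec, simulate_dataset, write_fai, write_fasta
from shardseq.alignment import write_sam


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    base = tmp_path_factory.mktemp("fixture")
    spec = SimulationSpec(
        seed=51, chrom_lengths=(12_000, 8_000), coverage=12, read_length=50,
        duplication_rate=0.1, interchrom_rate=0.04, boundary_rate=0.05,
        softclip_rate=0.1, n_snps=8, n_indels=2,
    )
    genome = GenomeIndex(tuple(zip(spec.chrom_names, spec.chrom_lengths)))
    plan = partition_genome(genome, 4, 1500)
    ds = simulate_dataset(spec, plan)
    write_fasta(ds.reference, base / "ref.fasta")
    write_sam(ds.records, base / "reads.sam", ds.header)
    return base, ds


def _config(base, workdir, **kw):
    defaults = dict(
        reference=base / "ref.fasta",
        inputs=(base / "reads.sam",),
        workdir=workdir,
        output=workdir / "final.vcf",
        subregions=4,
        overlap=1500,
        workers=1,
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)


class TestPlanning:
    def test_task_counts_m4_n2(self, dataset, tmp_path):
        base, ds = dataset
        cfg = _config(
            base, tmp_path / "w", inputs=(base / "reads.sam", base / "reads.sam")
        )
        pipeline = Pipeline(cfg)
        graph = pipeline.build_graph()
        split = [n for n in graph.tasks if n.startswith("split:")]
        merge = [n for n in graph.tasks if n.startswith("merge:")]
        assert len(split) == 2
        # 4 subregions + chrI; partitioning never crosses chromosomes so the
        # realized count may exceed M by (n_chroms - 1)
        assert len(merge) == len(pipeline.plan.subregions) + 1

    def test_m1_degenerates(self, dataset, tmp_path):
        base, _ = dataset
        pipeline = Pipeline(_config(base, tmp_path / "w", subregions=1))
        graph = pipeline.build_graph()
        assert len([n for n in graph.tasks if n.startswith("dedup:s")]) == 2  # 1/chrom

    def test_plan_deterministic(self, dataset, tmp_path):
        base, _ = dataset
        g1 = Pipeline(_config(base, tmp_path / "w1")).build_graph()
        g2 = Pipeline(_config(base, tmp_path / "w2")).build_graph()
        assert g1.serialized() == g2.serialized()

    def test_barriers_declared(self, dataset, tmp_path):
        base, _ = dataset
        graph = Pipeline(_config(base, tmp_path / "w")).build_graph()
        assert set(graph.barriers) == {"merge:chrI", "covar-merge", "concat"}
        # structurally: the only tasks whose deps span every subregion
        n_sub = len(Pipeline(_config(base, tmp_path / "w2")).plan.subregions)
        for name, task in graph.tasks.items():
            sub_deps = {d for d in task.deps if ":s" in d}
            if len(sub_deps) >= n_sub:
                assert name in graph.barriers

    def test_invalid_config_enumerates_problems(self, tmp_path):
        cfg = PipelineConfig(
            reference=tmp_path / "missing.fa",
            inputs=(tmp_path / "missing.sam",),
            workdir=tmp_path / "w",
            output=tmp_path / "out.vcf",
            workers=0,
            survivor="bogus",
        )
        with pytest.raises(ConfigError) as err:
            cfg.validate()
        msg = str(err.value)
        assert "workers" in msg and "reference" in msg and "survivor" in msg

    def test_default_subregions_heuristic(self, dataset, tmp_path):
        base, _ = dataset
        cfg = _config(base, tmp_path / "w", subregions=None, workers=3)
        assert cfg.effective_subregions == 6


class TestExecution:
    def test_workers_do_not_change_outputs(self, dataset, tmp_path):
        base, _ = dataset
        outputs = []
        for workers in (1, 4):
            wd = tmp_path / f"w{workers}"
            cfg = _config(base, wd, workers=workers)
            Pipeline(cfg).execute()
            outputs.append(
                (
                    (wd / "final.vcf").read_bytes(),
                    (wd / "covar" / "merged.tsv").read_bytes(),
                    sorted(p.name for p in (wd / "recal").glob("*.sam")),
                )
            )
        assert outputs[0] == outputs[1]

    def test_task_failure_aborts_dependents(self, dataset, tmp_path):
        base, _ = dataset
        cfg = _config(base, tmp_path / "w")
        pipeline = Pipeline(cfg)
        graph = pipeline.build_graph()

        def boom():
            raise RuntimeError("induced failure")

        graph.tasks["dedup:s0001"].fn = boom
        with pytest.raises(TaskFailure) as err:
            pipeline.execute(graph)
        assert err.value.task == "dedup:s0001"
        assert not (tmp_path / "w" / "final.vcf").exists()

    def test_resume_skips_completed(self, dataset, tmp_path):
        base, _ = dataset
        wd = tmp_path / "w"
        cfg = _config(base, wd)
        Pipeline(cfg).execute()
        first = (wd / "final.vcf").read_bytes()
        cfg2 = _config(base, wd, resume=True)
        pipeline = Pipeline(cfg2)
        pipeline.execute()
        log = (wd / "run.log.jsonl").read_text().splitlines()
        skipped = [json.loads(l) for l in log if json.loads(l).get("event") == "skipped"]
        assert skipped, "resume should skip completed tasks"
        assert (wd / "final.vcf").read_bytes() == first

    def test_metrics_written(self, dataset, tmp_path):
        base, _ = dataset
        wd = tmp_path / "w"
        Pipeline(_config(base, wd)).execute()
        metrics = json.loads((wd / "metrics.json").read_text())
        assert "calls:final" in metrics
        assert metrics["input:0"] > 0


class TestCli:
    def test_partition_command(self, tmp_path):
        fai = tmp_path / "ref.fa.fai"
        fai.write_text("chr1\t1000\nchr2\t500\n")
        out = tmp_path / "intervals.list"
        result = CliRunner().invoke(
            main, ["partition", "--reference-index", str(fai), "-m", "3", "--out", str(out)]
        )
        assert result.exit_code == 0
        assert out.exists()

    def test_partition_invalid_m(self, tmp_path):
        fai = tmp_path / "ref.fa.fai"
        fai.write_text("chr1\t1000\n")
        result = CliRunner().invoke(
            main,
            ["partition", "--reference-index", str(fai), "-m", "0", "--out", str(tmp_path / "x")],
        )
        assert result.exit_code == 2

    def test_run_from_yaml(self, dataset, tmp_path):
        base, _ = dataset
        wd = tmp_path / "w"
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            yaml.safe_dump(
                {
                    "reference": str(base / "ref.fasta"),
                    "inputs": [str(base / "reads.sam")],
                    "workdir": str(wd),
                    "output": str(wd / "final.vcf"),
                    "subregions": 2,
                    "overlap": 1500,
                }
            )
        )
        result = CliRunner().invoke(main, ["run", "--config", str(cfg_path)])
        assert result.exit_code == 0, result.output
        assert (wd / "final.vcf").exists()

    def test_run_invalid_config_exit_2(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            yaml.safe_dump(
                {
                    "reference": "nope.fa",
                    "inputs": ["nope.sam"],
                    "workdir": str(tmp_path / "w"),
                    "output": str(tmp_path / "out.vcf"),
                }
            )
        )
        result = CliRunner().invoke(main, ["run", "--config", str(cfg_path)])
        assert result.exit_code == 2

    def test_emit_scripts_writes_without_executing(self, dataset, tmp_path):
        base, _ = dataset
        wd = tmp_path / "w"
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            yaml.safe_dump(
                {
                    "reference": str(base / "ref.fasta"),
                    "inputs": [str(base / "reads.sam")],
                    "workdir": str(wd),
                    "output": str(wd / "final.vcf"),
                    "subregions": 2,
                }
            )
        )
        scripts_dir = tmp_path / "scripts"
        result = CliRunner().invoke(
            main, ["run", "--config", str(cfg_path), "--emit-scripts", str(scripts_dir)]
        )
        assert result.exit_code == 0, result.output
        scripts = list(scripts_dir.glob("task_*.sh"))
        assert scripts
        assert not (wd / "final.vcf").exists()
        body = scripts[0].read_text()
        assert "shardseq run-task" in body

    def test_simulate_command(self, tmp_path):
        out = tmp_path / "sim"
        result = CliRunner().invoke(
            main,
            [
                "simulate", "--seed", "3", "--chroms", "5000,2000", "--coverage", "4",
                "--read-length", "50", "--snps", "3", "--out", str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        for name in ("reference.fasta", "reads.sam", "truth.vcf", "spec.json"):
            assert (out / name).exists()
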