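import json
from pathlib import Path

import numpy as np
import pytest
import yaml
from click.testing import CliRunner
from hypothesis import given, settings
from hypothesis import strategies as st

from endotrawl.errors import ConfigurationError, EndotrawlError, ParseError
from endotrawl.interface.cli import main as cli_main
from endotrawl.interface.config import PipelineConfig
from endotrawl.interface.pipeline import run_pipeline, write_reports
from endotrawl.interface.seqio import (
    SeqRecord,
    read_fasta,
    read_fastq,
    read_sequences,
    write_fasta,
    write_fastq,
)
from endotrawl.quality import QualityReport
from endotrawl.simdata import derive_species, fragment_genome, simulate_timeseries

ids = st.text(alphabet="abcdefgh0123456789_", min_size=1, max_size=10)
dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestSeqio:
    def test_fasta_two_records(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">one desc\nACGT\nACGT\n>two\nTTTT\n")
        records = read_fasta(path)
        assert [(r.id, r.seq) for r in records] == [("one", "ACGTACGT"), ("two", "TTTT")]

    def test_fastq_length_mismatch(self, tmp_path):
        path = tmp_path / "x.fastq"
        path.write_text("@r1\nACGT\n+\nIII\n")
        with pytest.raises(ParseError) as err:
            read_fastq(path)
        assert err.value.line == 4

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(ParseError):
            read_fasta(path)

    def test_data_before_header(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text("ACGT\n>a\nACGT\n")
        with pytest.raises(ParseError) as err:
            read_fasta(path)
        assert err.value.line == 1

    @given(st.dictionaries(ids, dna, min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_fasta_round_trip(self, records):
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "r.fasta"
            write_fasta(sorted(records.items()), path, width=13)
            back = read_fasta(path)
            assert {r.id: r.seq for r in back} == records

    def test_fastq_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        records = [
            SeqRecord(f"r{i}", "".join(rng.choice(list("ACGT"), size=60)), "I" * 60)
            for i in range(50)
        ]
        path = tmp_path / "r.fastq"
        write_fastq(records, path)
        back = read_fastq(path)
        assert [(r.id, r.seq, r.qual) for r in back] == [
            (r.id, r.seq, r.qual) for r in records
        ]

    def test_format_inference(self, tmp_path):
        fq = tmp_path / "a.fq"
        fq.write_text("@r\nAC\n+\nII\n")
        assert read_sequences(fq)[0].qual == "II"


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        config = PipelineConfig(bsr_min=0.5, seed=7, outdir="out")
        path = tmp_path / "c.yaml"
        config.to_yaml(path)
        back = PipelineConfig.from_yaml(path)
        assert back == config

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError):
            PipelineConfig.from_yaml("bogus_key: 1")

    def test_threshold_validation(self):
        with pytest.raises(ConfigurationError):
            PipelineConfig(bsr_min=1.5)
        with pytest.raises(ConfigurationError):
            PipelineConfig(detect_tolerance=0.0)


class TestWriteReports:
    def test_quality_report_json_keys(self, tmp_path):
        report = QualityReport(
            bin_id="b", found_single=["m1"], found_multi=[], missing=["m2"],
            completeness=50.0, contamination=0.0, rrna_5s=True, rrna_16s=False,
            rrna_23s=False, trna_count=3, tier="medium",
        )
        write_reports([report], tmp_path, "qc")
        data = json.loads((tmp_path / "qc.json").read_text())
        assert set(data["records"][0]) == set(report.to_dict())
        restored = data["records"][0]
        assert restored["completeness"] == 50.0 and restored["tier"] == "medium"

    def test_empty_reports(self, tmp_path):
        digests = write_reports([], tmp_path, "empty")
        assert (tmp_path / "empty.json").exists()
        assert (tmp_path / "empty.tsv").exists()
        assert len(digests) == 2


@pytest.fixture(scope="module")
def scenario_dir(tmp_path_factory, small_scenario):
    """Files for the small planted scenario, as the pipeline expects them."""
    out = tmp_path_factory.mktemp("scenario")
    genome = small_scenario["genome"]
    reference = derive_species(genome, 0.03, 77)
    fragments, _ = fragment_genome(genome, 3, 5000, seed=78)
    contigs = dict(fragments)
    rng = np.random.default_rng(79)
    for i in range(5):
        contigs[f"bg_{i}"] = "".join(rng.choice(list("ACGT"), size=4000))
    write_fasta(sorted(contigs.items()), out / "contigs.fasta")
    write_fasta([("reference", reference)], out / "reference.fasta")
    write_fasta(small_scenario["catalog"], out / "markers.faa")
    write_fastq(
        [SeqRecord(rid, seq, "I" * len(seq)) for rid, seq in small_scenario["reads"]],
        out / "reads.fastq",
    )
    return out


def _config(scenario_dir, outdir, seed=1):
    return PipelineConfig(
        reads=str(scenario_dir / "reads.fastq"),
        contigs=str(scenario_dir / "contigs.fasta"),
        references=str(scenario_dir / "reference.fasta"),
        markers=str(scenario_dir / "markers.faa"),
        seed=seed,
        outdir=str(outdir),
    )


class TestRunPipeline:
    def test_end_to_end_pass(self, scenario_dir, tmp_path):
        manifest = run_pipeline(_config(scenario_dir, tmp_path / "run1"))
        stages = {s["stage"]: s for s in manifest.stages}
        assert stages["screen"]["verdict"] == "pass"
        assert stages["recruit"]["n_bins"] == 1
        assert list(stages["qc"]["tiers"].values()) == ["medium"]
        assert list(stages["detect"]["detected"].values()) == [True]
        qc = json.loads((tmp_path / "run1" / "qc.json").read_text())
        assert qc["records"][0]["completeness"] >= 80.0

    def test_no_symbiont_short_circuits(self, scenario_dir, tmp_path):
        rng = np.random.default_rng(80)
        null_reads = [
            SeqRecord(f"n{i}", "".join(rng.choice(list("ACGT"), size=150)), "I" * 150)
            for i in range(100)
        ]
        write_fastq(null_reads, tmp_path / "null.fastq")
        config = _config(scenario_dir, tmp_path / "run2")
        config.reads = str(tmp_path / "null.fastq")
        manifest = run_pipeline(config)
        assert [s["stage"] for s in manifest.stages] == ["screen"]
        assert manifest.stages[0]["verdict"] == "fail_stage1"

    def test_determinism_of_digests(self, scenario_dir, tmp_path):
        m1 = run_pipeline(_config(scenario_dir, tmp_path / "a"))
        m2 = run_pipeline(_config(scenario_dir, tmp_path / "b"))
        d1 = [
            {Path(k).name: v for k, v in s["outputs"].items()} for s in m1.stages
        ]
        d2 = [
            {Path(k).name: v for k, v in s["outputs"].items()} for s in m2.stages
        ]
        assert d1 == d2


class TestCli:
    def test_screen_command(self, scenario_dir, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "screen", "--reads", str(scenario_dir / "reads.fastq"),
                "--markers", str(scenario_dir / "markers.faa"),
                "--outdir", str(tmp_path), "--stdout",
            ],
        )
        assert result.exit_code == 0, result.output
        assert json.loads(result.output)["verdict"] == "pass"

    def test_recruit_and_qc_commands(self, scenario_dir, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "recruit", "--contigs", str(scenario_dir / "contigs.fasta"),
                "--references", str(scenario_dir / "reference.fasta"),
                "--outdir", str(tmp_path),
            ],
        )
        assert result.exit_code == 0, result.output
        bin_fasta = tmp_path / "bin_reference.fasta"
        assert bin_fasta.exists()
        result = runner.invoke(
            cli_main,
            [
                "qc", "--bin", str(bin_fasta),
                "--markers", str(scenario_dir / "markers.faa"),
                "--outdir", str(tmp_path),
            ],
        )
        assert result.exit_code == 0, result.output
        qc = json.loads((tmp_path / "qc.json").read_text())
        assert qc["records"][0]["completeness"] > 50

    def test_timeseries_command(self, tmp_path):
        dates = [f"2021-{m:02d}-01" for m in range(1, 13)]
        table, _ = simulate_timeseries(
            ["sp1", "sp2"], dates, {"sp1": 50, "sp2": 100}, seed=5
        )
        table_path = tmp_path / "counts.tsv"
        table.to_csv(table_path, sep="\t", index=False)
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "timeseries", "--table", str(table_path),
                "--outdir", str(tmp_path),
                "--plot", str(tmp_path / "plot.png"),
            ],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "detection_fractions.tsv").exists()
        assert (tmp_path / "plot.png").stat().st_size > 0

    def test_run_command(self, scenario_dir, tmp_path):
        config = _config(scenario_dir, tmp_path / "cli_run")
        config_path = tmp_path / "config.yaml"
        config.to_yaml(config_path)
        runner = CliRunner()
        result = runner.invoke(cli_main, ["run", "--config", str(config_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "cli_run" / "manifest.json").exists()
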