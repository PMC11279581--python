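"""Record I/O, FASTA, the end-to-end report, and the CLI surface."""

import json

import pytest
from click.testing import CliRunner

from cyclopep import (
    RunConfig,
    SynthConfig,
    example_background,
    generate_mic_pairs,
    generate_peptides,
    read_fasta,
    read_records,
    run_report,
    write_records,
)
from cyclopep.cli import main as cli_main
from cyclopep.io import InputError, records_to_table


@pytest.fixture(scope="module")
def records():
    return generate_peptides(SynthConfig(n_peptides=80, seed=23))


class TestRecordsIO:
    def test_round_trip_identity(self, records, tmp_path):
        path = tmp_path / "records.jsonl"
        write_records(records, path, include_truth=True)
        back = read_records(path).records
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.chain == b.chain
            assert a.bonds == b.bonds
            assert a.synthesis == b.synthesis
            assert a.truth == b.truth

    def test_lenient_collects_diagnostics(self, tmp_path):
        path = tmp_path / "mixed.jsonl"
        good = ('{"id": "ok", "sequence": "ACDEFGHIKC", '
                '"synthesis": "ribosomal", "bonds": []}')
        path.write_text(good + "\nnot json at all\n")
        result = read_records(path)
        assert len(result.records) == 1
        assert len(result.diagnostics) == 1
        assert "line 2" in result.diagnostics[0]

    def test_strict_aborts_on_first_violation(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"id": "x", "sequence": "AC", "bonds": '
                        '[{"kind": "DSB", "linkage": "SSB", "pos1": 1, "pos2": 9}]}\n')
        with pytest.raises(InputError):
            read_records(path, strict=True)
        lenient = read_records(path)
        assert lenient.records == [] and "out of range" in lenient.diagnostics[0]

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        result = read_records(path)
        assert result.records == []
        assert any("no records" in d for d in result.diagnostics)

    def test_flat_table(self, records):
        df = records_to_table(records)
        assert len(df) == len(records)
        assert {"id", "sequence", "length", "n_bonds"} <= set(df.columns)


class TestFasta:
    def test_reads_wrapped_sequences(self, tmp_path):
        path = tmp_path / "p.fa"
        path.write_text(">pep1 some description\nGIGKFLHSAK\nKFGKAFVGEI\n>pep2\nACDEF\n")
        chains = read_fasta(path)
        assert [c.id for c in chains] == ["pep1", "pep2"]
        assert chains[0].length == 20
        assert chains[0].sequence.startswith("GIGKFLHSAK")

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "d.fa"
        path.write_text(">a\nACD\n>a\nACD\n")
        with pytest.raises(InputError, match="duplicate"):
            read_fasta(path)

    def test_non_alphabet_rejected(self, tmp_path):
        path = tmp_path / "x.fa"
        path.write_text(">a\nACB\n")
        with pytest.raises(InputError):
            read_fasta(path)


class TestReport:
    def test_all_tables_emitted(self, records, tmp_path):
        pairs = generate_mic_pairs(SynthConfig(n_peptides=40, seed=23))
        cfg = RunConfig(out_dir=tmp_path / "rep", seed=23, n_shuffles=100,
                        background=example_background())
        manifest = run_report(records, cfg, mic_pairs=pairs)
        expected = {"size_classes.tsv", "ring_labels.tsv", "topology.tsv",
                    "disaap.tsv", "composition.tsv", "delta_mic.tsv"}
        assert set(manifest["tables"]) == expected
        for name in expected:
            assert (tmp_path / "rep" / name).exists()
        saved = json.loads((tmp_path / "rep" / "manifest.json").read_text())
        assert saved["input_digest_sha256"] == manifest["input_digest_sha256"]

    def test_missing_mic_pairs_skipped_with_reason(self, records, tmp_path):
        cfg = RunConfig(out_dir=tmp_path / "rep2", seed=23, n_shuffles=100)
        manifest = run_report(records, cfg)
        assert "delta_mic" in manifest["skipped"]
        assert not (tmp_path / "rep2" / "delta_mic.tsv").exists()

    def test_strict_mode_raises_on_skip(self, records, tmp_path):
        cfg = RunConfig(out_dir=tmp_path / "rep3", seed=23, n_shuffles=100,
                        strict=True)
        with pytest.raises(ValueError, match="skipped"):
            run_report(records, cfg)

    def test_rerun_is_byte_identical(self, records, tmp_path):
        outs = []
        for sub in ("r1", "r2"):
            cfg = RunConfig(out_dir=tmp_path / sub, seed=23, n_shuffles=100)
            run_report(records, cfg)
            outs.append({
                p.name: p.read_bytes()
                for p in sorted((tmp_path / sub).glob("*.tsv"))
            })
        assert outs[0] == outs[1]


class TestCLI:
    def test_simulate_classify_pipeline(self, tmp_path):
        runner = CliRunner()
        rec_path = tmp_path / "records.jsonl"
        truth_path = tmp_path / "truth.tsv"
        calls_path = tmp_path / "calls.tsv"
        res = runner.invoke(cli_main, [
            "simulate", "--n", "30", "--seed", "4",
            "--out", str(rec_path), "--truth", str(truth_path),
        ])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, [
            "classify", "--records", str(rec_path), "--out", str(calls_path),
        ])
        assert res.exit_code == 0, res.output
        import pandas as pd

        calls = pd.read_csv(calls_path, sep="\t")
        truth = pd.read_csv(truth_path, sep="\t")
        merged = calls.merge(truth, on="id")
        assert (merged["class"] == merged["truth"]).all()

    def test_disaap_requires_seed_for_shuffle(self, tmp_path):
        runner = CliRunner()
        fa = tmp_path / "p.fa"
        fa.write_text(">a\nCAAAAACGG\n>b\nCAAAAACGG\n")
        res = runner.invoke(cli_main, [
            "disaap", "--fasta", str(fa), "--pair", "CC",
            "--n-shuffles", "100", "--out", str(tmp_path / "o.tsv"),
        ])
        assert res.exit_code == 2

    def test_delta_mic_summary(self, tmp_path):
        runner = CliRunner()
        pairs = tmp_path / "pairs.tsv"
        pairs.write_text(
            "id\tsequence\tmic_linear\tmic_cyclic\tunit\tbond_set\tstrain\tgram\n"
            "p1\tGIGK\t8\t2\tug/mL\tDSB\tsa\tpositive\n"
            "p2\tGIGK\t8\t8\tug/mL\tHT\tsa\tpositive\n"
        )
        out = tmp_path / "summary.tsv"
        res = runner.invoke(cli_main, [
            "delta-mic", "--pairs", str(pairs), "--group", "bond_set",
            "--out", str(out),
        ])
        assert res.exit_code == 0, res.output
        import pandas as pd

        df = pd.read_csv(out, sep="\t").set_index("bond_set")
        assert df.loc["DSB", "n_cyclic_more_potent"] == 1
        assert df.loc["HT", "n_indistinguishable"] == 1
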