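import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from trpcensus.catalog import write_catalog
from trpcensus.cli import main as cli_main
from trpcensus.depth import write_structure
from trpcensus.pipelines import PipelineConfig, run_census, run_conserve, run_depth
from trpcensus.simulate import (
    BundleSpec,
    CategorySpec,
    MsaSpec,
    gen_helical_bundle,
    gen_msa,
    gen_proteome,
    write_msa,
)


@pytest.fixture
def census_inputs(tmp_path):
    specs = [
        CategorySpec("CERS", 30, length_range=(250, 250), tmd_count_range=(7, 7),
                     subcellular_location="Endoplasmic reticulum membrane"),
        CategorySpec("TM_6_10", 30, length_range=(250, 250), tmd_count_range=(6, 10)),
        CategorySpec("TLC_OTHER", 30, length_range=(250, 250), tmd_count_range=(6, 8)),
    ]
    records, _ = gen_proteome(specs, seed=17)
    write_catalog(records, tmp_path / "p.fasta", tmp_path / "p.tsv")
    (tmp_path / "cers.txt").write_text(
        "\n".join(r.accession for r in records if r.source_dataset == "CERS")
    )
    (tmp_path / "tlc.txt").write_text(
        "\n".join(r.accession for r in records if r.source_dataset == "TLC_OTHER")
    )
    return tmp_path


def census_config(base, out):
    return PipelineConfig(
        out_dir=str(out),
        input_path=str(base / "p.fasta"),
        input_table=str(base / "p.tsv"),
        cers_list=str(base / "cers.txt"),
        tlc_list=str(base / "tlc.txt"),
    )


class TestConfig:
    def test_round_trip_lossless(self, tmp_path):
        cfg = PipelineConfig(out_dir="x", seed=7, identity_threshold_c=0.65,
                             half_thickness_angstrom=17.5, reference_id="CerS5")
        path = tmp_path / "cfg.txt"
        cfg.to_file(path)
        assert PipelineConfig.from_file(path) == cfg

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(identity_threshold_c=1.4)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("identity_threshold = 0.7\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            PipelineConfig.from_file(path)


class TestRunCensus:
    def test_full_run_with_group_tests(self, census_inputs, tmp_path):
        result = run_census(census_config(census_inputs, tmp_path / "run"))
        assert result["counts"]["records_in"] == 90
        stats = result["stats"]
        assert set(stats["groups"]) == {"TM_6_10", "CERS", "TLC_OTHER"}
        assert stats["anova"]["p"] < 0.05
        assert len(stats["tukey"]) == 3
        table = pd.read_csv(tmp_path / "run" / "composition_table.tsv",
                            sep="\t", index_col=0)
        assert "CERS" in table.columns
        assert (tmp_path / "run" / "manifest.json").exists()

    def test_rerun_byte_identical(self, census_inputs, tmp_path):
        for tag in ("r1", "r2"):
            run_census(census_config(census_inputs, tmp_path / tag))
        for name in ("composition_table.tsv", "group_tests.json"):
            assert (tmp_path / "r1" / name).read_bytes() == (
                tmp_path / "r2" / name
            ).read_bytes()

    def test_single_category_skips_group_tests(self, tmp_path):
        records, _ = gen_proteome(
            [CategorySpec("SOLUBLE", 10, length_range=(80, 120))], seed=5
        )
        write_catalog(records, tmp_path / "s.fasta", tmp_path / "s.tsv")
        cfg = PipelineConfig(out_dir=str(tmp_path / "run"),
                             input_path=str(tmp_path / "s.fasta"),
                             input_table=str(tmp_path / "s.tsv"))
        result = run_census(cfg)
        assert "skipped" in result["stats"]


@pytest.fixture
def depth_inputs(tmp_path):
    models_dir = tmp_path / "models"
    models_dir.mkdir()
    rows = []
    misoriented = []
    for i in range(8):
        bad = i >= 6  # two deliberately misoriented models
        spec = BundleSpec(
            accession=f"M{i:03d}",
            hox_side=-1 if bad else +1,
            trp_depths=(-20.0, 7.5),
            tilt_deg=5.0 * (i % 3),
        )
        model, truth = gen_helical_bundle(spec, seed=30 + i)
        write_structure(model, models_dir / f"{model.accession}.pdb")
        if bad:
            misoriented.append(model.accession)
        rows.append(
            {
                "accession": model.accession,
                "cohort": "hox" if i % 2 == 0 else "non_hox",
                "hox_start": truth.hox_residue_range[0],
                "hox_end": truth.hox_residue_range[1],
                "nterm_start": truth.nterm_residue_range[0],
                "nterm_end": truth.nterm_residue_range[1],
                "cyto_start": truth.cterm_residue_range[0],
                "cyto_end": truth.cterm_residue_range[1],
            }
        )
    pd.DataFrame(rows).to_csv(tmp_path / "cohorts.tsv", sep="\t", index=False)
    return tmp_path, misoriented


class TestRunDepth:
    def test_misoriented_models_rejected(self, depth_inputs, tmp_path):
        base, misoriented = depth_inputs
        cfg = PipelineConfig(out_dir=str(tmp_path / "drun"),
                             models_dir=str(base / "models"),
                             cohorts_table=str(base / "cohorts.tsv"))
        result = run_depth(cfg)
        assert sorted(result["report"]["rejected"]) == sorted(misoriented)
        assert result["counts"]["models_profiled"] == 6
        assert "mann_whitney" in result["report"]
        table = pd.read_csv(tmp_path / "drun" / "residue_depths.tsv", sep="\t")
        assert set(table.columns) >= {"accession", "cohort", "z_angstrom", "region"}
        assert (table.z_angstrom.abs() <= 40).all()

    def test_missing_models_dir_raises(self, tmp_path):
        (tmp_path / "cohorts.tsv").write_text("accession\tcohort\nX\th\n")
        cfg = PipelineConfig(out_dir=str(tmp_path / "o"),
                             models_dir=str(tmp_path / "nope"),
                             cohorts_table=str(tmp_path / "cohorts.tsv"))
        with pytest.raises(FileNotFoundError):
            run_depth(cfg)


class TestRunConserve:
    @pytest.fixture
    def msa_path(self, tmp_path):
        spec = MsaSpec(n_rows=40, n_cols=30,
                       conserved_columns={4: "W", 11: "H", 22: "W"})
        aln, _ = gen_msa(spec, seed=19)
        path = tmp_path / "msa.fasta"
        write_msa(aln, path)
        return path

    def test_planted_columns_at_top(self, msa_path, tmp_path):
        cfg = PipelineConfig(out_dir=str(tmp_path / "crun"), msa_fasta=str(msa_path),
                             reference_id="seq0000", top_k=10)
        result = run_conserve(cfg)
        top3 = {e[0] for e in result["ranking"].entries[:3]}
        assert top3 == {4, 11, 22}
        ranking = pd.read_csv(tmp_path / "crun" / "ic_ranking.tsv", sep="\t")
        assert len(ranking) == 10
        assert ranking.ic_bits.is_monotonic_decreasing

    def test_k_zero_valid_empty_report(self, msa_path, tmp_path):
        cfg = PipelineConfig(out_dir=str(tmp_path / "c0"), msa_fasta=str(msa_path),
                             reference_id="seq0000", top_k=0)
        result = run_conserve(cfg)
        assert result["ranking"].entries == ()

    def test_rerun_byte_identical(self, msa_path, tmp_path):
        cfg = PipelineConfig(out_dir=str(tmp_path / "k"), msa_fasta=str(msa_path),
                             reference_id="seq0000")
        names = ("ic_ranking.tsv", "logo_heights.tsv", "manifest.json")
        run_conserve(cfg)
        first = {n: (tmp_path / "k" / n).read_bytes() for n in names}
        run_conserve(cfg)
        assert all((tmp_path / "k" / n).read_bytes() == first[n] for n in names)

    def test_absent_reference_raises(self, msa_path, tmp_path):
        cfg = PipelineConfig(out_dir=str(tmp_path / "cx"), msa_fasta=str(msa_path),
                             reference_id="missing")
        with pytest.raises(KeyError):
            run_conserve(cfg)


class TestCli:
    def test_simulate_and_dedupe_roundtrip(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "copies", "--seed", "3",
                                       "--out", str(tmp_path / "fix")])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, ["dedupe", "--in",
                                       str(tmp_path / "fix" / "copies.fasta"),
                                       "--c", "0.7",
                                       "--out", str(tmp_path / "ded")])
        assert res.exit_code == 0, res.output
        assert "1 representatives" in res.output

    def test_stats_subcommand(self, tmp_path):
        path = tmp_path / "samples.tsv"
        path.write_text(
            "group\tvalue\n" +
            "\n".join(f"a\t{v}" for v in (1, 2, 3)) + "\n" +
            "\n".join(f"b\t{v}" for v in (4, 5, 6)) + "\n"
        )
        runner = CliRunner()
        res = runner.invoke(cli_main, ["stats", "mwu", "--in", str(path)])
        assert res.exit_code == 0
        payload = json.loads(res.output)
        assert payload["p"] == pytest.approx(0.10)

    def test_conserve_cli(self, tmp_path):
        aln, _ = gen_msa(MsaSpec(n_rows=20, n_cols=12,
                                 conserved_columns={2: "W"}), seed=6)
        write_msa(aln, tmp_path / "m.fasta")
        runner = CliRunner()
        res = runner.invoke(cli_main, ["conserve", "--msa", str(tmp_path / "m.fasta"),
                                       "--ref", "seq0000",
                                       "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        ranking = pd.read_csv(tmp_path / "out" / "ic_ranking.tsv", sep="\t")
        assert ranking.iloc[0]["column"] == 2

    def test_missing_input_exit_code(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["depth", "--models", str(tmp_path),
                                       "--cohorts", str(tmp_path / "nope.tsv")])
        assert res.exit_code == 2
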