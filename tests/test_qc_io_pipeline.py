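"""QC filtering, file-format round trips, the end-to-end driver, and the CLI."""

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

import dsclocks as d
from dsclocks import io as dio
from dsclocks.cli import main as cli_main
from dsclocks.errors import DegenerateDataError, ValidationError

from conftest import make_cohort


def _toy_betas(n_samples=4):
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.uniform(0, 1, size=(5, n_samples)),
                      index=[f"cg{i}" for i in range(5)],
                      columns=[f"s{i}" for i in range(n_samples)])
    return d.BetaMatrix(df, pd.Series("1", index=df.index))


class TestQC:
    def test_detection_p_filter_removes_flagged_cpg(self):
        betas = _toy_betas()
        det = pd.DataFrame(0.001, index=betas.cpg_ids, columns=betas.sample_ids)
        det.loc["cg2"] = 0.02  # mean detection p above 0.01
        out, report = d.qc_filter(betas, det)
        assert report.n_cpgs_removed_detection == 1
        assert "cg2" not in out.cpg_ids

    def test_clean_matrix_passes_unchanged(self):
        betas = _toy_betas()
        out, report = d.qc_filter(betas)
        pd.testing.assert_frame_equal(out.values, betas.values)
        assert report.n_cpgs_removed_detection == 0
        assert report.n_cpgs_removed_missingness == 0
        assert report.n_samples_removed == 0

    def test_sample_above_missingness_threshold_removed(self):
        betas = _toy_betas(n_samples=10)
        vals = betas.values.copy()
        # 2/5 CpGs missing for s9 (40%); each CpG only 10% missing overall
        vals.loc[["cg0", "cg1"], "s9"] = np.nan
        out, report = d.qc_filter(d.BetaMatrix(vals, betas.chromosome))
        assert report.n_cpgs_removed_missingness == 0
        assert report.n_samples_removed == 1
        assert report.removed_samples == ["s9"]

    def test_cpg_missingness_applied_before_sample_missingness(self):
        # a mostly-missing CpG is dropped first, rescuing the samples
        betas = _toy_betas()
        vals = betas.values.copy()
        vals.loc["cg0", ["s0", "s1", "s2"]] = np.nan
        out, report = d.qc_filter(d.BetaMatrix(vals, betas.chromosome))
        assert report.n_cpgs_removed_missingness == 1
        assert report.n_samples_removed == 0

    def test_all_samples_removed_is_fatal(self):
        betas = _toy_betas()
        vals = betas.values.copy()
        vals.iloc[:, :] = np.nan
        with pytest.raises(DegenerateDataError):
            d.qc_filter(d.BetaMatrix(vals, betas.chromosome))

    def test_misaligned_detection_p_rejected(self):
        betas = _toy_betas()
        det = pd.DataFrame(0.001, index=betas.cpg_ids[:3], columns=betas.sample_ids)
        with pytest.raises(ValidationError, match="aligned"):
            d.qc_filter(betas, det)


class TestRoundTrips:
    def test_betas_tsv(self, tmp_path):
        _, _, _, betas, *_ = make_cohort(seed=1, n_ds=5, n_non_ds=5,
                                         mosaic_fraction_values=())
        path = tmp_path / "b.tsv"
        betas.to_tsv(path)
        back = d.BetaMatrix.read_tsv(path)
        pd.testing.assert_frame_equal(back.values, betas.values)
        pd.testing.assert_series_equal(back.chromosome, betas.chromosome,
                                       check_names=False)

    def test_betas_without_chromosome_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"s1": [0.1]}, index=["cg1"]).to_csv(path, sep="\t")
        with pytest.raises(ValidationError, match="chromosome"):
            d.BetaMatrix.read_tsv(path)

    def test_sheet_and_bins_csv(self, tmp_path):
        _, _, _, _, sheet, bins, _ = make_cohort(seed=2, n_ds=6, n_non_ds=6,
                                                 mosaic_fraction_values=())
        dio.write_sample_sheet(sheet, tmp_path / "sheet.csv")
        back = dio.read_sample_sheet(tmp_path / "sheet.csv")
        assert back["ds"].equals(sheet["ds"])
        assert np.allclose(back["chron_age_days"], sheet["chron_age_days"])
        dio.write_bins(bins, tmp_path / "bins.csv")
        back_bins = dio.read_bins(tmp_path / "bins.csv")
        assert np.allclose(back_bins["log2_ratio"], bins["log2_ratio"])

    def test_reference_csv(self, tmp_path, reference30):
        reference30.to_csv(tmp_path / "ref.csv")
        back = d.CellReference.read_csv(tmp_path / "ref.csv")
        pd.testing.assert_frame_equal(
            back.mean_betas.sort_index(), reference30.mean_betas.sort_index(),
            check_names=False,
        )

    def test_pipeline_config_yaml(self, tmp_path):
        cfg = d.PipelineConfig(simulate={"n_ds": 10}, seed=9, max_pcs=4)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = d.PipelineConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg

    def test_pipeline_config_rejects_unknown_keys(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text("not_a_key: 1\n")
        with pytest.raises(ValidationError, match="unknown config keys"):
            d.PipelineConfig.from_yaml(tmp_path / "cfg.yaml")


@pytest.fixture(scope="module")
def small_pipeline_result():
    cfg = d.PipelineConfig(
        simulate=dict(n_ds=70, n_non_ds=90, mosaic_fraction_values=(0.3, 0.4),
                      n_chr21_bins=51, n_other_bins=10, n_pcs=3),
        seed=21, n_deconv_cpgs=40, max_pcs=3,
    )
    return cfg, d.run_pipeline(cfg)


class TestRunPipeline:
    def test_report_contains_positive_ds_association(self, small_pipeline_result):
        _, res = small_pipeline_result
        base = res.model_table.query("model == 'base' and outcome == 'clock'").iloc[0]
        assert base["estimate"] > 0
        assert base["p_value"] < 1e-4
        assert "base" in res.report and "AA days" in res.report

    def test_rerun_is_bit_identical(self, small_pipeline_result):
        cfg, res = small_pipeline_result
        res2 = d.run_pipeline(cfg)
        assert res.report_hash() == res2.report_hash()
        pd.testing.assert_frame_equal(res.model_table, res2.model_table)

    def test_all_stages_produce_output(self, small_pipeline_result):
        _, res = small_pipeline_result
        assert set(res.clock_values) >= {"skinblood", "pantissue", "haftorn",
                                         "knight", "bohlin"}
        assert len(res.proportions.proportions) == 160
        assert (res.t21.calls["call"] == "likely_mosaic_partial").sum() == 2
        assert res.dnamaa["skinblood"].anchor == "nonDS-chronological"
        assert set(res.ga_dnamaa) == {"haftorn", "knight", "bohlin"}
        assert not res.bivariate.tests.empty

    def test_outputs_written_and_re_readable(self, small_pipeline_result, tmp_path):
        _, res = small_pipeline_result
        res.write(tmp_path)
        clocks = dio.read_clock_values(tmp_path / "clocks.csv")
        assert "skinblood" in clocks.columns
        table = pd.read_csv(tmp_path / "models.csv")
        assert {"estimate", "ci_low", "ci_high", "p_value", "n_used"} <= set(table.columns)
        assert (tmp_path / "report.txt").read_text() == res.report

    def test_null_ds_offset_rarely_significant(self):
        # with no injected DS effect the DS row should be non-significant
        # in the vast majority of runs
        hits = 0
        reps = 12
        for rep in range(reps):
            cfg = d.PipelineConfig(
                simulate=dict(n_ds=40, n_non_ds=50, ds_clock_offset_years=0.0,
                              gata1_fraction_ds=0.0, mosaic_fraction_values=(),
                              n_chr21_bins=11, n_other_bins=0, n_pcs=2),
                seed=1000 + rep, n_deconv_cpgs=30, max_pcs=2,
            )
            res = d.run_pipeline(cfg)
            base = res.model_table.query("model == 'base' and outcome == 'clock'").iloc[0]
            hits += base["p_value"] < 0.05
        assert hits <= 2


class TestCLI:
    def test_simulate_then_analyze_files(self, tmp_path):
        runner = CliRunner()
        sim_cfg = {"n_ds": 30, "n_non_ds": 40, "mosaic_fraction_values": [0.4],
                   "n_chr21_bins": 21, "n_other_bins": 5, "n_pcs": 2}
        cfg_path = tmp_path / "sim.yaml"
        cfg_path.write_text(yaml.safe_dump(sim_cfg))
        out = tmp_path / "cohort"
        r = runner.invoke(cli_main, ["simulate", "--config", str(cfg_path),
                                     "--seed", "4", "--out", str(out),
                                     "--n-deconv-cpgs", "30"])
        assert r.exit_code == 0, r.output
        for name in ("betas.tsv", "sample_sheet.csv", "bins.csv",
                     "cell_reference.csv", "truth.json", "clock_skinblood.csv"):
            assert (out / name).exists()

        r = runner.invoke(cli_main, ["qc", "--betas", str(out / "betas.tsv"),
                                     "--out", str(tmp_path / "qc.tsv")])
        assert r.exit_code == 0, r.output

        r = runner.invoke(cli_main, [
            "clock", "--clock", str(out / "clock_skinblood.csv"), "--name", "skinblood",
            "--betas", str(out / "betas.tsv"), "--out", str(tmp_path / "clocks.csv"),
        ])
        assert r.exit_code == 0, r.output

        r = runner.invoke(cli_main, [
            "deconv", "--betas", str(out / "betas.tsv"),
            "--reference", str(out / "cell_reference.csv"),
            "--out", str(tmp_path / "props.csv"),
        ])
        assert r.exit_code == 0, r.output

        r = runner.invoke(cli_main, [
            "cnv-call", "--bins", str(out / "bins.csv"),
            "--sheet", str(out / "sample_sheet.csv"),
            "--out", str(tmp_path / "calls.csv"),
        ])
        assert r.exit_code == 0, r.output
        assert "likely_mosaic_partial" in (tmp_path / "calls.csv").read_text()

        r = runner.invoke(cli_main, [
            "aa", "--clocks", str(tmp_path / "clocks.csv"),
            "--sheet", str(out / "sample_sheet.csv"),
            "--out", str(tmp_path / "aa.csv"),
        ])
        assert r.exit_code == 0, r.output

    def test_run_and_report(self, tmp_path):
        runner = CliRunner()
        cfg = d.PipelineConfig(
            simulate=dict(n_ds=40, n_non_ds=50, n_chr21_bins=21, n_other_bins=5,
                          n_pcs=2, mosaic_fraction_values=[0.4]),
            seed=5, n_deconv_cpgs=30, max_pcs=2,
        )
        cfg_path = tmp_path / "pipe.yaml"
        cfg.to_yaml(cfg_path)
        outdir = tmp_path / "results"
        r = runner.invoke(cli_main, ["run", "--config", str(cfg_path),
                                     "--out", str(outdir)])
        assert r.exit_code == 0, r.output
        assert (outdir / "models.csv").exists()
        r = runner.invoke(cli_main, ["report", "--models", str(outdir / "models.csv")])
        assert r.exit_code == 0, r.output
        assert "estimate" in r.output

    def test_validation_error_exits_2(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.tsv"
        bad.write_text("cpg_id\ts1\ncg1\t0.5\n")  # no chromosome column
        r = runner.invoke(cli_main, ["qc", "--betas", str(bad),
                                     "--out", str(tmp_path / "o.tsv")])
        assert r.exit_code == 2
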