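"""Covariate screening, PC selection, association models, GATA1, BH, bivariate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dsclocks as d
from dsclocks.errors import ConfigurationError, DegenerateDataError

from conftest import make_cohort


def _sheet(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "ds": np.repeat([True, False], n // 2),
        "x_null": rng.normal(size=n),
        "pc1": rng.normal(size=n),
        "pc2": rng.normal(size=n),
        "pc3": rng.normal(size=n),
    }, index=[f"s{i}" for i in range(n)])


class TestSelectCovariates:
    def test_perfect_predictor_retained(self):
        sheet = _sheet()
        outcome = sheet["x_null"] * 1.0
        kept = d.select_covariates(["x_null"], outcome, sheet)
        assert kept == ["x_null"]

    def test_constant_candidate_skipped_with_warning(self):
        sheet = _sheet()
        sheet["const"] = 1.0
        outcome = pd.Series(np.random.default_rng(1).normal(size=len(sheet)),
                            index=sheet.index)
        with pytest.warns(UserWarning, match="constant"):
            kept = d.select_covariates(["const"], outcome, sheet)
        assert kept == []

    def test_null_covariate_usually_excluded(self):
        # univariable p < 0.2 keeps an independent covariate ~20% of the time
        excluded = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            sheet = pd.DataFrame({"z": rng.normal(size=500)},
                                 index=[f"s{i}" for i in range(500)])
            outcome = pd.Series(rng.normal(size=500), index=sheet.index)
            if not d.select_covariates(["z"], outcome, sheet):
                excluded += 1
        assert excluded / reps >= 0.75


class TestSelectNumPCs:
    def test_outcome_equal_to_pc1_selects_at_least_one(self):
        sheet = _sheet()
        sel = d.select_num_pcs(sheet["pc1"] * 1.0, ["pc1", "pc2", "pc3"], sheet)
        assert sel.n_pcs >= 1
        assert sel.table.loc[1, "lrt_p"] < 1e-6

    def test_independent_outcome_mostly_selects_zero(self):
        zeros = 0
        reps = 30
        for rep in range(reps):
            sheet = _sheet(seed=200 + rep)
            outcome = pd.Series(
                np.random.default_rng(500 + rep).normal(size=len(sheet)),
                index=sheet.index,
            )
            sel = d.select_num_pcs(outcome, ["pc1", "pc2", "pc3"], sheet)
            zeros += sel.n_pcs == 0
        assert zeros / reps >= 0.6

    def test_max_pcs_capped_with_warning(self):
        sheet = _sheet()
        with pytest.warns(UserWarning, match="capped"):
            sel = d.select_num_pcs(sheet["pc1"] * 1.0, ["pc1", "pc2"], sheet, max_pcs=10)
        assert sel.table["k"].max() == 2


class TestModelSpecValidation:
    def test_clock_outcome_requires_age(self):
        with pytest.raises(ConfigurationError, match="chronological age"):
            d.ModelSpec(outcome="clock", covariates=("sex",))

    def test_dnamaa_must_not_adjust_for_age(self):
        with pytest.raises(ConfigurationError, match="must not adjust"):
            d.ModelSpec(outcome="dnamaa", covariates=("chron_age_days",))

    def test_granulocytes_never_a_covariate(self):
        with pytest.raises(ConfigurationError, match="Gran"):
            d.ModelSpec(outcome="dnamaa", covariates=("Gran",))


class TestFitModel:
    def test_recovers_injected_ds_offset_at_zero_noise(self, zero_noise_cohort):
        cfg, clocks, _, betas, sheet, _, _ = zero_noise_cohort
        cohort = make_cohort(seed=5, gata1_fraction_ds=0.0)
        cfg, clocks, _, betas, sheet, _, _ = cohort
        cv = d.compute_clock(betas, clocks[0])
        spec = d.ModelSpec(outcome="clock", covariates=("chron_age_days",))
        res = d.fit_model(spec, sheet, cv.values)
        assert res.estimate == pytest.approx(cfg.ds_clock_offset_years, abs=1e-8)

    def test_dnamaa_and_clock_models_agree_at_zero_noise(self):
        cfg, clocks, _, betas, sheet, _, _ = make_cohort(seed=13, gata1_fraction_ds=0.0)
        cv = d.compute_clock(betas, clocks[0])
        line = d.fit_reference_line(cv, sheet["chron_age_days"], ~sheet["ds"])
        aa = d.compute_dnamaa(cv, sheet["chron_age_days"], line)
        res_clock = d.fit_model(
            d.ModelSpec(outcome="clock", covariates=("chron_age_days",)), sheet, cv.values
        )
        res_aa = d.fit_model(d.ModelSpec(outcome="dnamaa"), sheet, aa.residuals)
        assert abs(res_clock.estimate - res_aa.estimate) < 1e-6

    def test_high_nrbc_exclusion_cannot_flip_clock_injected_sign(self):
        cfg, clocks, reference, betas, sheet, _, _ = make_cohort(
            seed=19, gata1_fraction_ds=0.0, high_nrbc_fraction_ds=0.3
        )
        cv = d.compute_clock(betas, clocks[0])
        props = d.deconvolve(betas, reference)
        base = d.fit_model(
            d.ModelSpec(outcome="clock", covariates=("chron_age_days",)),
            sheet, cv.values, props,
        )
        excl = d.fit_model(
            d.ModelSpec(outcome="clock", covariates=("chron_age_days",),
                        subset_rule="exclude_high_nrbc"),
            sheet, cv.values, props,
        )
        assert np.sign(base.estimate) == np.sign(excl.estimate) == 1.0
        assert excl.n_used < base.n_used

    def test_collinear_design_names_offender(self):
        sheet = _sheet()
        sheet["dup"] = sheet["pc1"]
        outcome = pd.Series(np.random.default_rng(0).normal(size=len(sheet)),
                            index=sheet.index)
        spec = d.ModelSpec(outcome="dnamaa", covariates=("pc1", "dup"))
        with pytest.raises(DegenerateDataError, match="dup"):
            d.fit_model(spec, sheet, outcome)

    def test_missing_covariates_reduce_n_used(self):
        sheet = _sheet()
        sheet.loc[sheet.index[:10], "pc1"] = np.nan
        outcome = pd.Series(np.random.default_rng(0).normal(size=len(sheet)),
                            index=sheet.index)
        res = d.fit_model(d.ModelSpec(outcome="dnamaa", covariates=("pc1",)),
                          sheet, outcome)
        assert res.n_used == len(sheet) - 10

    def test_single_group_subset_rejected(self):
        sheet = _sheet()
        sheet["gata1_status"] = np.where(sheet["ds"], 1.0, np.nan)  # no DS wildtype
        outcome = pd.Series(np.random.default_rng(0).normal(size=len(sheet)),
                            index=sheet.index)
        spec = d.ModelSpec(outcome="dnamaa", subset_rule="gata1_wildtype_plus_nonDS")
        with pytest.raises(DegenerateDataError, match="single DS group"):
            d.fit_model(spec, sheet, outcome)


class TestGATA1Models:
    def test_vaf_slope_recovered_over_reps(self):
        covered, estimates = 0, []
        reps = 15
        for rep in range(reps):
            cfg, clocks, reference, betas, sheet, _, _ = make_cohort(
                seed=300 + rep, n_ds=220, n_non_ds=60,
                noise_sd_clock_years=0.07, sequenced_fraction_ds=1.0,
                gata1_fraction_ds=0.25, high_nrbc_fraction_ds=0.0,
            )
            cv = d.compute_clock(betas, clocks[0])
            props = d.deconvolve(betas, reference)
            _, vaf_res = d.fit_gata1_models(sheet, cv.values, props, covariates=("sex",))
            estimates.append(vaf_res.estimate)
            covered += vaf_res.ci95[0] <= cfg.gata1_vaf_clock_slope <= vaf_res.ci95[1]
        assert abs(np.mean(estimates) - 1.78) < 0.1
        assert covered / reps >= 0.8

    def test_day_conversion_per_10pct_vaf(self):
        cfg, clocks, reference, betas, sheet, _, _ = make_cohort(
            seed=31, n_ds=150, n_non_ds=50, sequenced_fraction_ds=1.0,
            gata1_fraction_ds=0.3, high_nrbc_fraction_ds=0.0,
        )
        cv = d.compute_clock(betas, clocks[0])
        props = d.deconvolve(betas, reference)
        line = d.ReferenceLine(-0.6, 0.001, "non-DS", 50, 1.0)
        _, vaf_res = d.fit_gata1_models(sheet, cv.values, props, line=line)
        assert vaf_res.aa_days == pytest.approx(vaf_res.estimate * 0.1 / 0.001)

    def test_all_wildtype_errors_informatively(self):
        _, clocks, reference, betas, sheet, _, _ = make_cohort(
            seed=37, sequenced_fraction_ds=1.0, gata1_fraction_ds=0.0
        )
        cv = d.compute_clock(betas, clocks[0])
        with pytest.raises(DegenerateDataError, match="constant"):
            d.fit_gata1_models(sheet, cv.values, covariates=(),
                               include_cell_props=False)


class TestBenjaminiHochberg:
    def test_hand_checked_vector(self):
        adj = d.bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=12))
    def test_monotone_in_inputs(self, pvals):
        adj = d.bh_adjust(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)

    def test_constant_vectors_are_fixed_points(self):
        # the step-up correction is not idempotent in general; flat adjusted
        # vectors are its fixed points
        flat = np.full(5, 0.04)
        assert np.allclose(d.bh_adjust(flat), flat)


class TestBivariate:
    def test_identical_groups_give_null_statistics(self):
        n = 40
        sheet = pd.DataFrame({
            "ds": [True, False] * (n // 2),
            "chron_age_days": np.repeat([250.0, 260.0], n // 2),
            "birthweight_g": np.repeat([3000.0, 3100.0], n // 2),
        }, index=[f"s{i}" for i in range(n)])
        rep = d.bivariate_tests(sheet, continuous=("chron_age_days", "birthweight_g"),
                                categorical=())
        assert (rep.tests["p_value"] > 0.9).all()
        assert np.allclose(rep.tests["statistic"], 0.0, atol=1e-9)

    def test_spearman_clock_age_correlation_in_plausible_range(self):
        _, clocks, _, betas, sheet, _, _ = make_cohort(
            seed=23, n_ds=200, n_non_ds=300, noise_sd_clock_years=0.07,
        )
        cv = d.compute_clock(betas, clocks[0])
        rep = d.bivariate_tests(sheet, clocks={"sb": cv})
        row = rep.tests.query("variable == 'sb vs chron_age [non-DS]'").iloc[0]
        assert 0.05 < row["statistic"] < 0.45  # study reported r ~ 0.14-0.18

    def test_small_group_skipped_and_flagged(self):
        sheet = pd.DataFrame({
            "ds": [True] + [False] * 10,
            "chron_age_days": np.arange(11, dtype=float),
        }, index=[f"s{i}" for i in range(11)])
        rep = d.bivariate_tests(sheet, continuous=("chron_age_days",), categorical=())
        assert any("chron_age_days" in s[0] for s in rep.skipped)

    def test_three_level_t21_comparison_with_bh(self):
        _, clocks, _, betas, sheet, bins, truth = make_cohort(
            seed=29, n_ds=80, n_non_ds=80, noise_sd_clock_years=0.05,
            mosaic_fraction_values=(0.3, 0.35, 0.4),
        )
        cv = d.compute_clock(betas, clocks[0])
        groups = truth.t21_class.map({"full": "full", "mosaic": "mosaic", "none": "non-DS"})
        rep = d.bivariate_tests(sheet, clocks={"sb": cv}, groups=groups)
        assert (rep.tests.query("test == 'kruskal'")["p_value"] < 0.05).all()
        pair = rep.pairwise.query("variable == 'sb'")
        assert len(pair) == 3
        assert (pair["p_bh"] >= pair["p_raw"] - 1e-12).all()
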