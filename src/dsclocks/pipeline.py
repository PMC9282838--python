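"""End-to-end pipeline driver: QC -> clocks -> deconvolution -> CNV ->
age acceleration -> association models -> report.

The driver either consumes files (betas TSV, sample sheet CSV, bin table CSV,
reference CSV, clock coefficient CSVs) or, in simulation mode, generates a
synthetic cohort from a :class:`~dsclocks.simulate.SimulationConfig`.  All
stages are deterministic given the inputs and the seed; re-running a config
reproduces outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .acceleration import (
    DNAmAAVector,
    ReferenceLine,
    compute_dnamaa,
    estimate_to_days,
    fit_reference_line,
    gestational_dnamaa,
)
from .clocks import (
    TRANSFORM_CALIBRATED,
    ClockDefinition,
    ClockValues,
    compute_clock,
    impute_missing_clock_cpgs,
    load_clock,
    restrict_clock,
)
from .cnv import CALL_FULL, CALL_MOSAIC, T21Calls, chr21_medians, classify_t21
from .containers import BetaMatrix
from .deconvolution import (
    CellProportions,
    CellReference,
    compare_cell_props,
    deconvolve,
)
from .errors import DegenerateDataError, ValidationError
from .models import (
    ModelResult,
    ModelSpec,
    bivariate_tests,
    fit_gata1_models,
    fit_model,
    select_covariates,
    select_num_pcs,
)
from .qc import QCReport, qc_filter
from .simulate import SimulationConfig, default_clock_set, generate_cell_reference, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for one pipeline run.

    Either the four input paths (plus clock files) are set, or ``simulate``
    holds :class:`SimulationConfig` keyword arguments and inputs are
    generated.  Round-trips losslessly through YAML.
    """

    betas_path: str | None = None
    sheet_path: str | None = None
    bins_path: str | None = None
    reference_path: str | None = None
    detection_p_path: str | None = None
    clock_files: tuple = ()          # dicts: {"name", "path", "transform"}
    simulate: dict | None = None
    n_deconv_cpgs: int = 60
    detection_p_threshold: float = 0.01
    missingness_threshold: float = 0.15
    nrbc_threshold: float = 0.25
    full_t21_threshold: float = 0.2
    sd_multiplier: float = 2.0
    covariate_screen_p: float = 0.2
    max_pcs: int = 10
    seed: int = 0
    round_day_slope: bool = False  # use slope rounded to 3 dp for day conversion

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("detection_p_threshold", 0, 1), ("missingness_threshold", 0, 1),
            ("nrbc_threshold", 0, 1), ("covariate_screen_p", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.sd_multiplier <= 0 or self.max_pcs < 0:
            raise ValidationError("sd_multiplier must be > 0 and max_pcs >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("clock_files",):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything one pipeline run computed."""

    qc_report: QCReport
    clock_values: dict            # name -> ClockValues (incl. restricted variants)
    proportions: CellProportions
    t21: T21Calls
    reference_lines: dict         # clock name -> ReferenceLine
    dnamaa: dict                  # clock name -> DNAmAAVector (non-DS anchor)
    ga_dnamaa: dict               # gestational clock name -> DNAmAAVector
    model_table: pd.DataFrame
    gata1_results: dict           # outcome -> (status ModelResult, vaf ModelResult|None)
    cell_prop_results: dict
    bivariate: object
    pc_selection: dict            # outcome -> PCSelection
    screened_covariates: dict
    report: str
    config_hash: str = ""
    seed: int = 0

    def report_hash(self) -> str:
        return hashlib.sha256(self.report.encode()).hexdigest()

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dio.write_clock_values(self.clock_values, outdir / "clocks.csv")
        dio.write_proportions(self.proportions, outdir / "cell_proportions.csv")
        dio.write_t21_calls(self.t21, outdir / "t21_calls.csv")
        dio.write_dnamaa({**self.dnamaa, **self.ga_dnamaa}, outdir / "dnamaa.csv")
        dio.write_model_table(self.model_table, outdir / "models.csv")
        dio.write_json(self.qc_report.to_dict(), outdir / "qc_report.json")
        (outdir / "report.txt").write_text(self.report)


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc
    logger.info("stage %s: done", name)


def _result_row(name: str, outcome: str, subset: str, res: ModelResult) -> dict:
    return {
        "model": name, "outcome": outcome, "exposure": res.term, "subset": subset,
        "estimate": res.estimate, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
        "p_value": res.p_value, "n_used": res.n_used, "aa_days": res.aa_days,
    }


def analyze_cohort(
    betas: BetaMatrix,
    sheet: pd.DataFrame,
    bins: pd.DataFrame,
    reference: CellReference,
    clocks,
    detection_p: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on an in-memory cohort."""
    config = config or PipelineConfig()
    clocks = list(clocks)

    with _stage("qc"):
        betas, qc_report = qc_filter(
            betas, detection_p,
            detection_p_threshold=config.detection_p_threshold,
            missingness_threshold=config.missingness_threshold,
        )
        sheet = sheet.loc[sheet.index.intersection(betas.sample_ids)]

    with _stage("clocks"):
        clock_values: dict[str, ClockValues] = {}
        for clock in clocks:
            imputed = impute_missing_clock_cpgs(betas, clock)
            clock_values[clock.name] = compute_clock(imputed, clock)
        calibrated = [c for c in clocks if c.transform == TRANSFORM_CALIBRATED]
        gestational = [c for c in clocks if c.transform != TRANSFORM_CALIBRATED]
        variants: dict[str, ClockDefinition] = {}
        if calibrated:
            main = calibrated[0]
            exclude = set(reference.cpg_ids) & set(main.cpg_ids)
            try:
                variant = restrict_clock(
                    main, exclude=exclude, betas=betas, exclude_chromosomes=["21"]
                )
            except ValidationError:
                variant = None  # nothing to exclude
            if variant is not None and variant.name != main.name:
                variants[variant.name] = variant
                imputed = impute_missing_clock_cpgs(betas, variant)
                clock_values[variant.name] = compute_clock(imputed, variant)

    with _stage("deconvolution"):
        props = deconvolve(betas, reference, nrbc_threshold=config.nrbc_threshold)

    with _stage("cnv"):
        medians = chr21_medians(bins)
        medians = medians.reindex(sheet.index).dropna()
        t21 = classify_t21(
            medians, sheet["ds"],
            full_threshold=config.full_t21_threshold,
            sd_multiplier=config.sd_multiplier,
        )

    with _stage("age-acceleration"):
        non_ds = ~sheet["ds"].astype(bool)
        lines: dict[str, ReferenceLine] = {}
        dnamaa: dict[str, DNAmAAVector] = {}
        for clock in calibrated + list(variants.values()):
            cv = clock_values[clock.name]
            line = fit_reference_line(cv, sheet["chron_age_days"], non_ds)
            lines[clock.name] = line
            dnamaa[clock.name] = compute_dnamaa(cv, sheet["chron_age_days"], line)
        ga_dnamaa: dict[str, DNAmAAVector] = {}
        for clock in gestational:
            ga_dnamaa[clock.name] = gestational_dnamaa(
                clock_values[clock.name], sheet["ga_days"], sheet["ds"]
            )

    with _stage("models"):
        rows = []
        pc_sel: dict = {}
        screened: dict = {}
        gata1_results: dict = {}
        pc_cols = [c for c in sheet.columns if c.startswith("pc")]
        if calibrated:
            main_name = calibrated[0].name
            main_cv = clock_values[main_name]
            line = lines[main_name]
            day_slope = round(line.slope, 3) if config.round_day_slope else line.slope
            day_line = ReferenceLine(line.intercept, day_slope, line.fit_group,
                                     line.n_fit, line.r_squared)
            outcomes = {
                "clock": (main_cv.values, ["sex", "chron_age_days", "birthweight_g", "batch"]),
                "dnamaa": (dnamaa[main_name].residuals, ["sex", "birthweight_g", "batch"]),
            }
            nonds_sheet = sheet[non_ds]
            for kind, (outcome, candidates) in outcomes.items():
                kept = select_covariates(
                    candidates, outcome, nonds_sheet, p_threshold=config.covariate_screen_p
                )
                if kind == "clock" and "chron_age_days" not in kept:
                    kept = ["chron_age_days"] + kept  # age stays in clock models
                sel = select_num_pcs(outcome, pc_cols, sheet, max_pcs=config.max_pcs)
                pc_sel[kind] = sel
                screened[kind] = kept
                covs = tuple(kept + pc_cols[: sel.n_pcs])
                model_plan = [
                    ("base", False, "all"),
                    ("full", True, "all"),
                    ("full_excl_high_nrbc", True, "exclude_high_nrbc"),
                    ("full_gata1_wildtype", True, "gata1_wildtype_plus_nonDS"),
                ]
                for name, with_props, subset in model_plan:
                    spec = ModelSpec(outcome=kind, exposure="ds", covariates=covs,
                                     subset_rule=subset, include_cell_props=with_props,
                                     name=f"{kind}:{name}")
                    res = fit_model(spec, sheet, outcome, props, line=day_line)
                    rows.append(_result_row(name, kind, subset, res))
                try:
                    gata1_results[kind] = fit_gata1_models(
                        sheet, outcome, props, line=day_line,
                        covariates=[c for c in covs if c != "chron_age_days"] or (),
                    )
                except DegenerateDataError as exc:
                    warnings.warn(f"GATA1 models skipped: {exc}", stacklevel=2)
                    gata1_results[kind] = (None, None)
            for vname in variants:
                vline = lines[vname]
                vday = ReferenceLine(
                    vline.intercept,
                    round(vline.slope, 3) if config.round_day_slope else vline.slope,
                    vline.fit_group, vline.n_fit, vline.r_squared,
                )
                covs = tuple(screened["clock"] + pc_cols[: pc_sel["clock"].n_pcs])
                spec = ModelSpec(outcome="clock", exposure="ds", covariates=covs,
                                 subset_rule="all", include_cell_props=True,
                                 name=f"clock_variant:{vname}")
                res = fit_model(spec, sheet, clock_values[vname].values, props, line=vday)
                rows.append(_result_row("full", f"clock[{vname}]", "all", res))
                covs_aa = tuple(screened["dnamaa"] + pc_cols[: pc_sel["dnamaa"].n_pcs])
                spec = ModelSpec(outcome="dnamaa", exposure="ds", covariates=covs_aa,
                                 subset_rule="all", include_cell_props=True,
                                 name=f"dnamaa_variant:{vname}")
                res = fit_model(spec, sheet, dnamaa[vname].residuals, props, line=vday)
                rows.append(_result_row("full", f"dnamaa[{vname}]", "all", res))
        for clock in gestational:
            covs = ("sex", "ga_days", "birthweight_g", "batch") + tuple(pc_cols[:config.max_pcs])
            spec = ModelSpec(outcome="gest_clock", exposure="ds", covariates=covs,
                             subset_rule="all", include_cell_props=True,
                             name=f"gest_clock:{clock.name}")
            res = fit_model(spec, sheet, clock_values[clock.name].values, props)
            rows.append(_result_row("full", f"gest_clock[{clock.name}]", "all", res))
            covs_aa = ("sex", "birthweight_g", "batch") + tuple(pc_cols[:config.max_pcs])
            spec = ModelSpec(outcome="gest_dnamaa", exposure="ds", covariates=covs_aa,
                             subset_rule="all", include_cell_props=True,
                             name=f"gest_dnamaa:{clock.name}")
            res = fit_model(spec, sheet, ga_dnamaa[clock.name].residuals, props)
            rows.append(_result_row("full", f"gest_dnamaa[{clock.name}]", "all", res))
        model_table = pd.DataFrame(rows)

    with _stage("cell-type-models"):
        cell_results = compare_cell_props(props, sheet, n_pcs=min(10, len(pc_cols)))

    with _stage("bivariate"):
        groups = t21.calls["call"].map({
            CALL_FULL: "full T21",
            CALL_MOSAIC: "mosaic/partial T21",
        }).fillna("non-DS")
        groups[~sheet["ds"].reindex(groups.index).astype(bool)] = "non-DS"
        main_clocks = {n: clock_values[n] for n in clock_values}
        bivar = bivariate_tests(sheet, clocks=main_clocks, dnamaa=dnamaa, groups=groups)

    report = format_report(model_table, lines, qc_report, t21)
    return PipelineResult(
        qc_report=qc_report, clock_values=clock_values, proportions=props, t21=t21,
        reference_lines=lines, dnamaa=dnamaa, ga_dnamaa=ga_dnamaa,
        model_table=model_table, gata1_results=gata1_results,
        cell_prop_results=cell_results, bivariate=bivar, pc_selection=pc_sel,
        screened_covariates=screened, report=report,
        config_hash=config.config_hash(), seed=config.seed,
    )


def format_report(model_table: pd.DataFrame, lines: dict, qc_report: QCReport,
                  t21: T21Calls) -> str:
    """Human-readable run summary with a Table-2-shaped association block."""
    out = ["dsclocks pipeline report", "=" * 24, ""]
    out.append(
        f"QC: removed {qc_report.n_cpgs_removed_detection} CpGs (detection p), "
        f"{qc_report.n_cpgs_removed_missingness} CpGs and "
        f"{qc_report.n_samples_removed} samples (missingness)."
    )
    n_mosaic = int((t21.calls["call"] == CALL_MOSAIC).sum())
    n_full = int((t21.calls["call"] == CALL_FULL).sum())
    out.append(
        f"CNV: {n_full} full T21, {n_mosaic} likely mosaic/partial "
        f"(DS cohort mean {t21.mean_ds:.3f}, SD {t21.sd_ds:.3f}, "
        f"non-DS max {t21.max_nonds:.3f})."
    )
    for name, line in lines.items():
        out.append(
            f"Reference line [{name}]: slope {line.slope:.6f}/day, "
            f"intercept {line.intercept:.4f}, n = {line.n_fit}, R2 = {line.r_squared:.3f}."
        )
    out.append("")
    out.append("DS association models (estimate [95% CI], p, AA days):")
    hdr = f"{'model':<24}{'outcome':<28}{'estimate (95% CI)':<30}{'p':<12}{'n':<7}{'AA days':<9}"
    out.append(hdr)
    out.append("-" * len(hdr))
    for _, r in model_table.iterrows():
        est = f"{r.estimate:.4f} ({r.ci_low:.4f}–{r.ci_high:.4f})"
        p = "<0.0001" if r.p_value < 1e-4 else f"{r.p_value:.3g}"
        days = "" if pd.isna(r.aa_days) else f"{r.aa_days:.1f}"
        out.append(f"{r.model:<24}{r.outcome:<28}{est:<30}{p:<12}{r.n_used:<7}{days:<9}")
    return "\n".join(out) + "\n"


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Load or simulate inputs per the config, run the analysis, write outputs."""
    detection_p = None
    if config.simulate is not None:
        with _stage("simulate"):
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim = SimulationConfig(**sim_kwargs)
            reference = generate_cell_reference(config.n_deconv_cpgs, sim.seed + 104729)
            clocks = default_clock_set(sim.seed)
            betas, sheet, bins, _truth = generate_cohort(sim, clocks, reference)
    else:
        with _stage("load"):
            needed = {"betas_path": config.betas_path, "sheet_path": config.sheet_path,
                      "bins_path": config.bins_path, "reference_path": config.reference_path}
            missing = [k for k, v in needed.items() if not v]
            if missing:
                raise ValidationError(f"config missing input paths: {missing}")
            betas = BetaMatrix.read_tsv(config.betas_path)
            sheet = dio.read_sample_sheet(config.sheet_path)
            bins = dio.read_bins(config.bins_path)
            reference = CellReference.read_csv(config.reference_path)
            clocks = [
                load_clock(spec["path"], name=spec.get("name"),
                           transform=spec.get("transform", TRANSFORM_CALIBRATED))
                for spec in config.clock_files
            ]
            if not clocks:
                raise ValidationError("no clock coefficient files configured")
            if config.detection_p_path:
                detection_p = pd.read_csv(config.detection_p_path, sep="\t", index_col=0)

    result = analyze_cohort(betas, sheet, bins, reference, clocks,
                            detection_p=detection_p, config=config)
    if outdir is not None:
        result.write(outdir)
    return result
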