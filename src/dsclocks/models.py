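"""Inferential layer: covariate screening, PC selection, association models.

All fits are ordinary least squares (statsmodels) with Wald 95% confidence
intervals from the t distribution.  Effect estimates for clock-scale outcomes
are additionally expressed as days of age acceleration via the non-DS
reference slope.  Granulocytes are never entered as a covariate (the seven
proportions sum to one; dropping the largest class avoids collinearity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .acceleration import ReferenceLine, estimate_to_days
from .deconvolution import CELL_TYPES, REFERENCE_CELL
from .errors import ConfigurationError, DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

COVARIATE_SCREEN_P = 0.2
P_FLOOR_DISPLAY = 1e-4  # "p < 0.0001" formatting rule; raw p is always stored

OUTCOME_KINDS = ("clock", "dnamaa", "gest_clock", "gest_dnamaa", "cell_prop")
SUBSET_RULES = ("all", "exclude_high_nrbc", "gata1_wildtype_plus_nonDS", "ds_only")

CELL_COVARIATES = tuple(c for c in CELL_TYPES if c != REFERENCE_CELL)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one association model."""

    outcome: str                      # one of OUTCOME_KINDS
    exposure: str = "ds"
    covariates: tuple = ()
    subset_rule: str = "all"
    include_cell_props: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_KINDS:
            raise ConfigurationError(f"unknown outcome kind '{self.outcome}'")
        if self.subset_rule not in SUBSET_RULES:
            raise ConfigurationError(f"unknown subset rule '{self.subset_rule}'")
        has_chron = "chron_age_days" in self.covariates
        if self.outcome == "clock" and not has_chron:
            raise ConfigurationError("clock outcome requires chronological age as covariate")
        if self.outcome in ("dnamaa", "gest_dnamaa") and has_chron:
            raise ConfigurationError("age-acceleration outcomes must not adjust for age")
        if self.outcome == "gest_clock" and has_chron:
            raise ConfigurationError("gestational clocks adjust for GA, not chronological age")
        if REFERENCE_CELL in self.covariates:
            raise ConfigurationError(f"{REFERENCE_CELL} proportion is never a covariate")


@dataclass
class ModelResult:
    """Estimate, uncertainty and day-scale conversion for one exposure term."""

    label: str
    term: str
    estimate: float
    ci95: tuple
    p_value: float
    n_used: int
    aa_days: float | None = None
    fit: object = field(default=None, repr=False)

    @property
    def p_display(self) -> str:
        return "<0.0001" if self.p_value < P_FLOOR_DISPLAY else f"{self.p_value:.4g}"

    def summary(self) -> str:
        days = "" if self.aa_days is None else f", AA {self.aa_days:.1f} days"
        return (
            f"{self.label}: {self.term} = {self.estimate:.4f} "
            f"({self.ci95[0]:.4f}–{self.ci95[1]:.4f}), p {self.p_display}, "
            f"n = {self.n_used}{days}"
        )


@dataclass
class BivariateReport:
    """Univariate group comparisons plus BH-adjusted pairwise tests."""

    tests: pd.DataFrame         # variable, test, statistic, p_value
    pairwise: pd.DataFrame      # variable, group_a, group_b, p_raw, p_bh
    skipped: list = field(default_factory=list)


def _encode(frame: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns: bools -> 0/1, categoricals -> drop-first dummies."""
    pieces = []
    for col in frame.columns:
        s = frame[col]
        if s.dtype == bool:
            pieces.append(s.astype(float))
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            pieces.append(dummies)
        else:
            pieces.append(s.astype(float))
    return pd.concat(pieces, axis=1)


def _name_collinear(X: pd.DataFrame) -> list:
    """Columns linearly dependent on their predecessors (with intercept)."""
    cols = []
    base = np.ones((len(X), 1))
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)[:, None]
        coef, *_ = np.linalg.lstsq(base, v, rcond=None)
        resid = v - base @ coef
        scale = max(float(np.abs(v).max()), 1.0)
        if float(np.abs(resid).max()) < 1e-8 * scale:
            cols.append(col)
        else:
            base = np.hstack([base, v])
    return cols


def fit_ols_result(
    outcome: pd.Series,
    exposure: str,
    covariates,
    sheet: pd.DataFrame,
    props: pd.DataFrame | None = None,
    line: ReferenceLine | None = None,
    label: str = "",
    subset_index=None,
    days_scale: float = 1.0,
) -> ModelResult:
    """OLS of an outcome on an exposure plus covariates over complete cases.

    ``props`` (sample-by-cell-type proportions) are joined onto the sample
    sheet so cell types may appear among the covariates.  ``days_scale``
    rescales the day conversion (0.1 for per-10%-VAF effects).
    """
    data = sheet.copy()
    if props is not None:
        data = data.join(props, how="left")
    cols = [exposure] + list(covariates)
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValidationError(f"columns absent from sample sheet: {missing_cols}")

    idx = outcome.dropna().index.intersection(data.index)
    if subset_index is not None:
        idx = idx.intersection(pd.Index(subset_index))
    frame = data.loc[idx, cols]
    complete = frame.notna().all(axis=1)
    frame = frame[complete]
    y = outcome.loc[frame.index].to_numpy(dtype=float)
    n_used = len(frame)
    if n_used < len(cols) + 2:
        raise DegenerateDataError(
            f"model '{label}': only {n_used} complete cases for {len(cols)} terms"
        )

    X = _encode(frame)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)]))
    if rank < X.shape[1] + 1:
        bad = _name_collinear(X)
        raise DegenerateDataError(
            f"model '{label}': collinear design, offending columns {bad}"
        )
    exposure_col = exposure if exposure in X.columns else next(
        c for c in X.columns if c.startswith(f"{exposure}_")
    )
    res = sm.OLS(y, sm.add_constant(X)).fit()
    est = float(res.params[exposure_col])
    ci = res.conf_int().loc[exposure_col]
    aa_days = None
    if line is not None:
        if line.slope > 0:
            aa_days = estimate_to_days(est, line.slope) * days_scale
        else:
            warnings.warn(
                f"model '{label}': reference slope {line.slope:.2g} not positive; "
                "day conversion undefined", stacklevel=2,
            )
    return ModelResult(
        label=label or exposure,
        term=exposure_col,
        estimate=est,
        ci95=(float(ci[0]), float(ci[1])),
        p_value=float(res.pvalues[exposure_col]),
        n_used=n_used,
        aa_days=aa_days,
        fit=res,
    )


def apply_subset(rule: str, sheet: pd.DataFrame, high_nrbc: pd.Series | None = None) -> pd.Index:
    """Sample index retained by a sensitivity-subset rule."""
    if rule == "all":
        return sheet.index
    if rule == "exclude_high_nrbc":
        if high_nrbc is None:
            raise ValidationError("exclude_high_nrbc subset requires nRBC flags")
        flags = high_nrbc.reindex(sheet.index).fillna(False).astype(bool)
        return sheet.index[~flags]
    if rule == "gata1_wildtype_plus_nonDS":
        ds = sheet["ds"].astype(bool)
        wildtype = sheet["gata1_status"].eq(0)
        return sheet.index[(~ds) | (ds & wildtype)]
    if rule == "ds_only":
        return sheet.index[sheet["ds"].astype(bool)]
    raise ConfigurationError(f"unknown subset rule '{rule}'")


def fit_model(
    spec: ModelSpec,
    sheet: pd.DataFrame,
    outcome: pd.Series,
    props=None,
    line: ReferenceLine | None = None,
) -> ModelResult:
    """Fit one ModelSpec; the subset rule is applied before fitting."""
    prop_df = getattr(props, "proportions", props)
    high_nrbc = getattr(props, "high_nrbc", None)
    covariates = list(spec.covariates)
    if spec.include_cell_props:
        if prop_df is None:
            raise ValidationError("spec includes cell proportions but none supplied")
        covariates += [c for c in CELL_COVARIATES if c not in covariates]
    idx = apply_subset(spec.subset_rule, sheet, high_nrbc)
    if spec.exposure == "ds":
        ds = sheet.loc[idx, "ds"].astype(bool)
        if ds.all() or (~ds).any() is False or not ds.any():
            raise DegenerateDataError(
                f"subset '{spec.subset_rule}' leaves a single DS group; model undefined"
            )
    result = fit_ols_result(
        outcome=outcome,
        exposure=spec.exposure,
        covariates=covariates,
        sheet=sheet,
        props=prop_df,
        line=line if spec.outcome in ("clock", "dnamaa") else None,
        label=spec.name or f"{spec.outcome}~{spec.exposure}[{spec.subset_rule}]",
        subset_index=idx,
    )
    return result


def select_covariates(candidates, outcome: pd.Series, sheet_reference: pd.DataFrame,
                      p_threshold: float = COVARIATE_SCREEN_P) -> list:
    """Screen candidates by univariable regression in the reference group.

    Keeps every candidate whose univariable model on the outcome attains
    p < ``p_threshold`` (overall F test, so categorical candidates are screened
    as a block).  Constant candidates are skipped with a warning.
    """
    if not len(candidates):
        raise ValidationError("no candidate covariates supplied")
    kept = []
    for cand in candidates:
        if cand not in sheet_reference.columns:
            raise ValidationError(f"candidate '{cand}' not in sample sheet")
        sub = pd.concat([outcome.rename("__y"), sheet_reference[cand]], axis=1).dropna()
        if sub[cand].nunique() < 2:
            warnings.warn(f"covariate '{cand}' is constant; skipped", stacklevel=2)
            continue
        X = _encode(sub[[cand]])
        res = sm.OLS(sub["__y"].to_numpy(dtype=float), sm.add_constant(X)).fit()
        p = float(res.f_pvalue)
        if p < p_threshold:
            kept.append(cand)
    return kept


@dataclass
class PCSelection:
    """AIC-selected PC count with the nested-model comparison table."""

    n_pcs: int
    table: pd.DataFrame  # k, aic, llf, lrt_p


def select_num_pcs(outcome: pd.Series, pc_columns, sheet: pd.DataFrame,
                   max_pcs: int = 10) -> PCSelection:
    """Smallest k minimising AIC among nested models PC1..PCk (k = 0..max).

    Ties break toward smaller k; likelihood-ratio p values against the
    (k-1)-PC model are reported alongside.
    """
    pc_columns = list(pc_columns)
    if max_pcs > len(pc_columns):
        warnings.warn(
            f"max_pcs={max_pcs} exceeds the {len(pc_columns)} available PC columns; capped",
            stacklevel=2,
        )
        max_pcs = len(pc_columns)
    data = pd.concat([outcome.rename("__y"), sheet[pc_columns]], axis=1).dropna()
    y = data["__y"].to_numpy(dtype=float)
    rows = []
    prev_llf = None
    for k in range(max_pcs + 1):
        if k == 0:
            X = np.ones((len(y), 1))
        else:
            X = sm.add_constant(data[pc_columns[:k]].to_numpy(dtype=float))
        res = sm.OLS(y, X).fit()
        lrt_p = np.nan
        if prev_llf is not None:
            stat = 2.0 * (res.llf - prev_llf)
            lrt_p = float(scipy.stats.chi2.sf(max(stat, 0.0), df=1))
        rows.append({"k": k, "aic": float(res.aic), "llf": float(res.llf), "lrt_p": lrt_p})
        prev_llf = res.llf
    table = pd.DataFrame(rows)
    best = int(table.loc[table["aic"].idxmin(), "k"])  # idxmin -> first (smallest k) on ties
    return PCSelection(n_pcs=best, table=table)


def fit_gata1_models(
    sheet: pd.DataFrame,
    outcome: pd.Series,
    props=None,
    line: ReferenceLine | None = None,
    covariates=(),
    include_cell_props: bool = True,
    min_positive: int = 3,
):
    """GATA1 mutation-status and VAF models within sequenced DS newborns.

    The status model contrasts mutation-positive vs wildtype DS newborns; the
    VAF model is fitted among mutation-positive newborns only, and its day
    conversion is expressed per 10% VAF (estimate x 0.1 / slope).
    Returns (status_result, vaf_result_or_None).
    """
    prop_df = getattr(props, "proportions", props)
    ds = sheet["ds"].astype(bool)
    sequenced = sheet.index[ds & sheet["gata1_status"].notna()]
    if not len(sequenced):
        raise DegenerateDataError("no sequenced DS samples")
    status = sheet.loc[sequenced, "gata1_status"]
    if status.nunique() < 2:
        raise DegenerateDataError(
            "GATA1 status is constant among sequenced DS newborns; status model undefined"
        )
    covs = list(covariates)
    if include_cell_props:
        if prop_df is None:
            raise ValidationError("cell proportions requested but none supplied")
        covs += [c for c in CELL_COVARIATES if c not in covs]
    status_res = fit_ols_result(
        outcome, "gata1_status", covs, sheet, props=prop_df, line=line,
        label="gata1_status", subset_index=sequenced,
    )
    positives = sequenced[status.astype(float) > 0]
    vaf_res = None
    if len(positives) < min_positive:
        warnings.warn(
            f"only {len(positives)} GATA1-positive samples; VAF model skipped",
            stacklevel=2,
        )
    else:
        try:
            vaf_res = fit_ols_result(
                outcome, "gata1_vaf", covs, sheet, props=prop_df, line=line,
                label="gata1_vaf_per_10pct" if line is not None else "gata1_vaf",
                subset_index=positives, days_scale=0.1,
            )
        except DegenerateDataError as exc:
            warnings.warn(f"VAF model skipped: {exc}", stacklevel=2)
    return status_res, vaf_res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]



def _series_of(obj) -> pd.Series:
    """Clock values, DNAmAA residuals, or a plain Series, uniformly."""
    if hasattr(obj, "residuals"):
        return obj.residuals
    if hasattr(obj, "clock_name") and hasattr(obj, "values"):
        return obj.values
    return pd.Series(obj)

def bivariate_tests(
    sheet: pd.DataFrame,
    clocks: dict | None = None,
    dnamaa: dict | None = None,
    groups: pd.Series | None = None,
    continuous=("ga_days", "collection_age_hours", "chron_age_days", "birthweight_g"),
    categorical=("sex", "all_status"),
) -> BivariateReport:
    """Study-plan univariate comparisons.

    Two-group (DS vs non-DS): Student's t for continuous variables and clock
    outputs, chi-squared for categoricals, Spearman correlation of each clock
    with chronological age within group.  If a multi-level ``groups`` label is
    given (e.g. full T21 / likely mosaic / non-DS), clock and DNAmAA variables
    additionally get a Kruskal-Wallis test with BH-adjusted pairwise Wilcoxon
    rank-sum comparisons.
    """
    clocks = clocks or {}
    dnamaa = dnamaa or {}
    ds = sheet["ds"].astype(bool)
    rows, pair_rows, skipped = [], [], []

    def two_group(name, series):
        s = series.reindex(sheet.index) if len(series.index.intersection(sheet.index)) else series
        a = s[ds.reindex(s.index).fillna(False)].dropna()
        b = s[~ds.reindex(s.index).fillna(True)].dropna()
        if len(a) < 2 or len(b) < 2:
            skipped.append((name, "t-test", "group n < 2"))
            return
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        rows.append({"variable": name, "test": "t", "statistic": float(stat), "p_value": float(p)})

    for var in continuous:
        if var in sheet.columns:
            two_group(var, sheet[var])
    for name, cv in {**clocks, **dnamaa}.items():
        two_group(name, _series_of(cv))

    for var in categorical:
        if var not in sheet.columns:
            continue
        tab = pd.crosstab(ds, sheet[var])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            skipped.append((var, "chi2", "degenerate contingency table"))
            continue
        stat, p, _, _ = scipy.stats.chi2_contingency(tab)
        rows.append({"variable": var, "test": "chi2", "statistic": float(stat), "p_value": float(p)})

    if "chron_age_days" in sheet.columns:
        for name, cv in clocks.items():
            vals = _series_of(cv)
            for label, mask in (("DS", ds), ("non-DS", ~ds)):
                sub = pd.concat(
                    [vals.rename("clock"), sheet["chron_age_days"]], axis=1
                ).loc[mask.reindex(vals.index).fillna(False)].dropna()
                if len(sub) < 3:
                    skipped.append((name, f"spearman[{label}]", "n < 3"))
                    continue
                rho, p = scipy.stats.spearmanr(sub["clock"], sub["chron_age_days"])
                rows.append({
                    "variable": f"{name} vs chron_age [{label}]",
                    "test": "spearman", "statistic": float(rho), "p_value": float(p),
                })

    if groups is not None:
        for name, cv in {**clocks, **dnamaa}.items():
            vals = _series_of(cv)
            df = pd.concat([vals.rename("v"), groups.rename("g")], axis=1).dropna()
            levels = [lv for lv in df["g"].unique()]
            samples = {lv: df.loc[df["g"] == lv, "v"] for lv in levels}
            usable = {lv: s for lv, s in samples.items() if len(s) >= 2}
            if len(usable) < 2:
                skipped.append((name, "kruskal", "fewer than 2 usable groups"))
                continue
            stat, p = scipy.stats.kruskal(*usable.values())
            rows.append({"variable": name, "test": "kruskal", "statistic": float(stat),
                         "p_value": float(p)})
            pairs, praw = [], []
            keys = sorted(usable)
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    stat_w, p_w = scipy.stats.mannwhitneyu(
                        usable[keys[i]], usable[keys[j]], alternative="two-sided"
                    )
                    pairs.append((keys[i], keys[j]))
                    praw.append(p_w)
            p_bh = bh_adjust(praw)
            for (ga, gb), pr, pa in zip(pairs, praw, p_bh):
                pair_rows.append({"variable": name, "group_a": ga, "group_b": gb,
                                  "p_raw": float(pr), "p_bh": float(pa)})

    return BivariateReport(
        tests=pd.DataFrame(rows),
        pairwise=pd.DataFrame(pair_rows),
        skipped=skipped,
    )
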