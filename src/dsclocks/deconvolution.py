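"""Reference-based blood cell-type deconvolution.

Each sample's beta vector over the reference CpGs is projected onto the seven
cord-blood cell types (B, CD4T, CD8T, NK, Mono, Gran, nRBC) by nonnegative
least squares, and the solution is normalised to the unit simplex.  Newborns
whose nRBC proportion exceeds 25% are flagged: high erythroblast content
distorts genome-wide methylation and is handled as a sensitivity subset
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .containers import BetaMatrix
from .errors import DegenerateDataError, ValidationError

CELL_TYPES = ("B", "CD4T", "CD8T", "NK", "Mono", "Gran", "nRBC")
HIGH_NRBC_THRESHOLD = 0.25
REFERENCE_CELL = "Gran"  # dropped category in downstream regressions


@dataclass
class CellReference:
    """Mean beta profiles of the 7 reference cell types (cell x CpG)."""

    mean_betas: pd.DataFrame  # rows = cell types, columns = CpG ids

    def __post_init__(self) -> None:
        if sorted(self.mean_betas.index) != sorted(CELL_TYPES):
            raise ValidationError(
                f"reference rows must be a permutation of {CELL_TYPES}; got "
                f"{list(self.mean_betas.index)}"
            )
        if not self.mean_betas.columns.is_unique:
            raise ValidationError("duplicate CpG ids in cell reference")
        vals = self.mean_betas.to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
            raise ValidationError("reference mean betas must be in [0, 1]")
        if np.linalg.matrix_rank(vals) < len(CELL_TYPES):
            raise DegenerateDataError(
                "cell reference is rank-deficient; proportions are not identifiable"
            )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.mean_betas.columns

    def to_csv(self, path) -> None:
        long = self.mean_betas.stack().rename("mean_beta").reset_index()
        long.columns = ["cell_type", "cpg_id", "mean_beta"]
        long.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CellReference":
        df = pd.read_csv(path)
        need = {"cell_type", "cpg_id", "mean_beta"}
        if not need.issubset(df.columns):
            raise ValidationError(
                f"reference CSV needs columns {sorted(need)}; got {list(df.columns)}"
            )
        wide = df.pivot(index="cell_type", columns="cpg_id", values="mean_beta")
        wide = wide.reindex(list(CELL_TYPES))
        return cls(wide)


@dataclass
class CellProportions:
    """Per-sample simplex proportions with residual norms and high-nRBC flags."""

    proportions: pd.DataFrame  # rows = samples, columns = CELL_TYPES
    residual_norm: pd.Series
    high_nrbc: pd.Series


def deconvolve(betas: BetaMatrix, reference: CellReference,
               nrbc_threshold: float = HIGH_NRBC_THRESHOLD) -> CellProportions:
    """Constrained projection of each sample onto the cell reference.

    Solves ``min_w ||beta - R'w||^2 s.t. w >= 0`` per sample (R = cell-by-CpG
    reference), then normalises w to sum to 1.  The residual norm reported is
    that of the unnormalised NNLS solution.
    """
    missing = reference.cpg_ids.difference(betas.cpg_ids)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} reference CpGs missing from betas: {list(missing[:10])}"
        )
    A = reference.mean_betas.to_numpy(dtype=float).T  # CpG x cell
    block = betas.values.loc[reference.cpg_ids]
    if block.isna().to_numpy().any():
        raise ValidationError("missing betas at reference CpGs; run QC/imputation first")

    props = np.empty((betas.n_samples, len(CELL_TYPES)))
    resid = np.empty(betas.n_samples)
    for i, sample in enumerate(betas.sample_ids):
        w, rnorm = scipy.optimize.nnls(A, block[sample].to_numpy(dtype=float))
        total = w.sum()
        if total <= 0:
            raise DegenerateDataError(
                f"NNLS returned the zero vector for sample '{sample}'"
            )
        props[i] = w / total
        resid[i] = rnorm
    prop_df = pd.DataFrame(props, index=betas.sample_ids,
                           columns=list(reference.mean_betas.index))
    resid_s = pd.Series(resid, index=betas.sample_ids, name="residual_norm")
    flags = flag_high_nrbc(prop_df, nrbc_threshold)
    return CellProportions(proportions=prop_df, residual_norm=resid_s, high_nrbc=flags)


def flag_high_nrbc(proportions: pd.DataFrame, threshold: float = HIGH_NRBC_THRESHOLD) -> pd.Series:
    """True iff the nRBC proportion strictly exceeds the threshold (default 25%)."""
    return (proportions["nRBC"] > threshold).rename("high_nrbc")


def compare_cell_props(props: CellProportions, sheet: pd.DataFrame,
                       covariates=None, n_pcs: int = 10):
    """One linear model per cell type: proportion ~ DS + covariates.

    Default adjustment follows the study plan: sex, gestational age, collection
    age, birthweight, batch, and the first ``n_pcs`` ancestry PCs.  Returns a
    dict cell type -> ModelResult.
    """
    from .models import fit_ols_result  # local import to avoid a cycle

    if covariates is None:
        covariates = ["sex", "ga_days", "collection_age_hours", "birthweight_g",
                      "batch"] + [f"pc{i}" for i in range(1, n_pcs + 1)]
    results = {}
    for cell in CELL_TYPES:
        outcome = props.proportions[cell]
        results[cell] = fit_ols_result(
            outcome=outcome, exposure="ds", covariates=covariates, sheet=sheet,
            label=f"cellprop_{cell}",
        )
    return results
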