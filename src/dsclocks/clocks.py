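"""Epigenetic clock computation.

A clock is a linear predictor over CpG beta values — ``intercept + Σ w_j β_j``
— optionally passed through the calibrated age transform used by the adult
clocks (pan-tissue, skin & blood).  Gestational-age clocks (Haftorn, Knight,
Bohlin) return the linear predictor directly, in days.

The calibrated transform maps a linear predictor x to years as

    age(x) = (1 + A) * exp(x) - 1      for x < 0
    age(x) = (1 + A) * x + A           for x >= 0

with anchor ``A = adult_age = 20``: continuous, strictly increasing, equal to
A at x = 0.  Newborn samples live on the exponential branch, so predicted ages
lie in (-1, A).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import BetaMatrix
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

ADULT_AGE = 20.0
INTERCEPT_ID = "(Intercept)"

TRANSFORM_CALIBRATED = "calibrated-adult"
TRANSFORM_LINEAR_DAYS = "linear-days"
_TRANSFORMS = (TRANSFORM_CALIBRATED, TRANSFORM_LINEAR_DAYS)


@dataclass(frozen=True)
class ClockDefinition:
    """A named coefficient set plus its output transform.

    ``transform`` is ``calibrated-adult`` for age clocks (output in years) and
    ``linear-days`` for gestational clocks (output in days).
    """

    name: str
    intercept: float
    weights: pd.Series  # index = CpG ids, values = weights
    transform: str = TRANSFORM_CALIBRATED
    adult_age: float = ADULT_AGE

    def __post_init__(self) -> None:
        if len(self.weights) == 0:
            raise ValidationError(f"clock '{self.name}' has no CpG weights")
        if not self.weights.index.is_unique:
            raise ValidationError(f"clock '{self.name}' has duplicate CpG ids")
        if self.transform not in _TRANSFORMS:
            raise ValidationError(
                f"unknown transform '{self.transform}'; expected one of {_TRANSFORMS}"
            )

    @property
    def expected_n_cpgs(self) -> int:
        return len(self.weights)

    @property
    def cpg_ids(self) -> pd.Index:
        return self.weights.index

    @property
    def output_units(self) -> str:
        return "years" if self.transform == TRANSFORM_CALIBRATED else "days"


@dataclass
class ClockValues:
    """Per-sample clock output plus imputation bookkeeping."""

    values: pd.Series  # index = sample ids
    clock_name: str
    units: str
    n_imputed_cpgs: int = 0
    excluded_cpgs: frozenset = field(default_factory=frozenset)


def load_clock(path, name: str | None = None, transform: str = TRANSFORM_CALIBRATED) -> ClockDefinition:
    """Read a coefficient CSV with header (cpg_id, weight) and one intercept row.

    The intercept row uses the reserved id ``(Intercept)``. Duplicate CpG rows
    and non-numeric weights are rejected.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2 or cols[0] != "cpg_id" or cols[1] != "weight":
        raise ValidationError(
            f"clock file must have header 'cpg_id,weight'; got {cols}"
        )
    try:
        weights_all = df["weight"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric weight in clock file: {exc}") from None
    ids = df["cpg_id"].astype(str)
    is_int = ids == INTERCEPT_ID
    if is_int.sum() != 1:
        raise ValidationError(
            f"clock file must contain exactly one '{INTERCEPT_ID}' row; found {int(is_int.sum())}"
        )
    intercept = float(weights_all[is_int].iloc[0])
    cpg_ids = ids[~is_int]
    if cpg_ids.duplicated().any():
        dups = cpg_ids[cpg_ids.duplicated()].unique()
        raise ValidationError(f"duplicate CpG rows in clock file: {list(dups[:5])}")
    weights = pd.Series(weights_all[~is_int].to_numpy(), index=pd.Index(cpg_ids, name="cpg_id"))
    return ClockDefinition(
        name=name or str(path), intercept=intercept, weights=weights, transform=transform
    )


def inverse_age_transform(x, adult_age: float = ADULT_AGE):
    """Map the calibrated linear predictor back to years (vectorised)."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x < 0,
        (1.0 + adult_age) * np.exp(np.minimum(x, 0.0)) - 1.0,
        (1.0 + adult_age) * x + adult_age,
    )
    return out if out.ndim else float(out)


def forward_age_transform(age, adult_age: float = ADULT_AGE):
    """Inverse of :func:`inverse_age_transform`: years -> linear predictor.

    Defined for age > -1 (the transform's lower asymptote).
    """
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1.0):
        raise ValidationError("calibrated transform is undefined at or below -1 year")
    out = np.where(
        age < adult_age,
        np.log((1.0 + age) / (1.0 + adult_age)),
        (age - adult_age) / (1.0 + adult_age),
    )
    return out if out.ndim else float(out)


def impute_missing_clock_cpgs(
    betas: BetaMatrix, clock: ClockDefinition, method: str = "mean", knn_k: int = 10
) -> BetaMatrix:
    """Fill missing clock CpGs with each sample's mean over available clock CpGs.

    CpGs absent from the matrix entirely (e.g. 450K-only probes on an EPIC
    array) are appended; per-sample missing entries are filled likewise.
    ``method='knn'`` instead uses k-nearest-neighbour imputation across samples
    (scikit-learn), offered as a secondary path.  Non-clock CpGs are untouched.
    """
    clock_cpgs = clock.cpg_ids
    present = clock_cpgs.intersection(betas.cpg_ids)
    absent = clock_cpgs.difference(betas.cpg_ids)

    block = betas.values.reindex(clock_cpgs)  # absent CpGs become all-NaN rows
    available = block.notna().sum(axis=0)
    dead = available[available == 0]
    if len(dead):
        raise DegenerateDataError(
            f"no clock '{clock.name}' CpGs available for sample(s) "
            f"{list(dead.index[:5])}; cannot impute"
        )

    if method == "mean":
        sample_means = block.mean(axis=0, skipna=True)
        filled = block.fillna(sample_means)
    elif method == "knn":
        from sklearn.impute import KNNImputer

        imp = KNNImputer(n_neighbors=min(knn_k, max(1, betas.n_samples - 1)))
        # samples are observations, clock CpGs are features
        filled = pd.DataFrame(
            imp.fit_transform(block.T.to_numpy()).T,
            index=block.index,
            columns=block.columns,
        )
    else:
        raise ValidationError(f"unknown imputation method '{method}'")

    values = pd.concat([betas.values.drop(index=present), filled.loc[present]])
    chrom = betas.chromosome.copy()
    if len(absent):
        values = pd.concat([values, filled.loc[absent]])
        chrom = pd.concat([chrom, pd.Series("NA", index=absent)])
    # keep original CpG order, appended CpGs last
    order = betas.cpg_ids.append(absent)
    values = values.loc[order]
    n_filled = int(block.isna().to_numpy().sum())
    if n_filled:
        logger.info(
            "clock %s: imputed %d missing entries (%d CpGs absent from matrix)",
            clock.name, n_filled, len(absent),
        )
    return BetaMatrix(values, chrom.loc[order])


def compute_clock(betas: BetaMatrix, clock: ClockDefinition) -> ClockValues:
    """Apply a clock to an (already imputed) beta matrix.

    Per sample, the linear predictor is ``intercept + Σ_j w_j β_j`` over the
    clock's CpGs; calibrated clocks then pass it through
    :func:`inverse_age_transform`, gestational clocks return it unchanged
    (days).
    """
    missing = clock.cpg_ids.difference(betas.cpg_ids)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} clock '{clock.name}' CpGs missing from matrix "
            f"(e.g. {list(missing[:5])}); run impute_missing_clock_cpgs first"
        )
    block = betas.values.loc[clock.cpg_ids]
    if block.isna().to_numpy().any():
        raise ValidationError(
            f"clock '{clock.name}' CpGs contain missing values; impute first"
        )
    lp = clock.intercept + block.to_numpy().T @ clock.weights.to_numpy()
    if clock.transform == TRANSFORM_CALIBRATED:
        out = inverse_age_transform(lp, clock.adult_age)
    else:
        out = lp
    values = pd.Series(np.asarray(out, dtype=float), index=betas.sample_ids, name=clock.name)
    return ClockValues(values=values, clock_name=clock.name, units=clock.output_units)


def restrict_clock(
    clock: ClockDefinition,
    exclude=None,
    betas: BetaMatrix | None = None,
    exclude_chromosomes=None,
) -> ClockDefinition:
    """Drop CpGs from a clock's weight map (sensitivity-analysis variants).

    ``exclude`` is an explicit CpG-id set; ``exclude_chromosomes`` drops every
    clock CpG annotated to those chromosomes in ``betas`` (annotation
    required).  Excluded CpGs are removed, not imputed.  The variant is
    renamed ``<name>-excl<k>``.
    """
    exclude = set() if exclude is None else set(exclude)
    if exclude_chromosomes:
        if betas is None:
            raise ValidationError(
                "chromosome-based exclusion requires a beta matrix with annotation"
            )
        wanted = {str(c) for c in exclude_chromosomes}
        chrom = betas.chromosome
        on_chrom = [
            c for c in clock.cpg_ids
            if c in chrom.index and str(chrom.loc[c]) in wanted
        ]
        exclude.update(on_chrom)
    if not exclude:
        raise ValidationError("empty exclusion set")

    in_clock = exclude & set(clock.cpg_ids)
    stray = exclude - in_clock
    if stray:
        warnings.warn(
            f"{len(stray)} excluded CpGs not in clock '{clock.name}'; ignored",
            stacklevel=2,
        )
    if not in_clock:
        return clock
    kept = clock.weights.drop(index=list(in_clock))
    if len(kept) == 0:
        raise DegenerateDataError(
            f"exclusion removes every CpG of clock '{clock.name}'"
        )
    return replace(
        clock,
        name=f"{clock.name}-excl{len(in_clock)}",
        weights=kept,
    )
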