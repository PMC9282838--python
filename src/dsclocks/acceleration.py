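"""Epigenetic age acceleration (DNAmAA).

Age acceleration is a sample's deviation from the epigenetic age expected at
its chronological age (gestational age plus age at blood collection), where
"expected" is the ordinary least-squares line fitted in the non-DS reference
group only.  By construction the reference group's mean acceleration is zero.
Regression effect estimates on the clock scale are converted to days of
acceleration by dividing by the reference slope (clock units per day).

Gestational-age clocks use a different anchor: residuals from the model
clock ~ observed GA + DS status fitted on all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .clocks import ClockValues
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

ANCHOR_NONDS = "nonDS-chronological"
ANCHOR_GA_DS = "GA-adjusted-DS"


@dataclass(frozen=True)
class ReferenceLine:
    """OLS fit of a clock on chronological age within the reference group."""

    intercept: float
    slope: float  # clock units per day
    fit_group: str
    n_fit: int
    r_squared: float

    def predict(self, age_days):
        return self.intercept + self.slope * np.asarray(age_days, dtype=float)


@dataclass
class DNAmAAVector:
    """Per-sample residual acceleration in clock units."""

    residuals: pd.Series
    clock_name: str
    anchor: str
    n_excluded_missing: int = 0


def _clock_series(clock) -> pd.Series:
    return clock.values if isinstance(clock, ClockValues) else pd.Series(clock)


def fit_reference_line(
    clock, chron_age_days: pd.Series, reference_mask: pd.Series,
    fit_group: str = "non-DS",
) -> ReferenceLine:
    """OLS of clock output on chronological age over reference samples only."""
    values = _clock_series(clock)
    mask = reference_mask.reindex(values.index).fillna(False).astype(bool)
    age = chron_age_days.reindex(values.index)
    ok = mask & age.notna() & values.notna()
    if int(ok.sum()) < 3:
        raise DegenerateDataError(
            f"need >=3 reference samples with age; have {int(ok.sum())}"
        )
    x = age[ok].to_numpy(dtype=float)
    y = values[ok].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDataError("chronological age is constant in reference group")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ReferenceLine(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        fit_group=fit_group,
        n_fit=int(ok.sum()),
        r_squared=float(res.rsquared),
    )


def compute_dnamaa(clock, chron_age_days: pd.Series, line: ReferenceLine) -> DNAmAAVector:
    """Residual from the reference line for every sample (both groups).

    Samples with missing chronological age are excluded from the output with a
    logged count (they can enter neither fitting nor residuals).
    """
    values = _clock_series(clock)
    age = chron_age_days.reindex(values.index)
    ok = age.notna() & values.notna()
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("DNAmAA: excluded %d samples with missing age or clock value", n_excluded)
    resid = values[ok] - line.predict(age[ok])
    name = clock.clock_name if isinstance(clock, ClockValues) else str(values.name)
    return DNAmAAVector(
        residuals=resid.rename(f"dnamaa_{name}"),
        clock_name=name,
        anchor=ANCHOR_NONDS,
        n_excluded_missing=n_excluded,
    )


def estimate_to_days(estimate: float, slope: float) -> float:
    """Convert a clock-scale effect estimate to days of age acceleration.

    ``slope`` is the reference line's clock-units-per-day slope; applied to
    point estimates and CI bounds alike.
    """
    if not slope > 0:
        raise ValidationError(f"reference slope must be positive; got {slope}")
    return estimate / slope


def gestational_dnamaa(clock, obs_ga_days: pd.Series, ds_status: pd.Series) -> DNAmAAVector:
    """Residuals of a gestational clock on observed GA adjusted for DS status.

    Fitted on all samples with complete GA and DS status; OLS residuals sum to
    zero over the fitted set.
    """
    values = _clock_series(clock)
    ga = obs_ga_days.reindex(values.index)
    ds = ds_status.reindex(values.index)
    ok = ga.notna() & ds.notna() & values.notna()
    n_excluded = int((~ok).sum())
    if int(ok.sum()) < 3:
        raise DegenerateDataError("need >=3 samples with GA and DS status")
    X = np.column_stack([
        ga[ok].to_numpy(dtype=float),
        ds[ok].astype(float).to_numpy(),
    ])
    y = values[ok].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    name = clock.clock_name if isinstance(clock, ClockValues) else str(values.name)
    return DNAmAAVector(
        residuals=pd.Series(res.resid, index=values.index[ok], name=f"ga_dnamaa_{name}"),
        clock_name=name,
        anchor=ANCHOR_GA_DS,
        n_excluded_missing=n_excluded,
    )
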