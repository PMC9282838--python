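"""Chromosome-21 dosage calling from methylation-array intensity bins.

Trisomy 21 adds one chromosome copy, shifting chr21 probe intensities by
log2(3/2) ~= 0.585 in the ideal case; array compression attenuates the
observed shift, so full trisomy is called at a median chr21 log2 ratio >= 0.2
in Down-syndrome samples.  DS samples whose median falls more than 2 SD below
the DS-cohort mean yet above every non-DS median are flagged as likely
mosaic/partial trisomy (the two cannot be distinguished at array resolution).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .containers import validate_bin_table
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

CHR21 = "21"
FULL_T21_THRESHOLD = 0.2
SD_MULTIPLIER = 2.0

CALL_FULL = "full_T21"
CALL_MOSAIC = "likely_mosaic_partial"
CALL_NOT_ELEVATED = "not_elevated"


@dataclass
class T21Calls:
    """Per-sample call table plus the DS/non-DS cohort statistics used."""

    calls: pd.DataFrame  # columns: chr21_median_log2, ds, call
    mean_ds: float
    sd_ds: float
    max_nonds: float


def compute_bin_log2(sample_bins, reference_samples) -> np.ndarray:
    """Per-bin log2 ratio of one sample against the reference-cohort median.

    ``sample_bins`` is an intensity vector; ``reference_samples`` an iterable
    of equal-length intensity vectors (the randomly drawn non-DS reference).
    """
    sample = np.asarray(sample_bins, dtype=float)
    ref = np.asarray(list(reference_samples), dtype=float)
    if ref.ndim != 2 or ref.shape[0] < 1 or ref.shape[1] != sample.shape[0]:
        raise ValidationError(
            f"reference must be >=1 samples of {sample.shape[0]} bins; got shape {ref.shape}"
        )
    if (sample <= 0).any() or (ref <= 0).any():
        raise ValidationError("intensities must be strictly positive")
    ref_median = np.median(ref, axis=0)
    return np.log2(sample / ref_median)


def chr21_median_log2(bins: pd.DataFrame, sample_id) -> float:
    """Median log2 ratio over a sample's chr21 bins only."""
    bins = validate_bin_table(bins)
    sel = bins[(bins["sample_id"] == sample_id)
               & (bins["chromosome"].astype(str) == CHR21)]
    if sel.empty:
        raise DegenerateDataError(f"no chr21 bins for sample '{sample_id}'")
    return float(sel["log2_ratio"].median())


def chr21_medians(bins: pd.DataFrame) -> pd.Series:
    """chr21 median log2 ratio for every sample in a bin table."""
    bins = validate_bin_table(bins)
    chr21 = bins[bins["chromosome"].astype(str) == CHR21]
    if chr21.empty:
        raise DegenerateDataError("no chr21 bins in table")
    return chr21.groupby("sample_id")["log2_ratio"].median().rename("chr21_median_log2")


def classify_t21(
    medians: pd.Series,
    ds_labels: pd.Series,
    full_threshold: float = FULL_T21_THRESHOLD,
    sd_multiplier: float = SD_MULTIPLIER,
) -> T21Calls:
    """Classify DS samples as full T21, likely mosaic/partial, or not elevated.

    For DS samples the mosaic rule takes precedence: a median more than
    ``sd_multiplier`` SDs (ddof=1) below the mean over *all* DS samples and
    strictly above the non-DS maximum is called likely mosaic/partial.
    Otherwise a median >= ``full_threshold`` is full T21; anything else is
    not_elevated with a QC warning.  Non-DS samples are always not_elevated.
    """
    ds_labels = ds_labels.reindex(medians.index)
    if ds_labels.isna().any():
        raise ValidationError("DS label missing for some samples in median table")
    ds_labels = ds_labels.astype(bool)
    if not (~ds_labels).any():
        raise DegenerateDataError("no non-DS samples: mosaic window is undefined")
    if not ds_labels.any():
        raise DegenerateDataError("no DS samples: DS cohort statistics undefined")

    ds_med = medians[ds_labels]
    mean_ds = float(ds_med.mean())
    sd_ds = float(ds_med.std(ddof=1)) if len(ds_med) > 1 else 0.0
    max_nonds = float(medians[~ds_labels].max())

    lower = mean_ds - sd_multiplier * sd_ds
    calls = []
    for sample, med in medians.items():
        if not ds_labels.loc[sample]:
            call = CALL_NOT_ELEVATED
        elif med < lower and med > max_nonds:
            call = CALL_MOSAIC
        elif med >= full_threshold:
            call = CALL_FULL
        else:
            call = CALL_NOT_ELEVATED
            logger.warning(
                "DS sample %s: chr21 median %.3f below %.2f and outside the "
                "mosaic window; labelled not_elevated", sample, med, full_threshold,
            )
        calls.append(call)
    table = pd.DataFrame(
        {"chr21_median_log2": medians, "ds": ds_labels, "call": calls},
        index=medians.index,
    )
    return T21Calls(calls=table, mean_ds=mean_ds, sd_ds=sd_ds, max_nonds=max_nonds)
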