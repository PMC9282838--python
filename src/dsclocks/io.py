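"""Readers and writers for the pipeline's file formats.

All formats are plain text: betas as TSV (CpG rows, chromosome column, sample
columns), everything else as CSV with headers, truth/QC as JSON.  Every writer
produces output its reader round-trips.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .containers import BIN_COLUMNS, BetaMatrix, validate_bin_table
from .errors import ValidationError

SHEET_REQUIRED = ("ds",)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, index_col="sample_id")
    missing = [c for c in SHEET_REQUIRED if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing required columns {missing}")
    if not sheet.index.is_unique:
        raise ValidationError("duplicate sample ids in sample sheet")
    sheet["ds"] = sheet["ds"].astype(bool)
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    out = sheet.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_bins(path) -> pd.DataFrame:
    bins = pd.read_csv(path, dtype={"chromosome": str})
    return validate_bin_table(bins)


def write_bins(bins: pd.DataFrame, path) -> None:
    validate_bin_table(bins)[list(BIN_COLUMNS)].to_csv(path, index=False)


def write_clock_values(clock_values: dict, path) -> None:
    """Wide CSV: one row per sample, one column per clock."""
    frame = pd.DataFrame({name: cv.values for name, cv in clock_values.items()})
    frame.index.name = "sample_id"
    frame.to_csv(path)


def read_clock_values(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_proportions(props, path) -> None:
    out = props.proportions.copy()
    out["high_nrbc"] = props.high_nrbc
    out["residual_norm"] = props.residual_norm
    out.index.name = "sample_id"
    out.to_csv(path)


def write_t21_calls(calls, path) -> None:
    out = calls.calls.copy()
    out["mean_ds"] = calls.mean_ds
    out["sd_ds"] = calls.sd_ds
    out["max_nonds"] = calls.max_nonds
    out.index.name = "sample_id"
    out.to_csv(path)


def write_dnamaa(dnamaa: dict, path) -> None:
    """Long CSV: sample_id, clock_name, anchor, dnamaa."""
    rows = []
    for vec in dnamaa.values():
        for sample, value in vec.residuals.items():
            rows.append({"sample_id": sample, "clock_name": vec.clock_name,
                         "anchor": vec.anchor, "dnamaa": value})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_model_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_json(payload: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_default)


def write_clock_definition(clock, path) -> None:
    """Coefficient CSV (cpg_id, weight) with the reserved intercept row first."""
    pd.DataFrame({
        "cpg_id": ["(Intercept)"] + list(clock.cpg_ids),
        "weight": [clock.intercept] + list(clock.weights),
    }).to_csv(path, index=False)


read_betas = BetaMatrix.read_tsv


def write_betas(betas: BetaMatrix, path) -> None:
    betas.to_tsv(path)
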