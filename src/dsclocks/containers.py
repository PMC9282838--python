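"""In-memory containers for methylation betas and bin-level copy-number data.

Betas travel as a CpG-by-sample :class:`pandas.DataFrame` wrapped in
:class:`BetaMatrix`, which carries the per-CpG chromosome annotation needed for
chromosome-restricted clock variants.  The on-disk form is a TSV whose first
column after the CpG id is ``chromosome`` and whose remaining columns are
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CHROM_COL = "chromosome"
BIN_COLUMNS = ("sample_id", "chromosome", "bin_index", "log2_ratio")


@dataclass
class BetaMatrix:
    """CpG-by-sample methylation fractions in [0, 1], NaN = missing.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by unique CpG ids, columns by unique sample ids.
    chromosome : Series
        Chromosome label per CpG, aligned to ``values.index``. Labels are free
        strings (``"1"``..``"22"``, ``"X"`` ...); chr21 is spelled ``"21"``.
    """

    values: pd.DataFrame
    chromosome: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValidationError("duplicate CpG ids in beta matrix")
        if not self.values.columns.is_unique:
            raise ValidationError("duplicate sample ids in beta matrix")
        vals = self.values.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 1))
        if bad:
            raise ValidationError(
                f"{int(bad)} beta values outside [0, 1]; clip upstream if intended"
            )
        self.values = self.values.rename_axis(index="cpg_id", columns=None)
        if self.chromosome is None:
            self.chromosome = pd.Series("NA", index=self.values.index, name=CHROM_COL)
        else:
            missing = self.values.index.difference(self.chromosome.index)
            if len(missing):
                raise ValidationError(
                    f"chromosome annotation missing for {len(missing)} CpGs "
                    f"(e.g. {list(missing[:3])})"
                )
            self.chromosome = self.chromosome.reindex(self.values.index).astype(str)
            self.chromosome.name = CHROM_COL

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_cpgs(self, cpgs) -> "BetaMatrix":
        cpgs = pd.Index(cpgs)
        missing = cpgs.difference(self.values.index)
        if len(missing):
            raise ValidationError(f"CpGs absent from matrix: {list(missing[:5])}")
        return BetaMatrix(self.values.loc[cpgs], self.chromosome.loc[cpgs])

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, CHROM_COL, self.chromosome)
        out.index.name = "cpg_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if CHROM_COL not in df.columns:
            raise ValidationError(
                f"beta TSV must carry a '{CHROM_COL}' column right after the CpG id; "
                f"got columns {list(df.columns[:3])}..."
            )
        chrom = df.pop(CHROM_COL).astype(str)
        return cls(df.astype(float), chrom)


def clip_betas(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Clip an array into [0, 1] and count how many entries moved."""
    n_clipped = int(np.sum((values < 0) | (values > 1)))
    return np.clip(values, 0.0, 1.0), n_clipped


def validate_bin_table(bins: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format bin-level log2 table (sample, chromosome, bin, ratio)."""
    missing = [c for c in BIN_COLUMNS if c not in bins.columns]
    if missing:
        raise ValidationError(f"bin table missing columns {missing}")
    if not np.isfinite(bins["log2_ratio"].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite log2 ratios in bin table")
    return bins
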