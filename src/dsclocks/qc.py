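"""Probe- and sample-level quality filtering.

Order is fixed: (1) drop CpGs whose mean detection p value exceeds the
threshold, (2) drop CpGs with excess missingness, (3) drop samples with excess
missingness computed over the CpGs that survived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import BetaMatrix
from .errors import DegenerateDataError, ValidationError

DETECTION_P_THRESHOLD = 0.01
MISSINGNESS_THRESHOLD = 0.15


@dataclass
class QCReport:
    n_cpgs_removed_detection: int = 0
    n_cpgs_removed_missingness: int = 0
    n_samples_removed: int = 0
    detection_p_threshold: float = DETECTION_P_THRESHOLD
    missingness_threshold: float = MISSINGNESS_THRESHOLD
    removed_samples: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_cpgs_removed_detection": self.n_cpgs_removed_detection,
            "n_cpgs_removed_missingness": self.n_cpgs_removed_missingness,
            "n_samples_removed": self.n_samples_removed,
            "detection_p_threshold": self.detection_p_threshold,
            "missingness_threshold": self.missingness_threshold,
            "removed_samples": list(self.removed_samples),
        }


def qc_filter(
    betas: BetaMatrix,
    detection_p: pd.DataFrame | None = None,
    detection_p_threshold: float = DETECTION_P_THRESHOLD,
    missingness_threshold: float = MISSINGNESS_THRESHOLD,
) -> tuple[BetaMatrix, QCReport]:
    """Apply detection-p and missingness filters; returns filtered betas + report."""
    values = betas.values
    report = QCReport(
        detection_p_threshold=detection_p_threshold,
        missingness_threshold=missingness_threshold,
    )

    if detection_p is not None:
        if not detection_p.index.equals(values.index) or \
           not detection_p.columns.equals(values.columns):
            raise ValidationError("detection-p matrix is not aligned to the beta matrix")
        bad = detection_p.mean(axis=1) > detection_p_threshold
        report.n_cpgs_removed_detection = int(bad.sum())
        values = values.loc[~bad]

    cpg_miss = values.isna().mean(axis=1) > missingness_threshold
    report.n_cpgs_removed_missingness = int(cpg_miss.sum())
    values = values.loc[~cpg_miss]

    sample_miss = values.isna().mean(axis=0) > missingness_threshold
    report.n_samples_removed = int(sample_miss.sum())
    report.removed_samples = list(values.columns[sample_miss])
    values = values.loc[:, ~sample_miss]

    if values.shape[1] == 0 or values.shape[0] == 0:
        what = "sample" if values.shape[1] == 0 else "CpG"
        raise DegenerateDataError(
            f"QC removed every {what} (thresholds: detection {detection_p_threshold}, "
            f"missingness {missingness_threshold})"
        )
    return BetaMatrix(values, betas.chromosome.loc[values.index]), report
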