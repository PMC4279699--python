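"""Within-sample Z-score normalization of log10 intensities.

Every downstream statistic operates on the Z-score scale: each sample's
log10 intensities are standardized against the mean and standard deviation
of all probes in that same sample, removing sample-level location and scale
(labelling efficiency, scanner gain, RNA input).  Standardization uses all
probes in the (already intersected) matrix, and the sample standard
deviation uses the n−1 denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ValidationError

logger = logging.getLogger("zdat")

__all__ = ["ZMatrix", "log_transform", "zscore_per_sample", "normalize"]

#: default intensity floor before log10; floored cells map to 0 on the log scale
DEFAULT_LOG_FLOOR = 1.0


@dataclass
class ZMatrix:
    """Per-sample Z-scores (dimensionless) plus the log10 intensities they
    were derived from (kept for fold-difference computation)."""

    z: pd.DataFrame
    log_intensities: pd.DataFrame

    @property
    def probe_ids(self) -> pd.Index:
        return self.z.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.z.columns


def log_transform(
    m: ExpressionMatrix, floor: float = DEFAULT_LOG_FLOOR
) -> pd.DataFrame:
    """log10 of intensities, with values below ``floor`` clamped to it.

    Background subtraction leaves some intensities ≤ 0; the floor keeps the
    log defined.  The number of floored cells is logged.
    """
    if floor <= 0:
        raise ValueError(f"log floor must be positive, got {floor}")
    n_floored = int((m.intensities.to_numpy() < floor).sum())
    if n_floored:
        logger.info(
            "log_transform: %d of %d cells below floor %g were clamped",
            n_floored, m.intensities.size, floor,
        )
    return np.log10(m.intensities.clip(lower=floor))


def zscore_per_sample(logm: pd.DataFrame) -> ZMatrix:
    """Standardize each sample column: z = (x − mean over probes) / SD.

    SD uses ddof=1.  A sample with zero variance across probes is an error
    (the column cannot be standardized).
    """
    means = logm.mean(axis=0)
    sds = logm.std(axis=0, ddof=1)
    degenerate = sds.index[(sds == 0) | sds.isna()]
    if len(degenerate):
        raise ValidationError(
            f"zero variance across probes in sample(s): {degenerate.tolist()}"
        )
    z = (logm - means) / sds
    return ZMatrix(z=z, log_intensities=logm)


def normalize(
    m: ExpressionMatrix, floor: float = DEFAULT_LOG_FLOOR
) -> ZMatrix:
    """log10-transform then Z-score per sample (the full normalization)."""
    return zscore_per_sample(log_transform(m, floor=floor))
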