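"""Z-ratio and Z-test statistics and the combined DAT filter.

A differentially abundant transcript (DAT) for a two-group contrast must
jointly satisfy: |Z-ratio| ≥ 1.96, a Benjamini-Hochberg-adjusted two-sided
Z-test p ≤ 0.05, and detection in at least one sample of the two groups.

The Z-ratio divides each probe's group mean-Z difference by a single scalar
— the standard deviation of those differences across all probes — so it
measures how extreme a probe's shift is relative to the array-wide shift
distribution.  The Z-test is a per-probe two-sample z with unequal
(per-group) variances, referenced to the standard normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, ValidationError
from .normalize import ZMatrix

logger = logging.getLogger("zdat")

__all__ = [
    "ContrastSpec",
    "z_ratio",
    "z_test",
    "bh_adjust",
    "call_dats",
    "summarize_contrast",
]

DEFAULT_Z_RATIO_CUT = 1.96
DEFAULT_P_CUT = 0.05


@dataclass
class ContrastSpec:
    """A two-group comparison: sample IDs per group plus thresholds."""

    group1: list[str]
    group2: list[str]
    z_ratio_cut: float = DEFAULT_Z_RATIO_CUT
    p_cut: float = DEFAULT_P_CUT

    def __post_init__(self) -> None:
        overlap = set(self.group1) & set(self.group2)
        if overlap:
            raise ValidationError(f"groups share samples: {sorted(overlap)}")
        if len(self.group1) < 2 or len(self.group2) < 2:
            raise ValidationError(
                f"each group needs ≥2 samples "
                f"(got {len(self.group1)} and {len(self.group2)})"
            )
        for name, ids in (("group1", self.group1), ("group2", self.group2)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate sample IDs in {name}")

    def swapped(self) -> "ContrastSpec":
        return ContrastSpec(self.group2, self.group1,
                            self.z_ratio_cut, self.p_cut)

    def validate_against(self, sample_ids) -> None:
        missing = [s for s in (*self.group1, *self.group2)
                   if s not in sample_ids]
        if missing:
            raise ValidationError(f"contrast samples absent from data: {missing}")


def _group_frames(z: ZMatrix, spec: ContrastSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    spec.validate_against(z.sample_ids)
    return z.z[spec.group1], z.z[spec.group2]


def z_ratio(z: ZMatrix, spec: ContrastSpec) -> pd.Series:
    """Per-probe Z-ratio: group mean-Z difference over the scalar SD of
    those differences taken across all probes (ddof=1)."""
    g1, g2 = _group_frames(z, spec)
    d = g1.mean(axis=1) - g2.mean(axis=1)
    sd = d.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        if (d == 0).all():
            # null contrast: identical group means everywhere
            out = d.copy()
            out.name = "z_ratio"
            return out
        raise ValidationError(
            "SD of mean Z-score differences across probes is zero — "
            "degenerate contrast"
        )
    out = d / sd
    out.name = "z_ratio"
    return out


def z_test(z: ZMatrix, spec: ContrastSpec) -> tuple[pd.Series, pd.Series]:
    """Per-probe two-sample z with per-group variances, standard-normal p.

    Degenerate probes (both group variances zero) get z=0, p=1 when the
    means agree and p=0 (flagged in the log) when they differ.
    """
    g1, g2 = _group_frames(z, spec)
    n1, n2 = g1.shape[1], g2.shape[1]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    num = m1 - m2
    den = np.sqrt(v1 / n1 + v2 / n2)

    zero_den = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = num / den
    stat[zero_den & (num == 0)] = 0.0
    p = pd.Series(2.0 * stats.norm.sf(np.abs(stat)), index=stat.index)
    degenerate_signal = zero_den & (num != 0)
    if degenerate_signal.any():
        stat[degenerate_signal] = np.sign(num[degenerate_signal]) * np.inf
        p[degenerate_signal] = 0.0
        logger.warning(
            "z_test: %d probe(s) with zero variance in both groups but "
            "unequal means; p set to 0", int(degenerate_signal.sum()),
        )
    stat.name, p.name = "z_stat", "p_raw"
    return stat, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def call_dats(
    z: ZMatrix, expr: ExpressionMatrix, spec: ContrastSpec
) -> pd.DataFrame:
    """Full contrast table with the conjunction of all three DAT criteria.

    ``expressed_any`` is detection in ≥1 sample of the union of the two
    groups.  Direction is assigned only to DATs, from the Z-ratio sign.
    """
    if not z.probe_ids.equals(expr.probe_ids):
        raise ValidationError("Z matrix and expression matrix probes differ")
    zr = z_ratio(z, spec)
    zs, p_raw = z_test(z, spec)
    p_adj = pd.Series(bh_adjust(p_raw.to_numpy()), index=p_raw.index,
                      name="p_adj")
    contrast_samples = [*spec.group1, *spec.group2]
    expressed = expr.detected[contrast_samples].any(axis=1)

    g1, g2 = _group_frames(z, spec)
    is_dat = (
        (zr.abs() >= spec.z_ratio_cut)
        & (p_adj <= spec.p_cut)
        & expressed
    )
    direction = pd.Series("none", index=zr.index, name="direction")
    direction[is_dat & (zr > 0)] = "more_abundant"
    direction[is_dat & (zr < 0)] = "less_abundant"

    table = pd.DataFrame(
        {
            "mean_z_g1": g1.mean(axis=1),
            "mean_z_g2": g2.mean(axis=1),
            "z_ratio": zr,
            "z_stat": zs,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "expressed_any": expressed,
            "direction": direction,
            "is_dat": is_dat,
        }
    )
    table.index.name = "probe_id"
    n_up = int((direction == "more_abundant").sum())
    n_down = int((direction == "less_abundant").sum())
    logger.info("call_dats: %d DATs (%d more, %d less abundant)",
                n_up + n_down, n_up, n_down)
    return table


def summarize_contrast(table: pd.DataFrame) -> str:
    """One-line summary: ``N DATs (N_up more, N_down less abundant)``."""
    n_up = int((table["direction"] == "more_abundant").sum())
    n_down = int((table["direction"] == "less_abundant").sum())
    return f"{n_up + n_down} DATs ({n_up} more, {n_down} less abundant)"
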