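"""Covariate-adjusted DAT calling via a per-probe linear model.

Blood-cell composition shifts between disease phases: an acute sample with
more neutrophils will show neutrophil-programme transcripts as "up" even if
no cell changed its expression.  To separate composition from regulation,
each probe's Z-score is modelled as

    z_ij = β0 + β1·(lymphocytes, neutrophils, monocytes)_j + β2·group_j + ε

with group coded 1 for the first (acute-like) group and 0 for the second.
β2 is the covariate-adjusted group effect; its two-sided p-value uses the
large-sample normal reference on the coefficient z-value, BH-corrected over
probes.  A GLM DAT additionally needs a fold-difference > 1.5 between the
group geometric mean intensities.

All probes share one design matrix, so the fits are solved in a single
vectorized least-squares pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dat_zstats import ContrastSpec, bh_adjust
from .io_formats import SampleTable, ValidationError
from .normalize import ZMatrix

logger = logging.getLogger("zdat")

__all__ = [
    "DEFAULT_COVARIATES",
    "DEFAULT_FOLD_CUT",
    "fit_glm",
    "fold_difference",
    "call_dats_glm",
    "summarize_glm",
]

DEFAULT_COVARIATES = ["lymphocytes", "neutrophils", "monocytes"]
DEFAULT_FOLD_CUT = 1.5


def _design(
    meta: SampleTable, spec: ContrastSpec, covariates: list[str]
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Build the [1 | covariates | group] design over usable samples.

    Samples missing any covariate are dropped (logged).  Returns the design
    frame, the group indicator, and the kept sample IDs in design order.
    """
    samples = [*spec.group1, *spec.group2]
    meta.require_samples(samples)
    for col in covariates:
        if col not in meta.data.columns:
            raise ValidationError(f"covariate column {col!r} absent from metadata")
    sub = meta.data.loc[samples]
    if covariates:
        usable = sub[covariates].notna().all(axis=1)
    else:
        usable = pd.Series(True, index=sub.index)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info(
            "fit_glm: dropped %d sample(s) with missing covariates: %s",
            n_dropped, sub.index[~usable].tolist(),
        )
    kept = sub.index[usable].tolist()
    g1_kept = [s for s in kept if s in set(spec.group1)]
    g2_kept = [s for s in kept if s in set(spec.group2)]
    if len(g1_kept) < 2 or len(g2_kept) < 2:
        raise ValidationError(
            "fewer than 2 usable samples in a group after dropping "
            "missing covariates"
        )
    group = pd.Series(
        [1.0 if s in set(spec.group1) else 0.0 for s in kept],
        index=kept, name="group",
    )
    X = pd.DataFrame({"intercept": 1.0}, index=kept)
    for col in covariates:
        X[col] = sub.loc[kept, col].astype(float)
    X["group"] = group
    # diagnose rank deficiency by column before the generic check
    for col in covariates:
        if X[col].nunique() <= 1:
            raise ValidationError(
                f"covariate {col!r} is constant over the contrast samples — "
                "design matrix is rank deficient"
            )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    if X.shape[0] <= X.shape[1]:
        raise ValidationError(
            f"{X.shape[0]} samples cannot identify {X.shape[1]} parameters"
        )
    return X, group, kept


def fit_glm(
    z: ZMatrix,
    meta: SampleTable,
    spec: ContrastSpec,
    covariates: list[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-probe OLS of Z-score on [intercept, covariates, group].

    Returns a frame with the intercept, one column per covariate
    coefficient (``beta_<name>``), ``beta_group``, its standard error, and
    raw/BH-adjusted p-values from the normal reference.
    """
    X, _, kept = _design(meta, spec, covariates)
    Xm = X.to_numpy()                       # n × p
    Y = z.z[kept].to_numpy().T              # n × G
    n, p = Xm.shape
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    beta = xtx_inv @ Xm.T @ Y               # p × G
    resid = Y - Xm @ beta
    sigma2 = (resid**2).sum(axis=0) / (n - p)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # p × G
    gi = X.columns.get_loc("group")
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(se[gi] > 0, beta[gi] / se[gi], 0.0)
    p_raw = 2.0 * stats.norm.sf(np.abs(zval))

    out = pd.DataFrame(index=z.probe_ids)
    out["beta0"] = beta[X.columns.get_loc("intercept")]
    for col in covariates:
        out[f"beta_{col}"] = beta[X.columns.get_loc(col)]
    out["beta_group"] = beta[gi]
    out["se_group"] = se[gi]
    out["p_raw"] = p_raw
    out["p_adj"] = bh_adjust(p_raw)
    out.index.name = "probe_id"
    return out


def fold_difference(logm: pd.DataFrame, spec: ContrastSpec) -> pd.Series:
    """Ratio of group geometric mean intensities, folded to be ≥ 1.

    Computed as 10^|Δ| where Δ is the difference of group means of log10
    intensity — the standard microarray fold-change on unlogged scale.
    """
    spec.validate_against(logm.columns)
    delta = logm[spec.group1].mean(axis=1) - logm[spec.group2].mean(axis=1)
    fd = np.power(10.0, delta.abs())
    fd.name = "fold_diff"
    return fd


def call_dats_glm(
    z: ZMatrix,
    meta: SampleTable,
    spec: ContrastSpec,
    covariates: list[str] = DEFAULT_COVARIATES,
    p_cut: float = 0.05,
    fold_cut: float = DEFAULT_FOLD_CUT,
    model_fold: bool = False,
) -> pd.DataFrame:
    """GLM DAT calls: adjusted p < ``p_cut`` and fold-difference > ``fold_cut``.

    By default the fold-difference comes from the raw log10 intensities.
    With ``model_fold=True`` it is instead back-transformed from the
    adjusted group coefficient, 10^(|β2|·s̄), where s̄ is the mean per-sample
    SD of log10 intensities (the scale the Z-scores divided out).
    """
    table = fit_glm(z, meta, spec, covariates)
    if model_fold:
        scale = z.log_intensities.std(axis=0, ddof=1).mean()
        fd = np.power(10.0, table["beta_group"].abs() * scale)
        fd.name = "fold_diff"
    else:
        fd = fold_difference(z.log_intensities, spec)
    table["fold_diff"] = fd
    table["is_dat"] = (table["p_adj"] < p_cut) & (table["fold_diff"] > fold_cut)
    direction = pd.Series("none", index=table.index, name="direction")
    direction[table["is_dat"] & (table["beta_group"] > 0)] = "more_abundant"
    direction[table["is_dat"] & (table["beta_group"] < 0)] = "less_abundant"
    table["direction"] = direction
    n_up = int((direction == "more_abundant").sum())
    n_down = int((direction == "less_abundant").sum())
    logger.info("call_dats_glm: %d DATs (%d more, %d less abundant)",
                n_up + n_down, n_up, n_down)
    return table


def summarize_glm(table: pd.DataFrame) -> str:
    n_up = int((table["direction"] == "more_abundant").sum())
    n_down = int((table["direction"] == "less_abundant").sum())
    return f"{n_up + n_down} DATs ({n_up} more, {n_down} less abundant)"
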