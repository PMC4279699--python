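"""Synthetic microarray-like datasets with known ground truth.

The generator emulates a whole-blood bead-array study contrasting an
acute-phase group against a convalescent-phase group:

* per-sample absolute blood-cell counts drawn from group-specific normal
  distributions (the acute-like group has more neutrophils and fewer
  lymphocytes, as in an acute inflammatory response);
* probe baselines on the log10 intensity scale, uniform over a plausible
  fluorescence range, with i.i.d. normal residual noise;
* a spiked truly differentially-expressed (DE) probe class whose log10
  intensity shifts by ±``de_effect`` in the acute-like group;
* a disjoint confounder-only probe class whose log10 intensity tracks a
  driver cell count linearly (by default the neutrophil count, the natural
  behaviour of neutrophil-programme transcripts in whole blood) — these
  probes differ between groups only because the cell counts do, and are the
  false positives a composition-adjusted model should reject;
* a companion GMT collection in which a subset of "loaded" sets draws half
  its members from DE genes, so enrichment is testable end to end;
* a 1:1 probe → gene map with synthetic symbols.

All randomness flows from one ``numpy`` Generator seeded by the config, so
identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleTable,
    ValidationError,
)

__all__ = ["SimConfig", "SimTruth", "simulate", "truth_metrics"]

# cells/µL; acute-phase neutrophilia with mild relative lymphopenia.  The
# separation is deliberately moderate: it is calibrated jointly with
# confounder_slope so that unadjusted Z statistics flag most confounder-only
# probes while the count-adjusted GLM retains power (collinearity between
# the group indicator and the counts grows with the separation).
_DEFAULT_CELL_MEANS = {
    "acute": {"lymphocytes": 2950.0, "neutrophils": 5240.0, "monocytes": 520.0},
    "convalescent": {"lymphocytes": 3000.0, "neutrophils": 4000.0,
                     "monocytes": 500.0},
}
_DEFAULT_CELL_SDS = {
    "acute": {"lymphocytes": 500.0, "neutrophils": 1700.0, "monocytes": 220.0},
    "convalescent": {"lymphocytes": 500.0, "neutrophils": 1700.0,
                     "monocytes": 220.0},
}


@dataclass
class SimConfig:
    """Generator settings; defaults are the desk-scale study conditions."""

    n_probes: int = 5000
    n_per_group: tuple[int, int] = (40, 40)
    group_labels: tuple[str, str] = ("acute", "convalescent")
    baseline_range: tuple[float, float] = (1.5, 3.5)   # log10 units
    residual_sd: float = 0.25                          # log10 units
    de_fraction: float = 0.05
    de_effect: float = 0.25                            # log10 units
    confounded_fraction: float = 0.05
    # log10 units per 1,000 cells/µL of the driver count
    confounder_slope: float = 0.33
    # which count drives confounded probes: a cell column or "total"
    confounder_driver: str = "neutrophils"
    cell_means: dict = field(default_factory=lambda: _DEFAULT_CELL_MEANS)
    cell_sds: dict = field(default_factory=lambda: _DEFAULT_CELL_SDS)
    detection_dropout: float = 0.02
    n_sets: int = 50
    set_size: int = 20
    loaded_set_fraction: float = 0.2
    loaded_de_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (
            ("de_fraction", self.de_fraction),
            ("confounded_fraction", self.confounded_fraction),
            ("detection_dropout", self.detection_dropout),
            ("loaded_set_fraction", self.loaded_set_fraction),
            ("loaded_de_fraction", self.loaded_de_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {frac}")
        if self.de_fraction + self.confounded_fraction > 1.0:
            raise ValidationError("DE and confounded fractions overlap the probe set")
        if self.residual_sd <= 0:
            raise ValidationError("residual_sd must be > 0")
        for grp in self.group_labels:
            for counts in (self.cell_means, self.cell_sds):
                if grp not in counts:
                    raise ValidationError(f"cell-count model missing group {grp!r}")
            if any(v <= 0 for v in self.cell_sds[grp].values()):
                raise ValidationError("cell-count SDs must be > 0")
        if self.set_size > self.n_probes:
            raise ValidationError("set_size exceeds the number of probes")
        if any(n < 2 for n in self.n_per_group):
            raise ValidationError("each group needs at least 2 samples")


@dataclass
class SimTruth:
    """Ground truth: per-probe classes and effects, per-set loading."""

    is_de: pd.Series          # bool per probe
    is_confounded: pd.Series  # bool per probe
    effect: pd.Series         # signed log10 group effect per probe
    loaded_sets: pd.Series    # bool per gene-set name
    seed: int


def simulate(
    config: SimConfig | None = None,
) -> tuple[ExpressionMatrix, SampleTable, GeneSetCollection, pd.Series, SimTruth]:
    """Draw one dataset from the generative model.

    Returns (expression matrix, sample table, gene sets, probe→gene map,
    truth).  The log10 intensity of probe g in sample j is::

        baseline_g + effect_g · [j in group 1]
                   + slope · driver_cells_j/1000 · [g confounded]
                   + Normal(0, residual_sd)

    with intensities = 10**log10 value and detection flags subjected to a
    uniform dropout probability.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    g1, g2 = cfg.group_labels
    n1, n2 = cfg.n_per_group
    n_samples = n1 + n2
    probe_ids = pd.Index([f"P{i:05d}" for i in range(cfg.n_probes)],
                         name="probe_id")
    sample_ids = [f"{g1[:3].upper()}{i:03d}" for i in range(n1)] + [
        f"{g2[:3].upper()}{i:03d}" for i in range(n2)
    ]
    groups = np.array([g1] * n1 + [g2] * n2)
    group_ind = (groups == g1).astype(float)

    # per-sample blood-cell counts (cells/µL, truncated at zero)
    counts = {}
    for cell in ("lymphocytes", "neutrophils", "monocytes"):
        vals = np.concatenate([
            rng.normal(cfg.cell_means[g][cell], cfg.cell_sds[g][cell], n)
            for g, n in ((g1, n1), (g2, n2))
        ])
        counts[cell] = np.clip(vals, 0.0, None)
    if cfg.confounder_driver == "total":
        driver = sum(counts.values())
    elif cfg.confounder_driver in counts:
        driver = counts[cfg.confounder_driver]
    else:
        raise ValidationError(
            f"unknown confounder_driver {cfg.confounder_driver!r}"
        )

    # probe classes: disjoint DE and confounder-only sets
    n_de = round(cfg.de_fraction * cfg.n_probes)
    n_conf = round(cfg.confounded_fraction * cfg.n_probes)
    perm = rng.permutation(cfg.n_probes)
    de_idx, conf_idx = perm[:n_de], perm[n_de:n_de + n_conf]
    is_de = np.zeros(cfg.n_probes, dtype=bool)
    is_de[de_idx] = True
    is_conf = np.zeros(cfg.n_probes, dtype=bool)
    is_conf[conf_idx] = True
    effect = np.zeros(cfg.n_probes)
    effect[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * cfg.de_effect

    baseline = rng.uniform(*cfg.baseline_range, size=cfg.n_probes)
    logm = (
        baseline[:, None]
        + np.outer(effect, group_ind)
        + np.outer(is_conf * cfg.confounder_slope, driver / 1000.0)
        + rng.normal(0.0, cfg.residual_sd, size=(cfg.n_probes, n_samples))
    )
    intensities = pd.DataFrame(10.0**logm, index=probe_ids, columns=sample_ids)
    detected = pd.DataFrame(
        rng.random((cfg.n_probes, n_samples)) >= cfg.detection_dropout,
        index=probe_ids, columns=sample_ids,
    )
    expr = ExpressionMatrix(intensities, detected)

    meta = pd.DataFrame({"group": groups, **counts},
                        index=pd.Index(sample_ids, name="sample_id"))
    samples = SampleTable(meta)

    gene_ids = pd.Index([f"G{i:05d}" for i in range(cfg.n_probes)])
    probe_map = pd.Series(gene_ids, index=probe_ids, name="gene")

    de_genes = gene_ids[de_idx].to_numpy()
    n_loaded = round(cfg.loaded_set_fraction * cfg.n_sets)
    sets = []
    loaded_flags = {}
    for i in range(cfg.n_sets):
        name = f"SET{i:03d}"
        loaded = i < n_loaded and len(de_genes) > 0
        if loaded:
            k_de = min(round(cfg.loaded_de_fraction * cfg.set_size),
                       len(de_genes))
            chosen_de = rng.choice(de_genes, size=k_de, replace=False)
            rest_pool = gene_ids[~gene_ids.isin(chosen_de)].to_numpy()
            chosen_rest = rng.choice(rest_pool, size=cfg.set_size - k_de,
                                     replace=False)
            members = np.concatenate([chosen_de, chosen_rest])
        else:
            members = rng.choice(gene_ids.to_numpy(), size=cfg.set_size,
                                 replace=False)
        sets.append(GeneSet(name, "synthetic", tuple(sorted(members))))
        loaded_flags[name] = bool(loaded)
    collection = GeneSetCollection(sets)

    truth = SimTruth(
        is_de=pd.Series(is_de, index=probe_ids, name="is_de"),
        is_confounded=pd.Series(is_conf, index=probe_ids, name="is_confounded"),
        effect=pd.Series(effect, index=probe_ids, name="effect"),
        loaded_sets=pd.Series(loaded_flags, name="is_loaded"),
        seed=cfg.seed,
    )
    return expr, samples, collection, probe_map, truth


def truth_metrics(truth: SimTruth, calls: pd.DataFrame) -> dict:
    """Confusion-matrix summary of a call table against the ground truth.

    ``calls`` needs an ``is_dat`` column aligned on the truth's probes.
    Confounder-only probes are reported as their own false-positive class.
    When nothing is called, FDR is undefined and reported as 0 with
    ``no_calls`` set.
    """
    if not calls.index.equals(truth.is_de.index):
        raise ValidationError("call table probes do not match the truth")
    called = calls["is_dat"].astype(bool)
    de = truth.is_de
    conf = truth.is_confounded
    null = ~de & ~conf
    n_called = int(called.sum())
    tp = int((called & de).sum())
    fp = int((called & ~de).sum())
    return {
        "n_called": n_called,
        "sensitivity": tp / int(de.sum()) if de.any() else float("nan"),
        "fdr": fp / n_called if n_called else 0.0,
        "no_calls": n_called == 0,
        "fp_rate_null": float((called & null).sum() / null.sum())
        if null.any() else float("nan"),
        "fp_rate_confounded": float((called & conf).sum() / conf.sum())
        if conf.any() else float("nan"),
    }
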