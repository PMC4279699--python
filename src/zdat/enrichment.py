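"""Gene-set over-representation and cross-contrast pathway comparison.

Each gene set is tested with a one-sided Fisher exact test (equivalently,
the upper hypergeometric tail) for over-representation of DAT genes within
the universe of genes actually measured on the array, followed by BH
correction across sets.  ``compare_contrasts`` then classifies each set by
its significance pattern across several contrasts: shared by all
conditions, shared between a focal condition and one of two comparison
groups, specific to the focal condition, or other.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dat_zstats import bh_adjust
from .io_formats import GeneSetCollection, ValidationError

logger = logging.getLogger("zdat")

__all__ = [
    "fisher_enrich",
    "probe_to_gene",
    "compare_contrasts",
    "CATEGORIES",
]

CATEGORIES = (
    "all_conditions",
    "focal_plus_groupA",
    "focal_plus_groupB",
    "focal_specific",
    "other",
)


def fisher_enrich(
    dat_genes: set[str],
    universe: set[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided over-representation test per gene set.

    The 2×2 table for a set of size K (within the universe of size N) with
    k of the n DAT genes is [[k, K−k], [n−k, N−K−n+k]]; p is the
    hypergeometric upper tail P[X ≥ k].  Sets emptied by intersection with
    the universe are dropped and logged.  Odds ratios use a Haldane 0.5
    continuity shift only when a table margin is zero.
    """
    outside = set(dat_genes) - set(universe)
    if outside:
        raise ValidationError(
            f"DAT genes absent from universe: {sorted(outside)[:10]}"
        )
    N = len(universe)
    n = len(dat_genes)
    rows = []
    dropped = []
    for gs in sets:
        members = set(gs.members) & universe
        if not members:
            dropped.append(gs.name)
            continue
        K = len(members)
        k = len(members & dat_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b, c, d = k, K - k, n - k, N - K - n + k
        if min(a + b, c + d, a + c, b + d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((gs.name, k, K, n, N, odds, p))
    if dropped:
        logger.info(
            "fisher_enrich: dropped %d set(s) with no members in the "
            "universe: %s", len(dropped), dropped[:10],
        )
    if not rows:
        raise ValidationError("no gene set overlaps the universe")
    table = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "odds_ratio", "p_raw"]
    ).set_index("set_name")
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    with np.errstate(divide="ignore"):
        table["neg_log10_p_adj"] = -np.log10(table["p_adj"])
    return table


def probe_to_gene(
    table: pd.DataFrame, probe_map: pd.Series
) -> tuple[set[str], set[str]]:
    """Collapse a probe-level DAT table to gene symbols.

    A gene is a DAT gene if any of its probes is flagged; the universe is
    every mapped gene on the array.  Unmapped DAT probes are dropped with a
    logged count.
    """
    if "is_dat" not in table.columns:
        raise ValidationError("table lacks an 'is_dat' column")
    mapped = probe_map.reindex(table.index).dropna()
    if mapped.empty:
        raise ValidationError("probe map covers no probe of the table")
    universe = set(mapped)
    dat_probes = table.index[table["is_dat"]]
    unmapped = [p for p in dat_probes if p not in mapped.index]
    if unmapped:
        logger.info(
            "probe_to_gene: %d DAT probe(s) without a gene mapping dropped",
            len(unmapped),
        )
    dat_genes = set(mapped.reindex(dat_probes).dropna())
    logger.info(
        "probe_to_gene: %d DAT probes collapsed to %d genes "
        "(universe %d genes)", len(dat_probes), len(dat_genes), len(universe),
    )
    return dat_genes, universe


def _categorize(sig: pd.Series, focal: str, group_a: list[str],
                group_b: list[str]) -> str:
    """Label one set's significance pattern across contrasts."""
    in_a = any(sig[c] for c in group_a)
    in_b = any(sig[c] for c in group_b)
    only_focal = sig[focal] and not any(
        sig[c] for c in sig.index if c != focal
    )
    if sig.all():
        return "all_conditions"
    if not sig[focal]:
        return "other"
    if in_a and not in_b:
        return "focal_plus_groupA"
    if in_b and not in_a:
        return "focal_plus_groupB"
    if only_focal:
        return "focal_specific"
    return "other"


def compare_contrasts(
    tables: dict[str, pd.DataFrame],
    focal: str,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-contrast pathway comparison.

    ``tables`` maps contrast name → enrichment table (same gene-set
    collection in each).  Returns a sets × contrasts matrix of
    −log10(adjusted p) plus a ``category`` column: significant everywhere →
    ``all_conditions``; significant in the focal contrast and ≥1 contrast of
    one comparison group but none of the other → ``focal_plus_groupA``/``B``;
    significant only in the focal contrast → ``focal_specific``; anything
    else → ``other``.
    """
    names = list(tables)
    if focal not in names:
        raise ValidationError(f"focal contrast {focal!r} not among tables")
    if set(group_a) & set(group_b) or focal in set(group_a) | set(group_b):
        raise ValidationError("focal, groupA and groupB must be disjoint")
    for g in (*group_a, *group_b):
        if g not in names:
            raise ValidationError(f"contrast {g!r} not among tables")
    ref_index = tables[focal].index
    for name, t in tables.items():
        if not t.index.equals(ref_index):
            raise ValidationError(
                f"enrichment table {name!r} tests a different gene-set "
                "collection than the focal table"
            )
    matrix = pd.DataFrame(
        {name: t["neg_log10_p_adj"] for name, t in tables.items()}
    )
    sig = pd.DataFrame({name: t["p_adj"] <= alpha for name, t in tables.items()})
    matrix["category"] = [
        _categorize(sig.loc[s], focal, list(group_a), list(group_b))
        for s in matrix.index
    ]
    matrix.index.name = "set_name"
    return matrix
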