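"""Input/output for every external representation the pipeline touches.

Expression matrices, sample metadata, GMT gene-set collections, probe→gene
maps and results tables are all exchanged as UTF-8 tab-separated text, with
probes as rows and samples as columns — the orientation GEO series matrices
use.  Results tables round-trip to 12 significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("zdat")

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "GeneSet",
    "GeneSetCollection",
    "ValidationError",
    "read_expression",
    "read_samples",
    "read_probe_map",
    "intersect_probes",
    "read_gmt",
    "write_gmt",
    "read_results",
    "write_results",
    "read_geo_series_matrix",
]

#: significant digits preserved by write_results / read_results round trips
RESULT_PRECISION = 12


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """Background-subtracted probe intensities with per-cell detection flags.

    ``intensities`` is a probes × samples float frame (fluorescence units;
    background subtraction can push values ≤ 0).  ``detected`` is a boolean
    frame of identical shape: probe called present in that sample.
    """

    intensities: pd.DataFrame
    detected: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.intensities.index, "probe IDs")
        _check_unique(self.intensities.columns, "sample IDs")
        if self.detected.shape != self.intensities.shape:
            raise ValidationError(
                f"detected shape {self.detected.shape} != "
                f"intensities shape {self.intensities.shape}"
            )
        if not self.detected.index.equals(self.intensities.index) or not (
            self.detected.columns.equals(self.intensities.columns)
        ):
            raise ValidationError("detected axes do not match intensities")

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.intensities.loc[list(probes)], self.detected.loc[list(probes)]
        )


# required metadata columns; cell counts are optional and may be missing
CELL_COUNT_COLUMNS = ("lymphocytes", "neutrophils", "monocytes")


@dataclass
class SampleTable:
    """Per-sample clinical metadata.

    ``data`` is indexed by sample ID and must carry a ``group`` column;
    absolute blood-cell counts (cells/µL) are optional columns named
    ``lymphocytes``, ``neutrophils``, ``monocytes``.  Missing counts are
    permitted at load time — the GLM stage decides exclusion.  Any other
    column rides along as opaque clinical metadata.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample IDs")
        if "group" not in self.data.columns:
            raise ValidationError("sample table lacks required column 'group'")
        for col in CELL_COUNT_COLUMNS:
            if col in self.data.columns:
                bad = self.data.index[self.data[col] < 0]  # NaN compares False
                if len(bad):
                    raise ValidationError(
                        f"negative {col} for samples: {bad.tolist()}"
                    )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def group_of(self, sample: str) -> str:
        return self.data.loc[sample, "group"]

    def samples_in_group(self, group: str) -> list[str]:
        return self.data.index[self.data["group"] == group].tolist()

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT semantics)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = pd.Index([s.name for s in self.sets])
        _check_unique(names, "gene-set names")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_numeric_tsv(path: str | Path, what: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    non_numeric = frame.columns[
        [not pd.api.types.is_numeric_dtype(frame[c]) for c in frame.columns]
    ]
    if len(non_numeric):
        # locate the first offending cell for the error message
        for col in non_numeric:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad_rows = frame.index[coerced.isna() & frame[col].notna()]
            if len(bad_rows):
                raise ValidationError(
                    f"non-numeric value in {what} at row {bad_rows[0]!r}, "
                    f"column {col!r}: {frame.loc[bad_rows[0], col]!r}"
                )
        raise ValidationError(f"non-numeric column(s) in {what}: {list(non_numeric)}")
    return frame.astype(float)


def read_expression(
    path: str | Path,
    detection_path: str | Path | None = None,
    detection_floor: float = 0.0,
) -> ExpressionMatrix:
    """Read a probes × samples intensity TSV (first column probe IDs).

    If ``detection_path`` is given it must be a parallel boolean/0-1 matrix;
    otherwise ``detected := intensity > detection_floor``.
    """
    intensities = _read_numeric_tsv(path, f"expression matrix {path}")
    if detection_path is not None:
        det = pd.read_csv(detection_path, sep="\t", index_col=0)
        det.index = det.index.astype(str)
        det.columns = det.columns.astype(str)
        detected = det.astype(bool)
        if not detected.index.equals(intensities.index):
            detected = detected.reindex(index=intensities.index,
                                        columns=intensities.columns)
            if detected.isna().any().any():
                raise ValidationError(
                    "detection matrix does not cover the expression matrix"
                )
            detected = detected.astype(bool)
    else:
        detected = intensities > detection_floor
    return ExpressionMatrix(intensities, detected)


def read_samples(path: str | Path) -> SampleTable:
    """Read sample metadata: TSV with columns sample_id, group, and
    optionally lymphocytes/neutrophils/monocytes plus opaque extras."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValidationError("sample table lacks required column 'sample_id'")
    frame = frame.set_index("sample_id")
    return SampleTable(frame)


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a two-column probe_id → gene_symbol TSV (many-to-one allowed)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError("probe map needs two columns: probe_id, gene")
    series = frame.set_index(frame.columns[0])[frame.columns[1]]
    _check_unique(series.index, "probe IDs in probe map")
    series.name = "gene"
    return series


def intersect_probes(
    matrices: Sequence[ExpressionMatrix],
) -> list[ExpressionMatrix]:
    """Restrict every matrix to the probes present in all of them.

    Probe order follows the first matrix.  Raises on an empty intersection.
    """
    if not matrices:
        raise ValidationError("intersect_probes needs at least one matrix")
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if not common:
        raise ValidationError("probe intersection across matrices is empty")
    ordered = [p for p in matrices[0].probe_ids if p in common]
    n_dropped = sum(m.shape[0] - len(ordered) for m in matrices)
    if n_dropped:
        logger.info(
            "intersect_probes: %d common probes; %d probe rows dropped in total",
            len(ordered), n_dropped,
        )
    return [m.subset_probes(ordered) for m in matrices]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: tab-separated name, description, member symbols."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description and at least one member"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(
                    f"{path}:{lineno}: gene set {name!r} has an empty member list"
                )
            sets.append(GeneSet(name, description, tuple(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gs in collection:
            handle.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV, floats at 12 significant digits."""
    table.to_csv(path, sep="\t", float_format=f"%.{RESULT_PRECISION}g")


def read_results(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def read_geo_series_matrix(path: str | Path) -> pd.DataFrame:
    """Minimal GEO series-matrix reader: returns the numeric data block
    between the table-begin/table-end markers.  Convenience only; the
    pipeline's native dialect is the plain TSV of :func:`read_expression`.
    """
    rows: list[str] = []
    in_table = False
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if in_table:
                rows.append(line)
    if not rows:
        raise ValidationError(f"{path}: no series-matrix table block found")
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(rows)), sep="\t", index_col=0)
    frame.index = frame.index.astype(str).str.strip('"')
    frame.columns = frame.columns.astype(str).str.strip('"')
    return frame
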