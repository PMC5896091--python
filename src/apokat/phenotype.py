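"""Expression, drug-response, copy-number and cancer-category harmonization.

Produces the analysis-ready matrices consumed by the correlation layer:

* an expression table (cell line x gene, log2 scale) with probe-level
  measurements collapsed to one column per gene by arithmetic mean;
* a drug-response table (cell line x measure) with every column on the
  log10(IC50) scale, whichever dialect — natural-log IC50 or raw linear
  IC50 — the source used;
* copy-number loss calls thresholded on the log2 normalized ratio;
* a cell line -> cancer category map used for stratified analyses.

Missing values propagate as missing; downstream correlation uses
pairwise-complete observations, so no imputation is done here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)

#: log2 copy-number ratio below which a gene is called lost.
COPY_NUMBER_LOSS_THRESHOLD = -0.75


@dataclass
class ExpressionTable:
    """Cell line x gene matrix of log2 expression values.

    ``provenance`` records, per gene column, whether the value came from
    averaging multiple probes ("probe-averaged") or straight through
    ("direct").
    """

    values: pd.DataFrame
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated cell-line rows in expression table")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated gene columns in expression table")


@dataclass
class DrugResponseTable:
    """Cell line x drug-measure matrix, all values on the log10(IC50) scale.

    ``dialects`` records each column's source dialect ("natural-log" or
    "linear"); agents present in two sources keep two columns, so column
    names should carry the source (e.g. "lapatinib_GDSC", "lapatinib_CCLE").
    """

    values: pd.DataFrame
    dialects: dict[str, str]


@dataclass(frozen=True)
class CopyNumberCall:
    """Loss/intact call from a log2 normalized copy-number ratio."""

    cell_line_id: str
    log2_ratio: float
    status: str  # "intact" | "loss"


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> ExpressionTable:
    """Average multiple probes per gene into one column.

    ``probe_matrix`` has cell lines as rows and probes as columns (log2
    scale).  Probes without a gene assignment are dropped with a logged
    count.  The mean per (gene, cell line) ignores missing probe values; a
    value is missing only when all probes for that gene are missing in that
    cell line.
    """
    mapped = [p for p in probe_matrix.columns if p in probe_to_gene]
    unmapped = len(probe_matrix.columns) - len(mapped)
    if unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", unmapped)
    genes: dict[str, list[str]] = {}
    for probe in mapped:
        genes.setdefault(probe_to_gene[probe], []).append(probe)
    cols: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}
    for gene in sorted(genes):
        probes = genes[gene]
        cols[gene] = probe_matrix[probes].mean(axis=1, skipna=True)
        provenance[gene] = "probe-averaged" if len(probes) > 1 else "direct"
    values = pd.DataFrame(cols, index=probe_matrix.index)
    return ExpressionTable(values=values, provenance=provenance)


def harmonize_response(
    source_table: pd.DataFrame, dialect: str
) -> DrugResponseTable:
    """Convert a drug-response matrix to the log10(IC50) scale.

    ``dialect`` is "natural-log" (values are ln(IC50), divided by ln 10),
    "linear" (raw IC50, log10 taken; nonpositive values are an error), or
    "log10" (already on scale, passed through — this makes the operation
    idempotent).  Replicate measurements — duplicated (cell line, column)
    entries, i.e. duplicated row labels — are averaged on the log10 scale.
    """
    if dialect == "natural-log":
        values = source_table / LN10
    elif dialect == "linear":
        bad = source_table.le(0)
        if bad.any().any():
            rows, cols = np.nonzero(bad.to_numpy())
            r, c = rows[0], cols[0]
            raise ValueError(
                "nonpositive linear IC50 at "
                f"({source_table.index[r]!r}, {source_table.columns[c]!r})"
            )
        values = np.log10(source_table)
    elif dialect == "log10":
        values = source_table.copy()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    # replicate (cell line, agent) measurements collapse on the log10 scale
    if values.index.duplicated().any():
        values = values.groupby(level=0, sort=False).mean()
    stored = "log10" if dialect == "log10" else dialect
    return DrugResponseTable(
        values=values, dialects={c: stored for c in values.columns}
    )


def call_copy_number(cell_line_id: str, log2_ratio: float) -> CopyNumberCall:
    """Call copy-number loss when the log2 ratio falls below -0.75.

    The boundary belongs to "intact": a ratio of exactly -0.75 is not a
    loss.
    """
    if not math.isfinite(log2_ratio):
        raise ValueError(f"log2_ratio must be finite, got {log2_ratio}")
    status = "loss" if log2_ratio < COPY_NUMBER_LOSS_THRESHOLD else "intact"
    return CopyNumberCall(cell_line_id=cell_line_id, log2_ratio=log2_ratio, status=status)


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping cell line -> cancer category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("category map needs two columns: cell_line, category")
    cells, cats = df.iloc[:, 0], df.iloc[:, 1]
    if cells.duplicated().any():
        dup = cells[cells.duplicated()].iloc[0]
        raise ValueError(f"cell line {dup!r} mapped to more than one category")
    return dict(zip(cells, cats))


def write_category_map(mapping: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"cell_line": list(mapping), "category": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def apply_synonyms(
    table: pd.DataFrame, synonyms: Mapping[str, str]
) -> pd.DataFrame:
    """Rename cell-line row labels through a user-supplied synonym table.

    Reconciliation is exact-match only (no fuzzy matching); labels absent
    from the synonym table pass through unchanged.
    """
    renamed = table.rename(index=lambda s: synonyms.get(s, s))
    if renamed.index.duplicated().any():
        dup = renamed.index[renamed.index.duplicated()][0]
        raise ValueError(f"synonym mapping collapses two rows onto {dup!r}")
    return renamed


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix: header row of measure names, first column = cell line."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix TSV with full float precision (round-trip exact)."""
    df.to_csv(path, sep="\t", float_format="%.17g")
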