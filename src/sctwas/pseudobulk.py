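"""Cell-level QC, per-cell-type pseudobulk aggregation, and rank-percentile
expression targets.

Pseudobulk entries are sums of UMIs over the cells of one individual and one
cell type. Percentile targets use average-tie ranking mapped onto
``(rank - 1) / (G - 1)`` so values literally span 0..1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CellQCParams",
    "PseudobulkMatrix",
    "ExpressionPercentiles",
    "QCReport",
    "qc_filter",
    "aggregate_pseudobulk",
    "rank_percentile",
    "rank_percentile_per_individual",
]


@dataclass
class CellQCParams:
    max_total_counts: float = 10_000        # keep cells with total < this (strict)
    max_mito_fraction: float = 0.10         # keep cells with fraction < this (strict)
    min_genes_per_cell: int = 200           # keep cells expressing >= this many genes
    min_cells_per_gene: int = 3             # keep genes present in >= this many cells
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.max_total_counts < 0 or self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("QC thresholds must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    removed_total_counts: int
    removed_mito: int
    removed_min_genes: int
    removed_genes: int

    def __str__(self) -> str:  # pragma: no cover - logging convenience
        return (f"QC: {self.n_cells_in} cells in; removed {self.removed_total_counts} "
                f"(total counts), {self.removed_mito} (mito), "
                f"{self.removed_min_genes} (too few genes); "
                f"{self.removed_genes}/{self.n_genes_in} genes removed")


def qc_filter(counts: np.ndarray, meta: pd.DataFrame, gene_ids: Sequence[str],
              params: CellQCParams | None = None,
              ) -> tuple[np.ndarray, pd.DataFrame, list[str], QCReport]:
    """Drop cells violating any enabled threshold, then low-prevalence genes.

    ``counts`` is cells x genes. Thresholds can be disabled with ``math.inf``
    (upper bounds) or 0 (lower bounds). Raises if no cell survives.
    """
    params = params or CellQCParams()
    counts = np.asarray(counts)
    if counts.shape[0] != len(meta):
        raise ValueError("counts rows and metadata rows differ")
    if counts.shape[1] != len(gene_ids):
        raise ValueError("counts columns and gene_ids differ")
    gene_ids = list(gene_ids)

    total = counts.sum(axis=1)
    mito_mask = np.array([g.startswith(params.mito_prefix) for g in gene_ids])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, counts[:, mito_mask].sum(axis=1) / np.maximum(total, 1), 0.0)
    n_genes_expr = (counts > 0).sum(axis=1)

    ok_total = total < params.max_total_counts if math.isfinite(params.max_total_counts) \
        else np.ones(len(total), dtype=bool)
    ok_mito = mito_frac < params.max_mito_fraction if params.max_mito_fraction < 1.0 \
        else np.ones(len(total), dtype=bool)
    ok_genes = n_genes_expr >= params.min_genes_per_cell

    keep = ok_total & ok_mito & ok_genes
    report_counts = dict(
        removed_total_counts=int((~ok_total).sum()),
        removed_mito=int((~ok_mito).sum()),
        removed_min_genes=int((~ok_genes).sum()),
    )
    if not keep.any():
        raise ValueError(
            "all cells removed by QC: "
            + ", ".join(f"{k}={v}" for k, v in report_counts.items())
        )
    counts = counts[keep]
    meta = meta[keep].reset_index(drop=True)

    gene_prevalence = (counts > 0).sum(axis=0)
    gkeep = gene_prevalence >= params.min_cells_per_gene
    report = QCReport(
        n_cells_in=len(keep), n_genes_in=len(gene_ids),
        removed_genes=int((~gkeep).sum()), **report_counts,
    )
    counts = counts[:, gkeep]
    gene_ids = [g for g, k in zip(gene_ids, gkeep) if k]
    return counts, meta, gene_ids, report


@dataclass
class PseudobulkMatrix:
    """Gene x individual count sums for one cell type."""

    cell_type: str
    counts: pd.DataFrame                     # genes x individuals
    n_cells: pd.Series = field(default=None)  # per-individual cell counts

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("pseudobulk counts must be non-negative")


@dataclass
class ExpressionPercentiles:
    cell_type: str
    percentile: pd.Series  # gene -> value in [0, 1]


def aggregate_pseudobulk(counts: np.ndarray, meta: pd.DataFrame,
                         gene_ids: Sequence[str]) -> dict[str, PseudobulkMatrix]:
    """Sum UMIs per (gene, individual) within each cell type.

    Raises if any cell lacks an individual or cell-type label.
    """
    counts = np.asarray(counts)
    bad = meta.index[meta["individual_id"].isna() | meta["cell_type"].isna()]
    if len(bad):
        raise ValueError(f"cells with missing labels: {list(meta.loc[bad, 'cell_id'])}")
    out: dict[str, PseudobulkMatrix] = {}
    for ct, sub in meta.groupby("cell_type", sort=True):
        individuals = sorted(sub["individual_id"].unique())
        mat = np.zeros((len(gene_ids), len(individuals)))
        ncells = pd.Series(0, index=individuals, dtype=int)
        col_of = {ind: j for j, ind in enumerate(individuals)}
        for row, ind in zip(sub.index, sub["individual_id"]):
            mat[:, col_of[ind]] += counts[row]
            ncells[ind] += 1
        out[ct] = PseudobulkMatrix(
            cell_type=ct,
            counts=pd.DataFrame(mat, index=list(gene_ids), columns=individuals),
            n_cells=ncells,
        )
    return out


def _percentiles(values: np.ndarray) -> np.ndarray:
    ranks = rankdata(values, method="average")
    return (ranks - 1.0) / (len(values) - 1.0)


def rank_percentile(pb: PseudobulkMatrix) -> ExpressionPercentiles:
    """Across-gene target: mean count over individuals, ranked ascending
    (ties -> average rank), mapped to ``(rank - 1)/(G - 1)``."""
    if pb.counts.shape[0] < 2:
        raise ValueError("rank percentile undefined for a single gene")
    means = pb.counts.mean(axis=1).to_numpy()
    return ExpressionPercentiles(
        cell_type=pb.cell_type,
        percentile=pd.Series(_percentiles(means), index=pb.counts.index),
    )


def rank_percentile_per_individual(pb: PseudobulkMatrix) -> pd.DataFrame:
    """Across-individual target: the same transform applied within each
    individual's column independently; genes x individuals in [0, 1]."""
    if pb.counts.shape[0] < 2:
        raise ValueError("rank percentile undefined for a single gene")
    out = np.column_stack([
        _percentiles(pb.counts.iloc[:, j].to_numpy()) for j in range(pb.counts.shape[1])
    ])
    return pd.DataFrame(out, index=pb.counts.index, columns=pb.counts.columns)
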