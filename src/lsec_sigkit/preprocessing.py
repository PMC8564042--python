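"""Normalization and filtering of raw single-cell counts and bulk values.

Single-cell counts are rescaled to a fixed per-cell total (10,000 by
default) and natural-log1p transformed, the conventional representation the
downstream rank tests and module scores assume. Bulk values get an optional
log2-CPM transform; already-normalized tables pass through unchanged.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .io_formats import BulkMatrix, CountMatrix, NormalizedMatrix

__all__ = ["normalize_log1p_cp10k", "filter_cells_genes", "bulk_normalize_log2"]

DEFAULT_MIN_COUNTS_PER_CELL = 200
DEFAULT_MIN_CELLS_PER_GENE = 3


def normalize_log1p_cp10k(m: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """value(g, c) = log(1 + scale * count(g, c) / total(c)).

    Every cell must have a positive total count (filter first otherwise).
    The per-cell sum of exp(value) - 1 equals ``scale`` exactly up to
    floating point, so normalized cells are directly comparable.
    """
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = [m.cells[i] for i in np.flatnonzero(totals == 0)[:3]]
        raise ValueError(f"cells with zero total count (filter first): {bad}")
    x = m.counts.tocsc(copy=True).astype(float)
    # scale column c by scale / total(c); sparsity is preserved by log1p
    x = x @ sp.diags(scale / totals)
    x.data = np.log1p(x.data)
    return NormalizedMatrix(list(m.genes), list(m.cells), x.tocsr(), scale=scale)


def filter_cells_genes(
    m: CountMatrix,
    min_counts_per_cell: int = DEFAULT_MIN_COUNTS_PER_CELL,
    min_cells_per_gene: int = DEFAULT_MIN_CELLS_PER_GENE,
) -> CountMatrix:
    """Drop low-count cells, then genes detected in too few remaining cells.

    Order matters: cells are filtered first, so a gene's supporting cells are
    counted among retained cells only. Idempotent for fixed thresholds.
    """
    if min_counts_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("thresholds must be >= 0")
    cell_totals = np.asarray(m.counts.sum(axis=0)).ravel()
    keep_cells = cell_totals >= min_counts_per_cell
    if not keep_cells.any():
        raise ValueError("all cells removed by min_counts_per_cell filter")
    counts = m.counts[:, np.flatnonzero(keep_cells)]
    cells_per_gene = np.asarray((counts > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("all genes removed by min_cells_per_gene filter")
    return CountMatrix(
        [g for g, k in zip(m.genes, keep_genes) if k],
        [c for c, k in zip(m.cells, keep_cells) if k],
        counts[np.flatnonzero(keep_genes), :],
    )


def bulk_normalize_log2(m: BulkMatrix, mode: str = "cpm") -> BulkMatrix:
    """Bulk normalization: ``cpm`` -> log2(1 + 1e6 * v / column_sum); ``none`` -> identity."""
    if mode == "none":
        return m
    if mode != "cpm":
        raise ValueError(f"unknown mode {mode!r}; expected 'cpm' or 'none'")
    if np.any(m.values < 0):
        raise ValueError("cpm mode requires non-negative values")
    col_sums = m.values.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValueError("sample with zero column sum in cpm mode")
    vals = np.log2(1.0 + 1e6 * m.values / col_sums)
    return BulkMatrix(list(m.genes), list(m.samples), vals, dict(m.group))
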