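"""Per-gene two-group marker testing for single-cell data.

The marker definition used throughout the pipeline combines three filters:
a Wilcoxon rank-sum test on normalized expression (BH-adjusted), a linear
fold change computed on de-logged normalized means, and the fraction of
focal-population cells detecting the gene. A gene is flagged as a marker
when fc > min_fc (strictly), pct_focal >= min_pct_focal and q <= max_q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import CountMatrix, NormalizedMatrix

__all__ = [
    "wilcoxon_rank_sum",
    "fold_change",
    "pct_expressed",
    "bh_adjust",
    "find_markers",
    "MarkerTable",
]

FC_EPS = 1e-9
EXACT_MAX_N = 16


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when the pooled sample has <= 16 tie-free
    observations; otherwise the normal approximation with midranks,
    tie-corrected variance and continuity correction. Returns (U of the
    first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # complete overlap: no evidence either way
        return float(a.size * b.size / 2.0), 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and pooled.size <= EXACT_MAX_N) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _wilcoxon_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Wilcoxon p-values for genes x cells arrays.

    Same asymptotic path as :func:`wilcoxon_rank_sum`; rows where all pooled
    values are identical get p = 1.
    """
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.all(np.concatenate([a, b], axis=1) == a[:, :1], axis=1)
    p[constant | ~np.isfinite(p)] = 1.0
    return p


def fold_change(
    nm: NormalizedMatrix, focal_cells, ref_cells, gene: str
) -> tuple[float, float]:
    """Linear fold change focal/reference on de-logged normalized means.

    fc = (mean expm1(focal) + eps) / (mean expm1(ref) + eps), eps = 1e-9.
    """
    gi = nm.gene_idx([gene])[0]
    row = nm.values[gi, :].toarray().ravel()
    fa = np.expm1(row[nm.cell_idx(focal_cells)]).mean()
    fb = np.expm1(row[nm.cell_idx(ref_cells)]).mean()
    fc = (fa + FC_EPS) / (fb + FC_EPS)
    return float(fc), float(np.log2(fc))


def pct_expressed(cm: CountMatrix, cells, gene: str) -> float:
    """Fraction of the given cells with raw count > 0 for the gene."""
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell list")
    gi = cm.gene_idx([gene])[0]
    row = cm.counts[gi, cm.cell_idx(cells)].toarray().ravel()
    return float(np.mean(row > 0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return scipy.stats.false_discovery_control(p, method="bh")


@dataclass
class MarkerTable:
    """Differential-expression records for one two-group contrast."""

    focal: str
    reference: str
    records: pd.DataFrame  # columns: gene, fc, log2fc, pct_focal, pct_ref, p, q, significant
    params: dict = field(default_factory=dict)

    def significant_genes(self) -> list[str]:
        return list(self.records.loc[self.records["significant"], "gene"])

    def sorted(self) -> "MarkerTable":
        rec = self.records.sort_values(
            ["q", "log2fc"], ascending=[True, False], key=None
        ).reset_index(drop=True)
        return MarkerTable(self.focal, self.reference, rec, self.params)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def find_markers(
    cm: CountMatrix,
    nm: NormalizedMatrix,
    focal_cells,
    reference_cells,
    *,
    min_fc: float = 2.0,
    min_pct_focal: float = 0.0,
    max_q: float = 0.05,
    min_detect: float = 0.1,
    focal_label: str = "focal",
    reference_label: str = "reference",
) -> MarkerTable:
    """Test every sufficiently detected gene between two cell groups.

    Genes detected (raw count > 0) in at least ``min_detect`` of either group
    are tested; each record carries fc, log2fc, detection fractions, Wilcoxon
    p and BH q over the tested genes. ``significant`` requires fc strictly
    greater than ``min_fc``, pct_focal >= ``min_pct_focal`` and q <= ``max_q``.
    """
    focal_cells = list(focal_cells)
    reference_cells = list(reference_cells)
    if not focal_cells or not reference_cells:
        raise ValueError("focal and reference selections must be non-empty")
    if set(focal_cells) & set(reference_cells):
        raise ValueError("focal and reference selections overlap")

    fi = cm.cell_idx(focal_cells)
    ri = cm.cell_idx(reference_cells)
    raw_f = cm.counts[:, fi]
    raw_r = cm.counts[:, ri]
    pct_f = np.asarray((raw_f > 0).sum(axis=1)).ravel() / len(focal_cells)
    pct_r = np.asarray((raw_r > 0).sum(axis=1)).ravel() / len(reference_cells)

    tested = (pct_f >= min_detect) | (pct_r >= min_detect)
    if min_detect <= 0:
        tested = np.ones_like(tested, dtype=bool)
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        raise ValueError("no gene passes the detection prefilter")

    vals_f = nm.values[idx][:, nm.cell_idx(focal_cells)].toarray()
    vals_r = nm.values[idx][:, nm.cell_idx(reference_cells)].toarray()
    mean_f = np.expm1(vals_f).mean(axis=1)
    mean_r = np.expm1(vals_r).mean(axis=1)
    fc = (mean_f + FC_EPS) / (mean_r + FC_EPS)
    log2fc = np.log2(fc)
    p = _wilcoxon_matrix(vals_f, vals_r)
    q = bh_adjust(p)
    sig = (fc > min_fc) & (pct_f[idx] >= min_pct_focal) & (q <= max_q)

    records = pd.DataFrame(
        {
            "gene": [cm.genes[i] for i in idx],
            "fc": fc,
            "log2fc": log2fc,
            "pct_focal": pct_f[idx],
            "pct_ref": pct_r[idx],
            "p": p,
            "q": q,
            "significant": sig,
        }
    )
    params = {
        "min_fc": min_fc,
        "min_pct_focal": min_pct_focal,
        "max_q": max_q,
        "min_detect": min_detect,
        "n_focal": len(focal_cells),
        "n_reference": len(reference_cells),
    }
    return MarkerTable(focal_label, reference_label, records, params)
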