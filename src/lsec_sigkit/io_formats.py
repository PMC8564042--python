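"""Domain containers and readers/writers for the formats the pipeline touches.

Single-cell counts travel as 10x-style MatrixMarket triplets (matrix.mtx +
genes.tsv + barcodes.tsv), gene sets as GMT, per-cell annotations and bulk
matrices as plain TSV. All text output is UTF-8 and tab-separated.

Gene symbols are uppercased at the :class:`GeneSet` boundary only; expression
matrices keep their original case. Cross-species matching (e.g. mouse Fabp4
against human FABP4) is therefore done by case-insensitive symbol comparison
throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "CellAnnotation",
    "GeneSet",
    "GeneSetCollection",
    "BulkMatrix",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_gmt",
    "write_gmt",
    "read_cell_annotations",
    "write_cell_annotations",
    "read_bulk_tsv",
    "write_bulk_tsv",
    "concat_cells",
]


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(x for x in labels if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what}: {dup!r}")


@dataclass
class CountMatrix:
    """Raw counts, genes x cells, sparse-capable.

    Counts must be non-negative integers; gene symbols and cell ids are
    unique and order-preserving.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        _check_unique(self.genes, "gene symbol")
        _check_unique(self.cells, "cell id")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._cell_index = {c: i for i, c in enumerate(self.cells)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_idx(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def cell_idx(self, cells: Iterable[str]) -> np.ndarray:
        return np.array([self._cell_index[c] for c in cells], dtype=int)

    def subset_cells(self, cells: Sequence[str]) -> "CountMatrix":
        idx = self.cell_idx(cells)
        return CountMatrix(list(self.genes), list(cells), self.counts[:, idx])

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_idx(genes)
        return CountMatrix(list(genes), list(self.cells), self.counts[idx, :])


@dataclass
class NormalizedMatrix:
    """log1p of counts rescaled to a fixed per-cell total (genes x cells)."""

    genes: list[str]
    cells: list[str]
    values: sp.csr_matrix
    scale: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("normalized matrix shape mismatch")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._cell_index = {c: i for i, c in enumerate(self.cells)}

    def gene_idx(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def cell_idx(self, cells: Iterable[str]) -> np.ndarray:
        return np.array([self._cell_index[c] for c in cells], dtype=int)


@dataclass
class CellAnnotation:
    """Per-cell population and condition labels."""

    df: pd.DataFrame  # index: cell_id; columns: population, condition

    def __post_init__(self) -> None:
        missing = {"population", "condition"} - set(self.df.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValueError(f"duplicate cell_id: {dup!r}")
        if (self.df["population"].astype(str) == "").any() or (
            self.df["condition"].astype(str) == ""
        ).any():
            raise ValueError("population and condition labels must be non-empty")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.df.index)

    def cells(self, population: str | None = None, condition: str | None = None) -> list[str]:
        """Cell ids matching the given population and/or condition."""
        mask = pd.Series(True, index=self.df.index)
        if population is not None:
            mask &= self.df["population"] == population
        if condition is not None:
            mask &= self.df["condition"] == condition
        return list(self.df.index[mask])

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.df["population"]))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.df["condition"]))


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene symbols (stored uppercase) with a derivation trail."""

    name: str
    genes: frozenset[str]
    description: str = ""
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def with_note(self, note: str) -> "GeneSet":
        return GeneSet(self.name, self.genes, self.description, self.provenance + (note,))

    def renamed(self, name: str, description: str | None = None) -> "GeneSet":
        return GeneSet(
            name,
            self.genes,
            self.description if description is None else description,
            self.provenance,
        )

    def intersect(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(
            name or self.name,
            self.genes & other.genes,
            self.description,
            self.provenance
            + other.provenance
            + (f"intersect({self.name} [n={len(self)}], {other.name} [n={len(other)}])",),
        )

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered list of gene sets with unique names; GMT-serializable."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene-set name")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class BulkMatrix:
    """Bulk expression, genes x samples, with a two-group sample design."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    group: Mapping[str, str]  # sample_id -> group label

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("bulk matrix shape mismatch")
        _check_unique(self.genes, "gene symbol")
        _check_unique(self.samples, "sample id")
        if np.isnan(self.values).any():
            raise ValueError("bulk matrix contains missing values")
        missing = [s for s in self.samples if s not in self.group]
        if missing:
            raise ValueError(f"samples without group label: {missing[:3]}")
        labels = list(dict.fromkeys(self.group[s] for s in self.samples))
        if len(labels) != 2:
            raise ValueError(f"exactly two group labels required, found {labels}")
        counts = {lab: sum(self.group[s] == lab for s in self.samples) for lab in labels}
        if min(counts.values()) < 2:
            raise ValueError(f"each group needs >= 2 samples, found {counts}")
        self.group_order: list[str] = labels

    def sample_idx(self, label: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if self.group[s] == label])

    def group_values(self, label: str) -> np.ndarray:
        return self.values[:, self.sample_idx(label)]


# ---------------------------------------------------------------------------
# MatrixMarket triplets


def read_counts_mtx(directory_path: str | Path) -> CountMatrix:
    """Read a 10x-style triplet (matrix.mtx, genes.tsv, barcodes.tsv).

    The on-disk orientation is inferred from the label-file lengths: whichever
    axis matches the gene list becomes the row axis. An ambiguous square
    matrix is assumed to be genes x cells (logged).
    """
    d = Path(directory_path)
    mtx = d / "matrix.mtx"
    genes_f = d / "genes.tsv"
    cells_f = d / "barcodes.tsv"
    for f in (mtx, genes_f, cells_f):
        if not f.exists():
            raise FileNotFoundError(f"missing file: {f}")
    genes = genes_f.read_text().splitlines()
    cells = cells_f.read_text().splitlines()
    m = sp.coo_matrix(scipy.io.mmread(mtx))
    total = m.sum()
    if m.shape == (len(genes), len(cells)):
        if m.shape[0] == m.shape[1]:
            logger.warning("square matrix in %s: assuming genes x cells orientation", d)
    elif m.shape == (len(cells), len(genes)):
        m = m.T
    else:
        raise ValueError(
            f"matrix shape {m.shape} matches neither {len(genes)} genes x "
            f"{len(cells)} cells nor its transpose"
        )
    cm = CountMatrix(genes, cells, sp.csr_matrix(m))
    assert cm.counts.sum() == total  # orientation inference must not drop data
    return cm


def write_counts_mtx(cm: CountMatrix, directory_path: str | Path) -> None:
    """Write a CountMatrix as a genes x cells MatrixMarket triplet."""
    d = Path(directory_path)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / "matrix.mtx", sp.coo_matrix(cm.counts), field="integer")
    (d / "genes.tsv").write_text("\n".join(cm.genes) + "\n")
    (d / "barcodes.tsv").write_text("\n".join(cm.cells) + "\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB gene [TAB gene ...]."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
        sets.append(GeneSet(name, frozenset(g.upper() for g in genes), desc))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; the description field is written even if empty."""
    lines = []
    for s in collection:
        if not s.genes:
            raise ValueError(f"gene set {s.name!r} is empty; cannot serialize to GMT")
        lines.append("\t".join([s.name, s.description, *s.sorted_genes()]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation / bulk TSV


def read_cell_annotations(path: str | Path) -> CellAnnotation:
    """Read a TSV with columns cell_id, population, condition (extras ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "population", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id: {dup!r}")
    out = df.set_index("cell_id")[["population", "condition"]]
    return CellAnnotation(out)


def write_cell_annotations(ann: CellAnnotation, path: str | Path) -> None:
    ann.df.reset_index(names="cell_id").to_csv(path, sep="\t", index=False)


def read_bulk_tsv(values_path: str | Path, groups_path: str | Path) -> BulkMatrix:
    """Read a genes x samples TSV plus a (sample_id, group) TSV."""
    df = pd.read_csv(values_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(gdf.columns):
        raise ValueError("groups file needs columns sample_id, group")
    group = dict(zip(gdf["sample_id"], gdf["group"]))
    return BulkMatrix(list(df.index), list(df.columns), df.to_numpy(float), group)


def write_bulk_tsv(bulk: BulkMatrix, values_path: str | Path, groups_path: str | Path) -> None:
    pd.DataFrame(bulk.values, index=pd.Index(bulk.genes, name="gene"), columns=bulk.samples).to_csv(
        values_path, sep="\t"
    )
    pd.DataFrame(
        {"sample_id": bulk.samples, "group": [bulk.group[s] for s in bulk.samples]}
    ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Combination helpers


def concat_cells(a: CountMatrix, b: CountMatrix) -> CountMatrix:
    """Column-concatenate two count matrices sharing the same gene list."""
    if a.genes != b.genes:
        raise ValueError("matrices must share an identical gene list")
    overlap = set(a.cells) & set(b.cells)
    if overlap:
        raise ValueError(f"cell ids overlap: {sorted(overlap)[:3]}")
    return CountMatrix(list(a.genes), list(a.cells) + list(b.cells), sp.hstack([a.counts, b.counts]).tocsr())


def concat_annotations(a: CellAnnotation, b: CellAnnotation) -> CellAnnotation:
    return CellAnnotation(pd.concat([a.df, b.df]))
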