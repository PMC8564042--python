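"""Synthetic single-cell and bulk datasets with planted, known structure.

The single-cell generator draws negative-binomial counts with gene-level
log-normal baseline means and per-cell log-normal size factors — the minimal
model reproducing the overdispersion and detection-fraction behavior that
the marker filters (fold change > 2, expressed in >= 50% of focal cells)
depend on. Markers are planted by multiplying a gene's mean by a fold
change inside a chosen population (optionally restricted to one condition).

``simulate_case_study`` builds the full evaluation scenario: a healthy liver
dataset (LSEC, EC, macrophage, hepatocyte), a cirrhotic dataset sharing the
gene space with an extra damaged LSEC/EC population, and an acute-injury
style bulk experiment on sorted LSECs. Planted genes are given familiar
liver endothelial symbols purely as synthetic stand-ins; every ground-truth
membership is returned so derivation, scoring and enrichment can be checked
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import BulkMatrix, CellAnnotation, CountMatrix, GeneSet

__all__ = [
    "ScSimSpec",
    "BulkSimSpec",
    "GroundTruth",
    "CaseStudyBundle",
    "simulate_sc_dataset",
    "simulate_bulk_dataset",
    "simulate_case_study",
]


@dataclass
class ScSimSpec:
    """Parameters of one simulated single-cell dataset.

    ``populations`` lists (label, condition, n_cells); ``planted_markers``
    lists (population label, condition or None, gene indices, fold_change).
    A marker with condition None is planted in the population across all
    conditions. ``baseline_mean_override`` pins specific genes' baseline NB
    means so planted markers sit at a known expression level.
    """

    n_genes: int
    populations: list[tuple[str, str, int]]
    baseline_log_mean_mu: float = 0.0
    baseline_log_mean_sigma: float = 1.0
    dispersion: float = 2.0  # NB size parameter r; var = mu + mu^2 / r
    planted_markers: list[tuple[str, str | None, list[int], float]] = field(default_factory=list)
    baseline_mean_override: dict[int, float] = field(default_factory=dict)
    baseline_means: np.ndarray | None = None  # full per-gene baseline, shared across datasets
    library_size_factor_sigma: float = 0.2
    gene_names: list[str] | None = None
    cell_prefix: str = "cell"
    seed: int = 0

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if len({(lab, cond) for lab, cond, _ in self.populations}) != len(self.populations):
            raise ValueError("population labels must be unique per condition")
        for _, _, n in self.populations:
            if n < 2:
                raise ValueError("each population needs >= 2 cells")
        for pop, cond, idx, fc in self.planted_markers:
            if fc < 1:
                raise ValueError("planted fold_change must be >= 1")
            if any(i < 0 or i >= self.n_genes for i in idx):
                raise ValueError("marker gene index out of range")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length mismatch")
        if self.baseline_means is not None and len(self.baseline_means) != self.n_genes:
            raise ValueError("baseline_means length mismatch")


@dataclass
class BulkSimSpec:
    """Two-group bulk design on a log2 expression scale.

    values = log-normal baseline (per gene) + log2 shift in group 2 for
    planted genes + N(0, noise_sigma) noise.
    """

    n_genes: int
    groups: list[tuple[str, int]]  # exactly two (label, n_samples)
    noise_sigma: float = 0.25
    planted_sets: list[tuple[str, list[int], float]] = field(default_factory=list)
    baseline_mu: float = 6.0
    baseline_sigma: float = 2.0
    gene_names: list[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if len(self.groups) != 2:
            raise ValueError("exactly two groups required")
        for _, n in self.groups:
            if n < 3:
                raise ValueError("each group needs >= 3 samples")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name, idx, shift in self.planted_sets:
            if not np.isfinite(shift):
                raise ValueError("planted shift must be finite")
            if any(i < 0 or i >= self.n_genes for i in idx):
                raise ValueError("planted gene index out of range")


@dataclass
class GroundTruth:
    """Planted memberships: marker map and bulk-shift map, by gene symbol."""

    markers: dict[str, set[str]] = field(default_factory=dict)
    bulk_shifts: dict[str, set[str]] = field(default_factory=dict)

    def as_gene_sets(self) -> list[GeneSet]:
        out = [
            GeneSet(f"truth_markers_{k}", frozenset(v), "planted marker genes")
            for k, v in self.markers.items()
        ]
        out += [
            GeneSet(f"truth_bulk_{k}", frozenset(v), "planted bulk shift genes")
            for k, v in self.bulk_shifts.items()
        ]
        return out


def _default_gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"SGENE{i + 1:0{width}d}" for i in range(n)]


def simulate_sc_dataset(spec: ScSimSpec) -> tuple[CountMatrix, CellAnnotation, GroundTruth]:
    """Draw one NB count matrix with planted markers, plus labels and truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names or _default_gene_names(spec.n_genes)

    if spec.baseline_means is not None:
        baseline = np.asarray(spec.baseline_means, dtype=float).copy()
    else:
        baseline = rng.lognormal(
            spec.baseline_log_mean_mu, spec.baseline_log_mean_sigma, spec.n_genes
        )
    for gi, mean in spec.baseline_mean_override.items():
        baseline[gi] = mean

    n_cells = sum(n for _, _, n in spec.populations)
    size_factors = rng.lognormal(0.0, spec.library_size_factor_sigma, n_cells)

    cell_ids: list[str] = []
    pops: list[str] = []
    conds: list[str] = []
    mu = np.empty((spec.n_genes, n_cells))
    col = 0
    for label, condition, n in spec.populations:
        fold = np.ones(spec.n_genes)
        for mpop, mcond, idx, fc in spec.planted_markers:
            if mpop == label and (mcond is None or mcond == condition):
                fold[np.asarray(idx, dtype=int)] *= fc
        block_mu = (baseline * fold)[:, None] * size_factors[None, col : col + n]
        mu[:, col : col + n] = block_mu
        for j in range(n):
            cell_ids.append(f"{spec.cell_prefix}_{condition}_{label}_{j + 1}")
        pops += [label] * n
        conds += [condition] * n
        col += n

    r = spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    cm = CountMatrix(genes, cell_ids, sp.csr_matrix(counts))
    ann = CellAnnotation(
        pd.DataFrame({"population": pops, "condition": conds}, index=pd.Index(cell_ids, name="cell_id"))
    )
    truth = GroundTruth()
    for mpop, mcond, idx, fc in spec.planted_markers:
        if fc > 1:
            key = mpop if mcond is None else f"{mpop}@{mcond}"
            truth.markers.setdefault(key, set()).update(genes[i].upper() for i in idx)
    return cm, ann, truth


def simulate_bulk_dataset(spec: BulkSimSpec) -> tuple[BulkMatrix, GroundTruth]:
    """Draw a two-group log2-scale bulk matrix with planted group-2 shifts."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names or _default_gene_names(spec.n_genes)

    baseline = np.log2(rng.lognormal(spec.baseline_mu * np.log(2), spec.baseline_sigma * np.log(2), spec.n_genes))
    (lab1, n1), (lab2, n2) = spec.groups
    samples = [f"{lab1}_{i + 1}" for i in range(n1)] + [f"{lab2}_{i + 1}" for i in range(n2)]
    group = {s: (lab1 if i < n1 else lab2) for i, s in enumerate(samples)}

    values = baseline[:, None] + rng.normal(0.0, spec.noise_sigma, (spec.n_genes, n1 + n2))
    truth = GroundTruth()
    for name, idx, shift in spec.planted_sets:
        values[np.asarray(idx, dtype=int), n1:] += shift
        truth.bulk_shifts[name] = {genes[i].upper() for i in idx}
    return BulkMatrix(genes, samples, values, group), truth


# ---------------------------------------------------------------------------
# The default case study

# Synthetic stand-in symbols for the planted genes. Familiar liver
# endothelial names are used for readability of the derived signatures;
# the data behind them are simulated, not measured.
DAMAGED_SPECIFIC = ["FABP4", "FABP5", "VWF", "VWA1"]
SHARED_EC = ["PLVAP", "CD34", "PECAM1", "ENG", "CDH5", "ESAM"]
LSEC_INJURY_DOWN = [
    "STAB2", "CLEC4G", "OIT3", "PLPP3", "NTN4", "NPL",
    "CD209", "MRC1", "FCGR2B", "KDR", "NRP1", "GPR182",
]
LSEC_INJURY_UP = [
    "LYVE1", "CLEC1B", "CD36", "STAB1", "IL33", "CD14",
    "TIMP1", "TIMP2", "CCL6", "EHD3", "DNASE1L3", "F8",
    "MGP", "AQP1", "RAMP2", "GPIHBP1", "MAF", "WNT2",
]
LSEC_MARKERS = LSEC_INJURY_DOWN + LSEC_INJURY_UP

CASE_N_GENES = 2000
CASE_CELLS_PER_POP = 300
CASE_MARKER_FC = 8.0
CASE_MARKER_BASELINE = 1.0
CASE_BULK_SAMPLES = 8
CASE_BULK_NOISE = 0.25
CASE_BULK_DOWN_SHIFT = -2.0
CASE_BULK_UP_SHIFT = 1.0


@dataclass
class CaseStudyBundle:
    healthy_counts: CountMatrix
    healthy_annotation: CellAnnotation
    cirrhotic_counts: CountMatrix
    cirrhotic_annotation: CellAnnotation
    bulk: BulkMatrix
    truth: GroundTruth


def _case_gene_names() -> list[str]:
    special = LSEC_MARKERS + SHARED_EC + DAMAGED_SPECIFIC
    filler = _default_gene_names(CASE_N_GENES)
    names = list(special) + filler[: CASE_N_GENES - len(special)]
    return names


def simulate_case_study(seed: int = 1) -> CaseStudyBundle:
    """Healthy + cirrhotic single-cell datasets and an injury bulk dataset.

    Planted structure (all fold changes 8 on a baseline NB mean of 1):

    * 30 LSEC markers, expressed in the LSEC population of both conditions;
      in the bulk experiment 12 of them ("injury-down") are shifted -2 log2
      units in injured samples and the other 18 are shifted +1 (genes that
      rise upon acute injury and must be excluded from the restricted
      healthy signature).
    * 4 damaged-specific genes, up only in the cirrhotic-only damaged
      LSEC/EC population.
    * 6 shared endothelial genes, up in the damaged population and in
      healthy-condition ECs — enriched for damaged cells within cirrhotic
      livers but removed by the refine step against healthy ECs.
    """
    genes = _case_gene_names()
    name_to_idx = {g: i for i, g in enumerate(genes)}
    lsec_idx = [name_to_idx[g] for g in LSEC_MARKERS]
    dmg_idx = [name_to_idx[g] for g in DAMAGED_SPECIFIC]
    shared_idx = [name_to_idx[g] for g in SHARED_EC]
    override = {i: CASE_MARKER_BASELINE for i in lsec_idx + dmg_idx + shared_idx}

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    # one shared per-gene baseline: the two liver datasets describe the same
    # gene space, so baseline expression must not differ by condition
    baseline = rng.lognormal(0.0, 1.0, CASE_N_GENES)

    healthy_spec = ScSimSpec(
        n_genes=CASE_N_GENES,
        populations=[(p, "healthy", CASE_CELLS_PER_POP) for p in ("LSEC", "EC", "macrophage", "hepatocyte")],
        planted_markers=[
            ("LSEC", None, lsec_idx, CASE_MARKER_FC),
            ("EC", "healthy", shared_idx, CASE_MARKER_FC),
        ],
        baseline_means=baseline,
        baseline_mean_override=override,
        gene_names=genes,
        cell_prefix="h",
        seed=int(seeds[0]),
    )
    cirrhotic_spec = ScSimSpec(
        n_genes=CASE_N_GENES,
        populations=[
            (p, "cirrhotic", CASE_CELLS_PER_POP)
            for p in ("LSEC", "EC", "macrophage", "hepatocyte", "damaged_LSEC_EC")
        ],
        planted_markers=[
            ("LSEC", None, lsec_idx, CASE_MARKER_FC),
            ("damaged_LSEC_EC", None, dmg_idx, CASE_MARKER_FC),
            ("damaged_LSEC_EC", None, shared_idx, CASE_MARKER_FC),
        ],
        baseline_means=baseline,
        baseline_mean_override=override,
        gene_names=genes,
        cell_prefix="c",
        seed=int(seeds[1]),
    )
    # Bulk mimics sorted LSECs from healthy vs acutely injured livers, with
    # mouse-style mixed-case symbols to exercise case-insensitive matching.
    bulk_genes = [g.capitalize() for g in genes]
    bulk_spec = BulkSimSpec(
        n_genes=CASE_N_GENES,
        groups=[("healthy", CASE_BULK_SAMPLES), ("injured", CASE_BULK_SAMPLES)],
        noise_sigma=CASE_BULK_NOISE,
        planted_sets=[
            ("injury_down", [name_to_idx[g] for g in LSEC_INJURY_DOWN], CASE_BULK_DOWN_SHIFT),
            ("injury_up", [name_to_idx[g] for g in LSEC_INJURY_UP], CASE_BULK_UP_SHIFT),
        ],
        gene_names=bulk_genes,
        seed=int(seeds[2]),
    )

    h_cm, h_ann, h_truth = simulate_sc_dataset(healthy_spec)
    c_cm, c_ann, c_truth = simulate_sc_dataset(cirrhotic_spec)
    bulk, b_truth = simulate_bulk_dataset(bulk_spec)

    truth = GroundTruth(
        markers={
            "LSEC": set(g.upper() for g in LSEC_MARKERS),
            "damaged_specific": set(DAMAGED_SPECIFIC),
            "shared_EC": set(SHARED_EC),
        },
        bulk_shifts=b_truth.bulk_shifts,
    )
    return CaseStudyBundle(h_cm, h_ann, c_cm, c_ann, bulk, truth)
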