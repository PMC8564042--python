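"""Staged derivation of healthy- and damaged-LSEC gene sets and signatures.

The procedure mirrors how marker sets for a focal endothelial state are
built from annotated single-cell data:

1. *Population enrichment* — genes higher expressed in the focal population
   than in every other population separately (fold change strictly > 2,
   Wilcoxon q <= 0.05), additionally expressed in >= 50% of focal cells.
2. *Condition contrast* — genes up in healthy LSECs vs the damaged LSEC/EC
   population and vice versa.
3. *State gene sets* — intersection of (1) and (2) per state.
4. *Refined damaged signature* — the damaged state set restricted to genes
   also up against healthy endothelial cells, removing generic endothelial
   genes shared with healthy ECs.
5. *Concordance filter* — the healthy state set restricted by the sign of
   its behavior in a two-group bulk experiment (e.g. keep genes that drop
   in acutely injured LSECs), yielding the restricted healthy signature.

Cell groups are addressed with (population, condition) selectors so each
stage can be scoped to the condition it belongs to. Every returned
:class:`~lsec_sigkit.io_formats.GeneSet` carries its parameter trail in
``provenance``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential_expression import find_markers
from .io_formats import BulkMatrix, CellAnnotation, CountMatrix, GeneSet, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DerivationConfig",
    "IntersectionSummary",
    "enriched_vs_all_types",
    "condition_contrast",
    "build_state_genesets",
    "refine_damaged_signature",
    "concordance_filter",
    "intersection_summary",
    "derive_case_signatures",
]

Selector = tuple[str, str | None]  # (population, condition or None)


@dataclass
class DerivationConfig:
    """Thresholds and labels of the staged derivation."""

    fc_min: float = 2.0  # strict: fc must exceed this
    pct_min: float = 0.5  # focal detection fraction for enrichment sets
    max_q: float = 0.05
    min_detect: float = 0.1
    healthy_lsec: Selector = ("LSEC", "healthy")
    damaged_pop: Selector = ("damaged_LSEC_EC", "cirrhotic")
    healthy_ec: Selector = ("EC", "healthy")
    healthy_condition: str = "healthy"
    damaged_condition: str = "cirrhotic"
    comparison_mode: str = "one_vs_each"  # or "one_vs_pooled"

    def __post_init__(self) -> None:
        if self.fc_min <= 0 or self.pct_min < 0 or not (0 < self.max_q <= 1):
            raise ValueError("invalid derivation thresholds")
        if self.comparison_mode not in ("one_vs_each", "one_vs_pooled"):
            raise ValueError(f"unknown comparison_mode {self.comparison_mode!r}")


def _cells(ann: CellAnnotation, sel: Selector) -> list[str]:
    pop, cond = sel
    cells = ann.cells(population=pop, condition=cond)
    if not cells:
        raise ValueError(f"no cells match population={pop!r} condition={cond!r}")
    return cells


def _sel_name(sel: Selector) -> str:
    pop, cond = sel
    return pop if cond is None else f"{pop}@{cond}"


def enriched_vs_all_types(
    cm: CountMatrix,
    nm: NormalizedMatrix,
    annotation: CellAnnotation,
    focal: Selector,
    other_populations: list[Selector],
    config: DerivationConfig,
) -> GeneSet:
    """Genes enriched in the focal population against every other population.

    ``one_vs_each`` (default): intersection over separate pairwise marker
    calls, one per comparison population. ``one_vs_pooled``: a single call
    against all comparison cells pooled. In both modes the result is further
    restricted to genes detected in >= pct_min of focal cells.
    """
    if not other_populations:
        raise ValueError("need at least one comparison population")
    focal_cells = _cells(annotation, focal)
    provenance = [
        f"enriched_vs_all_types(focal={_sel_name(focal)}, fc>{config.fc_min}, "
        f"pct_focal>={config.pct_min}, q<={config.max_q}, mode={config.comparison_mode})"
    ]

    def flagged(ref_sel: Selector, ref_cells: list[str]) -> set[str]:
        table = find_markers(
            cm,
            nm,
            focal_cells,
            ref_cells,
            min_fc=config.fc_min,
            min_pct_focal=config.pct_min,
            max_q=config.max_q,
            min_detect=config.min_detect,
            focal_label=_sel_name(focal),
            reference_label=_sel_name(ref_sel),
        )
        genes = {g.upper() for g in table.significant_genes()}
        provenance.append(f"  vs {_sel_name(ref_sel)}: {len(genes)} genes")
        return genes

    if config.comparison_mode == "one_vs_pooled":
        pooled: list[str] = []
        for sel in other_populations:
            pooled += _cells(annotation, sel)
        result = flagged(("pooled_rest", None), pooled)
    else:
        sets = [flagged(sel, _cells(annotation, sel)) for sel in other_populations]
        result = set.intersection(*sets)
    return GeneSet(
        f"enriched_{_sel_name(focal)}",
        frozenset(result),
        f"genes enriched in {_sel_name(focal)} vs all other populations",
        tuple(provenance),
    )


def condition_contrast(
    cm: CountMatrix,
    nm: NormalizedMatrix,
    annotation: CellAnnotation,
    pop_a: Selector,
    pop_b: Selector,
    config: DerivationConfig,
) -> tuple[GeneSet, GeneSet]:
    """Genes up in population/state a vs b and vice versa (disjoint sets)."""
    cells_a = _cells(annotation, pop_a)
    cells_b = _cells(annotation, pop_b)
    note = f"condition_contrast({_sel_name(pop_a)} vs {_sel_name(pop_b)}, fc>{config.fc_min}, q<={config.max_q})"
    kwargs = dict(
        min_fc=config.fc_min, min_pct_focal=0.0, max_q=config.max_q, min_detect=config.min_detect
    )
    up_a = find_markers(cm, nm, cells_a, cells_b, **kwargs).significant_genes()
    up_b = find_markers(cm, nm, cells_b, cells_a, **kwargs).significant_genes()
    return (
        GeneSet(f"up_in_{_sel_name(pop_a)}", frozenset(up_a), "", (note,)),
        GeneSet(f"up_in_{_sel_name(pop_b)}", frozenset(up_b), "", (note,)),
    )


def build_state_genesets(
    enriched_healthy: GeneSet,
    enriched_damaged: GeneSet,
    up_in_healthy: GeneSet,
    up_in_damaged: GeneSet,
) -> tuple[GeneSet, GeneSet]:
    """Combine enrichment and condition contrast into per-state gene sets."""
    healthy = enriched_healthy.intersect(up_in_healthy, name="healthy_LSEC_geneset")
    damaged = enriched_damaged.intersect(up_in_damaged, name="damaged_LSEC_EC_geneset")
    return healthy, damaged


def refine_damaged_signature(
    damaged_geneset: GeneSet,
    cm: CountMatrix,
    nm: NormalizedMatrix,
    annotation: CellAnnotation,
    damaged_pop: Selector,
    healthy_ec_pop: Selector,
    config: DerivationConfig,
) -> GeneSet:
    """Restrict the damaged state set to genes also up vs healthy ECs.

    Removes generic endothelial genes shared with healthy ECs, leaving a
    compact damaged-LSEC signature. An empty result is allowed but logged.
    """
    if not damaged_geneset.genes:
        raise ValueError("damaged gene set is empty")
    table = find_markers(
        cm,
        nm,
        _cells(annotation, damaged_pop),
        _cells(annotation, healthy_ec_pop),
        min_fc=config.fc_min,
        min_pct_focal=0.0,
        max_q=config.max_q,
        min_detect=config.min_detect,
        focal_label=_sel_name(damaged_pop),
        reference_label=_sel_name(healthy_ec_pop),
    )
    up_vs_ec = GeneSet(
        f"up_{_sel_name(damaged_pop)}_vs_{_sel_name(healthy_ec_pop)}",
        frozenset(table.significant_genes()),
        "",
        (f"refine: fc>{config.fc_min}, q<={config.max_q}",),
    )
    sig = damaged_geneset.intersect(up_vs_ec, name="damaged_LSEC_signature")
    if not sig.genes:
        logger.warning("refined damaged signature is EMPTY: no state-set gene is up vs healthy ECs")
    return sig


def concordance_filter(
    geneset: GeneSet, bulk: BulkMatrix, direction: str = "down_in_group2"
) -> GeneSet:
    """Keep genes whose bulk group-2 minus group-1 mean has the required sign.

    Gene matching is case-insensitive; genes absent from the bulk matrix are
    dropped and recorded in provenance.
    """
    if direction not in ("down_in_group2", "up_in_group2"):
        raise ValueError(f"unknown direction {direction!r}")
    g1, g2 = bulk.group_order
    diff = bulk.group_values(g2).mean(axis=1) - bulk.group_values(g1).mean(axis=1)
    by_upper = {}
    for i, g in enumerate(bulk.genes):
        by_upper.setdefault(g.upper(), i)

    kept, absent = [], []
    for gene in geneset.sorted_genes():
        i = by_upper.get(gene)
        if i is None:
            absent.append(gene)
            continue
        d = diff[i]
        if (direction == "down_in_group2" and d < 0) or (direction == "up_in_group2" and d > 0):
            kept.append(gene)
    notes = (
        f"concordance_filter(direction={direction}, groups={g1}->{g2}, "
        f"kept {len(kept)}/{len(geneset)})",
    )
    if absent:
        notes += (f"  absent from bulk, dropped: {','.join(absent)}",)
        logger.info("concordance filter dropped %d genes absent from bulk", len(absent))
    return GeneSet(
        f"{geneset.name}_restricted", frozenset(kept), geneset.description, geneset.provenance + notes
    )


@dataclass
class IntersectionSummary:
    """Exclusive (upset-style) membership counts over a family of gene sets."""

    set_names: list[str]
    membership: pd.DataFrame  # genes x sets boolean
    counts: dict[frozenset[str], int] = field(init=False)

    def __post_init__(self) -> None:
        combos: dict[frozenset[str], int] = {}
        for _, row in self.membership.iterrows():
            combo = frozenset(self.membership.columns[row.to_numpy(bool)])
            combos[combo] = combos.get(combo, 0) + 1
        self.counts = combos

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"combination": "&".join(sorted(combo)), "degree": len(combo), "count": n}
            for combo, n in self.counts.items()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["degree", "combination"])
            .reset_index(drop=True)
        )


def intersection_summary(sets: list[GeneSet]) -> IntersectionSummary:
    """Upset semantics: each union gene counted in exactly one combination."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    union = sorted(set(itertools.chain.from_iterable(s.genes for s in sets)))
    membership = pd.DataFrame(
        {s.name: [g in s.genes for g in union] for s in sets}, index=union
    )
    return IntersectionSummary(names, membership)


def derive_case_signatures(
    cm: CountMatrix,
    nm: NormalizedMatrix,
    annotation: CellAnnotation,
    bulk: BulkMatrix | None,
    config: DerivationConfig | None = None,
) -> dict[str, GeneSet]:
    """Run the full staged derivation on a combined two-condition dataset.

    Population enrichment is scoped per condition (healthy set against other
    healthy-liver populations, damaged set against other cirrhotic-liver
    populations); the condition contrast and the refine step cross
    conditions. If ``bulk`` is given, the restricted healthy signature is
    added via the concordance filter (genes down in bulk group 2).
    """
    config = config or DerivationConfig()
    pops = annotation.populations

    def others(cond: str, exclude: str) -> list[Selector]:
        present = {
            p
            for p in pops
            if p != exclude and annotation.cells(population=p, condition=cond)
        }
        return [(p, cond) for p in sorted(present)]

    enriched_healthy = enriched_vs_all_types(
        cm, nm, annotation, config.healthy_lsec,
        others(config.healthy_condition, config.healthy_lsec[0]), config,
    )
    enriched_damaged = enriched_vs_all_types(
        cm, nm, annotation, config.damaged_pop,
        others(config.damaged_condition, config.damaged_pop[0]), config,
    )
    up_healthy, up_damaged = condition_contrast(
        cm, nm, annotation, config.healthy_lsec, config.damaged_pop, config
    )
    healthy_geneset, damaged_geneset = build_state_genesets(
        enriched_healthy, enriched_damaged, up_healthy, up_damaged
    )
    damaged_signature = refine_damaged_signature(
        damaged_geneset, cm, nm, annotation, config.damaged_pop, config.healthy_ec, config
    )
    out = {
        "enriched_healthy": enriched_healthy,
        "enriched_damaged": enriched_damaged,
        "up_in_healthy": up_healthy,
        "up_in_damaged": up_damaged,
        "healthy_geneset": healthy_geneset,
        "damaged_geneset": damaged_geneset,
        "damaged_signature": damaged_signature,
    }
    if bulk is not None:
        out["healthy_signature"] = concordance_filter(
            healthy_geneset, bulk, direction="down_in_group2"
        ).renamed("healthy_LSEC_signature")
    return out
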