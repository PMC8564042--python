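"""Weighted Kolmogorov-Smirnov gene set enrichment with permutation NES/FDR.

Genes are ranked by a signal-to-noise metric between the two sample groups;
the enrichment score (ES) of a set is the extremum of a running sum that
rises by the weighted hit mass at member genes and falls by a constant at
non-members. A permutation null (sample relabeling or random same-size
sets) yields the normalized score NES = ES / mean(|same-sign null ES|), a
nominal p from the same-sign tail, and an FDR q from the classic ratio of
null-to-observed NES tails. Records are then filtered with the
|NES| > 1 and FDR < 0.25 rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BulkMatrix, GeneSetCollection

__all__ = [
    "RankedList",
    "GseaRecord",
    "rank_genes_s2n",
    "enrichment_score",
    "gsea",
    "filter_enriched",
    "records_to_frame",
]

SIGMA_FLOOR_FRAC = 0.2
MIN_SET_SIZE = 5


@dataclass
class RankedList:
    """Gene symbols in descending metric order (ties broken by symbol)."""

    genes: list[str]
    metric: np.ndarray
    metric_name: str = "s2n"

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValueError("genes/metric length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")


@dataclass
class GseaRecord:
    name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str]


def _floored_sigma(sigma: np.ndarray, mean: np.ndarray) -> np.ndarray:
    floor = np.where(mean != 0, SIGMA_FLOOR_FRAC * np.abs(mean), SIGMA_FLOOR_FRAC)
    return np.maximum(sigma, floor)


def _s2n_metric(values: np.ndarray, idx_pos: np.ndarray, idx_neg: np.ndarray) -> np.ndarray:
    a, b = values[:, idx_pos], values[:, idx_neg]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    s1 = _floored_sigma(a.std(axis=1, ddof=1), m1)
    s2 = _floored_sigma(b.std(axis=1, ddof=1), m2)
    return (m1 - m2) / (s1 + s2)


def rank_genes_s2n(bulk: BulkMatrix, positive_group: str | None = None) -> RankedList:
    """Signal-to-noise ranking: (mean_pos - mean_other) / (sigma_pos + sigma_other).

    Each standard deviation is floored at 20% of |mean| (or at 0.2 when the
    mean is zero), the classic adjustment that keeps near-constant genes
    from dominating the ranking. ``positive_group`` (default: first group in
    sample order) gets the positive end of the list.
    """
    if positive_group is None:
        positive_group = bulk.group_order[0]
    if positive_group not in bulk.group_order:
        raise ValueError(f"unknown group {positive_group!r}")
    other = next(g for g in bulk.group_order if g != positive_group)
    ip, io = bulk.sample_idx(positive_group), bulk.sample_idx(other)
    if min(ip.size, io.size) < 2:
        raise ValueError("each group needs >= 2 samples for signal-to-noise ranking")
    metric = _s2n_metric(bulk.values, ip, io)
    order = np.lexsort((np.array(bulk.genes), -metric))
    return RankedList([bulk.genes[i] for i in order], metric[order], "s2n")


def _es_from_positions(abs_w: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Vectorized ES for hit-position rows against a fixed weighted ranking.

    ``abs_w``: |metric|^p of the ranked list (length N). ``positions``:
    (n_instances, k) array of 0-based ranked positions of the set members.
    """
    n = abs_w.size
    pos = np.sort(positions, axis=1)
    k = pos.shape[1]
    w = abs_w[pos]
    sumw = w.sum(axis=1, keepdims=True)
    # all hit weights zero (e.g. flat metric at p=1): fall back to equal mass
    flat = (sumw == 0).ravel()
    if flat.any():
        w[flat] = 1.0
        sumw = w.sum(axis=1, keepdims=True)
    cum_hit = np.cumsum(w, axis=1) / sumw
    miss_before = (pos - np.arange(k)) / (n - k)
    after = cum_hit - miss_before  # running sum just after each hit
    before = cum_hit - w / sumw - miss_before  # just before each hit
    max_dev = after.max(axis=1)
    min_dev = before.min(axis=1)
    es = np.where(np.abs(max_dev) >= np.abs(min_dev), max_dev, min_dev)
    return np.clip(es, -1.0, 1.0)  # guard cumulative-sum float drift


def enrichment_score(
    rl: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES, full running sum and leading edge of one gene set.

    Hits increment the running sum by |metric|^p normalized over hits;
    misses decrement by 1/(N - |S|). The ES is the running-sum value of
    maximal absolute deviation (first occurrence on ties); the leading edge
    holds the hit genes at or before (positive ES) / after (negative ES)
    the extremum.
    """
    genes = getattr(gene_set, "genes", gene_set)
    members = {g.upper() for g in genes}
    hit = np.array([g.upper() in members for g in rl.genes])
    k = int(hit.sum())
    n = len(rl.genes)
    if k == 0:
        raise ValueError("gene set matches no gene in the ranked list")
    if k == n:
        raise ValueError("gene set matches every gene in the ranked list")
    abs_w = np.abs(rl.metric) ** weight_p
    hit_w = abs_w[hit]
    if hit_w.sum() == 0:
        hit_w = np.ones(k)
    steps = np.where(hit, 0.0, -1.0 / (n - k))
    steps[hit] = hit_w / hit_w.sum()
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(np.clip(running[i_ext], -1.0, 1.0))
    hit_pos = np.flatnonzero(hit)
    if es >= 0:
        leading = [rl.genes[i] for i in hit_pos if i <= i_ext]
    else:
        leading = [rl.genes[i] for i in hit_pos if i >= i_ext]
    return es, running, leading


def _phenotype_null(
    bulk: BulkMatrix,
    positive_group: str,
    set_positions: dict[str, np.ndarray],
    gene_index: dict[str, int],
    weight_p: float,
    n_perm: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    other = next(g for g in bulk.group_order if g != positive_group)
    ip, io = bulk.sample_idx(positive_group), bulk.sample_idx(other)
    assign = np.concatenate([ip, io])
    n_pos = ip.size
    names = list(set_positions)
    set_gene_idx = {m: np.array([gene_index[g] for g in set_positions[m]]) for m in names}
    null = {m: np.empty(n_perm) for m in names}
    genes_arr = np.arange(len(bulk.genes))
    for t in range(n_perm):
        perm = rng.permutation(assign)
        metric = _s2n_metric(bulk.values, perm[:n_pos], perm[n_pos:])
        order = np.argsort(-metric, kind="stable")
        inv = np.empty_like(order)
        inv[order] = genes_arr
        abs_w = np.abs(metric[order]) ** weight_p
        for m in names:
            pos = inv[set_gene_idx[m]][None, :]
            null[m][t] = _es_from_positions(abs_w, pos)[0]
    return null


def _gene_set_null(
    abs_w: np.ndarray, sizes: dict[str, int], n_perm: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    n = abs_w.size
    draws = np.argsort(rng.random((n_perm, n)), axis=1)
    out = {}
    size_cache: dict[int, np.ndarray] = {}
    for name, k in sizes.items():
        if k not in size_cache:
            size_cache[k] = _es_from_positions(abs_w, draws[:, :k])
        out[name] = size_cache[k]
    return out


def gsea(
    bulk: BulkMatrix,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    perm_type: str | None = None,
    weight_p: float = 1.0,
    seed: int = 0,
    min_size: int = MIN_SET_SIZE,
    positive_group: str | None = None,
) -> list[GseaRecord]:
    """Score every sufficiently matched gene set against the two-group bulk.

    ``perm_type``: ``phenotype`` relabels samples and recomputes the ranking
    per permutation; ``gene_set`` resamples random sets of equal size from
    the observed ranking. Default: phenotype when both groups have >= 7
    samples, else gene_set. FDR follows the pooled NES tail-ratio estimator,
    clipped to [0, 1]. Deterministic for a fixed seed.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if positive_group is None:
        positive_group = bulk.group_order[0]
    if perm_type is None:
        sizes_ok = min(bulk.sample_idx(g).size for g in bulk.group_order) >= 7
        perm_type = "phenotype" if sizes_ok else "gene_set"
    if perm_type not in ("phenotype", "gene_set"):
        raise ValueError(f"unknown perm_type {perm_type!r}")

    rl = rank_genes_s2n(bulk, positive_group)
    rank_of = {g.upper(): i for i, g in enumerate(rl.genes)}
    gene_index = {g: i for i, g in enumerate(bulk.genes)}
    n = len(rl.genes)
    abs_w = np.abs(rl.metric) ** weight_p

    matched: dict[str, list[str]] = {}
    for s in collection:
        present = sorted(g for g in s.genes if g in rank_of)
        if min_size <= len(present) < n:
            matched[s.name] = present
    if not matched:
        raise ValueError(f"no gene set matches >= {min_size} ranked genes")

    observed: dict[str, tuple[float, list[str]]] = {}
    for name, present in matched.items():
        es, _, leading = enrichment_score(rl, present, weight_p)
        observed[name] = (es, leading)

    rng = np.random.default_rng(seed)
    if perm_type == "phenotype":
        # map matched symbols back to bulk gene spelling for relabeled rankings
        upper_to_bulk = {}
        for g in bulk.genes:
            upper_to_bulk.setdefault(g.upper(), g)
        set_pos = {m: [upper_to_bulk[g] for g in genes] for m, genes in matched.items()}
        null = _phenotype_null(bulk, positive_group, set_pos, gene_index, weight_p, n_perm, rng)
    else:
        null = _gene_set_null(abs_w, {m: len(g) for m, g in matched.items()}, n_perm, rng)

    # normalize observed and null ES by the same-sign null means, per set
    records: list[GseaRecord] = []
    null_nes_pool: list[np.ndarray] = []
    obs_nes: dict[str, float] = {}
    for name in matched:
        es, leading = observed[name]
        ne = null[name]
        pos_mean = ne[ne > 0].mean() if (ne > 0).any() else np.nan
        neg_mean = np.abs(ne[ne < 0]).mean() if (ne < 0).any() else np.nan
        nes_null = np.where(ne >= 0, ne / pos_mean, ne / neg_mean)
        null_nes_pool.append(nes_null[np.isfinite(nes_null)])

        same = ne[ne >= 0] if es >= 0 else ne[ne < 0]
        denom = pos_mean if es >= 0 else neg_mean
        if same.size == 0 or not np.isfinite(denom) or denom == 0:
            nes, p = 0.0, 1.0
        else:
            nes = es / denom
            p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + same.size)
        obs_nes[name] = nes
        records.append(GseaRecord(name, len(matched[name]), es, float(nes), float(p), 1.0, leading))

    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    all_obs = np.array([obs_nes[r.name] for r in records])
    for r in records:
        nes = obs_nes[r.name]
        if nes >= 0:
            num_tail = np.mean(pool >= nes) / max(np.mean(pool >= 0), 1e-12) if pool.size else 1.0
            den_tail = np.sum(all_obs >= nes) / max(np.sum(all_obs >= 0), 1)
        else:
            num_tail = np.mean(pool <= nes) / max(np.mean(pool < 0), 1e-12) if pool.size else 1.0
            den_tail = np.sum(all_obs <= nes) / max(np.sum(all_obs < 0), 1)
        r.fdr_q = float(np.clip(num_tail / max(den_tail, 1e-12), 0.0, 1.0))
    return records


def filter_enriched(
    records: list[GseaRecord], nes_abs_min: float = 1.0, fdr_max: float = 0.25
) -> list[GseaRecord]:
    """Keep records with |NES| strictly above the bound and FDR strictly below."""
    return [r for r in records if abs(r.nes) > nes_abs_min and r.fdr_q < fdr_max]


def records_to_frame(records: list[GseaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in records],
            "size": [r.size for r in records],
            "es": [r.es for r in records],
            "nes": [r.nes for r in records],
            "p_nominal": [r.p_nominal for r in records],
            "fdr_q": [r.fdr_q for r in records],
            "leading_edge": [";".join(r.leading_edge) for r in records],
        }
    )
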