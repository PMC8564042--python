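import numpy as np
import pytest

from lsec_sigkit import (
    BulkSimSpec,
    RankedList,
    enrichment_score,
    filter_enriched,
    gsea,
    rank_genes_s2n,
    simulate_bulk_dataset,
)
from lsec_sigkit.enrichment_gsea import GseaRecord
from lsec_sigkit.io_formats import BulkMatrix, GeneSet, GeneSetCollection


def brute_force_es(genes, metric, members, weight_p):
    """Independent oracle: literal running-sum walk over the ranked list."""
    members = {g.upper() for g in members}
    hits = [g.upper() in members for g in genes]
    k = sum(hits)
    n = len(genes)
    nr = sum(abs(m) ** weight_p for g, m, h in zip(genes, metric, hits) if h)
    running, best = 0.0, 0.0
    for g, m, h in zip(genes, metric, hits):
        if h:
            running += (abs(m) ** weight_p / nr) if nr > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def _bulk(values, n1=2, n2=2):
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    group = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return BulkMatrix(genes, samples, values, group)


class TestRanking:
    def test_sigma_floor_worked_example(self):
        vals = np.array([[2.0, 2.0, 1.0, 1.0]])
        rl = rank_genes_s2n(_bulk(vals))
        assert rl.metric[0] == pytest.approx(1.0 / 0.6)

    def test_identical_groups_metric_zero(self):
        vals = np.tile(np.arange(5.0)[:, None], (1, 4))
        rl = rank_genes_s2n(_bulk(vals))
        assert np.allclose(rl.metric, 0.0)

    def test_group_swap_negates_and_reverses(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 1, (20, 6))
        b = _bulk(vals, 3, 3)
        fwd = rank_genes_s2n(b, positive_group="A")
        rev = rank_genes_s2n(b, positive_group="B")
        m_fwd = dict(zip(fwd.genes, fwd.metric))
        m_rev = dict(zip(rev.genes, rev.metric))
        for g in fwd.genes:
            assert m_rev[g] == pytest.approx(-m_fwd[g])


class TestEnrichmentScore:
    @pytest.mark.parametrize(
        "members,expected",
        [({"A"}, 1.0), ({"D"}, -1.0), ({"A", "C"}, 0.5)],
    )
    def test_hand_walked_cases(self, members, expected):
        rl = RankedList(["A", "B", "C", "D"], np.array([4.0, 3.0, 2.0, 1.0]))
        es, running, _ = enrichment_score(rl, members, weight_p=0)
        assert es == pytest.approx(expected)
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_leading_edge_sides(self):
        rl = RankedList(["A", "B", "C", "D"], np.array([4.0, 3.0, 2.0, 1.0]))
        _, _, lead_top = enrichment_score(rl, {"A", "C"}, weight_p=0)
        assert lead_top == ["A"]
        _, _, lead_bottom = enrichment_score(rl, {"D"}, weight_p=0)
        assert lead_bottom == ["D"]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(5, 60))
            genes = [f"g{i}" for i in range(n)]
            metric = np.sort(rng.normal(0, 2, n))[::-1]
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, k, replace=False))
            p = float(rng.choice([0.0, 1.0, 1.5]))
            rl = RankedList(genes, metric)
            es, _, _ = enrichment_score(rl, members, weight_p=p)
            assert es == pytest.approx(brute_force_es(genes, metric, members, p), abs=1e-12)
            assert abs(es) <= 1.0 + 1e-12

    def test_reversed_ranking_negates_es_at_p0(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(30)]
        metric = np.sort(rng.normal(size=30))[::-1]
        members = set(rng.choice(genes, 7, replace=False))
        es_f, _, _ = enrichment_score(RankedList(genes, metric), members, weight_p=0)
        es_r, _, _ = enrichment_score(
            RankedList(genes[::-1], metric[::-1]), members, weight_p=0
        )
        assert es_r == pytest.approx(-es_f)

    def test_degenerate_sets_rejected(self):
        rl = RankedList(["A", "B"], np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="no gene"):
            enrichment_score(rl, {"Z"})
        with pytest.raises(ValueError, match="every gene"):
            enrichment_score(rl, {"A", "B"})


@pytest.fixture(scope="module")
def planted_bulk():
    spec = BulkSimSpec(
        n_genes=1000,
        groups=[("ctrl", 8), ("case", 8)],
        noise_sigma=0.25,
        planted_sets=[("planted", list(range(40)), 2.0)],
        seed=1,
    )
    bulk, _ = simulate_bulk_dataset(spec)
    rng = np.random.default_rng(5)
    sets = [GeneSet("planted", frozenset(bulk.genes[i] for i in range(40)))]
    for j in range(10):
        sets.append(
            GeneSet(f"null{j}", frozenset(rng.choice(bulk.genes, 40, replace=False)))
        )
    return bulk, GeneSetCollection(sets)


class TestGsea:
    def test_deterministic_under_seed(self, planted_bulk):
        bulk, coll = planted_bulk
        a = gsea(bulk, coll, n_perm=100, seed=4, positive_group="case")
        b = gsea(bulk, coll, n_perm=100, seed=4, positive_group="case")
        for ra, rb in zip(a, b):
            assert (ra.es, ra.nes, ra.p_nominal, ra.fdr_q) == (rb.es, rb.nes, rb.p_nominal, rb.fdr_q)

    def test_planted_set_detected_both_permutation_modes(self, planted_bulk):
        bulk, coll = planted_bulk
        for mode in ("gene_set", "phenotype"):
            recs = gsea(bulk, coll, n_perm=200, seed=2, perm_type=mode, positive_group="case")
            by = {r.name: r for r in recs}
            assert by["planted"].nes > 1
            assert by["planted"].p_nominal < 0.05
        # against the observed ranking, no random set can outscore the truth
        recs = gsea(bulk, coll, n_perm=200, seed=2, perm_type="gene_set", positive_group="case")
        by = {r.name: r for r in recs}
        assert by["planted"].nes == max(r.nes for r in recs)

    def test_nes_sign_follows_es(self, planted_bulk):
        bulk, coll = planted_bulk
        recs = gsea(bulk, coll, n_perm=100, seed=3, positive_group="ctrl")
        for r in recs:
            assert abs(r.es) <= 1
            if r.nes != 0:
                assert np.sign(r.nes) == np.sign(r.es)

    def test_small_n_perm_rejected(self, planted_bulk):
        bulk, coll = planted_bulk
        with pytest.raises(ValueError, match="n_perm"):
            gsea(bulk, coll, n_perm=5)

    def test_gseapy_cross_check_on_prerank_scores(self):
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 80
        genes = [f"G{i}" for i in range(n)]
        metric = np.sort(rng.normal(0, 1, n))[::-1]
        sets = {"S1": genes[5:20], "S2": [genes[i] for i in range(0, n, 9)]}
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": metric}),
            gene_sets=sets, permutation_num=10, min_size=3, max_size=60,
            weight=1.0, seed=1, outdir=None, no_plot=True,
        ).res2d.set_index("Term")
        rl = RankedList(genes, metric)
        for name, members in sets.items():
            es, _, _ = enrichment_score(rl, members, weight_p=1.0)
            assert es == pytest.approx(float(res.loc[name, "ES"]), abs=1e-9)


class TestFilterEnriched:
    @pytest.mark.parametrize(
        "nes,q,kept",
        [(1.4, 0.10, True), (-1.2, 0.24, True), (0.9, 0.01, False), (1.5, 0.25, False)],
    )
    def test_threshold_rule(self, nes, q, kept):
        rec = GseaRecord("s", 10, np.sign(nes) * 0.5, nes, 0.01, q, [])
        assert (len(filter_enriched([rec])) == 1) == kept
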