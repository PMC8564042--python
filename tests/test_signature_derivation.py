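import itertools

import numpy as np
import pytest

from lsec_sigkit import (
    DerivationConfig,
    ScSimSpec,
    build_state_genesets,
    concordance_filter,
    condition_contrast,
    enriched_vs_all_types,
    intersection_summary,
    normalize_log1p_cp10k,
    refine_damaged_signature,
    simulate_sc_dataset,
)
from lsec_sigkit.io_formats import BulkMatrix, GeneSet


class TestEnrichedVsAllTypes:
    def test_case_study_recovers_planted_lsec_markers(self, case_combined, case_bundle, derived_sets):
        truth = case_bundle.truth.markers["LSEC"]
        assert derived_sets["enriched_healthy"].genes == frozenset(truth)

    def test_low_detection_gene_excluded(self):
        # planted eight-fold but on a tiny baseline: enriched, yet detected in
        # fewer than half the focal cells, so the >=50% filter removes it
        spec = ScSimSpec(
            n_genes=300,
            populations=[("F", "x", 200), ("R", "x", 200)],
            planted_markers=[("F", None, [0, 1], 8.0)],
            baseline_mean_override={0: 1.0, 1: 0.03},
            seed=21,
        )
        cm, ann, _ = simulate_sc_dataset(spec)
        nm = normalize_log1p_cp10k(cm)
        cfg = DerivationConfig(healthy_lsec=("F", "x"))
        gs = enriched_vs_all_types(cm, nm, ann, ("F", "x"), [("R", "x")], cfg)
        g_strong, g_weak = cm.genes[0].upper(), cm.genes[1].upper()
        assert g_strong in gs.genes
        assert g_weak not in gs.genes

    def test_single_reference_matches_direct_call(self, case_combined):
        cm, ann, nm = case_combined
        cfg = DerivationConfig()
        one = enriched_vs_all_types(cm, nm, ann, ("LSEC", "healthy"), [("EC", "healthy")], cfg)
        pooled = enriched_vs_all_types(
            cm, nm, ann, ("LSEC", "healthy"), [("EC", "healthy")],
            DerivationConfig(comparison_mode="one_vs_pooled"),
        )
        assert one.genes == pooled.genes

    def test_monotone_in_thresholds(self, case_combined):
        cm, ann, nm = case_combined
        others = [("EC", "healthy"), ("macrophage", "healthy")]
        loose = enriched_vs_all_types(cm, nm, ann, ("LSEC", "healthy"), others, DerivationConfig())
        tight_fc = enriched_vs_all_types(
            cm, nm, ann, ("LSEC", "healthy"), others, DerivationConfig(fc_min=6.0)
        )
        tight_pct = enriched_vs_all_types(
            cm, nm, ann, ("LSEC", "healthy"), others, DerivationConfig(pct_min=0.95)
        )
        assert tight_fc.genes <= loose.genes
        assert tight_pct.genes <= loose.genes


class TestConditionContrast:
    def test_up_sets_are_disjoint(self, derived_sets):
        assert not (derived_sets["up_in_healthy"].genes & derived_sets["up_in_damaged"].genes)

    def test_identical_distributions_give_empty_sets(self):
        spec = ScSimSpec(n_genes=200, populations=[("A", "x", 100), ("B", "x", 100)], seed=13)
        cm, ann, _ = simulate_sc_dataset(spec)
        nm = normalize_log1p_cp10k(cm)
        up_a, up_b = condition_contrast(cm, nm, ann, ("A", "x"), ("B", "x"), DerivationConfig())
        assert up_a.genes == frozenset() and up_b.genes == frozenset()

    def test_damaged_contrast_contains_planted(self, derived_sets, case_bundle):
        assert set(case_bundle.truth.markers["damaged_specific"]) <= derived_sets["up_in_damaged"].genes


class TestStateSetsAndRefinement:
    def test_disjoint_inputs_yield_empty(self):
        a = GeneSet("a", frozenset({"X"}))
        b = GeneSet("b", frozenset({"Y"}))
        h, d = build_state_genesets(a, b, b, a)
        assert h.genes == frozenset() and d.genes == frozenset()

    def test_damaged_geneset_is_specific_plus_shared(self, derived_sets, case_bundle):
        t = case_bundle.truth
        assert derived_sets["damaged_geneset"].genes == frozenset(
            t.markers["damaged_specific"] | t.markers["shared_EC"]
        )

    def test_refinement_recovers_planted_four_genes(self, derived_sets, case_bundle):
        assert derived_sets["damaged_signature"].genes == frozenset(
            case_bundle.truth.markers["damaged_specific"]
        )

    def test_chain_containment(self, derived_sets):
        assert derived_sets["damaged_signature"].genes <= derived_sets["damaged_geneset"].genes
        assert derived_sets["damaged_geneset"].genes <= derived_sets["enriched_damaged"].genes

    def test_provenance_trail_recorded(self, derived_sets):
        sig = derived_sets["damaged_signature"]
        assert any("refine" in note for note in sig.provenance)
        assert any("enriched_vs_all_types" in note for note in sig.provenance)

    def test_empty_damaged_set_rejected(self, case_combined):
        cm, ann, nm = case_combined
        with pytest.raises(ValueError, match="empty"):
            refine_damaged_signature(
                GeneSet("d", frozenset()), cm, nm, ann,
                ("damaged_LSEC_EC", "cirrhotic"), ("EC", "healthy"), DerivationConfig(),
            )


class TestConcordanceFilter:
    def _bulk(self):
        vals = np.array(
            [
                [5.0, 5.0, 3.8, 3.8],  # down in group 2
                [5.0, 5.0, 6.0, 6.0],  # up in group 2
            ]
        )
        return BulkMatrix(
            ["Stab2", "Lyve1"], ["h1", "h2", "i1", "i2"], vals,
            {"h1": "healthy", "h2": "healthy", "i1": "injured", "i2": "injured"},
        )

    def test_sign_rule(self):
        gs = GeneSet("hl", frozenset({"STAB2", "LYVE1"}))
        down = concordance_filter(gs, self._bulk(), "down_in_group2")
        up = concordance_filter(gs, self._bulk(), "up_in_group2")
        assert down.genes == frozenset({"STAB2"})
        assert up.genes == frozenset({"LYVE1"})

    def test_absent_gene_dropped_and_logged_in_provenance(self):
        gs = GeneSet("hl", frozenset({"STAB2", "NOTINBULK"}))
        out = concordance_filter(gs, self._bulk(), "down_in_group2")
        assert out.genes == frozenset({"STAB2"})
        assert any("NOTINBULK" in note for note in out.provenance)

    def test_case_study_recovers_injury_down_subset(self, derived_sets, case_bundle):
        assert derived_sets["healthy_signature"].genes == frozenset(
            case_bundle.truth.bulk_shifts["injury_down"]
        )


class TestIntersectionSummary:
    def test_hand_enumeration(self):
        s1 = GeneSet("S1", frozenset({"A", "B"}))
        s2 = GeneSet("S2", frozenset({"B", "C"}))
        summary = intersection_summary([s1, s2])
        assert summary.counts == {
            frozenset({"S1"}): 1,
            frozenset({"S2"}): 1,
            frozenset({"S1", "S2"}): 1,
        }

    def test_identical_sets_all_mass_on_full_combination(self):
        s = frozenset({"A", "B", "C"})
        summary = intersection_summary([GeneSet("x", s), GeneSet("y", s)])
        assert summary.counts == {frozenset({"x", "y"}): 3}

    def test_counts_sum_to_union_random_families(self):
        rng = np.random.default_rng(17)
        universe = [f"G{i}" for i in range(40)]
        for _ in range(10):
            sets = [
                GeneSet(f"S{j}", frozenset(rng.choice(universe, rng.integers(1, 20), replace=False)))
                for j in range(5)
            ]
            summary = intersection_summary(sets)
            union = set().union(*(s.genes for s in sets))
            assert sum(summary.counts.values()) == len(union)
            # brute force: classify each union gene by its exact membership
            brute = {}
            for g in union:
                combo = frozenset(s.name for s in sets if g in s.genes)
                brute[combo] = brute.get(combo, 0) + 1
            assert summary.counts == brute

    def test_duplicate_names_rejected(self):
        s = GeneSet("same", frozenset({"A"}))
        with pytest.raises(ValueError, match="duplicate"):
            intersection_summary([s, s])
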