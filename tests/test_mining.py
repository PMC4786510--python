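"""Frequent-itemset mining, semantic pruning, and rule generation."""

import numpy as np
import pytest

from ontoapriori.mining import (
    MiningConfig,
    frequent_singletons,
    generate_candidates,
    generate_rules,
    mine_frequent,
    prune_semantic,
)
from ontoapriori.ontology import RelatednessPolicy, trivial_ontology
from ontoapriori.transactions import Itemset, ValidationError, support

from conftest import (
    CANCER,
    FAMILY,
    MILK,
    SMOKING,
    SURGERY,
    brute_force_frequent,
    random_dataset,
)

# The five frequent 2-itemsets printed in the worked example.
PRINTED_L2 = [
    Itemset([SURGERY, CANCER]),
    Itemset([SMOKING, CANCER]),
    Itemset([SURGERY, SMOKING]),
    Itemset([MILK, CANCER]),
    Itemset([FAMILY, CANCER]),
]
ALL_ITEMS = [CANCER, SURGERY, MILK, SMOKING, FAMILY]


class TestFrequentSingletons:
    def test_all_five_example_items_frequent_at_30pct(self, example_ds):
        L1 = frequent_singletons(example_ds, 0.30)
        assert len(L1) == 5

    def test_no_item_occurs_in_every_row(self, example_ds):
        assert frequent_singletons(example_ds, 1.0) == {}

    def test_tiny_threshold_keeps_all_observed_items(self, example_ds):
        assert len(frequent_singletons(example_ds, 1e-9)) == 5

    def test_threshold_is_inclusive(self, example_ds):
        # Milk consumption=yes has support exactly 0.5
        L1 = frequent_singletons(example_ds, 0.5)
        assert Itemset([MILK]) in L1


class TestGenerateCandidates:
    def test_printed_l2_extends_to_eight_unique_triples(self):
        cands = generate_candidates(PRINTED_L2, ALL_ITEMS, "extend-by-item")
        assert len(cands) == 8
        assert all(c.k == 3 for c in cands)

    def test_single_itemset_with_its_own_items_extends_to_nothing(self):
        s = Itemset(["A=x", "B=y"])
        assert generate_candidates([s], ["A=x", "B=y"], "extend-by-item") == ()

    def test_classic_join_textbook_case(self):
        L2 = [Itemset(["A=x", "B=x"]), Itemset(["A=x", "C=x"]),
              Itemset(["B=x", "C=x"])]
        cands = generate_candidates(L2, [], "classic-join")
        assert cands == (Itemset(["A=x", "B=x", "C=x"]),)

    def test_classic_join_prunes_missing_subset(self):
        L2 = [Itemset(["A=x", "B=x"]), Itemset(["A=x", "C=x"])]
        assert generate_candidates(L2, [], "classic-join") == ()

    def test_feature_conflicts_are_skipped(self):
        L1 = [Itemset(["A=x"]), Itemset(["A=y"]), Itemset(["B=x"])]
        cands = generate_candidates(L1, ["A=x", "A=y", "B=x"], "extend-by-item")
        assert cands == (Itemset(["A=x", "B=x"]), Itemset(["A=y", "B=x"]))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError, match="unknown candidate"):
            generate_candidates(PRINTED_L2, ALL_ITEMS, "magic")


class TestPruneSemantic:
    def test_example_triples_reduce_to_three(self, example_onto):
        cands = generate_candidates(PRINTED_L2, ALL_ITEMS, "extend-by-item")
        survivors, removed = prune_semantic(
            cands, example_onto, RelatednessPolicy()
        )
        assert len(survivors) == 3
        assert len(removed) == 5
        assert {s.items for s in survivors} == {
            Itemset([CANCER, SURGERY, MILK]).items,
            Itemset([CANCER, SURGERY, SMOKING]).items,
            Itemset([CANCER, SURGERY, FAMILY]).items,
        }
        assert all(r.reason == "semantic" and r.pair is not None for r in removed)

    def test_complete_policy_removes_nothing(self):
        feats = [i.partition("=")[0] for i in ALL_ITEMS]
        o = trivial_ontology(feats)
        cands = generate_candidates(PRINTED_L2, ALL_ITEMS, "extend-by-item")
        survivors, removed = prune_semantic(
            cands, o, RelatednessPolicy.complete(feats)
        )
        assert survivors == cands and removed == ()

    def test_empty_candidates(self, example_onto):
        assert prune_semantic([], example_onto, RelatednessPolicy()) == ((), ())


class TestMineFrequent:
    def test_worked_example_audit(self, example_ds, example_onto):
        cfg = MiningConfig(0.30, 0.80, policy=RelatednessPolicy())
        fl = mine_frequent(example_ds, cfg, example_onto)
        assert len(fl.level(1)) == 5
        level3 = fl.audit[2]
        assert level3.level == 3
        # semantic pruning leaves exactly 3 of the level-3 candidates
        assert len(level3.candidates) - len(level3.semantic_removed) == 3
        # the milk/surgery/cancer survivor then falls to the support filter
        milk_triple = Itemset([MILK, SURGERY, CANCER])
        support_removed = {r.itemset: r for r in level3.support_removed}
        assert milk_triple in support_removed
        assert support_removed[milk_triple].support == pytest.approx(0.2)

    def test_audit_partitions_candidates(self, example_ds, example_onto):
        cfg = MiningConfig(0.30, 0.80, policy=RelatednessPolicy())
        fl = mine_frequent(example_ds, cfg, example_onto)
        for a in fl.audit:
            removed = {r.itemset for r in a.removed}
            assert removed | set(a.survivors) == set(a.candidates)
            assert not removed & set(a.survivors)

    def test_policy_and_ontology_must_come_together(self, example_ds, example_onto):
        with pytest.raises(ValidationError):
            mine_frequent(example_ds, MiningConfig(0.3, 0.8), example_onto)
        with pytest.raises(ValidationError):
            mine_frequent(
                example_ds, MiningConfig(0.3, 0.8, policy=RelatednessPolicy())
            )

    @pytest.mark.parametrize("method", ["extend-by-item", "classic-join"])
    def test_classic_mining_matches_brute_force(self, method):
        """Classic Apriori equals exhaustive enumeration on random data."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            ds = random_dataset(rng, max_items=9, max_rows=40)
            min_support = float(rng.uniform(0.05, 0.6))
            cfg = MiningConfig(min_support, 0.5, candidate_method=method)
            mined = mine_frequent(ds, cfg).all_frequent()
            oracle = brute_force_frequent(ds, min_support)
            assert mined == oracle

    def test_constrained_with_complete_policy_equals_classic(self):
        rng = np.random.default_rng(43)
        for _ in range(15):
            ds = random_dataset(rng, max_items=8, max_rows=40)
            min_support = float(rng.uniform(0.05, 0.5))
            classic = mine_frequent(ds, MiningConfig(min_support, 0.5))
            feats = [i.partition("=")[0] for i in ds.item_ids]
            cfg = MiningConfig(
                min_support, 0.5, policy=RelatednessPolicy.complete(feats)
            )
            constrained = mine_frequent(ds, cfg, trivial_ontology(feats))
            assert constrained.all_frequent() == classic.all_frequent()

    def test_nothing_related_policy_yields_only_singletons(self, example_ds):
        feats = [i.partition("=")[0] for i in example_ds.item_ids]
        cfg = MiningConfig(0.3, 0.8, policy=RelatednessPolicy.nothing_related())
        fl = mine_frequent(example_ds, cfg, trivial_ontology(feats))
        assert fl.depth == 1 and len(fl.level(1)) == 5

    def test_max_level_caps_the_loop(self, example_ds):
        fl = mine_frequent(example_ds, MiningConfig(0.3, 0.8, max_level=2))
        assert fl.depth == 2


class TestGenerateRules:
    @pytest.fixture()
    def example_rules(self, example_ds):
        cfg = MiningConfig(0.30, 0.80)
        fl = mine_frequent(example_ds, cfg)
        return generate_rules(fl, example_ds, cfg)

    def test_surgery_implies_cancer_with_full_confidence(self, example_rules):
        by_key = {r.key: r for r in example_rules}
        rule = by_key[((SURGERY,), (CANCER,))]
        assert rule.confidence == pytest.approx(1.0)
        assert rule.support == pytest.approx(0.5)

    def test_cancer_implies_surgery_at_five_sixths(self, example_rules):
        by_key = {r.key: r for r in example_rules}
        rule = by_key[((CANCER,), (SURGERY,))]
        assert rule.confidence == pytest.approx(5 / 6)

    def test_confidence_threshold_is_inclusive(self, example_ds):
        cfg = MiningConfig(0.30, 1.0)
        fl = mine_frequent(example_ds, cfg)
        keys = generate_rules(fl, example_ds, cfg).keys()
        assert ((SURGERY,), (CANCER,)) in keys
        assert ((CANCER,), (SURGERY,)) not in keys

    def test_stored_values_recompute_from_raw_supports(self, example_ds):
        cfg = MiningConfig(0.30, 0.80)
        fl = mine_frequent(example_ds, cfg)
        for r in generate_rules(fl, example_ds, cfg):
            union = r.antecedent.union(r.consequent)
            assert r.support == pytest.approx(support(example_ds, union), abs=1e-12)
            assert r.confidence == pytest.approx(
                support(example_ds, union) / support(example_ds, r.antecedent),
                abs=1e-12,
            )
            assert r.support >= cfg.min_support - 1e-9
            assert r.confidence >= cfg.min_confidence - 1e-12

    def test_sorted_by_support_then_confidence(self, example_rules):
        rules = list(example_rules)
        keys = [(-r.support, -r.confidence, r.key) for r in rules]
        assert keys == sorted(keys)

    def test_all_partitions_mode_supersets_single_item(self, example_ds):
        single = MiningConfig(0.30, 0.80, consequent_mode="single-item")
        both = MiningConfig(0.30, 0.80, consequent_mode="all-partitions")
        fl = mine_frequent(example_ds, single)
        assert generate_rules(fl, example_ds, single).keys() <= generate_rules(
            fl, example_ds, both
        ).keys()

    def test_constrained_rules_contained_in_classic(self, example_ds, example_onto):
        classic_cfg = MiningConfig(0.30, 0.80)
        constrained_cfg = MiningConfig(0.30, 0.80, policy=RelatednessPolicy())
        classic = generate_rules(
            mine_frequent(example_ds, classic_cfg), example_ds, classic_cfg
        )
        constrained = generate_rules(
            mine_frequent(example_ds, constrained_cfg, example_onto),
            example_ds,
            constrained_cfg,
        )
        assert constrained.keys() <= classic.keys()

    def test_unrelating_a_pair_never_adds_rules(self, example_ds, example_onto):
        """Monotone pruning: adding an unrelated-pair override can only
        shrink the constrained output."""
        base_cfg = MiningConfig(0.30, 0.80, policy=RelatednessPolicy())
        base = generate_rules(
            mine_frequent(example_ds, base_cfg, example_onto),
            example_ds,
            base_cfg,
        )
        stricter_policy = RelatednessPolicy(
            explicit_overrides=RelatednessPolicy.overrides_from_pairs(
                [("History of stomach surgery", "Gastric cancer", False)]
            )
        )
        cfg = MiningConfig(0.30, 0.80, policy=stricter_policy)
        stricter = generate_rules(
            mine_frequent(example_ds, cfg, example_onto), example_ds, cfg
        )
        assert stricter.keys() <= base.keys()
        assert len(stricter) < len(base)
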