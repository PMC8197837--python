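import math

import numpy as np
import pytest

import vitalgan as vg
from vitalgan.rules import Condition, Rule, RuleSet
from vitalgan.workflow import RuleContingency, fet_pvalue
from vitalgan.schema import CLASS_HIGH, CLASS_LOW, ValidationError

from .conftest import make_dataset


def hypergeom_tail(a, b, c, d):
    """Independent enrichment p-value: hypergeometric upper tail by direct
    enumeration with exact binomial coefficients."""
    N, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(N, n)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k)
        for k in range(a, min(K, n) + 1)
    ) / denom


class TestFetPvalue:
    def test_hand_table(self):
        # P(X >= 8) for Hypergeom(N=20, K=10, n=9): (45*10 + 10*1)/C(20,9)
        p = fet_pvalue(RuleContingency(8, 1, 2, 9))
        assert p == pytest.approx(hypergeom_tail(8, 1, 2, 9), rel=1e-10)
        assert p == pytest.approx(460 / 167960, rel=1e-9)

    def test_matches_enumeration_on_small_tables(self):
        for total in range(4, 13):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        t = RuleContingency(a, b, c, d)
                        if t.degenerate:
                            continue
                        assert fet_pvalue(t) == pytest.approx(
                            hypergeom_tail(a, b, c, d), rel=1e-9, abs=1e-12
                        )

    def test_degenerate_margins_return_one(self):
        assert fet_pvalue(RuleContingency(0, 0, 22, 21)) == 1.0
        assert fet_pvalue(RuleContingency(22, 21, 0, 0)) == 1.0

    def test_no_enrichment_evidence_returns_one(self):
        # premise never fires on the consequence class
        assert fet_pvalue(RuleContingency(0, 3, 10, 7)) == 1.0

    def test_two_sided_invariant_under_class_swap(self):
        a, b, c, d = 8, 1, 2, 9
        p1 = fet_pvalue(RuleContingency(a, b, c, d), two_sided=True)
        p2 = fet_pvalue(RuleContingency(b, a, d, c), two_sided=True)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_rule_pvalue_on_dataset(self, real43):
        rule = vg.induce_rules_greedy(real43).rules[0]
        p = vg.fet_rule_pvalue(rule, real43)
        assert 0 < p <= 1
        t = vg.rule_contingency(rule, real43)
        assert t.n == real43.n
        assert p == pytest.approx(hypergeom_tail(t.a, t.b, t.c, t.d), rel=1e-9)

    def test_single_class_dataset_rejected(self, real43):
        rule = Rule((Condition("fev1", ">", 2.0),), CLASS_HIGH)
        with pytest.raises(ValidationError):
            vg.fet_rule_pvalue(rule, real43.subset_class(CLASS_HIGH))


class TestFilterRules:
    def _fixture(self):
        # one strongly predictive rule, one class-independent noise rule
        ds = make_dataset(
            {"fev1": [3.0] * 20 + [1.0] * 20, "map": list(np.linspace(80, 100, 40))},
            [CLASS_HIGH] * 20 + [CLASS_LOW] * 20,
        )
        good = Rule((Condition("fev1", ">", 2.0),), CLASS_HIGH)
        noise = Rule((Condition("map", ">", 90.0),), CLASS_HIGH)
        return ds, RuleSet([good, noise], CLASS_LOW)

    def test_noise_rule_filtered_out(self):
        ds, rs = self._fixture()
        kept = vg.filter_rules_fet(rs, ds, alpha=0.05)
        assert len(kept) == 1
        assert kept.rules[0].premise[0].feature == "fev1"
        assert kept.rules[0].p_value < 0.05

    def test_empty_ruleset_passes_through(self, real43):
        kept = vg.filter_rules_fet(RuleSet([], CLASS_LOW), real43)
        assert len(kept) == 0

    def test_alpha_one_is_vacuous(self):
        ds, rs = self._fixture()
        assert len(vg.filter_rules_fet(rs, ds, alpha=1.0)) == len(rs)

    def test_monotone_in_alpha(self):
        ds, rs = self._fixture()
        small = {(r.premise, r.consequence) for r in vg.filter_rules_fet(rs, ds, alpha=0.01)}
        large = {(r.premise, r.consequence) for r in vg.filter_rules_fet(rs, ds, alpha=0.2)}
        assert small <= large

    def test_bh_correction_never_keeps_more(self):
        ds, rs = self._fixture()
        plain = vg.filter_rules_fet(rs, ds, alpha=0.05)
        bh = vg.filter_rules_fet(rs, ds, alpha=0.05, bh_correct=True)
        assert len(bh) <= len(plain)


class TestEvaluateRuleset:
    def test_default_class_only(self):
        ds = make_dataset(
            {"fev1": [1.0] * 10}, [CLASS_LOW] * 6 + [CLASS_HIGH] * 4
        )
        acc, f1 = vg.evaluate_ruleset(RuleSet([], CLASS_LOW), ds)
        assert acc == pytest.approx(0.6)
        assert f1 == 0.0

    def test_always_high_on_balanced_data(self):
        ds = make_dataset(
            {"fev1": [1.0] * 20}, [CLASS_HIGH] * 10 + [CLASS_LOW] * 10
        )
        rs = RuleSet(
            [Rule((Condition("fev1", ">", 0.0),), CLASS_HIGH, covering=1.0, error=1.0)],
            CLASS_HIGH,
        )
        acc, f1 = vg.evaluate_ruleset(rs, ds)
        assert acc == pytest.approx(0.5)
        assert f1 == pytest.approx(2 / 3)

    def test_perfect_ruleset(self, toy_separable):
        rs = vg.induce_rules_tree(toy_separable, max_depth=1, min_leaf=1)
        assert vg.evaluate_ruleset(rs, toy_separable) == (1.0, 1.0)


class TestAugmentationWorkflow:
    def test_synthetic_equal_real_reproduces_baseline(self, real43):
        wf = vg.run_augmentation_workflow(real43, real43)
        assert [(r.premise, r.consequence) for r in wf.candidate_augmented] == [
            (r.premise, r.consequence) for r in wf.baseline
        ]

    def test_augmented_subset_of_candidate(self, real43, sim_synth_1000):
        wf = vg.run_augmentation_workflow(real43, sim_synth_1000)
        cand = {(r.premise, r.consequence) for r in wf.candidate_augmented}
        aug = {(r.premise, r.consequence) for r in wf.augmented}
        assert aug <= cand

    def test_positive_control_transfers(self, real43, sim_synth_1000):
        wf = vg.run_augmentation_workflow(real43, sim_synth_1000)
        assert wf.valid
        base = wf.reports["baseline_on_real"].accuracy
        aug = wf.reports["augmented_on_real"].accuracy
        assert abs(aug - base) <= 0.15

    def test_augmented_rules_scored_on_real_data(self, real43, sim_synth_1000):
        wf = vg.run_augmentation_workflow(real43, sim_synth_1000)
        for rule in wf.augmented:
            C, r = vg.covering_error(rule, real43)
            assert rule.covering == pytest.approx(C)
            assert rule.error == pytest.approx(r)

    def test_tree_inducer_also_supported(self, real43, sim_synth_1000):
        wf = vg.run_augmentation_workflow(real43, sim_synth_1000, inducer="tree",
                                          max_depth=2)
        assert wf.reports["baseline_on_real"].n_rules >= 1

    def test_unknown_inducer_rejected(self, real43, sim_synth_1000):
        with pytest.raises(ValidationError):
            vg.run_augmentation_workflow(real43, sim_synth_1000, inducer="nope")
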