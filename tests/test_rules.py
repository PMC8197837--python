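import numpy as np
import pytest

import vitalgan as vg
from vitalgan.rules import Condition, Rule, RuleParseError, RuleSet
from vitalgan.schema import CLASS_HIGH, CLASS_LOW, PREDICTOR_NAMES, ValidationError

from .conftest import make_dataset


def random_rule(rng):
    feats = rng.choice(len(PREDICTOR_NAMES), size=rng.integers(1, 4), replace=False)
    conds = tuple(
        Condition(PREDICTOR_NAMES[f], rng.choice(["<", "<=", ">", ">="]),
                  float(rng.normal(50, 10)))
        for f in feats
    )
    return Rule(conds, rng.choice([CLASS_HIGH, CLASS_LOW]))


class TestCoveringError:
    def test_perfect_rule(self):
        ds = make_dataset(
            {"fev1": [3.0] * 20 + [1.0] * 23},
            [CLASS_HIGH] * 20 + [CLASS_LOW] * 23,
        )
        rule = Rule((Condition("fev1", ">", 2.0),), CLASS_HIGH)
        assert vg.covering_error(rule, ds) == (1.0, 0.0)

    def test_partial_counts(self):
        # 7 of 10 high satisfy, 1 of 10 low satisfies
        ds = make_dataset(
            {"fev1": [3.0] * 7 + [1.0] * 3 + [1.0] * 9 + [3.0]},
            [CLASS_HIGH] * 10 + [CLASS_LOW] * 10,
        )
        rule = Rule((Condition("fev1", ">", 2.0),), CLASS_HIGH)
        assert vg.covering_error(rule, ds) == (0.7, 0.1)

    def test_absent_consequence_class_rejected(self, real43):
        rule = Rule((Condition("fev1", ">", 0.0),), CLASS_HIGH)
        with pytest.raises(ValidationError):
            vg.covering_error(rule, real43.subset_class(CLASS_LOW))

    def test_matches_per_record_counting(self, real43):
        rng = np.random.default_rng(17)
        for _ in range(30):
            try:
                rule = random_rule(rng)
            except ValidationError:
                continue
            C, r = vg.covering_error(rule, real43)
            n_own = n_other = c_cnt = r_cnt = 0
            for row, label in zip(real43.features, real43.labels):
                sat = all(
                    cond.satisfied(np.array([row[PREDICTOR_NAMES.index(cond.feature)]]))[0]
                    for cond in rule.premise
                )
                if label == rule.consequence:
                    n_own += 1
                    c_cnt += sat
                else:
                    n_other += 1
                    r_cnt += sat
            assert C == pytest.approx(c_cnt / n_own)
            assert r == pytest.approx(r_cnt / n_other)

    def test_dropping_a_condition_never_reduces_coverage(self, real43):
        rng = np.random.default_rng(23)
        for _ in range(30):
            rule = random_rule(rng)
            if len(rule.premise) < 2:
                continue
            C, r = vg.covering_error(rule, real43)
            for i in range(len(rule.premise)):
                sub = Rule(rule.premise[:i] + rule.premise[i + 1 :], rule.consequence)
                C2, r2 = vg.covering_error(sub, real43)
                assert C2 >= C and r2 >= r


class TestRuleValidation:
    def test_pef_condition_rejected(self):
        with pytest.raises(ValidationError):
            Condition("pef", ">", 400.0)

    def test_contradictory_bounds_rejected(self):
        with pytest.raises(ValidationError):
            Rule((Condition("fev1", ">", 3.0), Condition("fev1", "<", 2.0)), CLASS_HIGH)

    def test_duplicate_side_rejected(self):
        with pytest.raises(ValidationError):
            Rule((Condition("fev1", "<", 3.0), Condition("fev1", "<=", 2.0)), CLASS_HIGH)

    def test_duplicate_rules_rejected_in_ruleset(self):
        r = Rule((Condition("fev1", "<", 2.23),), CLASS_LOW)
        with pytest.raises(ValidationError):
            RuleSet([r, r], CLASS_LOW)


class TestTreeInduction:
    def test_separable_toy(self, toy_separable):
        rs = vg.induce_rules_tree(toy_separable, max_depth=1, min_leaf=1)
        assert len(rs) == 2
        assert {r.consequence for r in rs} == {CLASS_HIGH, CLASS_LOW}
        for r in rs:
            assert len(r.premise) == 1
            assert 2.0 < r.premise[0].threshold < 2.4
            assert r.covering == 1.0 and r.error == 0.0
        acc, f1 = vg.evaluate_ruleset(rs, toy_separable)
        assert acc == 1.0 and f1 == 1.0

    def test_xor_quadrants(self, xor_dataset):
        rs = vg.induce_rules_tree(xor_dataset, max_depth=2, min_leaf=2)
        assert len(rs) == 4
        for r in rs:
            assert r.covering == 0.5 and r.error == 0.0
        acc, _ = vg.evaluate_ruleset(rs, xor_dataset)
        assert acc == 1.0

    def test_single_class_rejected(self, real43):
        with pytest.raises(ValidationError):
            vg.induce_rules_tree(real43.subset_class(CLASS_HIGH))

    def test_zero_depth_rejected(self, real43):
        with pytest.raises(ValidationError):
            vg.induce_rules_tree(real43, max_depth=0)

    def test_deterministic(self, real43):
        a = vg.induce_rules_tree(real43)
        b = vg.induce_rules_tree(real43)
        assert [vg.format_rule(r) for r in a] == [vg.format_rule(r) for r in b]


class TestGreedyInduction:
    def test_separable_toy(self, toy_separable):
        rs = vg.induce_rules_greedy(toy_separable, q_bins=4, max_error=0.0)
        by_class = {r.consequence: r for r in rs}
        assert set(by_class) == {CLASS_HIGH, CLASS_LOW}
        for r in by_class.values():
            assert r.covering == 1.0 and r.error == 0.0
            # threshold within one bin of the true gap (2.0, 2.4)
            bin_w = (2.6 - 1.8) / 4
            assert 2.0 - bin_w <= r.premise[0].threshold <= 2.4 + bin_w

    def test_max_conditions_binds(self, xor_dataset):
        # XOR needs two conditions per rule; with one the error budget fails
        # everywhere or coverage stays partial
        rs = vg.induce_rules_greedy(xor_dataset, q_bins=2, max_conditions=1,
                                    max_error=0.0)
        assert all(r.covering < 1.0 for r in rs)

    def test_two_conditions_solve_xor(self, xor_dataset):
        rs = vg.induce_rules_greedy(xor_dataset, q_bins=2, max_conditions=2,
                                    max_error=0.0)
        acc, _ = vg.evaluate_ruleset(rs, xor_dataset)
        assert acc == 1.0

    def test_infeasible_budget_returns_empty_set(self):
        # identically distributed classes: zero error is unattainable
        rng = np.random.default_rng(3)
        vals = rng.normal(50, 5, size=200)
        ds = make_dataset({"fev1": vals}, rng.permutation([CLASS_HIGH, CLASS_LOW] * 100))
        rs = vg.induce_rules_greedy(ds, q_bins=4, max_error=0.0)
        assert len(rs) == 0  # empty with a warning, not an error

    def test_null_rules_rarely_survive_fet(self):
        # classes identical by construction: any induced rule should fail the
        # exact test in the vast majority of replicates
        rng = np.random.default_rng(11)
        reject = total = 0
        for i in range(100):
            vals = rng.normal(50, 5, size=200)
            labels = rng.permutation([CLASS_HIGH, CLASS_LOW] * 100)
            ds = make_dataset({"fev1": vals}, labels)
            rs = vg.induce_rules_greedy(ds, q_bins=4, max_error=0.45)
            for rule in rs:
                total += 1
                reject += vg.fet_rule_pvalue(rule, ds) < 0.05
        assert total > 0
        assert reject / total <= 0.10


class TestParseFormat:
    @pytest.mark.parametrize(
        "text,n_conds,cls,feats",
        [
            ("if((FEV1<2.23))then low", 1, CLASS_LOW, ["fev1"]),
            (
                "if((heartrate<74)∧(diastolicpressure>67))then high",
                2,
                CLASS_HIGH,
                ["heart_rate", "diastolic_pressure"],
            ),
            ("if((FEV1>2.18)∧(MAP>90.39))then high", 2, CLASS_HIGH, ["fev1", "map"]),
            ("if((FEV1<=2.23)∧(MAP<=104.18))then low", 2, CLASS_LOW, ["fev1", "map"]),
        ],
    )
    def test_printed_rule_syntax(self, text, n_conds, cls, feats):
        rule = vg.parse_rule(text)
        assert len(rule.premise) == n_conds
        assert rule.consequence == cls
        assert sorted(c.feature for c in rule.premise) == sorted(feats)

    def test_annotations_parsed(self):
        rule = vg.parse_rule("if((FEV1<2.23))then low (C = 41%) (r = 4.7%) (p = 0.003)")
        assert rule.covering == pytest.approx(0.41)
        assert rule.error == pytest.approx(0.047)
        assert rule.p_value == pytest.approx(0.003)

    def test_ampersand_conjunction_accepted(self):
        rule = vg.parse_rule("if((fev1>2.18)&(map>90.39))then high")
        assert len(rule.premise) == 2

    def test_parse_format_identity(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            rule = random_rule(rng)
            rule2 = vg.parse_rule(vg.format_rule(rule))
            assert rule2.premise == rule.premise
            assert rule2.consequence == rule.consequence

    @pytest.mark.parametrize(
        "bad",
        [
            "fev1 < 2.23 implies low",
            "if((cholesterol<2))then low",
            "if((fev1<2))then medium",
            "if()then low",
            "if((pef<400))then low",
        ],
    )
    def test_malformed_rejected(self, bad):
        with pytest.raises((RuleParseError, ValidationError)):
            vg.parse_rule(bad)

    def test_ruleset_serialization_round_trip(self, real43):
        rs = vg.induce_rules_greedy(real43)
        text = vg.serialize_ruleset(rs)
        back = vg.parse_ruleset(text)
        assert back.default_class == rs.default_class
        assert [(r.premise, r.consequence) for r in back] == [
            (r.premise, r.consequence) for r in rs
        ]


class TestClassify:
    def _record(self, **cols):
        row = np.full(len(PREDICTOR_NAMES), 50.0)
        for k, v in cols.items():
            row[PREDICTOR_NAMES.index(k)] = v
        return row

    def test_single_firing_rule_wins(self):
        rs = RuleSet(
            [Rule((Condition("fev1", ">", 2.0),), CLASS_HIGH, covering=0.5, error=0.0)],
            CLASS_LOW,
        )
        assert vg.classify(rs, self._record(fev1=3.0)) == CLASS_HIGH

    def test_no_firing_rule_gives_default(self):
        rs = RuleSet(
            [Rule((Condition("fev1", ">", 2.0),), CLASS_HIGH, covering=0.5, error=0.0)],
            CLASS_LOW,
        )
        assert vg.classify(rs, self._record(fev1=1.0)) == CLASS_LOW

    def test_weighted_vote_uses_covering_and_error(self):
        # high rule w=0.43*0.955 beats low rule w=0.41*0.953
        rs = RuleSet(
            [
                Rule((Condition("fev1", ">", 0.0),), CLASS_HIGH, covering=0.43, error=0.045),
                Rule((Condition("map", ">", 0.0),), CLASS_LOW, covering=0.41, error=0.047),
            ],
            CLASS_LOW,
        )
        assert vg.classify(rs, self._record(fev1=1.0, map=1.0)) == CLASS_HIGH

    def test_exact_tie_gives_default(self):
        rs = RuleSet(
            [
                Rule((Condition("fev1", ">", 0.0),), CLASS_HIGH, covering=0.5, error=0.0),
                Rule((Condition("map", ">", 0.0),), CLASS_LOW, covering=0.5, error=0.0),
            ],
            CLASS_LOW,
        )
        assert vg.classify(rs, self._record(fev1=1.0, map=1.0)) == CLASS_LOW

    def test_both_inducers_agree_on_separable_toy(self, toy_separable):
        tree = vg.induce_rules_tree(toy_separable, max_depth=1, min_leaf=1)
        greedy = vg.induce_rules_greedy(toy_separable, q_bins=4, max_error=0.0)
        pt = vg.predict(tree, toy_separable)
        pg = vg.predict(greedy, toy_separable)
        assert np.array_equal(pt, pg)
        assert np.array_equal(pt, toy_separable.labels)
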