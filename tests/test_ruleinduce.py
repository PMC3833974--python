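import numpy as np
import pytest

from allerules.dtable import AFFECTED, UNAFFECTED
from allerules.ruleinduce import (
    ABSTAIN,
    Rule,
    brute_force_reducts,
    classify,
    cross_validate,
    discernibility_clauses,
    induce_rules,
    johnson_reduct,
    parse_rule,
    rule_to_string,
)

from conftest import build_table, random_table

NO_FILTERS = dict(min_support=1, min_accuracy=0.0, cover_fraction=1.0, balance=False)


class TestDiscernibility:
    def test_clause_per_opposite_object(self, toy3):
        clauses = discernibility_clauses(toy3, "o1")
        assert sorted(map(set, clauses)) == [{"a"}, {"b"}]

    def test_same_class_pairs_produce_no_clause(self, toy3):
        assert len(discernibility_clauses(toy3, "o2")) == 1  # only o1 is opposite

    def test_indiscernible_pair_yields_empty_clause(self):
        table = build_table(
            {"a": ["0", "0"]}, [AFFECTED, UNAFFECTED], domains={"a": ("0", "1")}
        )
        clauses = discernibility_clauses(table, "o0")
        assert clauses == [frozenset()]

    def test_missing_never_discerns(self):
        table = build_table(
            {"a": [np.nan, "1"], "b": ["0", "1"]},
            [AFFECTED, UNAFFECTED],
            domains={"a": ("0", "1"), "b": ("0", "1")},
        )
        assert discernibility_clauses(table, "o0") == [frozenset({"b"})]


class TestJohnson:
    def test_greedy_with_lexicographic_tie(self):
        assert johnson_reduct([{"a", "b"}, {"a"}, {"b", "c"}]) == {"a", "b"}

    def test_single_clause_forced(self):
        assert johnson_reduct([{"x"}]) == {"x"}

    def test_no_clauses(self):
        assert johnson_reduct([]) == set()

    def test_empty_clause_fatal(self):
        with pytest.raises(ValueError, match="inconsistent"):
            johnson_reduct([{"a"}, set()])

    def test_cover_fraction_stops_early(self):
        clauses = [{"a"}] * 9 + [{"b"}]
        assert johnson_reduct(clauses, cover_fraction=0.9) == {"a"}
        assert johnson_reduct(clauses, cover_fraction=1.0) == {"a", "b"}


class TestBruteForce:
    def test_unique_minimal_reduct(self, toy3):
        assert brute_force_reducts(toy3, "o1") == [frozenset({"a", "b"})]

    def test_johnson_vs_oracle_on_random_tables(self):
        agree = covered = total = 0
        for seed in range(40):
            table = random_table(10, 8, seed=seed, n_categories=2)
            for obj in table.data.index:
                clauses = discernibility_clauses(table, obj)
                if any(not c for c in clauses):
                    continue  # inconsistent object: both operations refuse
                total += 1
                reduct = johnson_reduct(clauses)
                assert all(c & reduct for c in clauses)
                covered += 1
                minimal = brute_force_reducts(table, obj)
                assert all(all(c & m for c in clauses) for m in minimal)
                assert any(m <= reduct for m in minimal)
                agree += frozenset(reduct) in minimal
        assert covered == total and total > 100
        assert agree / total >= 0.8  # greedy is near-minimal, not always minimal


class TestInduceRules:
    def test_three_object_example(self, toy3):
        model = induce_rules(toy3, **NO_FILTERS)
        got = {(r.conditions, r.decision) for r in model.rules}
        assert got == {
            ((("a", "0"), ("b", "0")), UNAFFECTED),
            ((("a", "1"),), AFFECTED),
            ((("b", "1"),), AFFECTED),
        }
        assert all(r.support == 1 and r.accuracy == 1.0 for r in model.rules)

    def test_duplicate_objects_merge(self, toy3):
        doubled = build_table(
            {"a": ["0", "1", "0", "1"], "b": ["0", "0", "1", "0"]},
            [UNAFFECTED, AFFECTED, AFFECTED, AFFECTED],
        )
        model = induce_rules(doubled, **NO_FILTERS)
        rule = next(r for r in model.rules if r.conditions == (("a", "1"),))
        assert rule.support == 2

    def test_min_support_filters_all(self, toy3):
        model = induce_rules(toy3, min_support=2, min_accuracy=0.0,
                             cover_fraction=1.0, balance=False)
        assert model.rules == []

    def test_training_coverage_complete_without_filters(self):
        table = random_table(60, 6, seed=4)
        model = induce_rules(table, **NO_FILTERS)
        sub = table.classified()
        for oid in sub.data.index:
            row = sub.data.loc[oid]
            cls = sub.decision[oid]
            assert any(r.decision == cls and r.matches(row) for r in model.rules)

    def test_skip_mode_drops_inconsistent_objects(self):
        table = build_table(
            {"a": ["0", "0", "1"]}, [AFFECTED, UNAFFECTED, AFFECTED],
            domains={"a": ("0", "1")},
        )
        boundary = induce_rules(table, **NO_FILTERS)
        skip = induce_rules(table, inconsistent="skip", **NO_FILTERS)
        assert {r.conditions for r in skip.rules} < {r.conditions for r in boundary.rules}


class TestClassify:
    @pytest.fixture
    def model(self, toy3):
        return induce_rules(toy3, **NO_FILTERS)

    def test_vote_sums_support(self, model):
        assert classify(model, {"a": "1", "b": "1"}) == AFFECTED  # votes 2 vs 0

    def test_no_match_abstains(self, model):
        assert classify(model, {"a": None, "b": None}) == ABSTAIN

    def test_single_matching_rule(self, model):
        assert classify(model, {"a": "0", "b": "0"}) == UNAFFECTED


class TestCrossValidate:
    def test_perfectly_separable(self):
        n = 60
        table = build_table(
            {"decisive": ["1"] * 30 + ["0"] * 30, "junk": [str(i % 3) for i in range(n)]},
            [AFFECTED] * 30 + [UNAFFECTED] * 30,
        )
        cv = cross_validate(table, k=5, seed=1)
        assert cv.coverage == pytest.approx(1.0)
        assert cv.accuracy == pytest.approx(1.0)
        assert cv.mean_n_rules >= 2

    def test_noise_accuracy_near_chance(self):
        table = random_table(400, 8, seed=10)
        cv = cross_validate(table, k=5, seed=3)
        assert 0.35 < cv.accuracy < 0.65


class TestSerialization:
    def test_published_rule_string_parses(self):
        text = "IF ORMDL3_rs2305480=2[GG] AND RORA_rs17270362=1[AG] THEN current asthma"
        rule, phenotype = parse_rule(text)
        assert rule.conditions == (("ORMDL3_rs2305480", "2"), ("RORA_rs17270362", "1"))
        assert rule.decision == AFFECTED
        assert phenotype == "current asthma"

    def test_round_trip_random_rules(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_cond = rng.integers(1, 5)
            attrs = rng.choice([f"attr{j}" for j in range(8)], size=n_cond, replace=False)
            conds = tuple((a, str(rng.integers(0, 3))) for a in attrs)
            decision = AFFECTED if rng.random() < 0.5 else UNAFFECTED
            rule = Rule(conditions=conds, decision=decision, support=1, lhs_matches=1,
                        accuracy=1.0)
            back, phenotype = parse_rule(rule_to_string(rule, phenotype="wheeze"))
            assert back.conditions == rule.conditions
            assert back.decision == rule.decision
            assert phenotype == "wheeze"

    def test_empty_conditions_invalid(self):
        with pytest.raises(ValueError):
            Rule(conditions=(), decision=AFFECTED)

    def test_malformed_text_raises_with_position(self):
        with pytest.raises(ValueError, match="position"):
            parse_rule("IF a=?=1 THEN x=affected")
        with pytest.raises(ValueError, match="position"):
            parse_rule("WHENEVER a=1 THEN x")
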