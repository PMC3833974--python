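from fractions import Fraction
from math import comb

import numpy as np
import pytest

from allerules.dtable import AFFECTED, UNAFFECTED
from allerules.ruleinduce import Rule
from allerules.rulestats import (
    bonferroni,
    dose_response,
    hypergeom_sf,
    odds_ratio_2x2,
    odds_ratio_logistic,
    rule_or,
    rule_pvalue,
    score_rules,
    validate_rule_external,
)
from allerules.synthcohort import CohortSpec, EffectSpec, simulate_cohort

from conftest import build_table


def exact_upper_tail(k, N, K, n):
    """Exhaustive-enumeration oracle for P(X >= k), exact rational arithmetic."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return total


class TestHypergeometric:
    def test_printed_example(self):
        # all 6 drawn from the 10-member class: 210/38760
        assert hypergeom_sf(6, 20, 10, 6) == pytest.approx(210 / 38760, abs=1e-10)

    def test_k_zero_is_certain(self):
        assert hypergeom_sf(0, 50, 10, 5) == 1.0

    def test_tiny_margin(self):
        assert hypergeom_sf(2, 4, 2, 2) == pytest.approx(1 / 6, abs=1e-12)

    def test_inconsistent_margins_fatal(self):
        with pytest.raises(ValueError):
            hypergeom_sf(3, 4, 10, 2)

    def test_matches_enumeration_small(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeom_sf(k, N, K, n) == pytest.approx(
                            float(exact_upper_tail(k, N, K, n)), abs=1e-10
                        )

    def test_tail_non_increasing_in_k(self):
        vals = [hypergeom_sf(k, 30, 12, 9) for k in range(10)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestBonferroni:
    def test_printed_threshold_220_factors(self):
        per_test = 0.05 / 220
        assert float(f"{per_test:.1e}") == pytest.approx(2.3e-4)
        assert bonferroni([per_test], 220)[0] == pytest.approx(0.05)

    def test_direct(self):
        assert bonferroni([0.01, 0.5], 2) == [0.02, 1.0]

    def test_identity_for_single_test(self):
        assert bonferroni([0.2], 1) == [0.2]

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni([0.0], 2)
        with pytest.raises(ValueError):
            bonferroni([1.5], 2)

    def test_monotone_in_p_and_m(self):
        ps = [0.001, 0.01, 0.02]
        adj5 = bonferroni(ps, 5)
        adj50 = bonferroni(ps, 50)
        assert adj5 == sorted(adj5)
        assert all(a <= b for a, b in zip(adj5, adj50))


class TestOdds2x2:
    def test_woolf_example(self):
        res = odds_ratio_2x2(10, 5, 5, 10)
        assert res.or_estimate == pytest.approx(4.0)
        assert res.ci_low == pytest.approx(0.876, abs=2e-3)
        assert res.ci_high == pytest.approx(18.26, abs=2e-2)
        assert not res.correction_applied

    def test_symmetric_table_is_null(self):
        assert odds_ratio_2x2(7, 7, 7, 7).or_estimate == pytest.approx(1.0)

    def test_haldane_anscombe_correction(self):
        res = odds_ratio_2x2(10, 0, 5, 10)
        assert res.correction_applied
        assert res.or_estimate == pytest.approx((10.5 * 10.5) / (0.5 * 5.5), abs=1e-6)

    def test_empty_margin_fatal(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 5, 0, 10)

    def test_reciprocal_property(self):
        a, b, c, d = 12, 7, 9, 21
        assert odds_ratio_2x2(a, b, c, d).or_estimate * odds_ratio_2x2(
            b, a, d, c
        ).or_estimate == pytest.approx(1.0)


class TestLogisticOr:
    def _xy(self, a, b, c, d):
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        x = np.array([1] * (a + b) + [0] * (c + d))
        return y, x

    def test_equals_cross_product_ratio(self):
        y, x = self._xy(30, 18, 22, 41)
        res = odds_ratio_logistic(y, x)
        assert res.method == "logistic_wald"
        assert res.or_estimate == pytest.approx((30 * 41) / (18 * 22), abs=1e-4)

    def test_null_ci_contains_one(self):
        y, x = self._xy(100, 100, 100, 100)
        res = odds_ratio_logistic(y, x)
        assert res.ci_low < 1.0 < res.ci_high

    def test_separation_falls_back_to_corrected_2x2(self):
        y, x = self._xy(10, 0, 5, 10)
        res = odds_ratio_logistic(y, x)
        assert res.method == "woolf" and res.correction_applied

    def test_agrees_with_woolf_for_large_cells(self):
        y, x = self._xy(60, 45, 38, 82)
        lg = odds_ratio_logistic(y, x)
        wf = odds_ratio_2x2(60, 45, 38, 82)
        assert lg.or_estimate == pytest.approx(wf.or_estimate, rel=0.01)
        assert lg.ci_low == pytest.approx(wf.ci_low, rel=0.01)


def planted_cohort(or_value, n=20000, seed=5, baseline=0.1):
    spec = CohortSpec(
        name="p",
        n=n,
        snps=[("s1", 0.7), ("s2", 0.7), ("s3", 0.8)],
        effects=[
            EffectSpec("gene_gene", (("s1", "2"), ("s2", "1")), or_value, "asthma_dx_ever")
        ],
        baseline={
            "asthma_dx_ever": baseline,
            "wheeze_12m": 0.1,
            "eczema_dx": 0.1,
            "rhino_symptoms_12m": 0.1,
            "sensitized": 0.3,
        },
        missing_rate=0.0,
        seed=seed,
    )
    return simulate_cohort(spec).decision_table("asthma")


PAIR_RULE = Rule(
    conditions=(("s1", "2"), ("s2", "1")), decision=AFFECTED, support=1, lhs_matches=1,
    accuracy=1.0,
)


class TestRuleOr:
    @pytest.mark.parametrize("or_value", [1.5, 3.0, 7.0])
    def test_generating_or_recovered_within_ci(self, or_value):
        table = planted_cohort(or_value)
        res = rule_or(PAIR_RULE, table)
        assert res.ci_low <= or_value <= res.ci_high

    def test_protective_effect_estimates_below_one(self):
        table = planted_cohort(0.2)
        assert rule_or(PAIR_RULE, table).or_estimate < 1.0

    def test_rule_matching_everyone_fatal(self):
        universal = build_table({"x": ["1"] * 20}, [AFFECTED] * 10 + [UNAFFECTED] * 10)
        with pytest.raises(ValueError, match="reference"):
            rule_or(Rule(conditions=(("x", "1"),), decision=AFFECTED, support=1,
                         lhs_matches=1, accuracy=1.0), universal)

    def test_hypergeometric_enrichment_of_planted_rule(self):
        table = planted_cohort(3.0)
        test = rule_pvalue(PAIR_RULE, table)
        assert test.p < 1e-6
        assert test.N >= test.n and test.K >= test.k


class TestValidation:
    def test_absent_attribute_not_validatable(self):
        other = build_table({"z": ["0", "1"]}, [AFFECTED, UNAFFECTED])
        res = validate_rule_external(PAIR_RULE, other)
        assert not res.validatable and res.direction_match is None

    def test_shared_planted_effect_replicates_direction(self):
        res = validate_rule_external(PAIR_RULE, planted_cohort(3.0, seed=77))
        assert res.validatable and res.direction_match

    def test_affected_rule_with_protective_or_fails_direction(self):
        res = validate_rule_external(PAIR_RULE, planted_cohort(0.3, seed=78))
        assert res.validatable and res.direction_match is False


class TestDoseResponse:
    def test_single_condition_rule_rejected(self):
        rule = Rule(conditions=(("s1", "2"),), decision=AFFECTED, support=1,
                    lhs_matches=1, accuracy=1.0)
        with pytest.raises(ValueError):
            dose_response(rule, planted_cohort(2.0, n=500))

    def test_reference_level_is_unity_and_trend_increases(self):
        table = planted_cohort(3.5)
        levels = dose_response(PAIR_RULE, table)
        assert levels[0].or_estimate == 1.0
        assert levels[2].or_estimate > levels[1].or_estimate


class TestScoreRules:
    def test_family_adjustment_annotates_rules(self):
        table = planted_cohort(3.0, n=2000)
        rules = [
            Rule(conditions=(("s1", "2"), ("s2", "1")), decision=AFFECTED, support=5,
                 lhs_matches=5, accuracy=1.0, id=1),
            Rule(conditions=(("s3", "2"),), decision=UNAFFECTED, support=5,
                 lhs_matches=5, accuracy=1.0, id=2),
        ]
        stats = score_rules(rules, table, family_size=10)
        assert list(stats["rule_id"]) == [1, 2]
        for r in rules:
            assert r.p_adjusted == pytest.approx(min(1.0, 10 * r.p_value))
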