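import numpy as np
import pytest
from scipy import stats

from allerules.dtable import AFFECTED
from allerules.synthcohort import (
    CohortSpec,
    Cluster,
    EffectSpec,
    EnvFactor,
    default_cohort_pair,
    default_pair_specs,
    simulate_cohort_pair,
    simulate_environment,
    simulate_genotypes,
    simulate_raw_health,
)

BASELINES = {
    "asthma_dx_ever": 0.15,
    "wheeze_12m": 0.11,
    "eczema_dx": 0.09,
    "rhino_symptoms_12m": 0.15,
    "sensitized": 0.35,
}


def spec(n=10000, snps=None, env=None, clusters=(), effects=(), missing=0.0,
         baseline=None, seed=0):
    return CohortSpec(
        name="t",
        n=n,
        snps=snps or [("s1", 0.7)],
        env_factors=list(env or []),
        clusters=list(clusters),
        missing_rate=missing,
        effects=list(effects),
        baseline=baseline or dict(BASELINES),
        seed=seed,
    )


class TestGenotypes:
    def test_hardy_weinberg_fractions(self):
        geno = simulate_genotypes(spec())
        frac = geno["s1"].value_counts(normalize=True)
        assert frac["2"] == pytest.approx(0.49, abs=0.02)
        assert frac["1"] == pytest.approx(0.42, abs=0.02)
        assert frac["0"] == pytest.approx(0.09, abs=0.02)

    def test_degenerate_frequency(self):
        geno = simulate_genotypes(spec(n=500, snps=[("s1", 1.0)]))
        assert (geno["s1"] == "2").all()

    def test_deterministic_under_seed(self):
        a = simulate_genotypes(spec(n=200, seed=3))
        b = simulate_genotypes(spec(n=200, seed=3))
        assert a.equals(b)

    def test_marginals_within_three_binomial_se(self):
        for p in (0.6, 0.8, 0.9):
            geno = simulate_genotypes(spec(n=6000, snps=[("s", p)]))
            counts = geno["s"].map(int).sum()
            mean, se = 2 * 6000 * p, np.sqrt(2 * 6000 * p * (1 - p))
            assert abs(counts - mean) <= 3 * se


class TestEnvironment:
    def test_categorical_fraction(self):
        env = simulate_environment(spec(env=[EnvFactor("f", (0.8, 0.2))]))
        assert (env["f"] == "1").mean() == pytest.approx(0.2, abs=0.02)

    def _phi(self, env, a, b):
        x = (env[a] == "1").to_numpy()
        y = (env[b] == "1").to_numpy()
        return np.corrcoef(x, y)[0, 1]

    def test_clustered_factors_positively_correlated(self):
        factors = [EnvFactor("f1", (0.75, 0.25)), EnvFactor("f2", (0.75, 0.25))]
        cl = Cluster(members=("f1", "f2"), strength=0.5, prevalence=0.25)
        env = simulate_environment(spec(env=factors, clusters=[cl]))
        assert self._phi(env, "f1", "f2") > 0.1

    def test_zero_strength_is_independent(self):
        factors = [EnvFactor("f1", (0.75, 0.25)), EnvFactor("f2", (0.75, 0.25))]
        cl = Cluster(members=("f1", "f2"), strength=0.0, prevalence=0.25)
        env = simulate_environment(spec(env=factors, clusters=[cl]))
        assert abs(self._phi(env, "f1", "f2")) < 3 / np.sqrt(10000)


class TestRawHealth:
    def test_baseline_prevalence_without_effects(self):
        s = spec()
        geno = simulate_genotypes(s)
        env = simulate_environment(s)
        health = simulate_raw_health(s, geno, env)
        assert health["asthma_dx_ever"].mean() == pytest.approx(0.15, abs=0.01)
        # the calibrated intercept reduces to logit(baseline) with no effects
        from allerules.synthcohort import _calibrated_intercept

        assert _calibrated_intercept(np.zeros(10), 0.15) == pytest.approx(-1.7346, abs=1e-4)

    def test_null_effect_leaves_independence(self):
        s = spec(effects=[EffectSpec("main", (("s1", "2"),), 1.0, "asthma_dx_ever")])
        geno = simulate_genotypes(s)
        health = simulate_raw_health(s, geno, simulate_environment(s))
        table = np.array(
            [
                [
                    ((geno["s1"] == g) & health["asthma_dx_ever"]).sum(),
                    ((geno["s1"] == g) & ~health["asthma_dx_ever"]).sum(),
                ]
                for g in ("0", "1", "2")
            ]
        )
        assert stats.chi2_contingency(table)[1] > 0.01

    def test_planted_interaction_recovered_in_2x2(self):
        s = spec(
            n=20000,
            snps=[("s1", 0.7), ("s2", 0.7)],
            effects=[EffectSpec("gene_gene", (("s1", "2"), ("s2", "1")), 3.2, "asthma_dx_ever")],
        )
        geno = simulate_genotypes(s)
        health = simulate_raw_health(s, geno, simulate_environment(s))
        exposed = (geno["s1"] == "2") & (geno["s2"] == "1")
        y = health["asthma_dx_ever"]
        a, b = (exposed & y).sum(), (exposed & ~y).sum()
        c, d = (~exposed & y).sum(), (~exposed & ~y).sum()
        assert 2.6 < (a * d) / (b * c) < 3.9

    def test_ige_mixture_matches_sensitization(self):
        s = spec(n=4000)
        geno = simulate_genotypes(s)
        health = simulate_raw_health(s, geno, simulate_environment(s))
        sens = health[["ige_inhalant", "ige_food"]].max(axis=1) >= 0.35
        assert (sens == health["sensitized"]).all()

    def test_degenerate_baseline_fatal(self):
        s = spec(n=100, baseline={**BASELINES, "asthma_dx_ever": 1.0})
        with pytest.raises(ValueError):
            simulate_raw_health(s, simulate_genotypes(s), simulate_environment(s))


class TestCohortPair:
    def test_default_shapes_match_study(self):
        cohortA, cohortB, manifest = default_cohort_pair(seed=1)
        assert len(cohortA.data) == 2033
        assert len(cohortB.data) == 3113
        assert len(manifest["shared_snps"]) == 110
        assert sum(a.kind == "snp" for a in cohortB.attributes) == 188
        assert sum(a.kind != "snp" for a in cohortB.attributes) == 33
        assert manifest["planted_effects"]

    def test_default_prevalences_near_targets(self):
        cohortA, _, _ = default_cohort_pair(seed=2)
        for ingredient, target in (
            ("asthma_dx_ever", 0.150),
            ("wheeze_12m", 0.112),
            ("eczema_dx", 0.093),
            ("sensitized", 0.353),
        ):
            assert cohortA.health[ingredient].mean() == pytest.approx(target, abs=0.02)

    def test_disjoint_shared_list(self):
        sA = spec(n=200, snps=[("a1", 0.7)])
        sB = spec(n=300, snps=[("b1", 0.7)], seed=1)
        sA = CohortSpec(**{**sA.__dict__, "name": "A"})
        sB = CohortSpec(**{**sB.__dict__, "name": "B"})
        _, _, manifest = simulate_cohort_pair(sA, sB)
        assert manifest["shared_snps"] == []

    def test_shared_frequency_mismatch_fatal(self):
        sA, sB = default_pair_specs()
        sB.snps[0] = (sB.snps[0][0], 0.9)
        with pytest.raises(ValueError, match="frequencies differ"):
            simulate_cohort_pair(sA, sB)

    def test_shared_effect_mismatch_fatal(self):
        sA, sB = default_pair_specs()
        sB.effects.pop()
        with pytest.raises(ValueError, match="shared effect"):
            simulate_cohort_pair(sA, sB)

    def test_planted_rule_crude_ors_hit_targets(self):
        """The solved multipliers place the crude rule ORs on their targets."""
        from allerules.ruleinduce import Rule
        from allerules.rulestats import rule_or
        from allerules.experiments import ENV_PAIR, GENE_PAIR

        ors_gene, ors_env = [], []
        for seed in (11, 12, 13):
            cohortA, cohortB, _ = default_cohort_pair(seed=seed)
            gene_rule = Rule(conditions=GENE_PAIR, decision=AFFECTED, support=1,
                             lhs_matches=1, accuracy=1.0)
            env_rule = Rule(conditions=ENV_PAIR, decision=AFFECTED, support=1,
                            lhs_matches=1, accuracy=1.0)
            ors_gene.append(rule_or(gene_rule, cohortA.decision_table("asthma")).or_estimate)
            ors_env.append(rule_or(env_rule, cohortB.decision_table("asthma")).or_estimate)
        assert np.median(ors_gene) == pytest.approx(3.2, abs=0.8)
        assert np.median(ors_env) == pytest.approx(7.0, abs=2.0)
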