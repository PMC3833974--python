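"""Paired synthetic cohorts with planted gene-gene and gene-environment effects.

The generator emulates the statistical shape of the two epidemiological
materials the analysis was designed for: a Swedish birth-cohort-like study
(~2000 children, 110 SNPs) and a larger European cross-sectional-like study
(~3100 children, 188 SNPs plus 33 lifestyle/environment factors), with 110
SNPs shared between them. Genotypes are drawn under Hardy-Weinberg
equilibrium in major-allele-count coding; exposures are independent
categorical draws except for an optional "farm lifestyle" cluster whose
members share a latent binary variable; raw health ingredients (doctor's
asthma/eczema diagnoses, recent wheeze, rhinitis symptoms, IgE) follow
logistic models whose log-odds add ln(OR) for every planted effect the child
matches. IgE magnitudes come from a two-component log-normal mixture tied to
the sensitization ingredient so that the 0.35 kU/L threshold reproduces it
exactly.

Effects are multiplicative on the odds scale; the intercept of each
ingredient model is calibrated so the realized marginal prevalence matches
the configured baseline even in the presence of planted effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._seeds import substream
from .dtable import Attribute, DecisionTable
from .phenoderive import PHENOTYPES, derive_phenotypes

log = logging.getLogger(__name__)

INGREDIENTS = ("asthma_dx_ever", "wheeze_12m", "eczema_dx", "rhino_symptoms_12m", "sensitized")

# log-normal mixture for IgE (kU/L); components straddle the 0.35 and 3.5 thresholds
_IGE_LOW = (-2.0, 0.5)
_IGE_HIGH = (1.5, 1.0)
_SENS_THRESHOLD = 0.35


@dataclass(frozen=True)
class EffectSpec:
    """A planted effect: multiplicative on the odds of one raw ingredient."""

    kind: str  # main | gene_gene | gene_environment | env_env
    conditions: tuple[tuple[str, str], ...]
    odds_ratio: float
    target: str

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if self.target not in INGREDIENTS:
            raise ValueError(f"unknown ingredient {self.target!r}")
        object.__setattr__(
            self, "conditions", tuple((str(a), str(c)) for a, c in self.conditions)
        )


@dataclass(frozen=True)
class EnvFactor:
    name: str
    probs: tuple[float, ...]  # category probabilities for codes "0", "1", ...
    kind: str = "environment"
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: category probabilities must sum to 1")


@dataclass(frozen=True)
class Cluster:
    """Binary factors sharing a latent lifestyle variable (raises concordance)."""

    members: tuple[str, ...]
    strength: float = 0.5  # 0 = independent
    prevalence: float = 0.25  # of the latent variable


@dataclass
class CohortSpec:
    name: str
    n: int
    snps: list[tuple[str, float]]  # (name, major-allele frequency)
    env_factors: list[EnvFactor] = field(default_factory=list)
    clusters: list[Cluster] = field(default_factory=list)
    missing_rate: float = 0.02
    effects: list[EffectSpec] = field(default_factory=list)
    baseline: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    calibrate_intercept: bool = True

    def __post_init__(self) -> None:
        for name, p in self.snps:
            if not (0 < p <= 1):
                raise ValueError(f"SNP {name}: major-allele frequency must be in (0, 1]")
        if not (0 <= self.missing_rate <= 0.2):
            raise ValueError("missing_rate must be in [0, 0.2]")
        declared = {n for n, _ in self.snps} | {f.name for f in self.env_factors}
        for e in self.effects:
            for attr, _ in e.conditions:
                if attr not in declared:
                    raise ValueError(f"effect condition references undeclared attribute {attr!r}")

    def attributes(self) -> list[Attribute]:
        attrs = [Attribute(name=n, kind="snp") for n, _ in self.snps]
        for f in self.env_factors:
            labels = (
                {str(i): lab for i, lab in enumerate(f.labels)} if f.labels else None
            )
            attrs.append(
                Attribute(
                    name=f.name,
                    kind=f.kind,
                    domain=tuple(str(i) for i in range(len(f.probs))),
                    labels=labels,
                )
            )
        return attrs


@dataclass
class RawHealthRecord:
    """Raw health ingredients from which the 11 phenotypes are derived."""

    asthma_dx_ever: bool | None
    wheeze_12m: bool | None
    eczema_dx: bool | None
    rhino_symptoms_12m: bool | None
    ige_inhalant: float | None
    ige_food: float | None

    def __post_init__(self) -> None:
        for v in (self.ige_inhalant, self.ige_food):
            if v is not None and v < 0:
                raise ValueError("IgE values must be non-negative")


@dataclass
class SyntheticCohort:
    """One simulated cohort: attribute data, raw health and derived phenotypes."""

    name: str
    attributes: list[Attribute]
    data: pd.DataFrame  # category codes as strings, NaN for missing
    health: pd.DataFrame
    phenotypes: pd.DataFrame  # affected/unaffected/EXCLUDED per phenotype

    def decision_table(self, phenotype: str) -> DecisionTable:
        if phenotype not in self.phenotypes.columns:
            raise KeyError(phenotype)
        return DecisionTable(
            self.data.copy(),
            list(self.attributes),
            self.phenotypes[phenotype].copy(),
            decision_name=phenotype,
        )

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]


# -- simulation stages -----------------------------------------------------

def simulate_genotypes(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Hardy-Weinberg genotypes in major-allele-count coding ("0"/"1"/"2")."""
    seed = spec.seed if seed is None else seed
    ids = pd.Index([f"{spec.name}_{i:05d}" for i in range(spec.n)], name="id")
    out = {}
    for name, p in spec.snps:
        rng = substream(seed, "geno", name)
        copies = rng.binomial(2, p, size=spec.n)
        col = copies.astype("U1").astype(object)
        if spec.missing_rate > 0:
            miss = rng.random(spec.n) < spec.missing_rate
            col[miss] = np.nan
        out[name] = col
    return pd.DataFrame(out, index=ids)


def simulate_environment(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Categorical exposure draws; clustered binary factors share a latent state."""
    seed = spec.seed if seed is None else seed
    ids = pd.Index([f"{spec.name}_{i:05d}" for i in range(spec.n)], name="id")
    latent: dict[str, np.ndarray] = {}
    member_of: dict[str, Cluster] = {}
    for ci, cl in enumerate(spec.clusters):
        rng = substream(seed, "cluster", ci)
        z = rng.random(spec.n) < cl.prevalence
        for mname in cl.members:
            latent[mname] = z
            member_of[mname] = cl
    out = {}
    for f in spec.env_factors:
        rng = substream(seed, "env", f.name)
        if f.name in member_of and member_of[f.name].strength > 0:
            if len(f.probs) != 2:
                raise ValueError(f"clustered factor {f.name} must be binary")
            cl = member_of[f.name]
            p = f.probs[1]
            p1 = p + cl.strength * (1 - p)
            p0 = (p - cl.prevalence * p1) / (1 - cl.prevalence)
            if p0 < 0:
                raise ValueError(f"cluster strength too high for {f.name} (marginal {p})")
            z = latent[f.name]
            draw = (rng.random(spec.n) < np.where(z, p1, p0)).astype(int)
        else:
            draw = rng.choice(len(f.probs), size=spec.n, p=f.probs)
        col = draw.astype("U1").astype(object)
        if spec.missing_rate > 0:
            miss = rng.random(spec.n) < spec.missing_rate
            col[miss] = np.nan
        out[f.name] = col
    return pd.DataFrame(out, index=ids)


def _effect_offsets(spec: CohortSpec, covariates: pd.DataFrame, target: str) -> np.ndarray:
    """Summed ln(OR) per object over matching effects for one ingredient."""
    eta = np.zeros(len(covariates))
    for e in spec.effects:
        if e.target != target:
            continue
        match = np.ones(len(covariates), dtype=bool)
        for attr, code in e.conditions:
            match &= (covariates[attr] == code).to_numpy()
        eta += match * np.log(e.odds_ratio)
    return eta


def _calibrated_intercept(offsets: np.ndarray, baseline: float) -> float:
    """Intercept making the realized marginal prevalence equal the baseline.

    With no planted effects this is exactly logit(baseline).
    """
    if np.all(offsets == 0):
        return float(logit(baseline))

    def gap(c: float) -> float:
        return float(expit(c + offsets).mean() - baseline)

    return float(brentq(gap, -30.0, 30.0))


def _conditional_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float, above: bool
) -> np.ndarray:
    """Log-normal draws conditioned on the 0.35 kU/L sensitization threshold."""
    out = rng.lognormal(mu, sigma, size=n)
    for _ in range(1000):
        bad = (out < _SENS_THRESHOLD) if above else (out >= _SENS_THRESHOLD)
        if not bad.any():
            return out
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
    raise RuntimeError("rejection sampling for IgE did not terminate")


def simulate_raw_health(
    spec: CohortSpec,
    genotypes: pd.DataFrame,
    environment: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw raw health ingredients from the planted logistic models.

    Returns a DataFrame with the boolean ingredients and the two IgE columns;
    ``records()`` converts rows to RawHealthRecord objects.
    """
    seed = spec.seed if seed is None else seed
    if not genotypes.index.equals(environment.index) and len(environment.columns):
        raise ValueError("genotype and environment tables must share objects")
    cov = genotypes.join(environment) if len(environment.columns) else genotypes
    out = pd.DataFrame(index=cov.index)
    for ingredient in INGREDIENTS:
        baseline = spec.baseline.get(ingredient, 0.1)
        if not (0 < baseline < 1):
            raise ValueError(f"baseline prevalence for {ingredient} must be in (0, 1)")
        offsets = _effect_offsets(spec, cov, ingredient)
        if spec.calibrate_intercept:
            c = _calibrated_intercept(offsets, baseline)
        else:
            c = float(logit(baseline))
        p = expit(c + offsets)
        rng = substream(seed, "health", ingredient)
        out[ingredient] = rng.random(len(cov)) < p
    rng = substream(seed, "ige")
    s = out["sensitized"].to_numpy()
    ige_inh = np.empty(len(cov))
    ige_inh[s] = _conditional_lognormal(rng, int(s.sum()), *_IGE_HIGH, above=True)
    ige_inh[~s] = _conditional_lognormal(rng, int((~s).sum()), *_IGE_LOW, above=False)
    ige_food = _conditional_lognormal(rng, len(cov), *_IGE_LOW, above=False)
    out["ige_inhalant"] = ige_inh
    out["ige_food"] = ige_food
    return out


def records(health: pd.DataFrame) -> list[RawHealthRecord]:
    """Convert a raw-health DataFrame to RawHealthRecord objects."""
    return [
        RawHealthRecord(
            asthma_dx_ever=bool(r.asthma_dx_ever),
            wheeze_12m=bool(r.wheeze_12m),
            eczema_dx=bool(r.eczema_dx),
            rhino_symptoms_12m=bool(r.rhino_symptoms_12m),
            ige_inhalant=float(r.ige_inhalant),
            ige_food=float(r.ige_food),
        )
        for r in health.itertuples()
    ]


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> SyntheticCohort:
    """Run all simulation stages for one cohort and derive its phenotypes."""
    seed = spec.seed if seed is None else seed
    geno = simulate_genotypes(spec, seed)
    env = simulate_environment(spec, seed)
    health = simulate_raw_health(spec, geno, env, seed)
    pheno = derive_phenotypes(health)
    data = geno.join(env) if len(env.columns) else geno
    return SyntheticCohort(
        name=spec.name,
        attributes=spec.attributes(),
        data=data,
        health=health,
        phenotypes=pheno,
    )


def simulate_cohort_pair(
    specA: CohortSpec,
    specB: CohortSpec,
    shared: list[str] | None = None,
    seed: int | None = None,
) -> tuple[SyntheticCohort, SyntheticCohort, dict]:
    """Two cohorts plus a manifest of shared attributes and planted truth.

    Shared SNPs must have identical frequencies in both specs, and effects
    whose conditions involve only shared attributes must be declared
    identically in both (so that planted signals are recoverable in either).
    """
    freqA = dict(specA.snps)
    freqB = dict(specB.snps)
    if shared is None:
        shared = sorted(set(freqA) & set(freqB))
    for s in shared:
        if s not in freqA or s not in freqB:
            raise ValueError(f"shared SNP {s} missing from a spec")
        if freqA[s] != freqB[s]:
            raise ValueError(f"shared SNP {s}: frequencies differ between specs")
    shared_env = sorted(
        {f.name for f in specA.env_factors} & {f.name for f in specB.env_factors}
    )
    shared_attrs = set(shared) | set(shared_env)
    for a, b in ((specA, specB), (specB, specA)):
        for e in a.effects:
            if {attr for attr, _ in e.conditions} <= shared_attrs and e not in b.effects:
                raise ValueError(f"shared effect {e} not declared in both specs")
    seedA = specA.seed if seed is None else seed
    seedB = specB.seed if seed is None else seed + 1
    cohortA = simulate_cohort(specA, seedA)
    cohortB = simulate_cohort(specB, seedB)
    manifest = {
        "cohorts": {specA.name: specA.n, specB.name: specB.n},
        "shared_snps": list(shared),
        "shared_env_factors": shared_env,
        "planted_effects": [
            {
                "cohort": sp.name,
                "kind": e.kind,
                "conditions": list(map(list, e.conditions)),
                "odds_ratio": e.odds_ratio,
                "target": e.target,
            }
            for sp in (specA, specB)
            for e in sp.effects
        ],
        "seeds": {specA.name: seedA, specB.name: seedB},
        "notes": "exposure cluster structure is a synthetic construct of this generator",
    }
    return cohortA, cohortB, manifest


# -- default study-shaped scenario ----------------------------------------

_FREQ_CYCLE = (0.70, 0.62, 0.81, 0.74, 0.88, 0.67, 0.93, 0.58, 0.77, 0.85)

_NAMED_ENV: list[tuple[str, float, str]] = [
    ("formula_fed", 0.30, "lifestyle"),
    ("antibiotics_early", 0.30, "lifestyle"),
    ("farm_living", 0.25, "environment"),
    ("farm_milk", 0.25, "lifestyle"),
    ("farm_animal_contact", 0.30, "environment"),
    ("mother_farm_pregnancy", 0.15, "environment"),
]

_BASELINE_A = {
    "asthma_dx_ever": 0.150,
    "wheeze_12m": 0.112,
    "eczema_dx": 0.093,
    "rhino_symptoms_12m": 0.154,
    "sensitized": 0.353,
}
_BASELINE_B = {
    "asthma_dx_ever": 0.085,
    "wheeze_12m": 0.077,
    "eczema_dx": 0.131,
    "rhino_symptoms_12m": 0.070,
    "sensitized": 0.288,
}


def _snp_list(count: int) -> list[tuple[str, float]]:
    snps = []
    for i in range(1, count + 1):
        # the two headline-pair SNPs get balanced common-variant frequencies
        freq = _GENE_FREQ if i <= 2 else _FREQ_CYCLE[i % len(_FREQ_CYCLE)]
        snps.append((f"snp{i:03d}", freq))
    return snps


def _env_list(count: int) -> list[EnvFactor]:
    factors = [
        EnvFactor(name=n, probs=(1 - p, p), kind=k, labels=("no", "yes"))
        for n, p, k in _NAMED_ENV
    ]
    i = len(factors) + 1
    while len(factors) < count:
        if i % 5 == 0:
            probs = (0.5, 0.3, 0.2)
            labels = ("low", "mid", "high")
        else:
            p = 0.2 + 0.05 * (i % 7)
            probs = (1 - p, p)
            labels = ("no", "yes")
        factors.append(EnvFactor(name=f"exposure_{i:02d}", probs=probs, labels=labels))
        i += 1
    return factors


GENE_RULE_OR = 3.2  # crude OR of the planted genotype combination vs all others
GENE_MAIN_OR = 1.6  # marginal effect of each headline SNP, as GWAS loci carry
ENV_RULE_OR = 7.0
_GENE_FREQ = 0.74


def _solve_planted_multipliers(
    q: float,
    main_or: float,
    gene_target: float,
    env_prob: float,
    env_target: float,
    baseline_gene_cohort: float,
    baseline_env_cohort: float,
) -> tuple[float, float]:
    """Joint-cell odds multipliers making both planted rules' *crude* odds
    ratios hit their targets in the cohorts where they are measured.

    The crude (all-fulfilling vs all-other children) OR of one planted rule
    is attenuated by the other planted effect mixing into both comparison
    groups, so the two multipliers are solved jointly by alternation over the
    six genotype x exposure cells. ``q`` is the probability of each single
    genotype condition, ``env_prob`` the probability of the joint exposure.
    """
    gene_probs = np.array([q * q, 2 * q * (1 - q), (1 - q) ** 2])

    def crude_ors(b: float, E: float, baseline: float) -> tuple[float, float]:
        gene_mult = np.array([main_or**2 * b, main_or, 1.0])
        env_mult = np.array([E, 1.0])
        env_probs = np.array([env_prob, 1 - env_prob])
        probs = np.outer(gene_probs, env_probs)
        lin = np.log(np.outer(gene_mult, env_mult))

        def gap(c: float) -> float:
            return float((probs * expit(c + lin)).sum() - baseline)

        c = brentq(gap, -30.0, 30.0)
        risk = expit(c + lin)

        def odds_of(mask: np.ndarray) -> float:
            r = float((probs * risk * mask).sum() / (probs * mask).sum())
            return r / (1 - r)

        gene_mask = np.zeros_like(probs)
        gene_mask[0, :] = 1.0
        env_mask = np.zeros_like(probs)
        env_mask[:, 0] = 1.0
        gene_or = odds_of(gene_mask) / odds_of(1 - gene_mask)
        env_or = odds_of(env_mask) / odds_of(1 - env_mask)
        return gene_or, env_or

    b, E = gene_target, env_target
    for _ in range(8):
        b = float(
            brentq(lambda x: crude_ors(x, E, baseline_gene_cohort)[0] - gene_target, 1.0, 200.0)
        )
        E = float(
            brentq(lambda x: crude_ors(b, x, baseline_env_cohort)[1] - env_target, 1.0, 500.0)
        )
    return b, E


def default_pair_specs(seed: int = 0) -> tuple[CohortSpec, CohortSpec]:
    """Study-shaped default scenario: two planted headline-like interactions.

    A shared 2-SNP risk-genotype combination whose crude odds ratio versus all
    other children is 3.2 (each SNP also carries a modest main effect, OR 1.4,
    as established susceptibility loci do) on the asthma and wheeze
    ingredients, so the derived current-asthma phenotype carries it; and a
    formula-feeding x early-antibiotics pair (OR 7 on asthma). Cohort A holds
    the 110 shared SNPs and a subset of the exposures; cohort B holds 188
    SNPs and all 33 exposures.
    """
    gene_pair = (("snp001", "2"), ("snp002", "2"))
    env_pair = (("formula_fed", "1"), ("antibiotics_early", "1"))
    joint, env_mult = _solve_planted_multipliers(
        q=_GENE_FREQ**2,
        main_or=GENE_MAIN_OR,
        gene_target=GENE_RULE_OR,
        env_prob=0.3 * 0.3,
        env_target=ENV_RULE_OR,
        baseline_gene_cohort=_BASELINE_A["asthma_dx_ever"],
        baseline_env_cohort=_BASELINE_B["asthma_dx_ever"],
    )
    effects = []
    for target in ("asthma_dx_ever", "wheeze_12m"):
        effects += [
            EffectSpec("main", (gene_pair[0],), GENE_MAIN_OR, target),
            EffectSpec("main", (gene_pair[1],), GENE_MAIN_OR, target),
            EffectSpec("gene_gene", gene_pair, joint, target),
        ]
    effects.append(EffectSpec("env_env", env_pair, env_mult, "asthma_dx_ever"))
    all_env = _env_list(33)
    env_a_names = [n for n, _, _ in _NAMED_ENV[:4]] + [
        f.name for f in all_env if f.name.startswith("exposure_")
    ][:6]
    env_a = [f for f in all_env if f.name in env_a_names]
    cluster = Cluster(
        members=("farm_living", "farm_milk", "farm_animal_contact", "mother_farm_pregnancy"),
        strength=0.5,
        prevalence=0.25,
    )
    cluster_a = Cluster(members=("farm_living", "farm_milk"), strength=0.5, prevalence=0.25)
    specA = CohortSpec(
        name="cohortA",
        n=2033,
        snps=_snp_list(110),
        env_factors=env_a,
        clusters=[cluster_a],
        effects=list(effects),
        baseline=dict(_BASELINE_A),
        seed=seed,
    )
    specB = CohortSpec(
        name="cohortB",
        n=3113,
        snps=_snp_list(188),
        env_factors=all_env,
        clusters=[cluster],
        effects=list(effects),
        baseline=dict(_BASELINE_B),
        seed=seed,
    )
    return specA, specB


def default_cohort_pair(seed: int = 0):
    """Simulate the default scenario; returns (cohortA, cohortB, manifest)."""
    specA, specB = default_pair_specs(seed)
    return simulate_cohort_pair(specA, specB, seed=seed)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
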