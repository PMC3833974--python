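"""Orchestration of the two analysis designs and the randomization validation.

The *gene-gene* design runs the feature-selection + rule-induction chain on
the SNPs shared between two cohorts, once per phenotype per cohort (22
models), validating each model's Bonferroni-significant rules by effect
direction in the other cohort. The *gene-environment* design runs on one
cohort's full genetic + exposure data (11 models), validating every rule
whose factors are also measured in the other cohort. The randomization
validation re-runs the feature selection on column-permuted data alone and
on original + permuted data combined.

Published summaries of the two original analyses ship with the package as
transcribed TSVs; ``summary_report`` reproduces their printed per-column
averages from the row values.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from ._seeds import substream
from .dtable import DecisionTable
from .mcfs import MCFSParams, mcfs_null_validation, mcfs_significance
from .phenoderive import PHENOTYPES
from .ruleinduce import cross_validate, induce_rules
from .rulestats import score_rules, validate_rule_external
from .synthcohort import SyntheticCohort

log = logging.getLogger(__name__)


@dataclass
class ModelReport:
    """One row of a per-phenotype analysis summary."""

    phenotype: str
    cohort: str
    n_factors_significant: int
    cv_coverage: float  # percent
    cv_accuracy: float  # percent
    n_rules: int
    n_validatable_rules: int
    n_validated_rules: int

    def __post_init__(self) -> None:
        if not (
            self.n_validated_rules <= self.n_validatable_rules <= max(self.n_rules, self.n_validatable_rules)
        ):
            raise ValueError("validated <= validatable <= rules must hold")


@dataclass
class PipelineConfig:
    """Settings for every stage, serializable to/from YAML."""

    mcfs: MCFSParams = field(default_factory=MCFSParams)
    min_support: int = 5
    min_accuracy: float = 0.6
    cover_fraction: float = 0.9
    balance: bool = True
    cv_folds: int = 10
    rule_alpha: float = 0.05
    phenotypes: tuple = PHENOTYPES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcfs = MCFSParams(**raw.pop("mcfs", {}))
        return cls(mcfs=mcfs, **raw)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["phenotypes"] = list(self.phenotypes)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class ModelArtifacts:
    report: ModelReport
    ri_result: object = None
    model: object = None
    rule_stats: pd.DataFrame | None = None
    validations: list = field(default_factory=list)


def _empty_report(phenotype: str, cohort: str, n_factors: int = 0) -> ModelReport:
    return ModelReport(phenotype, cohort, n_factors, 0.0, 0.0, 0, 0, 0)


def analyze_model(
    table: DecisionTable,
    other_table: DecisionTable | None,
    config: PipelineConfig,
    phenotype: str,
    cohort: str,
    validate_significant_only: bool,
    seed: int,
) -> ModelArtifacts:
    """One phenotype/cohort model: feature selection, rules, CV, validation."""
    counts = table.classified().class_counts()
    if min(counts.values()) < max(10, config.cv_folds):
        log.warning("%s/%s: too few objects per class (%s); skipping", cohort, phenotype, counts)
        return ModelArtifacts(report=_empty_report(phenotype, cohort))
    params = replace(config.mcfs, seed=int(substream(seed, cohort, phenotype).integers(2**31 - 1)))
    ri = mcfs_significance(table, params)
    significant = sorted(ri.significant or ())
    if not significant:
        return ModelArtifacts(report=_empty_report(phenotype, cohort), ri_result=ri)
    sub = table.restrict(significant)
    rule_kwargs = dict(
        min_support=config.min_support,
        min_accuracy=config.min_accuracy,
        cover_fraction=config.cover_fraction,
        balance=config.balance,
    )
    model = induce_rules(sub, seed=params.seed, **rule_kwargs)
    cv = cross_validate(sub, k=config.cv_folds, seed=params.seed, **rule_kwargs)
    stats = score_rules(model.rules, sub)
    validations = []
    n_validatable = n_validated = 0
    if other_table is not None and model.rules:
        if validate_significant_only:
            candidates = [r for r in model.rules if (r.p_adjusted or 1.0) < config.rule_alpha]
        else:
            candidates = list(model.rules)
        for r in candidates:
            v = validate_rule_external(r, other_table)
            validations.append(v)
            if v.validatable:
                n_validatable += 1
                if v.direction_match:
                    n_validated += 1
    report = ModelReport(
        phenotype=phenotype,
        cohort=cohort,
        n_factors_significant=len(significant),
        cv_coverage=100.0 * cv.coverage,
        cv_accuracy=100.0 * (cv.accuracy if np.isfinite(cv.accuracy) else 0.0),
        n_rules=len(model.rules),
        n_validatable_rules=n_validatable,
        n_validated_rules=n_validated,
    )
    return ModelArtifacts(report, ri_result=ri, model=model, rule_stats=stats,
                          validations=validations)


def run_gene_gene(
    cohortA: SyntheticCohort,
    cohortB: SyntheticCohort,
    config: PipelineConfig,
    shared: list[str] | None = None,
) -> list[ModelArtifacts]:
    """Gene-gene design on the shared SNPs: one model per phenotype per cohort.

    Bonferroni-significant rules are validated by direction in the other
    cohort.
    """
    if shared is None:
        snpsA = {a.name for a in cohortA.attributes if a.kind == "snp"}
        snpsB = {a.name for a in cohortB.attributes if a.kind == "snp"}
        shared = sorted(snpsA & snpsB)
    if not shared:
        raise ValueError("no shared SNPs between the cohorts")
    out: list[ModelArtifacts] = []
    for ph in config.phenotypes:
        for cohort, other in ((cohortA, cohortB), (cohortB, cohortA)):
            if ph not in cohort.phenotypes.columns:
                log.warning("phenotype %s absent in %s; skipped", ph, cohort.name)
                continue
            table = cohort.decision_table(ph).restrict(shared)
            other_table = other.decision_table(ph).restrict(shared) if ph in other.phenotypes else None
            out.append(
                analyze_model(
                    table, other_table, config, ph, cohort.name,
                    validate_significant_only=True, seed=config.seed,
                )
            )
    return out


def run_gene_env(
    cohortB: SyntheticCohort,
    cohortA_for_validation: SyntheticCohort | None,
    config: PipelineConfig,
) -> list[ModelArtifacts]:
    """Gene-environment design on one cohort's full data (11 models).

    Every rule whose factors exist in the validation cohort is checked there
    by direction.
    """
    env = [a for a in cohortB.attributes if a.kind != "snp"]
    if not env:
        raise ValueError("cohort has no environment/lifestyle attributes")
    out: list[ModelArtifacts] = []
    for ph in config.phenotypes:
        table = cohortB.decision_table(ph)
        other_table = (
            cohortA_for_validation.decision_table(ph)
            if cohortA_for_validation is not None and ph in cohortA_for_validation.phenotypes
            else None
        )
        out.append(
            analyze_model(
                table, other_table, config, ph, cohortB.name,
                validate_significant_only=False, seed=config.seed,
            )
        )
    return out


def run_mcfs_validation(
    cohort: SyntheticCohort,
    config: PipelineConfig,
    phenotypes: tuple | None = None,
) -> pd.DataFrame:
    """Randomization validation of the feature selection, per phenotype."""
    frames = []
    for ph in phenotypes or config.phenotypes:
        params = replace(
            config.mcfs, seed=int(substream(config.seed, "nullval", ph).integers(2**31 - 1))
        )
        rep = mcfs_null_validation(cohort.decision_table(ph), params)
        rep.insert(0, "phenotype", ph)
        frames.append(rep)
    return pd.concat(frames, ignore_index=True)


# -- summary arithmetic ----------------------------------------------------

def reports_frame(artifacts: list[ModelArtifacts] | list[ModelReport]) -> pd.DataFrame:
    reports = [a.report if isinstance(a, ModelArtifacts) else a for a in artifacts]
    return pd.DataFrame(
        {
            "outcome": [r.phenotype for r in reports],
            "material": [r.cohort for r in reports],
            "factors": [r.n_factors_significant for r in reports],
            "coverage_pct": [r.cv_coverage for r in reports],
            "accuracy_pct": [r.cv_accuracy for r in reports],
            "rules": [r.n_rules for r in reports],
            "val_rules": [r.n_validatable_rules for r in reports],
            "valid": [r.n_validated_rules for r in reports],
        }
    )


def summary_report(reports) -> pd.DataFrame:
    """Append an ``Average`` row of per-column means, printed to 1 decimal."""
    df = reports if isinstance(reports, pd.DataFrame) else reports_frame(reports)
    if df.empty:
        raise ValueError("need at least one report")
    numeric = df.select_dtypes("number")
    avg = {c: round(float(numeric[c].mean()), 1) for c in numeric.columns}
    label_col = df.columns[0]
    avg[label_col] = "Average"
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def load_published_summary(which: str) -> pd.DataFrame:
    """Transcribed published per-phenotype summaries ('gene_gene' or 'gene_env')."""
    fname = {"gene_gene": "gene_gene_summary.tsv", "gene_env": "gene_env_summary.tsv"}[which]
    with resources.files("allerules").joinpath("data", fname).open() as fh:
        return pd.read_csv(fh, sep="\t")
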