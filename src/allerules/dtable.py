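"""Decision tables: the categorical data model shared by every pipeline stage.

A decision table holds objects (children) in rows and categorical condition
attributes in columns -- SNP genotypes coded as copies of the cohort's major
allele (0/1/2), environment and lifestyle factors as category codes -- plus a
binary decision (``affected``/``unaffected``). Children outside a phenotype's
reference group are marked ``EXCLUDED``: they stay in the files but are
dropped from every computation. Missing cells never match a rule condition
and never discern two objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from ._seeds import substream

log = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
AFFECTED = "affected"
UNAFFECTED = "unaffected"
EXCLUDED = "EXCLUDED"
CLASSES = (AFFECTED, UNAFFECTED)

SNP_DOMAIN = ("0", "1", "2")


@dataclass(frozen=True)
class Attribute:
    """A categorical condition attribute and its coding.

    ``domain`` is the ordered list of legal category codes; for SNPs these are
    "0"/"1"/"2" copies of the major allele. ``labels`` optionally maps codes to
    display strings (e.g. "2" -> "GG"), ``short_code`` is the one-letter node
    code used in rule-network figures (e.g. "V").
    """

    name: str
    kind: str = "snp"  # snp | environment | lifestyle | covariate
    domain: tuple[str, ...] = SNP_DOMAIN
    labels: dict[str, str] | None = None
    short_code: str | None = None

    def __post_init__(self) -> None:
        if not self.domain:
            raise ValueError(f"attribute {self.name!r}: empty domain")
        if len(set(self.domain)) != len(self.domain):
            raise ValueError(f"attribute {self.name!r}: duplicate category codes")
        if self.kind == "snp" and not set(self.domain) <= set(SNP_DOMAIN):
            raise ValueError(f"SNP attribute {self.name!r}: domain must be within 0/1/2")
        object.__setattr__(self, "domain", tuple(str(c) for c in self.domain))

    def label(self, code: str) -> str | None:
        return (self.labels or {}).get(code)


@dataclass
class DecisionTable:
    """Objects x categorical attributes plus a binary decision column.

    ``data`` holds category codes as strings with NaN for missing; ``decision``
    holds affected/unaffected/EXCLUDED per object. Only non-EXCLUDED objects
    take part in any computation.
    """

    data: pd.DataFrame
    attributes: list[Attribute]
    decision: pd.Series
    decision_name: str = "decision"
    n_warnings: int = 0

    def __post_init__(self) -> None:
        if not self.attributes:
            raise ValueError("a decision table needs at least one attribute")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate attribute names")
        if list(self.data.columns) != names:
            self.data = self.data.reindex(columns=names)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate object ids")
        self.decision = self.decision.reindex(self.data.index)
        bad = set(self.decision.dropna().unique()) - {AFFECTED, UNAFFECTED, EXCLUDED}
        if bad:
            raise ValueError(f"illegal decision values: {sorted(bad)}")
        self.decision = self.decision.fillna(EXCLUDED)

    # -- basic views ------------------------------------------------------
    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]

    @property
    def n_total(self) -> int:
        return len(self.data)

    def attribute(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def classified(self) -> "DecisionTable":
        """The sub-table of objects with a decision class (EXCLUDED dropped)."""
        keep = self.decision.isin(CLASSES)
        return DecisionTable(
            self.data.loc[keep].copy(),
            list(self.attributes),
            self.decision.loc[keep].copy(),
            self.decision_name,
        )

    def class_counts(self) -> dict[str, int]:
        vc = self.decision.value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}

    def restrict(self, attribute_names: list[str]) -> "DecisionTable":
        """Keep only the named attributes (order follows the argument)."""
        keep = [self.attribute(n) for n in attribute_names]
        return DecisionTable(
            self.data[attribute_names].copy(), keep, self.decision.copy(), self.decision_name
        )

    def subset(self, object_ids) -> "DecisionTable":
        return DecisionTable(
            self.data.loc[object_ids].copy(),
            list(self.attributes),
            self.decision.loc[object_ids].copy(),
            self.decision_name,
        )

    # -- integer encoding used by mcfs / ruleinduce -----------------------
    def encode(self) -> "EncodedTable":
        """Encode classified objects as an int matrix (missing = -1).

        Attribute columns are sorted by name and objects by id so that every
        downstream computation is invariant to input order.
        """
        sub = self.classified()
        attrs = sorted(sub.attributes, key=lambda a: a.name)
        order = sorted(sub.data.index)
        X = np.full((len(order), len(attrs)), -1, dtype=np.int8)
        data = sub.data.loc[order]
        for j, a in enumerate(attrs):
            col = data[a.name]
            codes = {c: i for i, c in enumerate(a.domain)}
            X[:, j] = col.map(codes).fillna(-1).to_numpy(dtype=np.int8)
        y = (sub.decision.loc[order] == AFFECTED).to_numpy(dtype=np.int8)
        return EncodedTable(
            X=X,
            y=y,
            attributes=attrs,
            object_ids=list(order),
            n_categories=np.array([len(a.domain) for a in attrs], dtype=np.int64),
        )


@dataclass
class EncodedTable:
    """Integer view of a classified decision table (missing cells = -1)."""

    X: np.ndarray
    y: np.ndarray
    attributes: list[Attribute]
    object_ids: list
    n_categories: np.ndarray

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]


@dataclass
class FoldAssignment:
    """A stratified k-fold partition of the classified objects."""

    k: int
    membership: dict
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [o for o, f in self.membership.items() if f == fold]


# -- TSV round trip -------------------------------------------------------

def read_table(
    path,
    schema: list[Attribute] | None = None,
    decision_col: str = "decision",
) -> DecisionTable:
    """Read a decision table from TSV (header row, first column ``id``).

    Cells are validated against each attribute's domain; out-of-domain or
    unparseable cells become missing and are counted in ``n_warnings``. Without
    a schema, domains are inferred from the observed codes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING_TOKEN], keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError("TSV must have an 'id' first column")
    if decision_col not in df.columns:
        raise ValueError(f"missing decision column {decision_col!r}")
    if df["id"].duplicated().any():
        raise ValueError("duplicate object ids")
    df = df.set_index("id")
    decision = df.pop(decision_col)
    if schema is None:
        schema = [
            Attribute(name=c, kind="environment", domain=tuple(sorted(df[c].dropna().unique())) or ("0",))
            for c in df.columns
        ]
    by_name = {a.name: a for a in schema}
    missing_cols = [c for c in df.columns if c not in by_name]
    if missing_cols:
        raise ValueError(f"columns without schema entry: {missing_cols}")
    attrs = [by_name[c] for c in df.columns]
    n_warnings = 0
    for a in attrs:
        col = df[a.name]
        bad = col.notna() & ~col.isin(a.domain)
        n_bad = int(bad.sum())
        if n_bad:
            n_warnings += n_bad
            df.loc[bad, a.name] = np.nan
            log.warning("%s: %d out-of-domain cells set to missing", a.name, n_bad)
    return DecisionTable(df, attrs, decision, decision_name=decision_col, n_warnings=n_warnings)


def write_table(table: DecisionTable, path) -> None:
    """Write a decision table as TSV (missing cells as ``NA``)."""
    out = table.data.copy()
    out[table.decision_name] = table.decision
    out.index.name = "id"
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def read_schema(path) -> list[Attribute]:
    """Read attribute metadata from YAML (name, kind, domain, labels, short_code)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    attrs = []
    for entry in raw:
        attrs.append(
            Attribute(
                name=entry["name"],
                kind=entry.get("kind", "snp"),
                domain=tuple(str(c) for c in entry["domain"]),
                labels={str(k): v for k, v in entry.get("labels", {}).items()} or None,
                short_code=entry.get("short_code"),
            )
        )
    return attrs


# -- VCF ingestion --------------------------------------------------------

def read_vcf_genotypes(path) -> pd.DataFrame:
    """Read biallelic GT fields from a VCF into major-allele-count coding.

    Per site the major allele is the allele with the higher observed sample
    frequency (tie -> REF); each genotype becomes the number of major-allele
    copies ("0"/"1"/"2"); ``./.`` and malformed genotypes become missing.
    Multiallelic records are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, list] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning("skipping multiallelic record %s", var.ID or var.POS)
            continue
        name = var.ID or f"{var.CHROM}_{var.POS}"
        alt_copies = np.full(len(samples), -1, dtype=int)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a in (0, 1)]
            if len(alleles) == 2:
                alt_copies[i] = sum(alleles)
        called = alt_copies >= 0
        n_alleles = 2 * int(called.sum())
        alt_freq = alt_copies[called].sum() / n_alleles if n_alleles else 0.0
        major_is_ref = alt_freq <= 0.5  # tie -> REF
        major = np.where(major_is_ref, 2 - alt_copies, alt_copies)
        columns[name] = [str(int(m)) if ok else np.nan for m, ok in zip(major, called)]
    return pd.DataFrame(columns, index=pd.Index(samples, name="id"))


# -- fold splitting and column randomization ------------------------------

def stratified_folds(table: DecisionTable, k: int, seed: int) -> FoldAssignment:
    """Stratified k-fold partition of the non-EXCLUDED objects.

    Per-fold class counts deviate from exact proportionality by at most one
    object. Fails if either class has fewer than k members.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sub = table.classified()
    counts = sub.class_counts()
    for cls, n in counts.items():
        if n < k:
            raise ValueError(f"class {cls!r} has {n} objects, fewer than k={k}")
    ids = np.array(sorted(sub.data.index), dtype=object)
    y = (sub.decision.loc[ids] == AFFECTED).to_numpy(dtype=int)
    rs = int(substream(seed, "folds").integers(0, 2**31 - 1))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
    membership: dict = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(ids), 1)), y)):
        for i in test_idx:
            membership[ids[i]] = fold
    return FoldAssignment(k=k, membership=membership, seed=seed)


def permute_columns(table: DecisionTable, seed: int) -> DecisionTable:
    """Independently permute every attribute column over objects.

    Category counts per column are preserved and the decision is untouched;
    this is the randomized-data construction used to validate the feature
    selection against non-informative factors.
    """
    data = table.data.copy()
    for name in table.attribute_names:
        rng = substream(seed, "permute", name)
        data[name] = rng.permutation(data[name].to_numpy())
    return DecisionTable(data, list(table.attributes), table.decision.copy(), table.decision_name)
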