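"""Rough-set rule induction in the ROSETTA style.

Per training object, the discernibility clauses against every opposite-class
object are covered greedily (Johnson set-cover heuristic) to obtain an
object-related reduct; the object's values on the reduct attributes become the
left-hand side of an IF-THEN rule predicting its class. Classification is by
support-weighted voting over the rules an object satisfies, with abstention
when no rule fires.

Two pragmatic defaults tailor the classical machinery to case-control cohort
tables: (i) indiscernible opposite-class pairs (boundary region) drop out of
the clause set instead of invalidating the object, so rules on heavily
inconsistent tables simply have accuracy < 1; (ii) the Johnson cover may stop
once a fraction of the clauses is covered (``cover_fraction``), giving the
short, high-support rules characteristic of ROSETTA's approximate reducers.
Induction optionally balances classes by undersampling, which keeps rule
accuracies comparable between a rare "affected" class and its reference.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import substream
from .dtable import AFFECTED, UNAFFECTED, Attribute, DecisionTable, stratified_folds

log = logging.getLogger(__name__)

ABSTAIN = "ABSTAIN"


@dataclass
class Rule:
    """An IF-THEN rule: a conjunction of attribute=category conditions."""

    conditions: tuple[tuple[str, str], ...]
    decision: str
    support: int = 0
    lhs_matches: int = 0
    accuracy: float = 0.0
    class_coverage: float = 0.0
    id: int = 0
    p_value: float | None = None
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a rule needs at least one condition")
        names = [a for a, _ in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("rule conditions must use distinct attributes")
        self.conditions = tuple((str(a), str(c)) for a, c in self.conditions)

    def matches(self, values) -> bool:
        """True iff every condition is met; missing values never match."""
        for attr, code in self.conditions:
            v = values.get(attr) if hasattr(values, "get") else values[attr]
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) != code:
                return False
        return True

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.conditions)


@dataclass
class RuleModel:
    rules: list[Rule]
    class_priors: dict[str, float]
    filters: dict = field(default_factory=dict)


@dataclass
class CVResult:
    """Cross-validated model quality: coverage, accuracy, mean rule count."""

    coverage: float
    accuracy: float
    mean_n_rules: float
    fold_stats: pd.DataFrame | None = None


# -- discernibility and reducts -------------------------------------------

def discernibility_clauses(table: DecisionTable, object_id) -> list[frozenset]:
    """One clause per opposite-class object: the attributes where both values
    are non-missing and differ. An empty clause marks an indiscernible pair
    (inconsistency)."""
    sub = table.classified()
    if object_id not in sub.data.index:
        raise KeyError(f"object {object_id!r} has no decision class")
    cls = sub.decision.loc[object_id]
    row = sub.data.loc[object_id]
    opposite = sub.data.loc[sub.decision != cls]
    clauses = []
    for _, other in opposite.iterrows():
        differ = frozenset(
            a
            for a in sub.attribute_names
            if pd.notna(row[a]) and pd.notna(other[a]) and row[a] != other[a]
        )
        if not differ:
            log.warning("object %r indiscernible from an opposite-class object", object_id)
        clauses.append(differ)
    return clauses


def _greedy_cover(D: np.ndarray, w: np.ndarray, fraction: float) -> list[int]:
    """Weighted Johnson cover over a clause-by-attribute incidence matrix.

    Picks the attribute covering the largest uncovered clause weight (ties go
    to the lowest column index) until ``fraction`` of the total weight is
    covered. Columns must be sorted by attribute name for lexicographic ties.
    """
    total = float(w.sum())
    target = total if fraction >= 1.0 else fraction * total
    uncovered = np.ones(len(w), dtype=bool)
    covered = 0.0
    chosen: list[int] = []
    while covered < target - 1e-9 and uncovered.any():
        scores = D[uncovered].astype(np.int64).T @ w[uncovered]
        j = int(np.argmax(scores))
        if scores[j] <= 0:
            break
        chosen.append(j)
        covered += float(scores[j])
        uncovered &= ~D[:, j]
    return chosen


def johnson_reduct(clauses, cover_fraction: float = 1.0) -> set:
    """Greedy hitting set of the given clauses (sets of attribute names).

    Raises on an empty clause (inconsistent object). With no clauses at all
    the empty set is returned.
    """
    clauses = [frozenset(c) for c in clauses]
    for c in clauses:
        if not c:
            raise ValueError("empty discernibility clause: inconsistent object")
    if not clauses:
        return set()
    attrs = sorted(set().union(*clauses))
    idx = {a: j for j, a in enumerate(attrs)}
    D = np.zeros((len(clauses), len(attrs)), dtype=bool)
    for i, c in enumerate(clauses):
        for a in c:
            D[i, idx[a]] = True
    chosen = _greedy_cover(D, np.ones(len(clauses), dtype=np.int64), cover_fraction)
    return {attrs[j] for j in chosen}


def brute_force_reducts(table: DecisionTable, object_id) -> list[frozenset]:
    """All minimal attribute sets covering the object's clauses (test oracle).

    Exhaustive over subsets; limited to tables with at most 12 attributes.
    """
    if len(table.attributes) > 12:
        raise ValueError("brute force is limited to d <= 12 attributes")
    clauses = [c for c in discernibility_clauses(table, object_id)]
    for c in clauses:
        if not c:
            raise ValueError("empty discernibility clause: inconsistent object")
    if not clauses:
        return [frozenset()]
    universe = sorted(set().union(*clauses))
    covers = []
    for r in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, r):
            s = frozenset(combo)
            if all(c & s for c in clauses):
                covers.append(s)
    return [s for s in covers if not any(o < s for o in covers)]


# -- rule induction --------------------------------------------------------

def induce_rules(
    table: DecisionTable,
    min_support: int = 5,
    min_accuracy: float = 0.6,
    cover_fraction: float = 0.9,
    balance: bool = True,
    inconsistent: str = "boundary",
    seed: int = 0,
) -> RuleModel:
    """Induce IF-THEN rules from per-object Johnson reducts.

    ``inconsistent`` chooses how indiscernible opposite-class pairs are
    handled: "boundary" drops the empty clauses (rule accuracy < 1), "skip"
    drops the offending objects entirely. ``balance`` undersamples the
    majority class (seeded) before induction; rule statistics refer to the
    induction table.
    """
    if inconsistent not in ("boundary", "skip"):
        raise ValueError("inconsistent must be 'boundary' or 'skip'")
    enc = table.classified().encode()
    X, y = enc.X, enc.y
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("rule induction needs both classes")
    priors = {AFFECTED: n1 / len(y), UNAFFECTED: n0 / len(y)}
    if balance and n0 != n1:
        rng = substream(seed, "balance")
        minority = 1 if n1 < n0 else 0
        keep = np.concatenate(
            [
                np.nonzero(y == minority)[0],
                rng.choice(np.nonzero(y == 1 - minority)[0], size=min(n0, n1), replace=False),
            ]
        )
        keep.sort()
        X, y = X[keep], y[keep]

    names = enc.names
    rules: dict[tuple, int] = {}
    n_skipped = 0
    for cls in (1, 0):
        own = X[y == cls]
        opp = X[y != cls]
        profiles, _ = np.unique(own, axis=0, return_counts=True)
        opp_profiles, opp_w = np.unique(opp, axis=0, return_counts=True)
        for p in profiles:
            if opp_profiles.size:
                D = (opp_profiles != p[None, :]) & (opp_profiles != -1) & (p[None, :] != -1)
                nonempty = D.any(axis=1)
                if (~nonempty).any():
                    if inconsistent == "skip":
                        n_skipped += 1
                        continue
                D = D[nonempty]
                w = opp_w[nonempty]
            else:
                D = np.zeros((0, len(names)), dtype=bool)
                w = np.zeros(0, dtype=np.int64)
            if D.shape[0] == 0:
                cols = [j for j in range(len(names)) if p[j] != -1]
            else:
                cols = _greedy_cover(D, w.astype(np.int64), cover_fraction)
            conditions = tuple(
                sorted((names[j], enc.attributes[j].domain[p[j]]) for j in cols if p[j] != -1)
            )
            if not conditions:
                n_skipped += 1
                continue
            rules.setdefault((conditions, cls), 0)
    if n_skipped:
        log.info("skipped %d object profiles (inconsistent or conditionless)", n_skipped)

    # statistics on the induction table; duplicates merged by construction
    out: list[Rule] = []
    col_of = {a: j for j, a in enumerate(names)}
    dom_of = {a.name: {c: i for i, c in enumerate(a.domain)} for a in enc.attributes}
    class_sizes = {1: int((y == 1).sum()), 0: int((y == 0).sum())}
    for conditions, cls in sorted(rules, key=lambda k: (k[0], -k[1])):
        mask = np.ones(len(y), dtype=bool)
        for attr, code in conditions:
            mask &= X[:, col_of[attr]] == dom_of[attr][code]
        lhs = int(mask.sum())
        support = int((mask & (y == cls)).sum())
        if lhs == 0 or support == 0:
            continue
        accuracy = support / lhs
        if support < min_support or accuracy < min_accuracy:
            continue
        out.append(
            Rule(
                conditions=conditions,
                decision=AFFECTED if cls == 1 else UNAFFECTED,
                support=support,
                lhs_matches=lhs,
                accuracy=accuracy,
                class_coverage=support / class_sizes[cls],
                id=len(out) + 1,
            )
        )
    return RuleModel(
        rules=out,
        class_priors=priors,
        filters={
            "min_support": min_support,
            "min_accuracy": min_accuracy,
            "cover_fraction": cover_fraction,
            "balance": balance,
        },
    )


# -- classification --------------------------------------------------------

def _vote(votes: dict[str, float], priors: dict[str, float]) -> str:
    if not votes or max(votes.values()) <= 0:
        return ABSTAIN
    best = max(votes.values())
    tied = sorted([c for c, v in votes.items() if v == best])
    if len(tied) == 1:
        return tied[0]
    winner = max(tied, key=lambda c: (priors.get(c, 0.0), c == AFFECTED))
    log.debug("vote tie %s resolved to %s by class prior", tied, winner)
    return winner


def classify(model: RuleModel, values) -> str:
    """Classify one object (mapping attribute -> code) by support voting."""
    votes: dict[str, float] = {}
    for r in model.rules:
        if r.matches(values):
            votes[r.decision] = votes.get(r.decision, 0.0) + r.support
    return _vote(votes, model.class_priors)


def classify_table(model: RuleModel, table: DecisionTable) -> pd.Series:
    """Vectorized voting over all classified objects of a table."""
    sub = table.classified()
    df = sub.data
    votes = {AFFECTED: np.zeros(len(df)), UNAFFECTED: np.zeros(len(df))}
    present = set(sub.attribute_names)
    for r in model.rules:
        if not set(r.attribute_names) <= present:
            continue
        mask = np.ones(len(df), dtype=bool)
        for attr, code in r.conditions:
            mask &= (df[attr] == code).to_numpy()
        votes[r.decision] += mask * r.support
    out = []
    for i in range(len(df)):
        out.append(_vote({c: votes[c][i] for c in votes if votes[c][i] > 0}, model.class_priors))
    return pd.Series(out, index=df.index)


def cross_validate(
    table: DecisionTable, k: int = 10, seed: int = 0, **induce_kwargs
) -> CVResult:
    """k-fold cross-validated model coverage and accuracy.

    Coverage is the fraction of held-out objects any rule fires on; accuracy
    is the fraction correct among those (abstentions excluded). Folds whose
    training part lacks a class are skipped with a warning.
    """
    sub = table.classified()
    folds = stratified_folds(sub, k, seed)
    rows = []
    for fold in range(k):
        test_ids = folds.fold_ids(fold)
        train_ids = [o for o in sub.data.index if folds.membership[o] != fold]
        train = sub.subset(train_ids)
        counts = train.class_counts()
        if min(counts.values()) == 0:
            log.warning("fold %d skipped: training part has a single class", fold)
            continue
        model = induce_rules(train, seed=seed, **induce_kwargs)
        test = sub.subset(test_ids)
        pred = classify_table(model, test)
        truth = test.decision
        fired = pred != ABSTAIN
        n_fired = int(fired.sum())
        coverage = n_fired / len(test_ids)
        accuracy = float((pred[fired] == truth[fired]).mean()) if n_fired else np.nan
        rows.append(
            {
                "fold": fold,
                "coverage": coverage,
                "accuracy": accuracy,
                "n_rules": len(model.rules),
            }
        )
    stats = pd.DataFrame(rows)
    if stats.empty:
        return CVResult(0.0, np.nan, 0.0, stats)
    return CVResult(
        coverage=float(stats["coverage"].mean()),
        accuracy=float(stats["accuracy"].mean(skipna=True)),
        mean_n_rules=float(stats["n_rules"].mean()),
        fold_stats=stats,
    )


# -- serialization ---------------------------------------------------------

_COND_RE = re.compile(r"^([^=\[\]\s]+)=([^=\[\]\s]+?)(?:\[([^\]]*)\])?$")


def rule_to_string(
    rule: Rule,
    attributes: list[Attribute] | None = None,
    phenotype: str = "decision",
) -> str:
    """Serialize a rule as ``IF a=0[label] AND b=1 THEN phenotype=class``."""
    by_name = {a.name: a for a in attributes or []}
    parts = []
    for attr, code in rule.conditions:
        label = by_name[attr].label(code) if attr in by_name else None
        parts.append(f"{attr}={code}[{label}]" if label else f"{attr}={code}")
    return f"IF {' AND '.join(parts)} THEN {phenotype}={rule.decision}"


def parse_rule(text: str, schema: list[Attribute] | None = None) -> tuple[Rule, str]:
    """Parse a rule string; returns (rule, phenotype name).

    A bare ``THEN phenotype`` (no ``=class``) is read as predicting
    ``affected``. Malformed text raises ValueError with the failing position.
    """
    m = re.match(r"^\s*IF\s+(.+?)\s+THEN\s+(.+?)\s*$", text)
    if not m:
        raise ValueError(f"not an IF-THEN rule (at position 0): {text!r}")
    conds = []
    for raw in re.split(r"\s+AND\s+", m.group(1)):
        cm = _COND_RE.match(raw.strip())
        if not cm:
            raise ValueError(f"malformed condition at position {text.find(raw)}: {raw!r}")
        conds.append((cm.group(1), cm.group(2)))
    target = m.group(2).strip()
    if "=" in target:
        phenotype, _, decision = target.rpartition("=")
        phenotype = phenotype.strip()
        decision = decision.strip()
        if decision not in (AFFECTED, UNAFFECTED):
            raise ValueError(
                f"unknown decision class at position {text.find(decision)}: {decision!r}"
            )
    else:
        phenotype, decision = target, AFFECTED
    if schema is not None:
        by_name = {a.name: a for a in schema}
        for attr, code in conds:
            if attr not in by_name:
                raise ValueError(f"unknown attribute {attr!r}")
            if code not in by_name[attr].domain:
                raise ValueError(f"code {code!r} outside the domain of {attr!r}")
    return Rule(conditions=tuple(conds), decision=decision, support=1, lhs_matches=1,
                accuracy=1.0), phenotype
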