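"""Rule-level statistics.

Each rule is scored on a cohort by an exact upper-tail hypergeometric test
(is the rule's class over-represented among the children matching its
left-hand side?), Bonferroni-corrected within the rule family of its model.
Effect sizes are crude odds ratios for fulfilling *all* conditions of a rule
versus all other children, with 95% confidence intervals from either the
Woolf (log) method on the 2x2 table or a single-predictor logistic fit (Wald).
Cross-cohort validation is direction-only: an affected-rule replicates when
its odds ratio in the other cohort exceeds 1, an unaffected-rule when it is
below 1. Dose-response stratifies children by the number of rule conditions
they fulfil.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dtable import AFFECTED, DecisionTable
from .ruleinduce import Rule

log = logging.getLogger(__name__)

Z95 = 1.96


@dataclass
class HypergeomTest:
    """Exact upper-tail hypergeometric probability for a rule.

    N classified objects, K in the rule's class, n matching the LHS, k of
    those in the rule's class; p = P(X >= k).
    """

    N: int
    K: int
    n: int
    k: int
    p: float
    p_adj: float | None = None


@dataclass
class ORResult:
    """Odds ratio with a 95% confidence interval."""

    or_estimate: float
    ci_low: float
    ci_high: float
    method: str  # woolf | logistic_wald
    a: int | None = None
    b: int | None = None
    c: int | None = None
    d: int | None = None
    correction_applied: bool = False


@dataclass
class ValidationResult:
    rule_id: int
    validatable: bool
    direction_match: bool | None = None
    other_or: ORResult | None = None


def rule_pvalue(rule: Rule, table: DecisionTable) -> HypergeomTest:
    """Hypergeometric enrichment of the rule's class among its LHS matches.

    Children missing a value on any condition attribute are excluded from the
    draw (they can neither match nor serve as reference for that rule).
    """
    sub = table.classified()
    mask, nonmissing = _exposure(rule, sub)
    y = (sub.decision == AFFECTED).to_numpy()
    affected_is_target = rule.decision == AFFECTED
    target = y if affected_is_target else ~y
    N = int(nonmissing.sum())
    K = int(target[nonmissing].sum())
    n = int(mask.sum())
    k = int((mask & target).sum())
    return HypergeomTest(N=N, K=K, n=n, k=k, p=hypergeom_sf(k, N, K, n))


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact via log-gamma."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K) + 1):
        raise ValueError(f"inconsistent margins N={N}, K={K}, n={n}, k={k}")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bonferroni(p_values, m: int) -> list[float]:
    """Family-wise correction: p -> min(1, m*p)."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError("family size m must be at least the number of tests")
    out = []
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p-value outside (0, 1]: {p}")
        out.append(min(1.0, m * p))
    return out


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> ORResult:
    """OR = ad/bc with a Woolf (log) 95% CI.

    Cells: a exposed-affected, b exposed-unaffected, c unexposed-affected,
    d unexposed-unaffected. Any zero cell triggers the Haldane-Anscombe
    +0.5 correction (flagged).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("2x2 counts must be non-negative")
    if a + c == 0 or b + d == 0:
        raise ValueError("a class margin is empty; odds ratio undefined")
    if a + b == 0 or c + d == 0:
        raise ValueError("an exposure margin is empty; odds ratio undefined")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5) for x in (a, b, c, d)) if corrected else (a, b, c, d)
    or_est = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return ORResult(
        or_estimate=float(or_est),
        ci_low=float(np.exp(np.log(or_est) - Z95 * se)),
        ci_high=float(np.exp(np.log(or_est) + Z95 * se)),
        method="woolf",
        a=a,
        b=b,
        c=c,
        d=d,
        correction_applied=corrected,
    )


def odds_ratio_logistic(y, exposure) -> ORResult:
    """Single-predictor logistic OR with a Wald 95% CI.

    Falls back to the corrected 2x2 when a cell is empty (separation) or the
    fit fails to converge; the fallback is flagged via ``method``/
    ``correction_applied``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(exposure, dtype=float)
    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    d = int(((x == 0) & (y == 0)).sum())
    if 0 in (a, b, c, d):
        log.info("empty 2x2 cell (a=%d b=%d c=%d d=%d): corrected Woolf fallback", a, b, c, d)
        res = odds_ratio_2x2(a, b, c, d)
        return res
    X = sm.add_constant(x)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False) or not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError("logistic fit did not converge")
        beta = float(fit.params[1])
        se = float(fit.bse[1])
    except Exception as exc:  # separation / singular designs
        log.warning("logistic fit failed (%s): corrected Woolf fallback", exc)
        return odds_ratio_2x2(a, b, c, d)
    return ORResult(
        or_estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        method="logistic_wald",
        a=a,
        b=b,
        c=c,
        d=d,
    )


def _exposure(rule: Rule, sub: DecisionTable) -> tuple[np.ndarray, np.ndarray]:
    """Boolean exposure (all conditions met) and the non-missing mask."""
    df = sub.data
    for attr, _ in rule.conditions:
        if attr not in df.columns:
            raise KeyError(f"rule attribute {attr!r} absent from the table")
    nonmissing = np.ones(len(df), dtype=bool)
    mask = np.ones(len(df), dtype=bool)
    for attr, code in rule.conditions:
        col = df[attr]
        nonmissing &= col.notna().to_numpy()
        mask &= (col == code).to_numpy()
    mask &= nonmissing
    return mask, nonmissing


def rule_or(rule: Rule, table: DecisionTable) -> ORResult:
    """Crude OR for fulfilling all rule conditions vs all other children.

    Children missing a value on any condition attribute are excluded from the
    2x2 entirely (logged), so the reference is not diluted by unknowns.
    """
    sub = table.classified()
    mask, nonmissing = _exposure(rule, sub)
    n_dropped = int((~nonmissing).sum())
    if n_dropped:
        log.debug("rule %d: %d children dropped for missing condition values", rule.id, n_dropped)
    y = (sub.decision == AFFECTED).to_numpy()[nonmissing]
    x = mask[nonmissing].astype(int)
    if x.sum() == 0:
        raise ValueError("no children fulfil the rule; odds ratio undefined")
    if x.sum() == len(x):
        raise ValueError("rule matches every child; no reference group")
    return odds_ratio_logistic(y, x)


def validate_rule_external(rule: Rule, other_table: DecisionTable) -> ValidationResult:
    """Direction-only replication of a rule in a second cohort.

    Validatable iff every condition's attribute exists in the other cohort and
    the condition's category is in its domain there. The rule replicates when
    the other-cohort OR lies on the side of 1 its decision class implies.
    """
    present = {a.name: a for a in other_table.attributes}
    validatable = all(
        attr in present and code in present[attr].domain for attr, code in rule.conditions
    )
    if not validatable:
        return ValidationResult(rule_id=rule.id, validatable=False)
    try:
        other = rule_or(rule, other_table)
    except ValueError as exc:
        log.warning("rule %d not validatable in other cohort: %s", rule.id, exc)
        return ValidationResult(rule_id=rule.id, validatable=False)
    if rule.decision == AFFECTED:
        match = other.or_estimate > 1.0
    else:
        match = other.or_estimate < 1.0
    return ValidationResult(rule_id=rule.id, validatable=True, direction_match=match,
                            other_or=other)


def dose_response(rule: Rule, table: DecisionTable) -> list[ORResult | None]:
    """OR per number of fulfilled conditions (0..L), each level vs level 0.

    Children missing a value on any condition attribute are excluded. Level 0
    is its own reference (OR 1); empty levels are reported as None.
    """
    L = len(rule.conditions)
    if L < 2:
        raise ValueError("dose-response needs a rule with at least 2 conditions")
    sub = table.classified()
    df = sub.data
    nonmissing = np.ones(len(df), dtype=bool)
    fulfilled = np.zeros(len(df), dtype=int)
    for attr, code in rule.conditions:
        col = df[attr]
        nonmissing &= col.notna().to_numpy()
        fulfilled += (col == code).to_numpy().astype(int)
    y = (sub.decision == AFFECTED).to_numpy()[nonmissing]
    fulfilled = fulfilled[nonmissing]
    base = fulfilled == 0
    out: list[ORResult | None] = []
    for level in range(L + 1):
        at = fulfilled == level
        if level == 0:
            out.append(
                ORResult(1.0, 1.0, 1.0, "reference", a=None, b=None,
                         c=int(y[base].sum()), d=int((~y[base]).sum()))
            )
            continue
        if not at.any() or not base.any():
            out.append(None)
            continue
        sel = at | base
        out.append(odds_ratio_logistic(y[sel], at[sel].astype(int)))
    return out


def score_rules(
    rules: list[Rule], table: DecisionTable, family_size: int | None = None
) -> pd.DataFrame:
    """Hypergeometric p and Bonferroni adjustment for a rule family.

    Annotates each rule in place (p_value, p_adjusted) and returns the table
    of test statistics. ``family_size`` defaults to the number of rules.
    """
    m = family_size if family_size is not None else len(rules)
    tests = [rule_pvalue(r, table) for r in rules]
    adj = bonferroni([t.p for t in tests], m) if tests else []
    rows = []
    for r, t, q in zip(rules, tests, adj):
        t.p_adj = q
        r.p_value = t.p
        r.p_adjusted = q
        rows.append(
            {"rule_id": r.id, "N": t.N, "K": t.K, "n": t.n, "k": t.k, "p": t.p, "p_adj": q}
        )
    return pd.DataFrame(rows)
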