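"""Three-stage rule screen: lift-increase pruning, significance, meaning.

1. **LIC pruning** — a rule with n+1 antecedent items must improve on its
   n-item base rules: LIC = Lift(X_{n+1} -> Y) / Lift(X_n -> Y) with
   X_n a subset of X_{n+1}.  Below the threshold (default 1.03) the added
   item buys no interest and the longer rule is redundant.  By default
   the improvement is required against *every* immediate sub-rule
   (strictest reading); ``mode="any"`` relaxes to at least one.
2. **Significance** — one-sided (positive-association) Fisher's exact
   test on the 2x2 contingency of antecedent presence vs consequent
   presence, Bonferroni-corrected over the rules entering this stage;
   keep p < alpha / m (default alpha 0.01).
3. **Meaningfulness** — a declarative blacklist removes tautological
   rules whose antecedent merely restates the consequent (e.g. an
   afternoon time band implying daylight, or a >80 km/h speed limit
   implying a freeway).  Matching is at category level with item-level
   overrides.

Stages run in this order and only ever remove rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml
from scipy.stats import hypergeom

from .catalog import FactorCatalog
from .mining import AssociationRule, rule_metrics
from .transactions import TransactionTable

#: category-level tautology pairs shipped by default, both directions.
DEFAULT_BLACKLIST: list[tuple[str, str]] = [
    ("Time", "Light condition"),
    ("Light condition", "Time"),
    ("Limit speed", "Road category"),
    ("Road category", "Limit speed"),
]


@dataclass
class FilterConfig:
    min_lic: float = 1.03
    lic_mode: str = "all"  # require LIC vs "all" immediate bases, or "any"
    alpha: float = 0.01
    correction: str = "bonferroni"  # or "none"
    blacklist: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_BLACKLIST)
    )

    def __post_init__(self) -> None:
        if self.min_lic <= 0:
            raise ValueError("min_lic must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lic_mode not in ("all", "any"):
            raise ValueError("lic_mode must be 'all' or 'any'")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")


@dataclass
class FilteredRule:
    """A candidate rule with its filter annotations."""

    rule: AssociationRule
    lic: float | None = None  # only defined for |lhs| >= 2
    p_value: float | None = None
    kept: bool = True
    rejection_reason: str = "none"  # lic | significance | meaningfulness | none

    def reject(self, reason: str) -> None:
        self.kept = False
        self.rejection_reason = reason


def lic(extended: AssociationRule, base: AssociationRule) -> float:
    """Lift ratio of an (n+1)-item rule over an n-item base rule."""
    if extended.rhs != base.rhs:
        raise ValueError("rules must share the same consequent")
    if not (base.lhs < extended.lhs and len(extended.lhs) == len(base.lhs) + 1):
        raise ValueError("base lhs must be an immediate subset of extended lhs")
    if base.lift <= 0:
        raise ZeroDivisionError("base rule has zero lift")
    return extended.lift / base.lift


def lic_filter(
    rules: list[AssociationRule],
    table: TransactionTable | None = None,
    min_lic: float = 1.03,
    mode: str = "all",
) -> list[FilteredRule]:
    """Annotate every rule; prune multi-item rules that fail the LIC test.

    Single-antecedent rules pass vacuously with ``lic`` undefined.  Base
    lifts are taken from the candidate list when present, otherwise
    recomputed from the table (base rules need not themselves meet the
    mining thresholds).  Under ``mode="all"`` the recorded LIC is the
    minimum over immediate bases (the binding comparison); under
    ``mode="any"`` the maximum.
    """
    by_key: dict[tuple, float] = {r.key: r.lift for r in rules}
    out: list[FilteredRule] = []
    for rule in rules:
        fr = FilteredRule(rule=rule)
        if len(rule.lhs) >= 2:
            ratios = []
            for drop in sorted(rule.lhs):
                base_lhs = frozenset(rule.lhs - {drop})
                key = (tuple(sorted(base_lhs)), rule.rhs)
                base_lift = by_key.get(key)
                if base_lift is None:
                    if table is None:
                        raise ValueError(
                            f"base rule {key} absent from candidates and no table given"
                        )
                    _, _, base_lift = rule_metrics(table, base_lhs, rule.rhs)
                if base_lift <= 0:
                    raise ZeroDivisionError("base rule has zero lift")
                ratios.append(rule.lift / base_lift)
            fr.lic = min(ratios) if mode == "all" else max(ratios)
            if fr.lic < min_lic:
                fr.reject("lic")
        out.append(fr)
    return out


def fisher_p(table: TransactionTable | None, rule: AssociationRule) -> float:
    """One-sided Fisher exact p for positive X-Y association.

    The 2x2 contingency (X&Y, X&!Y, !X&Y, !X&!Y) has fixed margins under
    the null of no association; the p-value is the upper hypergeometric
    tail P(a >= observed).  Degenerate margins (a row or column of the
    table empty) give p = 1 by convention.  Counts come from the table,
    or from the rule's own count annotations when no table is given.
    """
    if table is not None:
        n = table.n_records
        n_lhs = table.count(rule.lhs)
        n_rhs = table.count([rule.rhs])
        a = table.count(rule.lhs | {rule.rhs})
    elif rule.n_records:
        n, n_lhs, n_rhs, a = rule.n_records, rule.n_lhs, rule.n_rhs, rule.n_both
    else:
        raise ValueError("no table given and rule carries no counts")
    return fisher_p_counts(a, n_lhs, n_rhs, n)


def fisher_p_counts(a: int, n_lhs: int, n_rhs: int, n: int) -> float:
    """Upper-tail hypergeometric p from the four margin counts."""
    if n_lhs in (0, n) or n_rhs in (0, n):
        return 1.0
    return float(hypergeom.sf(a - 1, n, n_rhs, n_lhs))


def significance_filter(
    filtered: list[FilteredRule],
    alpha: float = 0.01,
    correction: str = "bonferroni",
    table: TransactionTable | None = None,
) -> list[FilteredRule]:
    """Fisher-test every surviving rule; keep p < alpha / m (Bonferroni).

    m is the number of rules entering this stage (those still kept after
    LIC pruning).  p-values are annotated on every entering rule.
    """
    entering = [fr for fr in filtered if fr.kept]
    m = len(entering)
    if m == 0:
        raise ValueError("no rules enter the significance stage")
    threshold = alpha / m if correction == "bonferroni" else alpha
    for fr in entering:
        fr.p_value = fisher_p(table, fr.rule)
        if not fr.p_value < threshold:
            fr.reject("significance")
    return filtered


def matches_blacklist(
    rule: AssociationRule,
    blacklist: list[tuple[str, str]],
    catalog: FactorCatalog | None,
) -> bool:
    """True if any (lhs item, rhs) pairing matches a blacklist entry.

    Each entry side names either an item or a category; with no catalog
    only item-level entries can match.
    """
    cat_of = catalog.category_of if catalog is not None else {}
    rhs_names = {rule.rhs, cat_of.get(rule.rhs)}
    for lhs_item in rule.lhs:
        lhs_names = {lhs_item, cat_of.get(lhs_item)}
        for left, right in blacklist:
            if left in lhs_names and right in rhs_names:
                return True
    return False


def meaningfulness_filter(
    filtered: list[FilteredRule],
    blacklist: list[tuple[str, str]] | None = None,
    catalog: FactorCatalog | None = None,
) -> list[FilteredRule]:
    """Reject surviving rules that match the tautology blacklist."""
    entries = DEFAULT_BLACKLIST if blacklist is None else blacklist
    for fr in filtered:
        if fr.kept and matches_blacklist(fr.rule, entries, catalog):
            fr.reject("meaningfulness")
    return filtered


def apply_filters(
    rules: list[AssociationRule],
    table: TransactionTable,
    config: FilterConfig | None = None,
    catalog: FactorCatalog | None = None,
) -> list[FilteredRule]:
    """Run the full three-stage screen in order; monotone shrinkage."""
    config = config or FilterConfig()
    filtered = lic_filter(rules, table, config.min_lic, config.lic_mode)
    if any(fr.kept for fr in filtered):
        significance_filter(filtered, config.alpha, config.correction, table)
    meaningfulness_filter(filtered, config.blacklist, catalog)
    return filtered


def kept_rules(filtered: list[FilteredRule]) -> list[AssociationRule]:
    return [fr.rule for fr in filtered if fr.kept]


def filter_report_frame(filtered: list[FilteredRule]) -> pd.DataFrame:
    """Audit table: every candidate with lic, p, kept, rejection_reason."""
    return pd.DataFrame(
        {
            "lhs": [";".join(sorted(fr.rule.lhs)) for fr in filtered],
            "rhs": [fr.rule.rhs for fr in filtered],
            "support": [fr.rule.support for fr in filtered],
            "confidence": [fr.rule.confidence for fr in filtered],
            "lift": [fr.rule.lift for fr in filtered],
            "lic": [fr.lic for fr in filtered],
            "p_value": [fr.p_value for fr in filtered],
            "kept": [fr.kept for fr in filtered],
            "rejection_reason": [fr.rejection_reason for fr in filtered],
        }
    )


def write_blacklist_yaml(blacklist: list[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump([list(pair) for pair in blacklist], fh, allow_unicode=True)


def read_blacklist_yaml(path) -> list[tuple[str, str]]:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return [(str(a), str(b)) for a, b in data]
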