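"""Rule-set summaries: rankings, consequent subsets, antecedent groups,
value distributions and construct-combination profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .catalog import FactorCatalog
from .mining import AssociationRule
from .transactions import SYSTEM_CONSTRUCTS, TransactionTable, construct_profile

_KEYS = ("lift", "support", "confidence")


def top_rules(
    rules: list[AssociationRule], key: str = "lift", n: int = 15
) -> list[AssociationRule]:
    """Top-n rules by one metric, descending.

    Ties break on the other two metrics (descending) and finally on the
    canonical rule label so output is deterministic.
    """
    if key not in _KEYS:
        raise ValueError(f"key must be one of {_KEYS}")
    if n <= 0:
        raise ValueError("n must be positive")
    others = [k for k in _KEYS if k != key]
    ranked = sorted(
        rules,
        key=lambda r: (
            -getattr(r, key),
            -getattr(r, others[0]),
            -getattr(r, others[1]),
            r.key,
        ),
    )
    return ranked[:n]


def subset_by_rhs(
    rules: list[AssociationRule], rhs
) -> list[AssociationRule] | tuple[list[AssociationRule], list[AssociationRule]]:
    """Rules with a given consequent; a pair of items gives two subsets."""
    if isinstance(rhs, str):
        out = [r for r in rules if r.rhs == rhs]
        if not out:
            import warnings

            warnings.warn(f"item {rhs!r} never appears as a consequent", stacklevel=2)
        return out
    a, b = rhs
    return (
        [r for r in rules if r.rhs == a],
        [r for r in rules if r.rhs == b],
    )


@dataclass
class GroupedAntecedents:
    """K-means grouping of rules by antecedent membership."""

    k: int
    assignment: dict[tuple, int]  # rule.key -> group
    labels: dict[int, list[str]]  # group -> dominant antecedent items

    def group_of(self, rule: AssociationRule) -> int:
        return self.assignment[rule.key]


def group_antecedents(
    rules: list[AssociationRule], k: int = 20, seed: int = 0
) -> GroupedAntecedents:
    """Cluster rules over binary antecedent-membership vectors.

    One dimension per factor appearing in any antecedent; consequents are
    excluded.  Standard k-means with a fixed seed; each group is labelled
    by its up-to-three most frequent antecedent items.
    """
    if k > len(rules):
        raise ValueError(f"k={k} exceeds rule count {len(rules)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(rules, key=lambda r: r.key)
    factors = sorted({i for r in ordered for i in r.lhs})
    x = np.zeros((len(ordered), len(factors)))
    fidx = {f: j for j, f in enumerate(factors)}
    for ri, r in enumerate(ordered):
        for item in r.lhs:
            x[ri, fidx[item]] = 1.0
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    groups = km.fit_predict(x)
    assignment = {r.key: int(g) for r, g in zip(ordered, groups)}
    labels: dict[int, list[str]] = {}
    for g in range(k):
        members = [r for r, gg in zip(ordered, groups) if gg == g]
        freq: dict[str, int] = {}
        for r in members:
            for item in r.lhs:
                freq[item] = freq.get(item, 0) + 1
        labels[g] = [
            f for f, _ in sorted(freq.items(), key=lambda t: (-t[1], t[0]))[:3]
        ]
    return GroupedAntecedents(k=k, assignment=assignment, labels=labels)


def rule_value_distribution(rules: list[AssociationRule]) -> dict[str, float]:
    """Summary fractions of a rule set's metric distribution.

    Bands follow the standard reporting convention: support within
    [6%, 10%] (inclusive), confidence strictly above 80%, lift strictly
    above 2; plus the observed lift range.
    """
    if not rules:
        raise ValueError("empty rule set")
    n = len(rules)
    lifts = [r.lift for r in rules]
    return {
        "n_rules": n,
        "support_6_10_fraction": sum(1 for r in rules if 0.06 <= r.support <= 0.10) / n,
        "confidence_gt_80_fraction": sum(1 for r in rules if r.confidence > 0.80) / n,
        "lift_gt_2_fraction": sum(1 for r in rules if r.lift > 2.0) / n,
        "lift_min": min(lifts),
        "lift_max": max(lifts),
    }


def combination_profile(
    table: TransactionTable, catalog: FactorCatalog
) -> dict[frozenset[str], float]:
    """Venn-cell fractions of records by exact construct combination.

    Each record falls in the cell of the system constructs (driver,
    vehicle, roadway, environment) for which it has at least one true
    item; records touching no construct belong to no cell, so the cell
    fractions sum to at most 1.
    """
    profiles = construct_profile(table, catalog)
    n = len(profiles)
    cells: dict[frozenset[str], float] = {}
    for p in profiles:
        if p:
            cells[p] = cells.get(p, 0.0) + 1.0
    return {cell: count / n for cell, count in cells.items()}


def combination_profile_frame(
    cells: dict[frozenset[str], float]
) -> pd.DataFrame:
    rows = [
        {
            "constructs": "+".join(sorted(cell, key=SYSTEM_CONSTRUCTS.index)),
            "n_constructs": len(cell),
            "fraction": frac,
        }
        for cell, frac in cells.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["n_constructs", "constructs"])
        .reset_index(drop=True)
    )
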