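"""Apriori frequent-itemset enumeration and association-rule generation.

Rules have an itemset antecedent X (LHS) and a single-item consequent Y
(RHS), scored by

* support    Supp(X->Y) = #(X u Y) / N
* confidence Conf(X->Y) = Supp(X u Y) / Supp(X)
* lift       Lift(X->Y) = Conf(X->Y) / Supp(Y)

Lift 1 means X and Y occur independently; the mining thresholds default
to the calibrated working point S >= 6%, C >= 75%, L > 1.3 (support and
confidence inclusive, lift strictly greater, mirroring how the working
point is stated).  All metrics are computed from integer record counts,
so the identity support = confidence * Supp(LHS) holds to float rounding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transactions import TransactionTable

Itemset = frozenset[str]


@dataclass(frozen=True)
class FrequentItemset:
    items: Itemset
    support: float
    count: int


@dataclass(frozen=True)
class AssociationRule:
    """X -> Y with metrics; carries the raw counts behind them."""

    lhs: Itemset
    rhs: str
    support: float
    confidence: float
    lift: float
    n_both: int = 0      # records with X and Y
    n_lhs: int = 0       # records with X
    n_rhs: int = 0       # records with Y
    n_records: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lhs", frozenset(self.lhs))
        if self.rhs in self.lhs:
            raise ValueError("rhs must be disjoint from lhs")

    @property
    def key(self) -> tuple[tuple[str, ...], str]:
        return (tuple(sorted(self.lhs)), self.rhs)

    def label(self, sep: str = ";") -> str:
        return f"{sep.join(sorted(self.lhs))} => {self.rhs}"


@dataclass
class MiningConfig:
    """Thresholds of the rule search; ``min_lift`` strict, others inclusive."""

    min_support: float = 0.06
    min_confidence: float = 0.75
    min_lift: float | None = 1.3
    max_lhs_size: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")
        if not 0 <= self.min_confidence <= 1:
            raise ValueError("min_confidence must be in [0, 1]")
        if self.min_lift is not None and self.min_lift < 0:
            raise ValueError("min_lift must be nonnegative")
        if self.max_lhs_size < 1:
            raise ValueError("max_lhs_size must be >= 1")


def _canonical(itemsets: dict[Itemset, int]) -> list[Itemset]:
    return sorted(itemsets, key=lambda s: (len(s), tuple(sorted(s))))


def frequent_itemsets(
    table: TransactionTable, min_support: float, max_size: int
) -> list[FrequentItemset]:
    """Level-wise enumeration of all itemsets with support >= min_support.

    Returns every itemset of size <= max_size meeting the threshold, in
    canonical order (by size, then lexicographically).  Downward closure
    (every subset of a frequent itemset is frequent at the same
    threshold) is what makes the level-wise candidate pruning exact.
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    if table.n_records == 0:
        raise ValueError("empty table")
    n = table.n_records
    min_count = int(np.ceil(min_support * n - 1e-9))

    cols = {item: table.matrix[:, j] for j, item in enumerate(table.items)}
    counts: dict[Itemset, int] = {}
    # level 1
    level: dict[Itemset, np.ndarray] = {}
    for item in sorted(table.items):
        c = int(cols[item].sum())
        if c >= min_count:
            key = frozenset({item})
            counts[key] = c
            level[key] = cols[item]

    size = 1
    while level and size < max_size:
        size += 1
        keys = sorted(level, key=lambda s: tuple(sorted(s)))
        tuples = [tuple(sorted(k)) for k in keys]
        next_level: dict[Itemset, np.ndarray] = {}
        for a, b in itertools.combinations(range(len(tuples)), 2):
            ta, tb = tuples[a], tuples[b]
            if ta[:-1] != tb[:-1]:
                continue
            candidate = frozenset(ta) | frozenset(tb)
            if any(
                frozenset(candidate - {i}) not in level for i in candidate
            ):
                continue
            mask = level[keys[a]] & cols[tb[-1]]
            c = int(mask.sum())
            if c >= min_count:
                counts[candidate] = c
                next_level[candidate] = mask
        level = next_level

    return [
        FrequentItemset(items=s, support=counts[s] / n, count=counts[s])
        for s in _canonical(counts)
    ]


def rule_metrics(
    table: TransactionTable, lhs: Itemset | set[str], rhs: str
) -> tuple[float, float, float]:
    """(support, confidence, lift) of lhs -> rhs from raw record counts."""
    lhs = frozenset(lhs)
    if rhs in lhs:
        raise ValueError("rhs must be disjoint from lhs")
    n = table.n_records
    n_lhs = table.count(lhs)
    if n_lhs == 0:
        raise ZeroDivisionError("zero-support antecedent: confidence undefined")
    n_rhs = table.count([rhs])
    n_both = table.count(lhs | {rhs})
    if n_both == 0:
        return 0.0, 0.0, 0.0
    if n_rhs == 0:
        raise ZeroDivisionError("zero-support consequent: lift undefined")
    confidence = n_both / n_lhs
    return n_both / n, confidence, confidence * n / n_rhs


def generate_rules(
    frequents: list[FrequentItemset],
    table: TransactionTable,
    config: MiningConfig | None = None,
) -> list[AssociationRule]:
    """All rules X -> y with X u {y} frequent, passing the config thresholds.

    ``frequents`` must have been computed at (or below) the config's
    ``min_support`` so every antecedent and consequent count is available
    by downward closure.  Output is in canonical order (LHS size, then
    sorted labels).
    """
    config = config or MiningConfig()
    counts = {f.items: f.count for f in frequents}
    n = table.n_records
    rules: list[AssociationRule] = []
    for f in frequents:
        if len(f.items) < 2 or len(f.items) > config.max_lhs_size + 1:
            continue
        for rhs in sorted(f.items):
            lhs = frozenset(f.items - {rhs})
            n_lhs = counts.get(lhs)
            n_rhs = counts.get(frozenset({rhs}))
            if n_lhs is None or n_rhs is None:  # pragma: no cover - closure
                continue
            confidence = f.count / n_lhs
            lift = confidence * n / n_rhs
            if confidence < config.min_confidence:
                continue
            if config.min_lift is not None and not lift > config.min_lift:
                continue
            rules.append(
                AssociationRule(
                    lhs=lhs,
                    rhs=rhs,
                    support=f.count / n,
                    confidence=confidence,
                    lift=lift,
                    n_both=f.count,
                    n_lhs=n_lhs,
                    n_rhs=n_rhs,
                    n_records=n,
                )
            )
    rules.sort(key=lambda r: (len(r.lhs), r.key))
    return rules


def mine_rules(
    table: TransactionTable, config: MiningConfig | None = None
) -> list[AssociationRule]:
    """Convenience: frequent itemsets then rule generation in one call."""
    config = config or MiningConfig()
    freq = frequent_itemsets(table, config.min_support, config.max_lhs_size + 1)
    return generate_rules(freq, table, config)


def threshold_sweep(
    table: TransactionTable,
    grid: list[tuple[float, float]],
    max_lhs_size: int = 3,
) -> pd.DataFrame:
    """Rule count and lift range at each (min_support, min_confidence) point.

    No lift threshold is applied during the sweep, so the returned lift
    range describes the raw candidate set at each working point — the
    calibration view used to pick a final threshold triple.
    """
    rows = []
    for min_support, min_confidence in grid:
        try:
            rules = mine_rules(
                table,
                MiningConfig(
                    min_support=min_support,
                    min_confidence=min_confidence,
                    min_lift=None,
                    max_lhs_size=max_lhs_size,
                ),
            )
        except ValueError:
            rules = []
        lifts = [r.lift for r in rules]
        rows.append(
            {
                "min_support": min_support,
                "min_confidence": min_confidence,
                "n_rules": len(rules),
                "lift_min": min(lifts) if lifts else float("nan"),
                "lift_max": max(lifts) if lifts else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# -- rules CSV dialect (";"-joined LHS) --------------------------------


def rules_to_frame(rules: list[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lhs": [";".join(sorted(r.lhs)) for r in rules],
            "rhs": [r.rhs for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
        }
    )


def write_rules_csv(rules: list[AssociationRule], path) -> None:
    rules_to_frame(rules).to_csv(path, index=False)


def read_rules_csv(path) -> list[AssociationRule]:
    """Read the ";"-joined rules dialect back into AssociationRule objects."""
    df = pd.read_csv(path)
    required = {"lhs", "rhs", "support", "confidence", "lift"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rules CSV missing columns: {sorted(missing)}")
    rules = []
    for row in df.itertuples(index=False):
        lhs = frozenset(s.strip() for s in str(row.lhs).split(";") if s.strip())
        rules.append(
            AssociationRule(
                lhs=lhs,
                rhs=str(row.rhs).strip(),
                support=float(row.support),
                confidence=float(row.confidence),
                lift=float(row.lift),
            )
        )
    return rules
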