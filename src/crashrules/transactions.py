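"""Boolean transaction tables: the record x item matrix all stages consume.

A crash-record CSV is read either as already-boolean 0/1 columns named by
catalog items, or as raw categorical columns (one per catalog category,
cell = level label) which are one-hot expanded against the catalog.
Missing/blank categorical cells encode as all-false across that category's
items: the record count N is preserved and no data is invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import FactorCatalog


@dataclass
class TransactionTable:
    """N records x M items boolean matrix with ordered item labels."""

    items: list[str]
    matrix: np.ndarray  # (N, M) bool
    provenance: str = ""
    catalog: FactorCatalog | None = None
    unknown_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if self.matrix.shape[1] != len(self.items):
            raise ValueError("column count does not match item list")
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item identifiers")

    @property
    def n_records(self) -> int:
        return int(self.matrix.shape[0])

    def column(self, item: str) -> np.ndarray:
        try:
            idx = self.items.index(item)
        except ValueError:
            raise KeyError(f"unknown item: {item!r}") from None
        return self.matrix[:, idx]

    def mask(self, itemset: Iterable[str]) -> np.ndarray:
        """Boolean row mask of records where every item in *itemset* is true."""
        out = np.ones(self.n_records, dtype=bool)
        for item in itemset:
            out &= self.column(item)
        return out

    def count(self, itemset: Iterable[str]) -> int:
        return int(self.mask(itemset).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.astype(int), columns=self.items)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def marginal_support(table: TransactionTable, itemset: Iterable[str]) -> float:
    """Fraction of records containing every item of *itemset*.

    The empty itemset has support 1 (a vacuous conjunction holds in every
    record).  Unknown items raise ``KeyError``.
    """
    if table.n_records == 0:
        raise ValueError("empty table")
    return table.count(itemset) / table.n_records


def load_crash_table(
    path, catalog: FactorCatalog | None = None, provenance: str | None = None
) -> TransactionTable:
    """Read a crash-record CSV into boolean transaction form.

    Columns whose names are catalog items (or, with no catalog, any
    column) holding only 0/1/true/false values are taken as booleans.
    Columns named after a catalog *category* are treated as raw
    categoricals and one-hot expanded: cell value ``v`` sets the item
    whose label is ``v`` itself or ``"<column>: <v>"``.  Columns matching
    neither are kept out of the matrix but reported in
    ``unknown_columns`` rather than silently dropped.
    """
    raw_header = pd.read_csv(path, header=None, nrows=1, dtype=str)
    cols = [str(c).strip() for c in raw_header.iloc[0]]
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"duplicate header names: {dupes}")
    df = pd.read_csv(path, dtype=object)
    if df.shape[1] == 0:
        raise ValueError("unreadable or column-free file")
    cols = list(df.columns)
    if df.shape[0] == 0:
        raise ValueError("empty table: file has a header but no data rows")

    known_items = set(catalog.items) if catalog is not None else None
    categories = set(catalog.categories) if catalog is not None else set()

    item_order: list[str] = []
    columns: dict[str, np.ndarray] = {}
    unknown: list[str] = []
    n = df.shape[0]

    for col in cols:
        series = df[col]
        if known_items is None or col in known_items:
            columns[col] = _to_bool(series, col)
            item_order.append(col)
        elif col in categories:
            assert catalog is not None
            level_items = catalog.items_of_category(col)
            by_label = {it: it for it in level_items}
            # accept bare level labels ("plain" for "Terrain: plain")
            for it in level_items:
                if ": " in it:
                    by_label.setdefault(it.split(": ", 1)[1], it)
            expanded = {it: np.zeros(n, dtype=bool) for it in level_items}
            for ridx, value in enumerate(series):
                if value is None or (isinstance(value, float) and np.isnan(value)):
                    continue
                label = str(value).strip()
                if not label:
                    continue
                target = by_label.get(label) or by_label.get(f"{col}: {label}")
                if target is None:
                    raise ValueError(
                        f"row {ridx}: level {label!r} not in catalog category {col!r}"
                    )
                expanded[target][ridx] = True
            for it in level_items:
                columns[it] = expanded[it]
                item_order.append(it)
        else:
            unknown.append(col)

    if not item_order:
        raise ValueError("no recognised item or category columns in file")

    matrix = np.column_stack([columns[i] for i in item_order])
    return TransactionTable(
        items=item_order,
        matrix=matrix,
        provenance=provenance or str(path),
        catalog=catalog,
        unknown_columns=unknown,
    )


def _to_bool(series: pd.Series, name: str) -> np.ndarray:
    mapping = {
        "0": False, "1": True, "true": True, "false": False,
        "yes": True, "no": False, "": False,
    }
    out = np.zeros(len(series), dtype=bool)
    for i, v in enumerate(series):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        key = str(v).strip().lower()
        if key not in mapping:
            raise ValueError(f"column {name!r}: non-boolean value {v!r}")
        out[i] = mapping[key]
    return out


@dataclass
class ValidationReport:
    """Outcome of checking a table against catalog exclusivity constraints."""

    violations: list[tuple[int, tuple[str, ...], tuple[str, ...]]]
    unknown_items: list[str]
    missing_rates: dict[str, float]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate(table: TransactionTable, catalog: FactorCatalog) -> ValidationReport:
    """List every record where >1 item of an exclusive group is true.

    Violations are ordered by record index, then by group.  Items present
    in the table but absent from the catalog are reported as
    ``unknown_items``.  ``missing_rates`` gives, per exclusive group
    label, the fraction of records with *no* item of that group set
    (unset values are encoded as all-false).
    """
    table_items = set(table.items)
    unknown = sorted(table_items - set(catalog.items))
    violations: list[tuple[int, tuple[str, ...], tuple[str, ...]]] = []
    missing_rates: dict[str, float] = {}

    groups = []
    for group in catalog.exclusive_groups:
        present = [i for i in group if i in table_items]
        if len(present) < 2:
            continue
        groups.append((tuple(group), present, table.to_frame()[present].to_numpy(bool)))

    for gi, (group, present, block) in enumerate(groups):
        row_sums = block.sum(axis=1)
        missing_rates["|".join(group)] = float((row_sums == 0).mean())
        for ridx in np.nonzero(row_sums > 1)[0]:
            simultaneous = tuple(p for p, v in zip(present, block[ridx]) if v)
            violations.append((int(ridx), group, simultaneous))

    violations.sort(key=lambda v: (v[0], v[1]))
    return ValidationReport(violations, unknown, missing_rates)


#: constructs that constitute the causal system level; context items
#: (time, severity) never contribute to a record's construct profile.
SYSTEM_CONSTRUCTS = ("driver", "vehicle", "roadway", "environment")


def construct_profile(
    table: TransactionTable, catalog: FactorCatalog
) -> list[frozenset[str]]:
    """Per-record set of system-level constructs with >= 1 true item."""
    masks = {}
    for construct in SYSTEM_CONSTRUCTS:
        cols = [i for i in catalog.items_of_construct(construct) if i in table.items]
        if cols:
            idx = [table.items.index(c) for c in cols]
            masks[construct] = table.matrix[:, idx].any(axis=1)
        else:
            masks[construct] = np.zeros(table.n_records, dtype=bool)
    return [
        frozenset(c for c in SYSTEM_CONSTRUCTS if masks[c][r])
        for r in range(table.n_records)
    ]
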