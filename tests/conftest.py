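import itertools
from math import comb

import numpy as np
import pytest

from crashrules.catalog import default_catalog
from crashrules.transactions import TransactionTable


def make_table(columns: dict[str, list[int]], **kw) -> TransactionTable:
    items = list(columns)
    matrix = np.array([columns[i] for i in items], dtype=bool).T
    return TransactionTable(items=items, matrix=matrix, **kw)


@pytest.fixture
def catalog():
    return default_catalog()


@pytest.fixture
def toy_table():
    # 10 records: A in 6, B in 5, A&B in 4
    return make_table(
        {
            "A": [1, 1, 1, 1, 1, 1, 0, 0, 0, 0],
            "B": [1, 1, 1, 1, 0, 0, 1, 0, 0, 0],
        }
    )


def brute_force_frequent(table: TransactionTable, min_support: float, max_size: int):
    """Exhaustive oracle: support of every itemset up to max_size."""
    n = table.n_records
    out = {}
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(sorted(table.items), size):
            c = table.count(combo)
            if c / n >= min_support - 1e-12:
                out[frozenset(combo)] = c / n
    return out


def fisher_oracle(a: int, n_lhs: int, n_rhs: int, n: int) -> float:
    """Fixed-margins enumeration: P(overlap >= a) under the null."""
    if n_lhs in (0, n) or n_rhs in (0, n):
        return 1.0
    hi = min(n_lhs, n_rhs)
    denom = comb(n, n_lhs)
    return sum(
        comb(n_rhs, k) * comb(n - n_rhs, n_lhs - k) for k in range(a, hi + 1)
    ) / denom


def random_table(rng: np.random.Generator, n_records: int, n_items: int,
                 p_lo: float = 0.1, p_hi: float = 0.7) -> TransactionTable:
    probs = rng.uniform(p_lo, p_hi, size=n_items)
    items = [f"i{j:02d}" for j in range(n_items)]
    matrix = rng.random((n_records, n_items)) < probs
    return TransactionTable(items=items, matrix=matrix)
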