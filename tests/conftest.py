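"""Shared fixtures: toy datasets, reference oracles, and desk-scale CV runs.

The expensive stochastic experiments (repeated CV and permutation runs on the
desk-scale synthetic benchmark) are session-scoped so the acceptance tests
share one computation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from dfqsar import (
    DescriptorTable,
    ForestConfig,
    LabeledDataset,
    cross_validate,
    generate_dataset,
    permutation_test,
    scaled_config,
    sparse_signal_config,
)


# ---------------------------------------------------------------- oracles

def oracle_best_split(values, labels, min_leaf):
    """Exhaustive enumeration of every midpoint threshold (independent reference)."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    sv = [float(values[i]) for i in order]
    sl = [int(labels[i]) for i in order]
    total_pos = sum(sl)
    if total_pos in (0, n) or n < 2 * min_leaf:
        return None

    def h(pos, m):
        if m == 0 or pos in (0, m):
            return 0.0
        p = pos / m
        return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))

    best = None
    for i in range(1, n):
        if sv[i] == sv[i - 1] or i < min_leaf or n - i < min_leaf:
            continue
        pos_l = sum(sl[:i])
        gain = h(total_pos, n) - (i * h(pos_l, i) + (n - i) * h(total_pos - pos_l, n - i)) / n
        if best is None or gain > best[1] + 1e-12:
            best = ((sv[i - 1] + sv[i]) / 2, gain)
    if best is None:
        return None
    return best[0], max(best[1], 0.0)


def oracle_grow_tree(X, y, pool_cols, names, min_leaf, max_depth=None, depth=0):
    """Naive recursive reference tree grower mirroring the stated growth rules."""
    n = len(y)
    n_pos = int(sum(y))
    leaf = {"binder_fraction": n_pos / n, "n_train": n}
    if n_pos in (0, n) or n < 2 * min_leaf:
        return leaf
    if max_depth is not None and depth >= max_depth:
        return leaf
    best_gain, best_col, best_thr = 0.0, -1, 0.0
    for col in pool_cols:
        found = oracle_best_split(X[:, col], y, min_leaf)
        if found is None:
            continue
        thr, gain = found
        if gain > best_gain:
            best_gain, best_col, best_thr = gain, col, thr
    if best_col < 0 or best_gain <= 0.0:
        return leaf
    mask = X[:, best_col] <= best_thr
    return {
        "descriptor_name": names[best_col],
        "threshold": best_thr,
        "left": oracle_grow_tree(X[mask], y[mask], pool_cols, names, min_leaf,
                                 max_depth, depth + 1),
        "right": oracle_grow_tree(X[~mask], y[~mask], pool_cols, names, min_leaf,
                                  max_depth, depth + 1),
    }


# ---------------------------------------------------------------- toy data

@pytest.fixture
def toy_table() -> DescriptorTable:
    rng = np.random.default_rng(42)
    return DescriptorTable(
        [f"C{i}" for i in range(12)], ["d1", "d2", "d3"], rng.normal(size=(12, 3))
    )


@pytest.fixture
def separable_dataset() -> LabeledDataset:
    """60 compounds, one perfectly separating descriptor plus two noise columns."""
    rng = np.random.default_rng(7)
    y = np.array([1] * 40 + [0] * 20)
    sep = np.where(y == 1, 1.0, -1.0) + rng.normal(0, 0.05, 60)
    table = DescriptorTable(
        [f"C{i}" for i in range(60)], ["sep", "n1", "n2"],
        np.column_stack([sep, rng.normal(size=60), rng.normal(size=60)]),
    )
    return LabeledDataset(table, y)


@pytest.fixture
def random_dataset() -> LabeledDataset:
    """60-sample mixed-signal dataset for structural comparisons."""
    rng = np.random.default_rng(11)
    y = (rng.random(60) < 0.5).astype(int)
    X = rng.normal(size=(60, 5)) + 0.8 * y[:, None] * rng.random(5)
    table = DescriptorTable([f"C{i}" for i in range(60)],
                            [f"d{j}" for j in range(5)], X)
    return LabeledDataset(table, y)


# ------------------------------------------------- desk-scale experiments

@pytest.fixture(scope="session")
def benchmark_data():
    """The imbalanced desk-scale benchmark: 480 binders / 20 non-binders,
    50 descriptors, 18 planted informative."""
    return generate_dataset(scaled_config(seed=1))


@pytest.fixture(scope="session")
def benchmark_cv(benchmark_data):
    dataset, _ = benchmark_data
    return cross_validate(dataset, k=5, iterations=20, base_seed=101)


@pytest.fixture(scope="session")
def benchmark_permutation(benchmark_data):
    dataset, _ = benchmark_data
    return permutation_test(dataset, replicates=100, k=5, base_seed=900)


@pytest.fixture(scope="session")
def sparse_data():
    """Sparse-signal benchmark: 3 planted informative of 50 descriptors."""
    return generate_dataset(sparse_signal_config(seed=1))


@pytest.fixture(scope="session")
def sparse_cv(sparse_data):
    dataset, _ = sparse_data
    return cross_validate(dataset, k=5, iterations=20, base_seed=77)
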