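"""The Decision Forest learner.

A Decision Forest (DF) is an ensemble of decision trees trained sequentially
on mutually exclusive descriptor subsets: the first tree is grown on the full
descriptor pool with all samples, the descriptors it used in split nodes are
then removed from the pool, and the next tree is grown on what remains.  The
cycle stops when adding a tree no longer improves the consensus, when the
pool is exhausted, or when the next tree degenerates to a single leaf.  The
consensus binder probability of a compound is the unweighted mean of the leaf
binder fractions the trees route it to.

This is deliberately different from Random Forests: DF uses few, deep,
deterministic trees built on all samples, and diversity comes from disjoint
descriptor pools rather than from bootstrapping and random feature draws.
Training involves no randomness at all — ties in split gain are broken by
descriptor column order, so a dataset and a configuration fully determine the
model.

Trees split numeric descriptors at midpoints between adjacent distinct sorted
values, choosing the threshold that maximises information gain (Shannon
entropy reduction) subject to a minimum leaf size.  Growth stops at class
purity, the minimum leaf size, an optional depth cap, or when no split has
strictly positive gain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .data_model import BINDER, NON_BINDER, DescriptorTable, LabeledDataset

__all__ = [
    "ForestConfig",
    "TreeNode",
    "ForestModel",
    "Prediction",
    "best_split",
    "build_tree",
    "train_forest",
    "predict_proba",
    "predict_table",
    "classify",
    "prediction_confidence",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ForestConfig:
    """Training configuration.

    max_trees: hard cap on the number of trees (the stopping rule usually
        halts earlier).
    min_leaf: minimum samples per leaf; guards consensus against singleton
        leaves in a 98.8%-binder training set.
    max_depth: optional depth cap; ``None`` grows trees to purity ("deep and
        accurate" trees are a defining DF trait).
    improvement_epsilon: a new tree is kept only if it raises consensus
        training balanced accuracy by more than this.
    """

    max_trees: int = 10
    min_leaf: int = 5
    max_depth: int | None = None
    improvement_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.max_trees < 1:
            raise ValueError("max_trees must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")
        if self.improvement_epsilon < 0:
            raise ValueError("improvement_epsilon must be >= 0")


@dataclass
class TreeNode:
    """Internal node (descriptor_name, threshold, children) or leaf (binder_fraction).

    Internal nodes route value <= threshold left and value > threshold right.
    """

    descriptor_name: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    binder_fraction: float | None = None
    n_train: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.descriptor_name is None

    def used_descriptors(self) -> set[str]:
        """Names appearing in any split node of this subtree."""
        if self.is_leaf:
            return set()
        out = {self.descriptor_name}
        out |= self.left.used_descriptors()
        out |= self.right.used_descriptors()
        return out

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"binder_fraction": self.binder_fraction, "n_train": self.n_train}
        return {
            "descriptor_name": self.descriptor_name,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "binder_fraction" in d:
            return cls(binder_fraction=float(d["binder_fraction"]), n_train=int(d["n_train"]))
        if not {"descriptor_name", "threshold", "left", "right"} <= d.keys():
            raise ValueError("malformed tree node in model file")
        return cls(
            descriptor_name=str(d["descriptor_name"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class ForestModel:
    """An ordered list of trees with pairwise-disjoint descriptor sets."""

    trees: list[TreeNode]
    descriptor_sets: list[list[str]]
    config: ForestConfig
    kept_names: list[str]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("a forest needs at least one tree")
        seen: set[str] = set()
        for names in self.descriptor_sets:
            overlap = seen & set(names)
            if overlap:
                raise ValueError(f"descriptor sets not disjoint: {sorted(overlap)}")
            seen |= set(names)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def used_descriptors(self) -> set[str]:
        return set().union(*(set(s) for s in self.descriptor_sets))


@dataclass(frozen=True)
class Prediction:
    """Consensus binder probability P, class call and confidence for one compound."""

    compound_id: str
    probability: float
    label: str
    confidence: float


def _entropy(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary Shannon entropy (bits) of groups with ``pos`` positives out of ``n``."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = pos / n
        q = 1.0 - p
        h = -(np.where(p > 0, p * np.log2(p), 0.0) + np.where(q > 0, q * np.log2(q), 0.0))
    return h


def best_split(
    values: np.ndarray, labels: np.ndarray, min_leaf: int
) -> tuple[float, float] | None:
    """Best midpoint threshold by information gain, or ``None`` if no admissible split.

    Candidate thresholds are midpoints between adjacent distinct sorted values;
    a candidate is admissible when both children hold at least ``min_leaf``
    samples.  Returns ``(threshold, gain)`` for the gain-maximising candidate,
    smallest threshold on ties.  Pure labels give ``None``.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise ValueError(f"length mismatch: {v.shape} values vs {y.shape} labels")
    n = v.size
    pos_total = int(y.sum())
    if pos_total == 0 or pos_total == n or n < 2 * min_leaf:
        return None
    order = np.argsort(v, kind="stable")
    sv = v[order]
    cum_pos = np.cumsum(y[order])
    # split after position i (1..n-1): left = first i samples
    i = np.arange(1, n)
    admissible = (sv[1:] > sv[:-1]) & (i >= min_leaf) & (n - i >= min_leaf)
    if not admissible.any():
        return None
    i = i[admissible]
    pos_left = cum_pos[i - 1]
    h_parent = _entropy(np.array([pos_total]), np.array([n]))[0]
    h_left = _entropy(pos_left, i)
    h_right = _entropy(pos_total - pos_left, n - i)
    gain = h_parent - (i * h_left + (n - i) * h_right) / n
    best = int(np.argmax(gain))  # argmax returns the first maximum: smallest threshold
    thr = 0.5 * (sv[i[best] - 1] + sv[i[best]])
    return float(thr), float(max(gain[best], 0.0))


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    pool_cols: list[int],
    names: Sequence[str],
    config: ForestConfig,
    depth: int,
) -> TreeNode:
    n = y.size
    n_pos = int(y.sum())
    leaf = TreeNode(binder_fraction=n_pos / n, n_train=n)
    if n_pos in (0, n) or n < 2 * config.min_leaf:
        return leaf
    if config.max_depth is not None and depth >= config.max_depth:
        return leaf
    best_gain = 0.0
    best_col = -1
    best_thr = 0.0
    for col in pool_cols:  # pool order = table column order; first wins gain ties
        found = best_split(X[:, col], y, config.min_leaf)
        if found is None:
            continue
        thr, gain = found
        if gain > best_gain:
            best_gain, best_col, best_thr = gain, col, thr
    if best_col < 0 or best_gain <= 0.0:
        return leaf
    mask = X[:, best_col] <= best_thr
    return TreeNode(
        descriptor_name=names[best_col],
        threshold=best_thr,
        left=_grow(X[mask], y[mask], pool_cols, names, config, depth + 1),
        right=_grow(X[~mask], y[~mask], pool_cols, names, config, depth + 1),
    )


def build_tree(
    dataset: LabeledDataset, pool: Sequence[str], config: ForestConfig = ForestConfig()
) -> TreeNode:
    """Grow one decision tree greedily on the given descriptor pool."""
    if not pool:
        raise ValueError("empty descriptor pool")
    idx = dataset.table.column_index()
    missing = [p for p in pool if p not in idx]
    if missing:
        raise KeyError(f"pool descriptor(s) not in table: {missing}")
    pool_cols = sorted(idx[p] for p in pool)  # table column order
    return _grow(
        dataset.table.values, dataset.labels, pool_cols,
        dataset.table.descriptor_names, config, depth=0,
    )


def _route(node: TreeNode, X: np.ndarray, col_of: dict[str, int], rows: np.ndarray,
           out: np.ndarray) -> None:
    if node.is_leaf:
        out[rows] = node.binder_fraction
        return
    go_left = X[rows, col_of[node.descriptor_name]] <= node.threshold
    _route(node.left, X, col_of, rows[go_left], out)
    _route(node.right, X, col_of, rows[~go_left], out)


def _tree_fractions(tree: TreeNode, table: DescriptorTable) -> np.ndarray:
    col_of = table.column_index()
    missing = sorted(tree.used_descriptors() - col_of.keys())
    if missing:
        raise KeyError(f"table lacks descriptor(s) required by the model: {missing}")
    out = np.empty(table.n_compounds, dtype=float)
    _route(tree, table.values, col_of, np.arange(table.n_compounds), out)
    return out


def _consensus_proba(trees: Sequence[TreeNode], table: DescriptorTable) -> np.ndarray:
    return np.mean([_tree_fractions(t, table) for t in trees], axis=0)


def _balanced_accuracy(y: np.ndarray, proba: np.ndarray) -> float:
    pred = proba >= 0.5
    pos = y == 1
    sens = (pred & pos).sum() / pos.sum()
    spec = (~pred & ~pos).sum() / (~pos).sum()
    return (sens + spec) / 2


def train_forest(dataset: LabeledDataset, config: ForestConfig = ForestConfig(),
                 pool: Sequence[str] | None = None) -> ForestModel:
    """Train a Decision Forest by sequential disjoint-pool tree construction.

    After each tree its split descriptors leave the pool.  A candidate tree is
    kept only if it raises consensus training balanced accuracy by more than
    ``config.improvement_epsilon``; otherwise it is discarded and training
    stops.  Training also stops at ``max_trees``, on pool exhaustion, or when
    the candidate degenerates to a single leaf.
    """
    if dataset.n_binders == 0 or dataset.n_nonbinders == 0:
        raise ValueError("training requires both classes present")
    remaining = list(pool if pool is not None else dataset.table.descriptor_names)
    trees: list[TreeNode] = []
    descriptor_sets: list[list[str]] = []
    fractions: list[np.ndarray] = []
    score = -np.inf
    while len(trees) < config.max_trees and remaining:
        tree = build_tree(dataset, remaining, config)
        if tree.is_leaf and trees:
            break
        candidate = fractions + [_tree_fractions(tree, dataset.table)]
        new_score = _balanced_accuracy(dataset.labels, np.mean(candidate, axis=0))
        if trees and new_score - score <= config.improvement_epsilon:
            break  # non-improving tree discarded
        trees.append(tree)
        fractions = candidate
        score = new_score
        used = sorted(tree.used_descriptors())
        descriptor_sets.append(used)
        remaining = [d for d in remaining if d not in set(used)]
        if tree.is_leaf:
            break
    return ForestModel(trees, descriptor_sets, config,
                       list(dataset.table.descriptor_names))


def classify(p: float) -> str:
    """Class call from a consensus probability: binder iff P >= 0.5."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return BINDER if p >= 0.5 else NON_BINDER


def prediction_confidence(p: float) -> float:
    """Confidence = |P - 0.5| / 0.5, ranging 0 (uninformative) to 1 (certain)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return abs(p - 0.5) / 0.5


def predict_proba(model: ForestModel, row: dict[str, float]) -> float:
    """Consensus P for one compound given as a descriptor-name -> value mapping."""
    missing = sorted(set(model.kept_names) - row.keys())
    if missing:
        raise KeyError(f"row lacks descriptor(s): {missing}")
    table = DescriptorTable(
        ["_row"], list(model.kept_names),
        np.array([[float(row[n]) for n in model.kept_names]]),
    )
    return float(_consensus_proba(model.trees, table)[0])


def predict_table(model: ForestModel, table: DescriptorTable) -> list[Prediction]:
    """Consensus predictions for every compound in a descriptor table."""
    missing = sorted(set(model.kept_names) - set(table.descriptor_names))
    if missing:
        raise KeyError(f"table lacks descriptor(s): {missing}")
    proba = _consensus_proba(model.trees, table)
    return [
        Prediction(cid, float(p), classify(float(p)), prediction_confidence(float(p)))
        for cid, p in zip(table.compound_ids, proba)
    ]


_SCHEMA = "dfqsar-forest-v1"


def save_model(model: ForestModel, path) -> None:
    """Persist a forest as JSON (config, kept descriptor list, trees, pools)."""
    doc = {
        "schema": _SCHEMA,
        "config": asdict(model.config),
        "kept_names": model.kept_names,
        "descriptor_sets": model.descriptor_sets,
        "trees": [t.to_dict() for t in model.trees],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> ForestModel:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"corrupted model file {path}: {e}") from e
    if not isinstance(doc, dict) or doc.get("schema") != _SCHEMA:
        raise ValueError(f"{path} is not a {_SCHEMA} model file")
    cfg = doc["config"]
    return ForestModel(
        trees=[TreeNode.from_dict(t) for t in doc["trees"]],
        descriptor_sets=[list(s) for s in doc["descriptor_sets"]],
        config=ForestConfig(**cfg),
        kept_names=list(doc["kept_names"]),
    )
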