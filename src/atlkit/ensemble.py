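"""Improves-over-baseline classification with generational forest ensembles.

The unit of learning is a *member*: a small random forest of depth-limited
decision trees trained on a bootstrap of the labeled reactions.  An
:class:`Ensemble` is an ordered list of members carrying generation tags; new
generations trained on freshly observed target reactions are concatenated onto
the ensemble, while trees that endorsed conditions later observed to fail are
pruned out.

Trees are trained with scikit-learn and immediately frozen into a plain
array-based representation so that prediction, pruning and serialization are
pure, deterministic and independent of the training library.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .errors import DimensionError, TrainingError
from .reagent_space import Condition, FeaturizationSchema

LEAF = -2  # sklearn sentinel for "no split at this node"


@dataclass(frozen=True)
class Tree:
    """A frozen decision tree: parallel node arrays plus per-node P(improve).

    ``feature[i] == LEAF`` marks a leaf.  ``prob_pos`` holds the
    positive-class (improvement) probability at every node; only leaf entries
    are used for prediction.
    """

    feature: tuple[int, ...]
    threshold: tuple[float, ...]
    left: tuple[int, ...]
    right: tuple[int, ...]
    prob_pos: tuple[float, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def split_features(self) -> list[int]:
        """Feature indices of every split node (empty for leaf-only stumps)."""
        return [f for f in self.feature if f != LEAF]

    def route(self, x: np.ndarray) -> int:
        """Return the leaf node index that ``x`` reaches."""
        node = 0
        while self.feature[node] != LEAF:
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.left[node]
            else:
                node = self.right[node]
        return node

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Vectorized P(improve) for every row of ``X``."""
        X = np.atleast_2d(X)
        node = np.zeros(len(X), dtype=np.intp)
        feat = np.asarray(self.feature)
        thr = np.asarray(self.threshold)
        left = np.asarray(self.left)
        right = np.asarray(self.right)
        active = feat[node] != LEAF
        while active.any():
            idx = np.flatnonzero(active)
            n = node[idx]
            go_left = X[idx, feat[n]] <= thr[n]
            node[idx] = np.where(go_left, left[n], right[n])
            active = feat[node] != LEAF
        return np.asarray(self.prob_pos)[node]


def tree_from_sklearn(est, classes: Sequence) -> Tree:
    """Freeze a fitted sklearn decision tree into a :class:`Tree`.

    ``classes`` is the label vocabulary of the enclosing forest; the
    positive-class column is the one whose label equals 1.  A forest trained
    on a single-class set yields constant-probability leaf trees.
    """
    t = est.tree_
    counts = t.value.reshape(t.node_count, -1)
    totals = counts.sum(axis=1)
    classes = list(classes)
    if 1 in classes:
        pos = counts[:, classes.index(1)] / np.maximum(totals, 1e-300)
    else:
        pos = np.zeros(t.node_count)
    return Tree(
        feature=tuple(int(f) for f in t.feature),
        threshold=tuple(float(x) for x in t.threshold),
        left=tuple(int(x) for x in t.children_left),
        right=tuple(int(x) for x in t.children_right),
        prob_pos=tuple(float(p) for p in pos),
    )


@dataclass(frozen=True)
class ForestMember:
    """One voting member: a small forest with a generation tag and seed."""

    generation: int
    seed: int
    trees: tuple[Tree, ...]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean of the member's trees' P(improve), per row of ``X``."""
        X = np.atleast_2d(X)
        acc = np.zeros(len(X))
        for t in self.trees:
            acc += t.predict_proba(X)
        return acc / len(self.trees)


@dataclass
class Ensemble:
    """Ordered collection of forest members; the unit that votes."""

    members: list[ForestMember]
    n_features: int

    def __post_init__(self) -> None:
        for m in self.members:
            if not m.trees:
                raise ValueError("ensemble member with zero trees")
        gens = [m.generation for m in self.members]
        if gens != sorted(gens):
            raise ValueError("generation tags must be non-decreasing")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_trees(self) -> int:
        return sum(len(m.trees) for m in self.members)

    @property
    def generations(self) -> list[int]:
        return [m.generation for m in self.members]


@dataclass
class ModelConfig:
    """Hyperparameters for one generation of forest members."""

    n_models: int = 100
    trees_per_model: int = 10
    max_depth: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_models, self.trees_per_model, self.max_depth) < 1:
            raise ValueError("n_models, trees_per_model and max_depth must be >= 1")


@dataclass
class LabeledSet:
    """Feature matrix with strict improves-over-threshold binary labels."""

    X: np.ndarray
    y: np.ndarray
    threshold_percent: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D and aligned with y")


@dataclass(frozen=True)
class ReactionRecord:
    """An observed reaction with domain and iteration provenance."""

    substrate_pair: tuple[str, str]
    condition: Condition
    yield_percent: float
    domain: str  # "source" | "target"
    iteration: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.yield_percent <= 100.0:
            raise ValueError(f"yield {self.yield_percent} outside [0, 100]")
        if self.domain not in ("source", "target"):
            raise ValueError(f"domain must be source|target, got {self.domain!r}")
        if self.iteration < 0:
            raise ValueError("iteration must be >= 0")


def label_records(
    records: Sequence[ReactionRecord],
    threshold_percent: float,
    *,
    schema: FeaturizationSchema,
    catalog,
) -> LabeledSet:
    """Label reactions 1 iff yield strictly exceeds the baseline threshold."""
    from .reagent_space import featurize_all

    if not records:
        raise TrainingError("cannot label an empty record list")
    pair = records[0].substrate_pair
    X = featurize_all([r.condition for r in records], pair, schema, catalog)
    y = np.array([1 if r.yield_percent > threshold_percent else 0 for r in records])
    return LabeledSet(X=X, y=y, threshold_percent=threshold_percent)


def train_forest_batch(
    data: LabeledSet,
    config: ModelConfig,
    generation: int,
    seed: int | None = None,
) -> Ensemble:
    """Train ``config.n_models`` bootstrap forests of depth <= ``max_depth``.

    Member ``i`` is seeded ``seed + i`` so the batch is reproducible and
    members are decorrelated.  A single-class training set degrades to
    leaf-only stumps predicting the empirical positive rate (0 or 1).
    """
    if len(data.X) == 0:
        raise TrainingError("empty training set")
    base_seed = config.seed if seed is None else seed
    members = []
    single_class = len(np.unique(data.y)) < 2
    n = len(data.y)
    X32 = np.ascontiguousarray(data.X, dtype=np.float32)
    y = data.y
    for i in range(config.n_models):
        member_seed = base_seed + i
        if single_class:
            p = float(y[0])
            stump = Tree(
                feature=(LEAF,), threshold=(0.0,), left=(-1,), right=(-1,),
                prob_pos=(p,),
            )
            trees = tuple([stump] * config.trees_per_model)
        else:
            rng = np.random.default_rng(member_seed)
            trees = []
            for _ in range(config.trees_per_model):
                idx = rng.integers(0, n, size=n)  # bootstrap with replacement
                est = DecisionTreeClassifier(
                    max_depth=config.max_depth,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                est.fit(X32[idx], y[idx], check_input=False)
                trees.append(tree_from_sklearn(est, est.classes_))
            trees = tuple(trees)
        members.append(ForestMember(generation=generation, seed=member_seed, trees=trees))
    return Ensemble(members=members, n_features=data.X.shape[1])


def predict_improvement(ensemble: Ensemble, features: np.ndarray) -> np.ndarray:
    """Per-member P(improve).

    For a single feature vector returns shape ``(n_members,)``; for a matrix
    of conditions returns ``(n_members, n_conditions)``.
    """
    features = np.asarray(features, dtype=float)
    single = features.ndim == 1
    X = np.atleast_2d(features)
    if X.shape[1] != ensemble.n_features:
        raise DimensionError(
            f"feature width {X.shape[1]} != training width {ensemble.n_features}"
        )
    out = np.vstack([m.predict_proba(X) for m in ensemble.members])
    return out[:, 0] if single else out


def prune_failed(ensemble: Ensemble, failed: np.ndarray) -> Ensemble:
    """Drop every tree that classifies any failed condition as positive.

    ``failed`` is a feature matrix of conditions observed at or below the
    campaign threshold.  A tree "suggested" a condition when its routed leaf
    probability exceeds 0.5.  Members left with no trees are dropped; with no
    offending trees the ensemble is returned unchanged (identity).
    """
    failed = np.atleast_2d(np.asarray(failed, dtype=float))
    if failed.size == 0:
        return ensemble
    if failed.shape[1] != ensemble.n_features:
        raise DimensionError(
            f"feature width {failed.shape[1]} != training width {ensemble.n_features}"
        )
    new_members = []
    changed = False
    for m in ensemble.members:
        kept = tuple(
            t for t in m.trees if not (t.predict_proba(failed) > 0.5).any()
        )
        if len(kept) == len(m.trees):
            new_members.append(m)
        else:
            changed = True
            if kept:
                new_members.append(replace(m, trees=kept))
    if not changed:
        return ensemble
    return Ensemble(members=new_members, n_features=ensemble.n_features)


def combine(old: Ensemble, new: Ensemble) -> Ensemble:
    """Concatenate two ensembles, preserving order and generation tags."""
    if not old.members:
        return new
    if not new.members:
        return old
    if old.n_features != new.n_features:
        raise DimensionError(
            f"cannot combine ensembles of widths {old.n_features} and {new.n_features}"
        )
    return Ensemble(members=old.members + new.members, n_features=old.n_features)


def descriptor_usage(
    ensemble: Ensemble,
    schema: FeaturizationSchema,
    by_generation: bool = False,
) -> dict:
    """Fraction of split nodes attributable to each reagent class.

    Counts every split node's feature index across the ensemble, maps it to a
    reagent class through the schema and normalizes to fractions summing to 1.
    Leaf-only stumps contribute nothing.  With ``by_generation`` the counts
    are normalized within each generation tag separately.
    """
    class_of = schema.class_of_feature

    def tally(members: Iterable[ForestMember]) -> dict[str, float]:
        counts: dict[str, int] = {}
        for m in members:
            for t in m.trees:
                for f in t.split_features:
                    cls = class_of[f]
                    counts[cls] = counts.get(cls, 0) + 1
        total = sum(counts.values())
        if total == 0:
            return {}
        return {cls: n / total for cls, n in sorted(counts.items())}

    if not by_generation:
        return tally(ensemble.members)
    out: dict[int, dict[str, float]] = {}
    for gen in sorted(set(ensemble.generations)):
        out[gen] = tally(m for m in ensemble.members if m.generation == gen)
    return out
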