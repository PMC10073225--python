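"""SVM-based recursive feature elimination with cross-validated subset-size search.

The selection procedure has three stages:

1. **RFE ranking** (:func:`svm_rfe_rank`) — a linear SVM is trained on the
   current feature set; the features with the smallest absolute weight are
   removed; the model is refit; repeat until the target count remains.
2. **Optimal-k search** (:func:`optimal_k_search`) — for every candidate
   subset size k, RFE-to-k is rerun inside each leave-one-out split on the
   training subjects only and the held-out subject is predicted from the
   k surviving features; the k with the highest mean held-out accuracy
   wins (ties broken toward the smallest k).
3. **Fold voting** (:func:`vote_selection`) — RFE-to-k runs once per
   stratified fold; every feature a fold selects gains one vote; the final
   subset is the top-k features by votes across folds.

Features are z-scored from training subjects within every fit (linear-SVM
weights are scale-sensitive), so no statistic of a held-out subject ever
influences elimination or standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from braingut.features import FeatureMatrix

__all__ = [
    "RFEConfig",
    "VoteTally",
    "SelectionResult",
    "svm_rfe_rank",
    "optimal_k_search",
    "vote_selection",
    "select_features",
    "default_k_grid",
    "loo_split_feature_sets",
]


@dataclass
class RFEConfig:
    """Tunables of the selection procedure.

    ``elimination_step`` features are removed per RFE iteration (1 is the
    classical procedure; larger values trade fidelity for speed).
    ``rfe_scope`` controls whether the optimal-k search reruns RFE inside
    every leave-one-out split (``"split"``, the default) or ranks once on
    all subjects (``"global"``).
    """

    candidate_k_grid: list[int] | None = None  # None → default_k_grid(p)
    elimination_step: int = 1
    svm_cost: float = 1.0
    n_folds: int = 10
    seed: int = 0
    standardize: bool = True
    rfe_scope: str = "split"

    def validate(self, n_features: int | None = None) -> None:
        if self.elimination_step < 1:
            raise ValueError("elimination_step must be >= 1")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.rfe_scope not in ("split", "global"):
            raise ValueError("rfe_scope must be 'split' or 'global'")
        if self.candidate_k_grid is not None:
            grid = self.candidate_k_grid
            if not grid:
                raise ValueError("candidate_k_grid must not be empty")
            if sorted(set(grid)) != list(grid):
                raise ValueError("candidate_k_grid must be strictly increasing")
            if grid[0] < 1 or (n_features is not None and grid[-1] > n_features):
                raise ValueError(f"candidate_k_grid must lie within [1, {n_features}]")


@dataclass
class VoteTally:
    """Per-feature vote counts across the stratified RFE folds."""

    counts: dict[str, int]
    n_folds: int
    target_n: int

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        expected = self.n_folds * self.target_n
        if total != expected:
            raise ValueError(
                f"vote total {total} != n_folds × target_n = {expected}; "
                "each fold must select exactly target_n features"
            )
        bad = {f: v for f, v in self.counts.items() if not 0 <= v <= self.n_folds}
        if bad:
            raise ValueError(f"votes outside [0, n_folds]: {bad}")


@dataclass
class SelectionResult:
    """Output of the full selection procedure."""

    accuracy_curve: dict[int, float]
    optimal_k: int
    votes: VoteTally | None
    final_features: list[str]

    def __post_init__(self) -> None:
        if any(not 0.0 <= a <= 1.0 for a in self.accuracy_curve.values()):
            raise ValueError("accuracy values must lie in [0, 1]")
        best = max(self.accuracy_curve.values())
        if self.accuracy_curve[self.optimal_k] != best:
            raise ValueError("optimal_k must attain the accuracy curve's maximum")


def default_k_grid(n_features: int, max_points: int = 15) -> list[int]:
    """Candidate subset sizes: the full range for small p, else a geometric
    grid densified near small k (where the accuracy curve moves fastest)."""
    if n_features <= 2 * max_points:
        return list(range(1, n_features + 1))
    geo = np.unique(np.round(np.geomspace(1, n_features, max_points)).astype(int))
    grid = sorted(set(geo) | {1, 2, 3, 4, 5})
    return [k for k in grid if 1 <= k <= n_features]


def _as_xy(X: FeatureMatrix | pd.DataFrame, labels=None):
    if isinstance(X, FeatureMatrix):
        return X.values, np.asarray(X.labels)
    if labels is None:
        raise ValueError("labels required when X is a plain table")
    return pd.DataFrame(X), np.asarray(labels)


def _train_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = values.mean(axis=0)
    scale = values.std(axis=0)
    return center, scale


def _fit_svm(values: np.ndarray, y: np.ndarray, config: RFEConfig) -> np.ndarray:
    """Fit a linear SVM and return its weight vector (standardized scale)."""
    if config.standardize:
        center, scale = _train_stats(values)
        values = (values - center) / np.where(scale == 0, 1.0, scale)
    model = SVC(kernel="linear", C=config.svm_cost)
    model.fit(values, y)
    return model.coef_[0]


def _drop_constant(values: pd.DataFrame, warn: bool = True) -> pd.DataFrame:
    """Remove zero-variance features (degenerate under standardization)."""
    const = values.columns[values.std(axis=0) == 0]
    if len(const):
        if warn:
            warnings.warn(f"dropping constant features before RFE: {list(const)}")
        values = values.drop(columns=const)
    return values

def _rfe_survivor_sets(
    values: pd.DataFrame, y: np.ndarray, ks: list[int], config: RFEConfig
) -> tuple[dict[int, list[str]], list[str]]:
    """Run one elimination pass, capturing the survivor set at every requested k.

    Elimination is nested: the survivors at a smaller k are always a subset
    of the survivors at a larger k, so a single pass down to min(ks) yields
    RFE-to-k for every k. Returns ``{k: survivor names}`` (in original
    column order) and the elimination order (first-removed first).
    """
    targets = sorted(set(ks), reverse=True)
    if targets[0] > values.shape[1]:
        raise ValueError(f"k={targets[0]} exceeds {values.shape[1]} features")
    current = list(values.columns)
    eliminated: list[str] = []
    survivors: dict[int, list[str]] = {}
    for k in targets:
        if k == len(current):
            survivors[k] = list(current)
    X = values.to_numpy(dtype=float)
    col_index = {name: i for i, name in enumerate(values.columns)}
    remaining_targets = [k for k in targets if k < len(current)]
    while remaining_targets:
        next_k = remaining_targets[0]
        w = _fit_svm(X[:, [col_index[c] for c in current]], y, config)
        n_drop = min(config.elimination_step, len(current) - next_k)
        # stable argsort: ties in |weight| resolved by column order
        drop_pos = np.argsort(np.abs(w), kind="stable")[:n_drop]
        for pos in sorted(drop_pos, reverse=True):
            eliminated.append(current.pop(pos))
        if len(current) == next_k:
            survivors[next_k] = list(current)
            remaining_targets.pop(0)
    return survivors, eliminated


def svm_rfe_rank(
    X: FeatureMatrix | pd.DataFrame,
    k_target: int,
    config: RFEConfig | None = None,
    labels=None,
) -> tuple[list[str], list[str]]:
    """Recursive feature elimination down to ``k_target`` features.

    Returns ``(survivors, elimination_order)``; the elimination order lists
    the removed features first-removed first and has length
    ``n_features − k_target`` (constant features, dropped before fitting,
    count as eliminated first). Deterministic given inputs.
    """
    config = config or RFEConfig()
    values, y = _as_xy(X, labels)
    config.validate(values.shape[1])
    if not 1 <= k_target <= values.shape[1]:
        raise ValueError(f"k_target must be in [1, {values.shape[1]}]")
    kept = _drop_constant(values)
    pre_dropped = [c for c in values.columns if c not in kept.columns]
    if k_target > kept.shape[1]:
        raise ValueError(
            f"k_target={k_target} exceeds the {kept.shape[1]} non-constant features"
        )
    survivors, eliminated = _rfe_survivor_sets(kept, y, [k_target], config)
    return survivors[k_target], pre_dropped + eliminated


def loo_split_feature_sets(
    X: FeatureMatrix | pd.DataFrame,
    holdout_index: int,
    ks: list[int],
    config: RFEConfig | None = None,
    labels=None,
) -> dict[int, list[str]]:
    """Survivor sets for one leave-one-out split, from training subjects only.

    Exposed so that the no-leakage property (the held-out subject's values
    cannot influence elimination) can be verified directly against
    :func:`svm_rfe_rank` on the reduced data.
    """
    config = config or RFEConfig()
    values, y = _as_xy(X, labels)
    train = np.arange(len(y)) != holdout_index
    kept = _drop_constant(values.iloc[train], warn=False)
    survivors, _ = _rfe_survivor_sets(kept, y[train], ks, config)
    return survivors


def _predict_holdout(
    values: pd.DataFrame, y: np.ndarray, train: np.ndarray, i: int,
    features: list[str], config: RFEConfig,
) -> int:
    Xtr = values.iloc[train][features].to_numpy(dtype=float)
    xte = values.iloc[[i]][features].to_numpy(dtype=float)
    if config.standardize:
        center, scale = _train_stats(Xtr)
        scale = np.where(scale == 0, 1.0, scale)
        Xtr = (Xtr - center) / scale
        xte = (xte - center) / scale
    model = SVC(kernel="linear", C=config.svm_cost)
    model.fit(Xtr, y[train])
    return int(model.predict(xte)[0])


def optimal_k_search(
    X: FeatureMatrix | pd.DataFrame,
    config: RFEConfig | None = None,
    labels=None,
) -> tuple[dict[int, float], int]:
    """Leave-one-out search over candidate subset sizes.

    For every candidate k and every LOO split, features are eliminated to k
    on the n−1 training subjects and the held-out subject is predicted from
    the survivors; the curve value at k is the mean held-out accuracy.
    Returns ``(accuracy_curve, optimal_k)`` with ties broken toward the
    smallest k.
    """
    config = config or RFEConfig()
    values, y = _as_xy(X, labels)
    config.validate()
    ks = config.candidate_k_grid or default_k_grid(values.shape[1])
    if ks[-1] > values.shape[1]:  # shared grids get clamped to this block's width
        ks = [k for k in ks if k <= values.shape[1]]
        if not ks:
            raise ValueError(f"no candidate k within [1, {values.shape[1]}]")
        warnings.warn(f"candidate k grid clamped to {ks} for {values.shape[1]} features")
    n = len(y)
    correct = {k: 0 for k in ks}
    if config.rfe_scope == "global":
        global_sets, _ = _rfe_survivor_sets(_drop_constant(values), y, ks, config)
    for i in range(n):
        train = np.arange(n) != i
        if config.rfe_scope == "split":
            kept = _drop_constant(values.iloc[train], warn=False)
            split_ks = [k for k in ks if k <= kept.shape[1]]
            survivor_sets, _ = _rfe_survivor_sets(kept, y[train], split_ks, config)
        else:
            survivor_sets = global_sets
        for k, features in survivor_sets.items():
            pred = _predict_holdout(values, y, train, i, features, config)
            correct[k] += int(pred == y[i])
    curve = {k: correct[k] / n for k in ks}
    best = max(curve.values())
    optimal_k = min(k for k, a in curve.items() if a == best)
    return curve, optimal_k


def vote_selection(
    X: FeatureMatrix | pd.DataFrame,
    target_n: int,
    config: RFEConfig | None = None,
    labels=None,
) -> tuple[VoteTally, list[str]]:
    """Stratified-fold RFE voting for the final feature subset.

    RFE-to-``target_n`` runs once per fold on the fold's training portion;
    each selected feature gains one vote. The final subset is the top
    ``target_n`` features by votes; ties at the boundary are broken by the
    larger mean |SVM weight| across the folds that selected the feature,
    then by name.
    """
    config = config or RFEConfig()
    values, y = _as_xy(X, labels)
    config.validate(values.shape[1])
    if not 1 <= target_n <= values.shape[1]:
        raise ValueError(f"target_n must be in [1, {values.shape[1]}]")
    class_counts = np.bincount(y)
    if class_counts.min() < config.n_folds:
        raise ValueError(
            f"cannot stratify {config.n_folds} folds with class counts {class_counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    votes: dict[str, int] = {name: 0 for name in values.columns}
    weight_sums: dict[str, float] = {name: 0.0 for name in values.columns}
    for train_idx, _ in skf.split(values, y):
        kept = _drop_constant(values.iloc[train_idx], warn=False)
        survivors, _ = _rfe_survivor_sets(kept, y[train_idx], [target_n], config)
        selected = survivors[target_n]
        w = _fit_svm(kept[selected].to_numpy(dtype=float), y[train_idx], config)
        for name, weight in zip(selected, w):
            votes[name] += 1
            weight_sums[name] += abs(weight)
    tally = VoteTally(counts=dict(votes), n_folds=config.n_folds, target_n=target_n)

    def sort_key(name: str):
        v = votes[name]
        mean_w = weight_sums[name] / v if v else 0.0
        return (-v, -mean_w, name)

    ranked = sorted(values.columns, key=sort_key)
    return tally, sorted(ranked[:target_n], key=list(values.columns).index)


def nested_loo_accuracy(
    X: FeatureMatrix | pd.DataFrame,
    k: int,
    config: RFEConfig | None = None,
    labels=None,
) -> float:
    """Honest LOO accuracy at subset size k with selection rerun per split.

    Unlike evaluating a model on a feature subset that was selected using
    all subjects (which is optimistically biased under the null), this
    estimator re-eliminates to k features inside every leave-one-out split,
    so the held-out subject never influences its own feature set.
    """
    config = config or RFEConfig()
    cfg = RFEConfig(
        candidate_k_grid=[k],
        elimination_step=config.elimination_step,
        svm_cost=config.svm_cost,
        n_folds=config.n_folds,
        seed=config.seed,
        standardize=config.standardize,
    )
    curve, _ = optimal_k_search(X, cfg, labels=labels)
    return curve[k]


def select_features(
    X: FeatureMatrix | pd.DataFrame,
    config: RFEConfig | None = None,
    labels=None,
) -> SelectionResult:
    """Full selection: optimal-k search, then fold voting at the optimal k."""
    config = config or RFEConfig()
    curve, optimal_k = optimal_k_search(X, config, labels=labels)
    tally, final = vote_selection(X, optimal_k, config, labels=labels)
    return SelectionResult(
        accuracy_curve=curve, optimal_k=optimal_k, votes=tally, final_features=final
    )
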