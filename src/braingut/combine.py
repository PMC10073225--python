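"""Combined brain+metabolite model merge and label-permutation validation.

The combined feature set unions, from the final brain and metabolite
models, the features whose standardized |weight| falls in the top fraction
(default 90%) of each block's ranking; covariates never participate in the
ranking. The permutation test retrains the final model on uniformly
shuffled labels and scores it with stratified ten-fold cross-validation,
building an empirical null for the observed accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from braingut.evaluate import TrainedModel, decision_scores, train_linear

__all__ = [
    "MergeSpec",
    "MergeResult",
    "PermutationResult",
    "merge_top_fraction",
    "kfold_accuracy",
    "permutation_test",
]


@dataclass
class MergeSpec:
    """How to merge the two block models' features.

    ``fraction`` keeps the ceiling(fraction × block size) top-|weight|
    ranks per block (ties at the cut are kept together and reported);
    ``count_override`` forces exact per-block counts instead, e.g.
    ``{"brain": 76, "metabolite": 50}``.
    """

    fraction: float = 0.9
    count_override: dict[str, int] | None = None

    def validate(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")


@dataclass
class MergeResult:
    """Merged feature list with per-block provenance and tie report."""

    features: list[str]
    provenance: dict[str, str]  # feature -> block
    kept_per_block: dict[str, int]
    ties_at_cut: dict[str, list[str]] = field(default_factory=dict)


def _top_by_weight(model: TrainedModel, n_keep: int) -> tuple[list[str], list[str]]:
    """Features in the top ``n_keep`` |weight| ranks, ties at the cut included."""
    w = model.selectable_weights.abs().sort_values(ascending=False, kind="stable")
    if n_keep >= len(w):
        return list(w.index), []
    cut = w.iloc[n_keep - 1]
    kept = w[w > cut].index.tolist()
    tied = sorted(w[w == cut].index.tolist())
    return kept + tied, tied if len(kept) + len(tied) > n_keep else []


def merge_top_fraction(
    brain_model: TrainedModel, met_model: TrainedModel, spec: MergeSpec | None = None
) -> MergeResult:
    """Union the top-|weight| fraction of each block model's features."""
    spec = spec or MergeSpec()
    spec.validate()
    blocks = {"brain": brain_model, "metabolite": met_model}
    features: list[str] = []
    provenance: dict[str, str] = {}
    kept_per_block: dict[str, int] = {}
    ties: dict[str, list[str]] = {}
    for block, model in blocks.items():
        size = len(model.selectable_weights)
        if spec.count_override and block in spec.count_override:
            n_keep = spec.count_override[block]
            if n_keep > size:
                raise ValueError(f"count_override[{block!r}]={n_keep} exceeds block size {size}")
        else:
            n_keep = math.ceil(spec.fraction * size)
        kept, tied = _top_by_weight(model, n_keep)
        if tied:
            ties[block] = tied
        kept_per_block[block] = len(kept)
        for f in kept:
            features.append(f)
            provenance[f] = block
    return MergeResult(
        features=features, provenance=provenance,
        kept_per_block=kept_per_block, ties_at_cut=ties,
    )


@dataclass
class PermutationResult:
    """Observed vs. label-shuffled ten-fold CV accuracies."""

    observed_accuracy: float
    permuted_accuracies: list[float]
    empirical_p: float
    seed: int

    def __post_init__(self) -> None:
        accs = [self.observed_accuracy, *self.permuted_accuracies]
        if any(not 0.0 <= a <= 1.0 for a in accs):
            raise ValueError("accuracies must lie in [0, 1]")
        if not 0.0 < self.empirical_p <= 1.0:
            raise ValueError("empirical p must lie in (0, 1]")


def kfold_accuracy(
    design: pd.DataFrame,
    labels,
    family: str = "svm",
    cost: float = 1.0,
    n_folds: int = 10,
    seed: int = 0,
    covariate_names: list[str] | None = None,
) -> float:
    """Stratified k-fold CV accuracy of one linear family (training-only scaling)."""
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(design, y):
        model = train_linear(
            design.iloc[train_idx], y[train_idx], family=family, cost=cost,
            covariate_names=covariate_names,
        )
        preds = (decision_scores(model, design.iloc[test_idx]) > 0).astype(int)
        correct += int((preds == y[test_idx]).sum())
    return correct / len(y)


def permutation_test(
    design: pd.DataFrame,
    labels,
    R: int = 199,
    seed: int = 0,
    family: str = "svm",
    cost: float = 1.0,
    n_folds: int = 10,
    covariate_names: list[str] | None = None,
) -> PermutationResult:
    """Label-permutation null for the final model's ten-fold CV accuracy.

    Each of the R replicates shuffles the labels uniformly, retrains the
    model and records its stratified ten-fold CV accuracy (folds reseeded
    per replicate); the observed accuracy uses the unshuffled labels.
    ``empirical_p = (1 + #{permuted ≥ observed}) / (R + 1)``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = kfold_accuracy(
        design, y, family=family, cost=cost, n_folds=n_folds, seed=seed,
        covariate_names=covariate_names,
    )
    permuted: list[float] = []
    for r in range(R):
        y_perm = rng.permutation(y)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        permuted.append(
            kfold_accuracy(
                design, y_perm, family=family, cost=cost, n_folds=n_folds,
                seed=fold_seed, covariate_names=covariate_names,
            )
        )
    p = (1 + sum(a >= observed for a in permuted)) / (R + 1)
    return PermutationResult(
        observed_accuracy=observed, permuted_accuracies=permuted,
        empirical_p=p, seed=seed,
    )
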