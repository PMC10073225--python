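"""Final linear models and leave-one-out evaluation.

Three linear families are supported — linear-kernel SVM, ridge classifier,
and L2-penalized logistic regression — trained on the selected features
plus covariates (age and sex always; diet whenever the design includes
metabolite features). Evaluation is leave-one-out: the model is refit on
the remaining n−1 subjects (standardization included) and the held-out
subject predicted; the report aggregates all n predictions into a
confusion matrix, accuracy, per-class precision/recall and an ROC curve
built from the retained decision scores.

Protocol caveat: when the feature subset was selected on all subjects (the
voting stage sees every subject), the LOO evaluation of the final model
inherits that selection. Reports carry a ``selection_inherited`` note; for
honest generalization estimates, nest the selection inside each split.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.svm import SVC

from braingut.features import FeatureMatrix

__all__ = [
    "FAMILIES",
    "TrainedModel",
    "EvaluationReport",
    "assemble_design",
    "train_linear",
    "decision_scores",
    "loo_evaluate",
    "precision_recall",
    "roc_points",
]

FAMILIES = ("svm", "ridge", "logistic")

#: blocks whose designs include the diet covariate (metabolite features present)
_DIET_BLOCKS = ("metabolite", "combined")


@dataclass
class TrainedModel:
    """A fitted linear decision rule with its standardization parameters.

    ``weights`` are on the standardized scale; ``center``/``scale`` map raw
    inputs onto that scale, so the raw-space score of subject x is
    ``weights · (x − center)/scale + intercept``. Prediction is
    ``1 if score > 0 else 0`` for every family (for logistic the score is
    the log-odds).
    """

    family: str
    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ValueError("one weight per feature required")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def selectable_weights(self) -> pd.Series:
        """Weights of the non-covariate features (the rankable ones)."""
        keep = [f for f in self.feature_names if f not in self.covariate_names]
        s = pd.Series(self.weights, index=self.feature_names)
        return s[keep]


@dataclass
class EvaluationReport:
    """Aggregated leave-one-out predictions (class 1 = obese = positive)."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: dict[int, float]
    recall: dict[int, float]
    undefined_metrics: list[str]
    roc: pd.DataFrame  # columns threshold, fpr, tpr
    auc: float
    scores: np.ndarray
    predictions: np.ndarray
    family: str
    notes: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __post_init__(self) -> None:
        if any(c < 0 for c in (self.tp, self.fp, self.fn, self.tn)):
            raise ValueError("confusion counts must be nonnegative")
        expected = (self.tp + self.tn) / self.n
        if abs(self.accuracy - expected) > 1e-12:
            raise ValueError("accuracy inconsistent with confusion matrix")


def assemble_design(
    X: FeatureMatrix, selected: list[str], block: str
) -> tuple[pd.DataFrame, list[str]]:
    """Selected features plus covariates as a model matrix.

    Age and sex are always appended; diet is appended iff the block
    includes metabolite features (``"metabolite"`` or ``"combined"``).
    Returns the design and the covariate column names (flagged
    non-selectable downstream).
    """
    if block not in ("brain", *_DIET_BLOCKS):
        raise ValueError(f"unknown block {block!r}")
    missing = [f for f in selected if f not in X.values.columns]
    if missing:
        raise KeyError(f"selected features absent from the matrix: {missing}")
    covs = ["age", "sex"] + (["diet"] if block in _DIET_BLOCKS else [])
    absent = [c for c in covs if c not in X.covariates.columns]
    if absent:
        raise ValueError(f"covariates missing from the cohort table: {absent}")
    design = pd.concat([X.values[selected], X.covariates[covs]], axis=1)
    return design, covs


def _standardize_fit(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale per column; binary 0/1 indicator columns are left raw."""
    values = design.to_numpy(dtype=float)
    center = values.mean(axis=0)
    scale = values.std(axis=0)
    for j, col in enumerate(design.columns):
        uniq = np.unique(values[:, j])
        if set(uniq).issubset({0.0, 1.0}):
            center[j], scale[j] = 0.0, 1.0
        elif scale[j] == 0:
            warnings.warn(f"constant column {col!r}; left unscaled")
            scale[j] = 1.0
    return center, scale


def train_linear(
    design: pd.DataFrame,
    labels,
    family: str = "svm",
    cost: float = 1.0,
    covariate_names: list[str] | None = None,
) -> TrainedModel:
    """Fit one linear family on a standardized design.

    ``cost`` is the SVM/logistic C (inverse regularization) or the ridge
    penalty's inverse (ridge alpha = 1/cost). The fit is deterministic
    given inputs; weights are reported on the standardized scale with the
    standardization parameters stored for raw-scale application.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train")
    center, scale = _standardize_fit(design)
    Z = (design.to_numpy(dtype=float) - center) / scale
    if family == "svm":
        model = SVC(kernel="linear", C=cost)
    elif family == "ridge":
        model = RidgeClassifier(alpha=1.0 / cost)
    elif family == "logistic":
        model = LogisticRegression(C=cost, max_iter=5000)
    else:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    model.fit(Z, y)
    return TrainedModel(
        family=family,
        feature_names=list(design.columns),
        weights=np.atleast_2d(model.coef_)[0],
        intercept=float(np.atleast_1d(model.intercept_)[0]),
        center=center,
        scale=scale,
        covariate_names=list(covariate_names or []),
    )


def decision_scores(model: TrainedModel, design: pd.DataFrame) -> np.ndarray:
    """Signed linear score per subject (margin for SVM/ridge, log-odds for logistic)."""
    Z = (design[model.feature_names].to_numpy(dtype=float) - model.center) / model.scale
    return Z @ model.weights + model.intercept


def precision_recall(tp: int, fp: int, fn: int, tn: int) -> tuple[dict, dict, list[str]]:
    """Per-class precision and recall from a 2×2 confusion matrix.

    Class 1 uses (tp, fp, fn); class 0 is scored with the roles exchanged.
    A 0/0 ratio is reported as NaN and the metric name is listed in the
    returned flags rather than silently coerced to 0.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    precision = {
        1: ratio(tp, tp + fp, "precision[1]"),
        0: ratio(tn, tn + fn, "precision[0]"),
    }
    recall = {
        1: ratio(tp, tp + fn, "recall[1]"),
        0: ratio(tn, tn + fp, "recall[0]"),
    }
    return precision, recall, undefined


def roc_points(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve by threshold sweep over the unique scores, with trapezoidal area.

    Ties in score are grouped; the curve runs from (0, 0) to (1, 1) with
    class 1 as positive.
    """
    y = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thresholds = _roc_curve(y, scores, drop_intermediate=False)
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return roc, float(_auc(fpr, tpr))


def loo_evaluate(
    design: pd.DataFrame,
    labels,
    family: str = "svm",
    cost: float = 1.0,
    covariate_names: list[str] | None = None,
    selection_inherited: bool = True,
) -> EvaluationReport:
    """Leave-one-out evaluation of one linear family.

    Each subject is predicted by a model refit on the other n−1 subjects,
    with standardization re-estimated from those subjects alone; the
    decision scores are retained for the ROC.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out evaluation needs at least 3 subjects")
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        train = np.arange(n) != i
        model = train_linear(
            design.iloc[train], y[train], family=family, cost=cost,
            covariate_names=covariate_names,
        )
        score = decision_scores(model, design.iloc[[i]])[0]
        scores[i] = score
        preds[i] = int(score > 0)
    tp = int(((preds == 1) & (y == 1)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    precision, recall, undefined = precision_recall(tp, fp, fn, tn)
    roc, area = roc_points(scores, y)
    notes = {
        "selection_inherited": selection_inherited,
        "protocol": (
            "feature selection used all subjects; LOO refits the final model only"
            if selection_inherited
            else "fully nested: selection rerun inside every split"
        ),
    }
    return EvaluationReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / n,
        precision=precision, recall=recall, undefined_metrics=undefined,
        roc=roc, auc=area, scores=scores, predictions=preds,
        family=family, notes=notes,
    )
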