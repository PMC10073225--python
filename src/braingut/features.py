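"""Subjects × features container shared by the selection and evaluation stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Covariate columns that are model predictors but never selectable features.
COVARIATE_COLUMNS = ("age", "sex", "diet")


@dataclass
class FeatureMatrix:
    """A labelled feature block with covariates kept apart from selectable features.

    Parameters
    ----------
    values
        Subjects × features table; column names are the feature names.
    labels
        Binary group per subject: 0 = overweight, 1 = obese.
    covariates
        Per-subject covariates (``age`` in years, ``sex`` and ``diet`` as
        0/1 indicators). Covariates are appended to model designs by
        :func:`braingut.evaluate.assemble_design` but are excluded from
        recursive feature elimination.
    """

    values: pd.DataFrame
    labels: pd.Series
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.labels = pd.Series(self.labels, index=self.values.index)
        if not self.covariates.empty:
            self.covariates = self.covariates.loc[self.values.index]
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dups}")
        classes = set(np.unique(self.labels))
        if not classes <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(classes)}")
        if len(classes) < 2:
            raise ValueError("both label classes must be present")
        overlap = set(self.values.columns) & set(COVARIATE_COLUMNS)
        if overlap:
            raise ValueError(f"covariate names used as feature columns: {sorted(overlap)}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, feature_names: list[str]) -> "FeatureMatrix":
        """Restrict to the named features, preserving labels and covariates."""
        missing = [f for f in feature_names if f not in self.values.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return FeatureMatrix(self.values[feature_names], self.labels, self.covariates)
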