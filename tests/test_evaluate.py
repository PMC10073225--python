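"""Final linear models, LOO evaluation, precision/recall, ROC."""

import math

import numpy as np
import pandas as pd
import pytest

from braingut.evaluate import (
    assemble_design,
    decision_scores,
    loo_evaluate,
    precision_recall,
    roc_points,
    train_linear,
)
from conftest import planted_features


class TestAssembleDesign:
    def test_brain_block_adds_age_and_sex(self):
        fm = planted_features(n=20, n_informative=3, n_noise=2, seed=0)
        design, covs = assemble_design(fm, fm.feature_names[:3], "brain")
        assert design.shape[1] == 5  # 3 + age + sex
        assert covs == ["age", "sex"]
        assert "diet" not in design.columns

    def test_metabolite_and_combined_blocks_add_diet(self):
        fm = planted_features(n=20, n_informative=4, n_noise=2, seed=1)
        for block in ("metabolite", "combined"):
            design, covs = assemble_design(fm, fm.feature_names[:4], block)
            assert design.shape[1] == 7  # 4 + age + sex + diet
            assert covs == ["age", "sex", "diet"]

    def test_unknown_feature_listed_in_error(self):
        fm = planted_features(n=20, seed=2)
        with pytest.raises(KeyError, match="ghost"):
            assemble_design(fm, ["inf0", "ghost"], "brain")


class TestTrainLinear:
    def test_weight_vector_width_and_families(self):
        fm = planted_features(n=30, n_informative=2, n_noise=3, seed=3)
        design, covs = assemble_design(fm, fm.feature_names, "metabolite")
        for family in ("svm", "ridge", "logistic"):
            model = train_linear(design, fm.labels, family=family, covariate_names=covs)
            assert len(model.weights) == design.shape[1]
            assert model.family == family
            assert set(model.selectable_weights.index) == set(fm.feature_names)

    def test_separable_duplicate_feature_perfect_training(self):
        y = np.array([0] * 10 + [1] * 10)
        design = pd.DataFrame({"f": y.astype(float), "g": y.astype(float)})
        model = train_linear(design, y, family="svm")
        preds = (decision_scores(model, design) > 0).astype(int)
        assert (preds == y).all()

    def test_ridge_matches_closed_form(self):
        """Ridge weights equal the hand-solved normal equations on the
        standardized design with ±1 targets and unpenalized intercept."""
        rng = np.random.default_rng(4)
        design = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        model = train_linear(design, y, family="ridge", cost=1.0)  # alpha = 1
        Z = (design.to_numpy() - model.center) / model.scale
        t = 2.0 * y - 1.0
        Zc = Z - Z.mean(axis=0)
        tc = t - t.mean()
        w = np.linalg.solve(Zc.T @ Zc + np.eye(2), Zc.T @ tc)
        assert model.weights == pytest.approx(w, abs=1e-8)

    def test_single_class_rejected(self):
        design = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="both classes"):
            train_linear(design, np.zeros(3, dtype=int))

    def test_binary_columns_left_unscaled(self):
        fm = planted_features(n=30, seed=5)
        design, covs = assemble_design(fm, ["inf0"], "metabolite")
        model = train_linear(design, fm.labels, covariate_names=covs)
        j = model.feature_names.index("sex")
        assert model.center[j] == 0.0 and model.scale[j] == 1.0
        j_age = model.feature_names.index("age")
        assert model.scale[j_age] != 1.0


class TestLooEvaluate:
    def test_separable_clusters_perfect_scores(self):
        rng = np.random.default_rng(6)
        n = 30
        y = np.array([0, 1] * (n // 2))
        design = pd.DataFrame({"x": 20.0 * y - 10.0 + rng.normal(size=n)})
        for family in ("svm", "ridge", "logistic"):
            rep = loo_evaluate(design, y, family=family)
            assert rep.accuracy == 1.0
            assert rep.precision[0] == 1.0 and rep.precision[1] == 1.0
            assert rep.auc == 1.0

    def test_confusion_counts_sum_to_n_and_accuracy_identity(self):
        fm = planted_features(n=25, n_informative=1, n_noise=4, effect=1.0, seed=7)
        design, _ = assemble_design(fm, fm.feature_names, "brain")
        rep = loo_evaluate(design, fm.labels)
        assert rep.n == 25
        assert rep.accuracy == pytest.approx(
            float(np.mean(rep.predictions == np.asarray(fm.labels)))
        )

    def test_null_features_near_majority_rate(self):
        """Labels independent of features: LOO accuracy stays near the
        majority-class rate over replicates."""
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n0, n1 = 11, 14
            y = np.array([0] * n0 + [1] * n1)
            y = y[rng.permutation(n0 + n1)]
            design = pd.DataFrame(rng.normal(size=(n0 + n1, 3)), columns=list("abc"))
            accs.append(loo_evaluate(design, y).accuracy)
        assert 0.30 < np.mean(accs) < 0.72  # chance band around 14/25 = 0.56

    def test_refit_excludes_held_out_subject(self):
        """An extreme outlier in the held-out row cannot leak into the model
        that predicts it: that model equals the fit without the row."""
        fm = planted_features(n=20, n_informative=2, n_noise=2, seed=8)
        design, _ = assemble_design(fm, fm.feature_names, "brain")
        design = design.copy()
        i = 3
        design.iloc[i, 0] = 1e6
        y = np.asarray(fm.labels)
        model_without = train_linear(design.drop(design.index[i]), np.delete(y, i))
        rep = loo_evaluate(design, y)
        expected_score = decision_scores(model_without, design.iloc[[i]])[0]
        assert rep.scores[i] == pytest.approx(expected_score)

    def test_three_families_agree_on_separable_cohort(self):
        from braingut.cohort import CohortSpec, generate_cohort
        from braingut.features import FeatureMatrix

        spec = CohortSpec(n_regions=2, n_metabolites=20, edge_density=1.0,
                          informative_metabolites=[0, 1, 2, 3],
                          metabolite_effect=2.5, seed=12)
        cohort = generate_cohort(spec)
        fm = FeatureMatrix(
            np.log(cohort.metabolite_table), cohort.labels, cohort.covariates
        )
        design, covs = assemble_design(fm, cohort.truth["metabolites"], "metabolite")
        accs = {
            fam: loo_evaluate(design, fm.labels, family=fam, covariate_names=covs).accuracy
            for fam in ("svm", "ridge", "logistic")
        }
        assert max(accs.values()) - min(accs.values()) <= 0.05


class TestPrecisionRecall:
    def test_direct_formula(self):
        precision, recall, undefined = precision_recall(tp=9, fp=1, fn=3, tn=7)
        assert precision[1] == pytest.approx(0.9)
        assert recall[1] == pytest.approx(0.75)
        assert precision[0] == pytest.approx(0.7)
        assert undefined == []

    def test_degenerate_zero_over_zero_flagged(self):
        precision, recall, undefined = precision_recall(tp=0, fp=0, fn=0, tn=5)
        assert math.isnan(recall[1])
        assert "recall[1]" in undefined and "precision[1]" in undefined

    def test_label_swap_symmetry(self):
        p1, r1, _ = precision_recall(tp=8, fp=2, fn=3, tn=7)
        p2, r2, _ = precision_recall(tp=7, fp=3, fn=2, tn=8)  # classes exchanged
        assert p1[1] == p2[0] and r1[1] == r2[0]
        assert p1[0] == p2[1] and r1[0] == r2[1]


class TestRoc:
    def test_scores_equal_labels_area_one(self):
        y = np.array([0, 1, 1, 0, 1])
        roc, area = roc_points(y.astype(float), y)
        assert area == 1.0
        assert roc["fpr"].iloc[0] == 0.0 and roc["tpr"].iloc[-1] == 1.0

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        roc, _ = roc_points(rng.normal(size=30), y)
        assert (roc["fpr"].diff().dropna() >= 0).all()
        assert (roc["tpr"].diff().dropna() >= 0).all()
        assert (roc[["fpr", "tpr"]].iloc[0] == 0).all()
        assert (roc[["fpr", "tpr"]].iloc[-1] == 1).all()

    def test_sign_reversal_maps_area(self):
        rng = np.random.default_rng(10)
        y = np.array([0, 1] * 15)
        s = rng.normal(size=30) + 0.8 * y
        _, a = roc_points(s, y)
        _, a_rev = roc_points(-s, y)
        assert a_rev == pytest.approx(1.0 - a)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(11)
        areas = [
            roc_points(rng.normal(size=40), np.array([0, 1] * 20))[1] for _ in range(20)
        ]
        assert np.mean(areas) == pytest.approx(0.5, abs=0.08)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_points(np.ones(3), np.ones(3, dtype=int))
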