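import itertools

import numpy as np
import pandas as pd
import pytest

from epihub import clf
from epihub.data import ExpressionData


def cloud_expr(n_pos=15, n_neg=15, d=10, sep=6.0, seed=0):
    """Two Gaussian clouds, linearly separable when sep is large."""
    rng = np.random.default_rng(seed)
    x = np.hstack(
        [
            rng.normal(0, 1, size=(d, n_pos)) + sep,
            rng.normal(0, 1, size=(d, n_neg)),
        ]
    )
    cols = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    values = pd.DataFrame(x, index=[f"g{i}" for i in range(d)], columns=cols)
    meta = pd.DataFrame(
        {"condition": ["GDM"] * n_pos + ["control"] * n_neg},
        index=values.columns,
    )
    return ExpressionData(values=values, samples=meta, level="gene")


class TestSplitSamples:
    def meta(self, n_pos=30, n_neg=25):
        return pd.DataFrame(
            {"condition": ["GDM"] * n_pos + ["control"] * n_neg},
            index=[f"s{i}" for i in range(n_pos + n_neg)],
        )

    def test_deterministic_given_seed(self):
        meta = self.meta()
        a = clf.split_samples(meta, {"GDM": 15, "control": 12}, seed=7)
        b = clf.split_samples(meta, {"GDM": 15, "control": 12}, seed=7)
        assert a == b

    def test_study_shape_counts(self):
        # 15/12 training from 30 GDM / 25 control leaves 15 GDM / 13 control
        split = clf.split_samples(self.meta(), {"GDM": 15, "control": 12}, 1)
        meta = self.meta()
        val_cond = meta.loc[list(split.validation), "condition"]
        assert len(split.train) == 27 and len(split.validation) == 28
        assert (val_cond == "GDM").sum() == 15
        assert (val_cond == "control").sum() == 13

    def test_no_leftover_validation_rejected(self):
        with pytest.raises(ValueError):
            clf.split_samples(self.meta(4, 4), {"GDM": 4, "control": 2}, 0)


class TestTrainSvm:
    def test_separable_clouds_perfect_cv(self):
        expr = cloud_expr()
        model = clf.train_svm(expr, list(expr.values.index), seed=0)
        assert model.cv_accuracy == 1.0

    def test_training_evaluation_perfect_on_separable(self):
        expr = cloud_expr()
        model = clf.train_svm(expr, list(expr.values.index), seed=0)
        report = clf.evaluate(model, expr)
        assert report.accuracy == 1.0 and report.auc == 1.0

    def test_permuted_labels_near_chance(self):
        expr = cloud_expr(sep=6.0, n_pos=14, n_neg=14)
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            permuted = expr.samples.copy()
            permuted["condition"] = rng.permutation(
                permuted["condition"].to_numpy()
            )
            shuffled = ExpressionData(
                values=expr.values, samples=permuted, level="gene"
            )
            model = clf.train_svm(
                shuffled, list(expr.values.index), seed=seed
            )
            accs.append(model.cv_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_single_class_rejected(self):
        expr = cloud_expr(n_neg=0, n_pos=12)
        with pytest.raises(ValueError):
            clf.train_svm(expr, list(expr.values.index), seed=0)

    def test_missing_feature_gene_rejected(self):
        expr = cloud_expr()
        model = clf.train_svm(expr, list(expr.values.index), seed=0)
        other = cloud_expr(d=3)
        with pytest.raises(KeyError):
            model.decision_scores(other)


def concordance_auc(scores, labels):
    """Oracle: exhaustive pairwise concordance with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRankAuc:
    def test_perfect_ordering(self):
        assert clf.rank_auc([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_hand_computed_partial(self):
        # positives [0.9, 0.6], negatives [0.7, 0.5]: 3 of 4 pairs concordant
        assert clf.rank_auc([0.9, 0.6, 0.7, 0.5], [1, 1, 0, 0]) == 0.75

    def test_all_tied_is_half(self):
        assert clf.rank_auc([1, 1, 1, 1], [1, 1, 0, 0]) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        scores = rng.integers(0, 6, size=n).astype(float)  # many ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert clf.rank_auc(scores, labels) == pytest.approx(
            concordance_auc(scores, labels), abs=1e-12
        )


class TestEvalReport:
    def test_confusion_identities(self):
        expr = cloud_expr(sep=1.0, seed=3)
        model = clf.train_svm(expr, list(expr.values.index), seed=1)
        rep = clf.evaluate(model, expr)
        assert rep.tp + rep.fn == 15
        assert rep.tn + rep.fp == 15
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / 30)
        assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))

    def test_roc_starts_at_origin_ends_at_one(self):
        expr = cloud_expr(sep=1.0, seed=4)
        model = clf.train_svm(expr, list(expr.values.index), seed=1)
        roc = clf.evaluate(model, expr).roc
        assert roc.iloc[0]["fpr"] == 0 and roc.iloc[0]["tpr"] == 0
        assert roc.iloc[-1]["fpr"] == 1 and roc.iloc[-1]["tpr"] == 1
        assert roc["fpr"].is_monotonic_increasing


class TestStabilityResample:
    def test_all_normal_predictions_mass_at_zero(self):
        expr = cloud_expr(n_pos=10, n_neg=20, sep=8.0, seed=5)
        model = clf.train_svm(expr, list(expr.values.index), seed=0)
        normals = expr.subset_samples(
            expr.samples.index[expr.samples["condition"] == "control"]
        )
        hist = clf.stability_resample(model, normals, reps=50, seed=0)
        assert hist == {0: 50}

    def test_frac_one_removes_resampling_variance(self):
        expr = cloud_expr(n_pos=10, n_neg=12, sep=0.5, seed=6)
        model = clf.train_svm(expr, list(expr.values.index), seed=0)
        normals = expr.subset_samples(
            expr.samples.index[expr.samples["condition"] == "control"]
        )
        hist = clf.stability_resample(model, normals, frac=1.0, reps=30, seed=0)
        assert len(hist) == 1


class TestCompareCovariates:
    def test_confounded_covariate_strongly_separated(self):
        expr = cloud_expr(n_pos=40, n_neg=40, sep=4.0, seed=7)
        model = clf.train_svm(expr, list(expr.values.index), seed=0)
        scores = model.decision_scores(expr)
        predictions = model.predict(expr)
        covar = pd.DataFrame({"score_like": scores})
        out = clf.compare_covariates(predictions, covar).iloc[0]
        assert out["computable"]
        assert out["p"] < 1e-6
        assert out["mean_pred_GDM"] > out["mean_pred_normal"]

    def test_empty_predicted_group_not_computable(self):
        predictions = pd.Series(["GDM", "GDM"], index=["a", "b"])
        covar = pd.DataFrame({"age": [30.0, 31.0]}, index=["a", "b"])
        out = clf.compare_covariates(predictions, covar).iloc[0]
        assert not out["computable"]


def test_model_json_round_trip(tmp_path):
    expr = cloud_expr()
    model = clf.train_svm(expr, list(expr.values.index), seed=0)
    path = tmp_path / "model.json"
    clf.save_model_json(model, path)
    import json

    loaded = json.loads(path.read_text())
    assert loaded["genes"] == model.genes
    assert len(loaded["weights"]) == len(model.genes)
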