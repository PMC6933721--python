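"""SVM diagnostic classifier over hub-gene expression.

Workflow: a seeded random split of the cohort into training and validation
sets, a linear-kernel SVM on z-scaled hub-gene expression with the cost
parameter chosen from a small grid by stratified ten-fold cross-validation,
confusion/ROC evaluation with GDM as the positive class, external-cohort
prediction, repeated-subsample stability of the predictions on known
normals, and covariate comparison between predicted groups.

The AUC is the rank (Mann-Whitney) statistic: the probability that a random
case scores above a random control, with half credit for ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import cohort_stats
from .data import ExpressionData

POSITIVE = "GDM"
NEGATIVE = "control"
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class SplitSpec:
    """A train/validation partition of the cohort sample ids."""

    train: tuple[str, ...]
    validation: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.validation):
            raise ValueError("train and validation sets overlap")


def split_samples(
    samples: pd.DataFrame, train_counts: dict[str, int], seed: int
) -> SplitSpec:
    """Uniform per-class random draw of the training set; rest is validation.

    ``train_counts`` maps condition label to the number of training samples
    to draw from that class. Both parts must end up with both classes.
    """
    rng = np.random.default_rng(seed)
    train: list[str] = []
    validation: list[str] = []
    for label in (POSITIVE, NEGATIVE):
        ids = list(samples.index[samples["condition"] == label])
        want = train_counts.get(label, 0)
        if not 0 < want < len(ids):
            raise ValueError(
                f"infeasible training count {want} for class {label!r} "
                f"with {len(ids)} samples"
            )
        chosen = rng.choice(len(ids), size=want, replace=False)
        chosen_set = set(chosen.tolist())
        train += [s for i, s in enumerate(ids) if i in chosen_set]
        validation += [s for i, s in enumerate(ids) if i not in chosen_set]
    return SplitSpec(tuple(train), tuple(validation), seed)


@dataclass
class SVMModel:
    """A trained linear SVM plus its feature list and z-scaler."""

    genes: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    svc: SVC
    cv_accuracy: float
    cv_fold_accuracies: list[float] = field(default_factory=list)
    C: float = 1.0

    def _features(self, expr: ExpressionData, sample_ids) -> np.ndarray:
        missing = [g for g in self.genes if g not in expr.values.index]
        if missing:
            raise KeyError(f"expression matrix lacks model genes: {missing}")
        x = expr.values.loc[self.genes, list(sample_ids)].to_numpy(dtype=float).T
        return (x - self.scaler_mean) / self.scaler_sd

    def decision_scores(self, expr: ExpressionData, sample_ids=None) -> pd.Series:
        ids = list(expr.sample_ids if sample_ids is None else sample_ids)
        scores = self.svc.decision_function(self._features(expr, ids))
        return pd.Series(scores, index=pd.Index(ids, name="sample_id"))

    def predict(self, expr: ExpressionData, sample_ids=None) -> pd.Series:
        scores = self.decision_scores(expr, sample_ids)
        return scores.map(lambda s: POSITIVE if s > 0 else NEGATIVE)

    def to_json_dict(self) -> dict:
        return {
            "genes": self.genes,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "kernel": self.svc.kernel,
            "C": self.C,
            "weights": self.svc.coef_.ravel().tolist(),
            "intercept": float(self.svc.intercept_[0]),
            "cv_accuracy": self.cv_accuracy,
            "cv_fold_accuracies": self.cv_fold_accuracies,
        }


def _cv_accuracy(x, y, C, folds, seed) -> list[float]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(x, y):
        svc = SVC(kernel="linear", C=C)
        svc.fit(x[tr], y[tr])
        accs.append(float((svc.predict(x[te]) == y[te]).mean()))
    return accs


def train_svm(
    expr: ExpressionData,
    genes,
    sample_ids=None,
    folds: int = 10,
    seed: int = 0,
    c_grid=DEFAULT_C_GRID,
) -> SVMModel:
    """Train a linear SVM on z-scaled expression of ``genes``.

    The cost parameter is chosen from ``c_grid`` by stratified ``folds``-fold
    cross-validated accuracy (seeded fold assignment; ties favour the
    smaller C); the reported ``cv_accuracy`` is the winning grid point's
    mean fold accuracy. The z-scaler is learned on the training samples
    only.
    """
    ids = list(expr.sample_ids if sample_ids is None else sample_ids)
    if len(ids) < folds:
        raise ValueError("fewer training samples than folds")
    genes = list(genes)
    labels = expr.condition_of(ids).to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes")
    x_raw = expr.values.loc[genes, ids].to_numpy(dtype=float).T
    mean = x_raw.mean(axis=0)
    sd = x_raw.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    x = (x_raw - mean) / sd
    y = (labels == POSITIVE).astype(int)
    best = None
    for C in c_grid:
        fold_accs = _cv_accuracy(x, y, C, folds, seed)
        score = float(np.mean(fold_accs))
        if best is None or score > best[0]:
            best = (score, C, fold_accs)
    cv_accuracy, C, fold_accs = best
    svc = SVC(kernel="linear", C=C)
    svc.fit(x, y)
    return SVMModel(
        genes=genes,
        scaler_mean=mean,
        scaler_sd=sd,
        svc=svc,
        cv_accuracy=cv_accuracy,
        cv_fold_accuracies=fold_accs,
        C=C,
    )


def rank_auc(scores, labels) -> float:
    """Mann-Whitney AUC with half credit for ties.

    ``labels`` are booleans (True = positive). Equals the probability that
    a uniformly drawn positive outscores a uniformly drawn negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR) pairs swept over all distinct decision thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    n_pos = max(int(labels.sum()), 1)
    n_neg = max(int((~labels).sum()), 1)
    tps = np.cumsum(l)
    fps = np.cumsum(~l)
    # collapse runs of equal scores to their last index
    distinct = np.r_[np.where(np.diff(s))[0], s.size - 1]
    frame = pd.DataFrame(
        {
            "threshold": s[distinct],
            "fpr": fps[distinct] / n_neg,
            "tpr": tps[distinct] / n_pos,
        }
    )
    origin = pd.DataFrame({"threshold": [np.inf], "fpr": [0.0], "tpr": [0.0]})
    return pd.concat([origin, frame], ignore_index=True)


@dataclass
class EvalReport:
    """Confusion counts and threshold-free metrics for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    roc: pd.DataFrame

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def evaluate(model: SVMModel, expr: ExpressionData, sample_ids=None) -> EvalReport:
    """Confusion counts at the decision threshold, plus ROC and rank AUC."""
    ids = list(expr.sample_ids if sample_ids is None else sample_ids)
    scores = model.decision_scores(expr, ids).to_numpy()
    truth = expr.condition_of(ids).to_numpy() == POSITIVE
    pred = scores > 0
    return EvalReport(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        auc=rank_auc(scores, truth),
        roc=roc_points(scores, truth),
    )


def stability_resample(
    model: SVMModel,
    normal_expr: ExpressionData,
    frac: float = 0.5,
    reps: int = 1000,
    seed: int = 0,
) -> dict[int, int]:
    """Histogram of predicted-GDM counts over repeated normal-only subsamples.

    Each rep draws floor(frac * n) known-normal samples without replacement
    and counts how many the model misclassifies as GDM. A stable classifier
    puts most mass at zero.
    """
    ids = list(normal_expr.sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 normal samples")
    size = int(np.floor(frac * len(ids)))
    if size < 1:
        raise ValueError("subsample size is zero")
    rng = np.random.default_rng(seed)
    pred_gdm = (model.decision_scores(normal_expr).to_numpy() > 0).astype(int)
    hist: dict[int, int] = {}
    for _ in range(reps):
        idx = rng.choice(len(ids), size=size, replace=False)
        count = int(pred_gdm[idx].sum())
        hist[count] = hist.get(count, 0) + 1
    return dict(sorted(hist.items()))


def compare_covariates(
    predictions: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Two-sample t-test per covariate between predicted-GDM and predicted-normal."""
    rows = []
    for var in covariates.columns:
        values = covariates.loc[predictions.index, var]
        a = values[predictions == POSITIVE].dropna()
        b = values[predictions == NEGATIVE].dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append({"covariate": var, "computable": False,
                         "mean_pred_GDM": np.nan, "mean_pred_normal": np.nan,
                         "t": np.nan, "p": np.nan})
            continue
        t, df, p = cohort_stats.t_test_raw(a, b)
        rows.append(
            {
                "covariate": var,
                "computable": True,
                "mean_pred_GDM": float(a.mean()),
                "mean_pred_normal": float(b.mean()),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def save_model_json(model: SVMModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_json_dict(), fh, indent=2)


class _LinearDecision:
    """Decision function rebuilt from serialised linear-SVM weights."""

    kernel = "linear"

    def __init__(self, weights, intercept):
        self.coef_ = np.asarray(weights, dtype=float).reshape(1, -1)
        self.intercept_ = np.asarray([intercept], dtype=float)

    def decision_function(self, x):
        return x @ self.coef_.ravel() + self.intercept_[0]


def load_model_json(path) -> SVMModel:
    """Rehydrate a linear model saved by :func:`save_model_json`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("kernel") != "linear":
        raise ValueError("only linear models can be rehydrated from JSON")
    return SVMModel(
        genes=payload["genes"],
        scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
        scaler_sd=np.asarray(payload["scaler_sd"], dtype=float),
        svc=_LinearDecision(payload["weights"], payload["intercept"]),
        cv_accuracy=payload["cv_accuracy"],
        cv_fold_accuracies=payload.get("cv_fold_accuracies", []),
        C=payload.get("C", 1.0),
    )
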