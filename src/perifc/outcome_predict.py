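"""Leave-one-out SVM prediction of survival group and KPS change.

Each subject is summarized by a fixed, low-dimensional feature vector derived
from their connectivity difference map (a cohort of a dozen subjects cannot
support high-dimensional features): mean perilesional whole-brain z, mean
contralateral whole-brain z, their difference (the subject metric), the SD of
the difference-map entries, and the fraction of negative entries.  A
``metric_only`` switch restricts to the scalar metric alone.

Classification (survival above/below the cutoff, positive class = long
survival coded 1) uses a Gaussian-kernel SVM with fixed hyperparameters
C = 1 and kernel width 1/n_features on standardized inputs; regression of the
KPS change uses either a Gaussian-kernel SVR or ordinary linear regression on
identical folds.  Standardization statistics are computed inside each
training fold only — the held-out subject never influences the model that
predicts it — and there is no inner tuning loop, which would be
leakage-prone at this sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVC, SVR

from .cohort_stats import spearman
from .connectivity import DifferenceMap

FEATURE_NAMES_SUMMARY5 = (
    "mean_peri_z",
    "mean_contra_z",
    "subject_metric",
    "entry_sd",
    "frac_negative",
)


class PredictError(Exception):
    """Base class for prediction failures."""


def build_features(
    diffmaps: Sequence[DifferenceMap],
    feature_set: str = "summary5",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Deterministic, order-preserving per-subject feature table."""
    rows = []
    for dm in diffmaps:
        vals = np.asarray(list(dm.entries.values()), dtype=float)
        zp = float(np.mean(list(dm.z_peri.values())))
        zc = float(np.mean(list(dm.z_contra.values())))
        row = {
            "mean_peri_z": zp,
            "mean_contra_z": zc,
            "subject_metric": dm.subject_metric,
            "entry_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "frac_negative": float(np.mean(vals < 0)),
        }
        rows.append(row)
    if feature_set == "summary5":
        names = FEATURE_NAMES_SUMMARY5
    elif feature_set == "metric_only":
        names = ("subject_metric",)
    else:
        raise ValueError(f"unknown feature_set {feature_set!r}")
    X = np.asarray([[r[n] for n in names] for r in rows], dtype=float)
    if X.size and not np.isfinite(X).all():
        raise PredictError("non-finite feature value")
    return X, names


def _fold_standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


@dataclass
class LoocvClassReport:
    accuracy: float
    tpr: float
    fpr: float
    tnr: float
    fnr: float
    predictions: np.ndarray
    labels: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "tnr": self.tnr,
            "fnr": self.fnr,
            "predictions": [int(v) for v in self.predictions],
            "labels": [int(v) for v in self.labels],
        }


@dataclass
class LoocvRegReport:
    predictions: np.ndarray
    targets: np.ndarray
    abs_error_mean: float
    abs_error_sd: float
    spearman_rho_true_vs_pred: float
    spearman_p: float
    model: str

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "predictions": [float(v) for v in self.predictions],
            "targets": [float(v) for v in self.targets],
            "abs_error_mean": self.abs_error_mean,
            "abs_error_sd": self.abs_error_sd,
            "spearman_rho_true_vs_pred": self.spearman_rho_true_vs_pred,
            "spearman_p": self.spearman_p,
        }


def loocv_classify(
    features: np.ndarray,
    labels: Sequence[int],
    svm_c: float = 1.0,
    svm_gamma: float | None = None,
) -> LoocvClassReport:
    """Leave-one-out Gaussian-kernel SVM classification with fold-internal scaling.

    ``svm_gamma=None`` means 1/n_features on the standardized inputs.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=int)
    n = X.shape[0]
    if n < 4:
        raise PredictError("LOOCV needs at least 4 subjects")
    if y.size != n:
        raise PredictError("labels do not match feature rows")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise PredictError("need two classes with at least 2 members each")
    gamma = svm_gamma if svm_gamma is not None else 1.0 / X.shape[1]
    preds = np.empty(n, dtype=int)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, Xte = _fold_standardize(X[tr], X[[i]])
        clf = SVC(C=svm_c, kernel="rbf", gamma=gamma)
        clf.fit(Xtr, y[tr])
        preds[i] = int(clf.predict(Xte)[0])
    pos = y == 1
    neg = y == 0
    tp = int(((preds == 1) & pos).sum())
    fn = int(((preds == 0) & pos).sum())
    tn = int(((preds == 0) & neg).sum())
    fp = int(((preds == 1) & neg).sum())
    return LoocvClassReport(
        accuracy=float((preds == y).mean()),
        tpr=tp / pos.sum() if pos.any() else float("nan"),
        fnr=fn / pos.sum() if pos.any() else float("nan"),
        tnr=tn / neg.sum() if neg.any() else float("nan"),
        fpr=fp / neg.sum() if neg.any() else float("nan"),
        predictions=preds,
        labels=y,
    )


def loocv_regress(
    features: np.ndarray,
    targets: Sequence[float],
    model: str = "svm_rbf",
    svm_c: float = 1.0,
    svm_gamma: float | None = None,
) -> LoocvRegReport:
    """Leave-one-out regression of KPS change on connectivity features.

    Features and target are standardized with training-fold statistics; the
    prediction is mapped back to the target scale.  ``model`` selects the
    Gaussian-kernel SVR or ordinary linear regression on identical folds.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise PredictError("LOOCV needs at least 4 subjects")
    if y.size != n:
        raise PredictError("targets do not match feature rows")
    if model not in ("svm_rbf", "linear"):
        raise ValueError(f"model must be 'svm_rbf' or 'linear', got {model!r}")
    gamma = svm_gamma if svm_gamma is not None else 1.0 / X.shape[1]
    preds = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        sd_y = ytr.std(ddof=0)
        if sd_y == 0:
            raise PredictError("zero target variance in a training fold")
        Xtr, Xte = _fold_standardize(X[tr], X[[i]])
        ytr_s = (ytr - ytr.mean()) / sd_y
        if model == "svm_rbf":
            reg = SVR(C=svm_c, kernel="rbf", gamma=gamma)
        else:
            reg = LinearRegression()
        reg.fit(Xtr, ytr_s)
        preds[i] = float(reg.predict(Xte)[0]) * sd_y + ytr.mean()
    abs_err = np.abs(preds - y)
    rho, p = spearman(y, preds)
    return LoocvRegReport(
        predictions=preds,
        targets=y,
        abs_error_mean=float(abs_err.mean()),
        abs_error_sd=float(abs_err.std(ddof=1)),
        spearman_rho_true_vs_pred=rho,
        spearman_p=p,
        model=model,
    )
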