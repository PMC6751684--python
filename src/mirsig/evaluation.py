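"""Evaluation battery: repeated stratified-CV accuracy, per-class accuracy,
binary task construction, paired statistical comparison, cross-dataset mode.

"Accuracy" throughout is the plain fraction of correct predictions (micro
accuracy); per-class accuracy is the recall of each class, reported
separately. Standardization is always fitted on the training partition of a
fold and applied to the held-out fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._classifiers import make_classifier
from .io import Standardizer, stratified_folds

__all__ = [
    "CVReport",
    "repeated_cv_accuracy",
    "per_class_accuracy",
    "build_binary_task",
    "paired_comparison",
    "cross_dataset_accuracy",
]


@dataclass
class CVReport:
    """Per-fold accuracies of one classifier family on one feature set."""

    family: str
    feature_set: str
    accuracies: np.ndarray  # shape (n_repeats, n_folds)
    per_class: pd.Series
    seed: int

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=0))

    def summary(self) -> str:
        return (
            f"{self.family} on {self.feature_set}: "
            f"accuracy {self.mean:.4f} ± {self.sd:.4f} "
            f"({self.accuracies.shape[0]}x{self.accuracies.shape[1]} stratified CV)"
        )

    def to_frame(self) -> pd.DataFrame:
        n_rep, n_folds = self.accuracies.shape
        return pd.DataFrame(
            {
                "repeat": np.repeat(np.arange(n_rep), n_folds),
                "fold": np.tile(np.arange(n_folds), n_rep),
                "accuracy": self.accuracies.ravel(),
            }
        )

    def save_json(self, path) -> None:
        payload = {
            "family": self.family,
            "feature_set": self.feature_set,
            "seed": self.seed,
            "mean": self.mean,
            "sd": self.sd,
            "accuracies": self.accuracies.tolist(),
            "per_class": {str(k): (None if pd.isna(v) else v) for k, v in self.per_class.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def per_class_accuracy(predictions, truths, classes=None) -> pd.Series:
    """Recall per class: fraction of true-class-c samples predicted as c.

    Classes with zero truth samples are reported as missing (NaN).
    """
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if len(pred) != len(true):
        raise ValueError("predictions and truths must be aligned")
    if classes is None:
        classes = np.unique(true)
    out = {}
    for c in classes:
        mask = true == c
        out[c] = float((pred[mask] == c).mean()) if mask.any() else np.nan
    return pd.Series(out)


def repeated_cv_accuracy(
    X: pd.DataFrame,
    y,
    family: str,
    feature_subset=None,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    n_estimators: int = 300,
    max_iter: int = 1000,
) -> CVReport:
    """Mean ± SD accuracy of one classifier family over repeated stratified CV.

    Each repeat draws fresh stratified folds; each fold standardizes on its
    training partition only. ``feature_subset=None`` uses every feature.
    """
    y = np.asarray(y)
    cols = list(X.columns) if feature_subset is None else list(feature_subset)
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"feature subset not in matrix: {missing[:5]}")
    values = X[cols]
    accs = np.zeros((n_repeats, n_folds))
    pred_all: list[np.ndarray] = []
    true_all: list[np.ndarray] = []
    for rep in range(n_repeats):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))
        fold_index = stratified_folds(y, n_folds, rep_seed)
        for fold in range(n_folds):
            tr = fold_index != fold
            te = ~tr
            scaler = Standardizer().fit(values.iloc[tr])
            clf = make_classifier(
                family, rep_seed + fold, n_estimators=n_estimators, max_iter=max_iter
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(scaler.transform(values.iloc[tr]).to_numpy(), y[tr])
                pred = clf.predict(scaler.transform(values.iloc[te]).to_numpy())
            accs[rep, fold] = float((pred == y[te]).mean())
            pred_all.append(pred)
            true_all.append(y[te])
    per_class = per_class_accuracy(np.concatenate(pred_all), np.concatenate(true_all))
    label = "all_features" if feature_subset is None else f"subset[{len(cols)}]"
    return CVReport(family, label, accs, per_class, seed)


def build_binary_task(labels: pd.DataFrame, positive, name: str = "positive") -> pd.Series:
    """Two-class labels from a per-sample predicate (e.g. TT-vs-NT, TNBC-vs-rest).

    ``positive`` is a callable applied to each label row, or a column/value
    pair ``(column, value)``. Both resulting classes must be non-empty.
    """
    if isinstance(positive, tuple):
        col, val = positive
        mask = labels[col] == val
    else:
        mask = labels.apply(positive, axis=1).astype(bool)
    binary = pd.Series(np.where(mask, name, f"not_{name}"), index=labels.index)
    counts = binary.value_counts()
    if len(counts) < 2:
        raise ValueError("binary task is degenerate: one class is empty")
    binary.attrs["counts"] = {str(k): int(v) for k, v in counts.items()}
    return binary


def paired_comparison(report_a: CVReport, report_b: CVReport, test: str = "paired_t") -> dict:
    """Two-sided comparison of two per-fold accuracy samples.

    ``paired_t`` pairs fold-by-fold (requires aligned fold structure);
    ``ks`` compares the two accuracy distributions. A paired-t with zero
    variance of the differences is reported with a degenerate flag instead of
    failing.
    """
    a = report_a.accuracies.ravel()
    b = report_b.accuracies.ravel()
    if test == "paired_t":
        if a.shape != b.shape:
            raise ValueError("paired t-test requires aligned per-fold accuracies")
        diff = a - b
        degenerate = bool(np.allclose(diff, diff[0]))
        if degenerate:
            stat, p = (np.nan, 1.0 if np.allclose(diff, 0) else 0.0)
        else:
            stat, p = stats.ttest_rel(a, b)
        return {
            "test": "paired_t",
            "statistic": float(stat) if np.isfinite(stat) else None,
            "p_value": float(p),
            "mean_difference": float(diff.mean()),
            "degenerate_variance": degenerate,
        }
    if test == "ks":
        stat, p = stats.ks_2samp(a, b)
        return {
            "test": "ks",
            "statistic": float(stat),
            "p_value": float(p),
            "mean_difference": float(a.mean() - b.mean()),
            "degenerate_variance": False,
        }
    raise ValueError("test must be 'paired_t' or 'ks'")


def cross_dataset_accuracy(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    family: str,
    feature_subset=None,
    seed: int = 0,
    n_estimators: int = 300,
    max_iter: int = 1000,
) -> dict:
    """Train on one matrix, test on another (the cross-platform validation mode).

    The usable features are the intersection of both matrices (and of the
    subset if given); the count is reported so a reduced overlap — 98 or 75
    of 100 in the cross-platform study — is visible.
    """
    common = [c for c in X_train.columns if c in set(X_test.columns)]
    if feature_subset is not None:
        wanted = set(feature_subset)
        common = [c for c in common if c in wanted]
    if not common:
        raise ValueError("no common features between train and test matrices")
    scaler = Standardizer().fit(X_train[common])
    clf = make_classifier(family, seed, n_estimators=n_estimators, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(scaler.transform(X_train[common]).to_numpy(), np.asarray(y_train))
        pred = clf.predict(scaler.transform(X_test[common]).to_numpy())
    y_test = np.asarray(y_test)
    return {
        "family": family,
        "common_features": len(common),
        "accuracy": float((pred == y_test).mean()),
        "per_class": per_class_accuracy(pred, y_test).to_dict(),
    }
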