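"""Comparison feature selectors: UFS, RFE, LASSO / elastic net, EFS-CLA, random.

All selectors share the same contract: given a samples × features expression
matrix and class labels, return exactly ``min(k, n_features)`` unique feature
names, plus whatever per-feature score the method defines and the number of
internal classifier fits it spent. Inputs are standardized internally (whole
matrix; selection is not an out-of-sample evaluation).

* UFS — univariate selection by the one-way ANOVA F statistic.
* RFE — recursive feature elimination with a linear classifier, removing the
  single lowest-|coefficient| feature per iteration, hence exactly
  ``n_features − k`` fits (1046 − 100 = 946 at the study's scale).
* LASSO / EN — penalized linear models with the regularization strength set
  by an internal 3-fold CV; features ranked by aggregated |coefficient|.
* EFS-CLA — repeated subsampled linear-SVC fits, averaged |weights|, dropping
  the bottom E% of surviving features per iteration.
* random — uniform selection without replacement, the baseline reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import ElasticNetCV, LassoCV
from sklearn.svm import LinearSVC

from .importance import importance_from_linear_coefficients
from .io import Standardizer

__all__ = [
    "BaselineResult",
    "ufs_select",
    "rfe_select",
    "penalized_select",
    "efs_cla_select",
    "random_select",
    "signature_overlap",
]


@dataclass
class BaselineResult:
    """Outcome of one baseline selector."""

    method: str
    selected: list
    scores: pd.Series | None = None
    fit_count: int = 0
    notes: list = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected features must be unique")

    def save_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# method={self.method} fit_count={self.fit_count}\n")
            rows = pd.DataFrame({"rank": np.arange(1, len(self.selected) + 1), "feature": self.selected})
            if self.scores is not None:
                rows["score"] = [self.scores.get(f, np.nan) for f in self.selected]
            rows.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _standardized(X: pd.DataFrame) -> np.ndarray:
    return Standardizer().fit(X).transform(X).to_numpy()


def _top_k_by_score(scores: pd.Series, k: int) -> list:
    """Descending score, ties by ascending feature name."""
    order = sorted(scores.index, key=lambda f: (-scores[f], str(f)))
    return order[: min(k, len(order))]


def ufs_select(X: pd.DataFrame, y, k: int) -> BaselineResult:
    """Univariate selection by the one-way ANOVA F statistic across classes.

    Constant features have no between/within variance ratio; their score is
    defined as 0 so they rank last.
    """
    y = np.asarray(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features trigger divide warnings
        F, _ = f_classif(X.to_numpy(dtype=float), y)
    F = np.nan_to_num(F, nan=0.0, posinf=0.0, neginf=0.0)
    scores = pd.Series(F, index=X.columns)
    return BaselineResult("ufs", _top_k_by_score(scores, k), scores, fit_count=0)


def rfe_select(X: pd.DataFrame, y, k: int, base_estimator=None) -> BaselineResult:
    """Recursive feature elimination, one feature per iteration.

    Each iteration fits ``base_estimator`` (default: linear SVC) on the
    surviving features and removes the single feature with the lowest
    aggregated |coefficient| (ties: alphabetically first name removed, for
    determinism). Stops at ``k`` features; fit_count is exactly
    ``n_features − k``.
    """
    if k >= X.shape[1]:
        raise ValueError("k must be smaller than the number of features")
    y = np.asarray(y)
    values = pd.DataFrame(_standardized(X), columns=X.columns, index=X.index)
    surviving = list(X.columns)
    fit_count = 0
    while len(surviving) > k:
        est = base_estimator if base_estimator is not None else LinearSVC(max_iter=2000, random_state=0)
        est.fit(values[surviving].to_numpy(), y)
        fit_count += 1
        iv = importance_from_linear_coefficients(est.coef_, surviving)
        scores = pd.Series(iv.importance, index=surviving)
        # lowest importance; among ties drop the alphabetically first name
        worst = sorted(surviving, key=lambda f: (scores[f], str(f)))[0]
        surviving.remove(worst)
    final_scores = pd.Series(
        {f: float(len(surviving) - i) for i, f in enumerate(surviving)}
    )
    return BaselineResult("rfe", surviving, final_scores, fit_count=fit_count)


def penalized_select(X: pd.DataFrame, y, k: int, mode: str = "lasso", seed: int = 0) -> BaselineResult:
    """LASSO or elastic-net selection with internal 3-fold CV over alpha.

    Multiclass handling is one-vs-rest: one penalized regression per class
    against a 0/1 indicator, coefficients aggregated by the sum of absolute
    values. Zero-coefficient features rank below every nonzero one, ordered
    by name; if they are needed to reach ``k`` the result is flagged padded.
    """
    if mode not in ("lasso", "elastic_net"):
        raise ValueError("mode must be 'lasso' or 'elastic_net'")
    y = np.asarray(y)
    values = _standardized(X)
    classes = np.unique(y)
    agg = np.zeros(X.shape[1])
    fit_count = 0
    targets = [(y == c).astype(float) for c in classes] if len(classes) > 2 else [
        (y == classes[1]).astype(float)
    ]
    for target in targets:
        model = (
            LassoCV(cv=3, random_state=seed)
            if mode == "lasso"
            else ElasticNetCV(cv=3, random_state=seed)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(values, target)
        agg += np.abs(model.coef_)
        fit_count += 1
    scores = pd.Series(agg, index=X.columns)
    nonzero = [f for f in scores.index if scores[f] > 0]
    ranked = sorted(nonzero, key=lambda f: (-scores[f], str(f)))
    notes = []
    if len(ranked) < min(k, X.shape[1]):
        pad = sorted(f for f in scores.index if scores[f] == 0)
        ranked += pad
        notes.append(f"padded with {min(k, X.shape[1]) - len(nonzero)} zero-coefficient features")
        if not nonzero:
            warnings.warn("all coefficients are zero; falling back to name order", UserWarning)
    return BaselineResult(mode, ranked[: min(k, X.shape[1])], scores, fit_count, notes)


def efs_cla_select(
    X: pd.DataFrame,
    y,
    k: int,
    E: float = 20.0,
    calls_per_step: int = 40,
    subsample_fraction: float = 0.5,
    seed: int = 0,
) -> BaselineResult:
    """Ensemble feature selection with complete linear aggregation.

    Per iteration: fit ``calls_per_step`` linear SVCs on random sample
    subsets, average the absolute weights of the surviving features, and drop
    the bottom ``E``% (floored, at least 1). Iterations stop before a
    reduction would undershoot ``k``; the final step trims to exactly ``k``
    by lowest averaged weight.
    """
    if not (0 < E < 100):
        raise ValueError("E must be a percentage in (0, 100)")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(_standardized(X), columns=X.columns, index=X.index)
    surviving = list(X.columns)
    fit_count = 0
    last_weights = pd.Series(0.0, index=surviving)

    def averaged_weights(feats: list) -> pd.Series:
        nonlocal fit_count
        acc = np.zeros(len(feats))
        n_sub = max(2, int(round(subsample_fraction * len(values))))
        for _ in range(calls_per_step):
            idx = rng.choice(len(values), size=n_sub, replace=False)
            sub_y = y[idx]
            if len(np.unique(sub_y)) < 2:  # degenerate subsample: resample classes
                continue
            est = LinearSVC(max_iter=2000, random_state=int(rng.integers(2**31)))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(values[feats].to_numpy()[idx], sub_y)
            except Exception:
                continue  # skip-and-log contract: a failed call is dropped
            fit_count += 1
            acc += np.abs(np.atleast_2d(est.coef_)).sum(axis=0)
        return pd.Series(acc / max(1, calls_per_step), index=feats)

    while len(surviving) > k:
        n_drop = max(1, math.floor(len(surviving) * E / 100.0))
        last_weights = averaged_weights(surviving)
        if len(surviving) - n_drop < k:
            n_drop = len(surviving) - k  # final trim to exactly k
        drop = sorted(surviving, key=lambda f: (last_weights[f], str(f)))[:n_drop]
        surviving = [f for f in surviving if f not in set(drop)]
    return BaselineResult("efs_cla", surviving, last_weights.reindex(surviving), fit_count)


def efs_cla_survivor_counts(n_features: int, k: int, E: float = 20.0) -> list[int]:
    """Survivor-count schedule of :func:`efs_cla_select` (floor recurrence)."""
    counts = [n_features]
    n = n_features
    while n > k:
        drop = max(1, math.floor(n * E / 100.0))
        if n - drop < k:
            drop = n - k
        n -= drop
        counts.append(n)
    return counts


def random_select(feature_names, k: int, seed: int) -> BaselineResult:
    """Uniform selection of ``k`` features without replacement (baseline)."""
    names = list(feature_names)
    if k > len(names):
        raise ValueError("k cannot exceed the number of features")
    rng = np.random.default_rng(seed)
    chosen = [names[i] for i in rng.choice(len(names), size=k, replace=False)]
    return BaselineResult("random", chosen, None, fit_count=0)


def signature_overlap(a, b) -> int:
    """Number of features shared by two signatures."""
    return len(set(a) & set(b))
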