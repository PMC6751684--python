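"""Per-instance feature importance extraction and ranking.

Two classifier typologies contribute ranked lists to the ensemble:

* tree ensembles (bagging, random forest, gradient boosting) — a feature's
  importance is the raw number of internal splits made on it across all
  trees ("counted by frequency", not impurity-weighted);
* linear models — a feature's importance is the sum over class rows of the
  absolute value of its coefficient.

Only the resulting ordering is consumed downstream, so the heterogeneous
scales of the two rules never mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImportanceVector",
    "RankedList",
    "importance_from_tree_ensemble",
    "importance_from_linear_coefficients",
    "rank_top_k",
]


@dataclass(frozen=True)
class ImportanceVector:
    feature_names: tuple
    importance: np.ndarray
    source_typology: str  # "tree_ensemble" or "linear"

    def __post_init__(self):
        imp = np.asarray(self.importance, dtype=float)
        if len(imp) != len(self.feature_names):
            raise ValueError("importance length != number of features")
        if not np.isfinite(imp).all() or (imp < 0).any():
            raise ValueError("importance values must be finite and non-negative")
        object.__setattr__(self, "importance", imp)


@dataclass(frozen=True)
class RankedList:
    """Feature names ordered most → least important for one classifier instance."""

    features: tuple
    instance_id: tuple = ("unknown", 0)


def _iter_trees(ensemble):
    """Yield sklearn ``Tree`` objects from a fitted ensemble or tree iterable."""
    estimators = getattr(ensemble, "estimators_", ensemble)
    arr = np.asarray(estimators, dtype=object).ravel()
    for est in arr:
        yield est.tree_ if hasattr(est, "tree_") else est


def importance_from_tree_ensemble(ensemble, feature_names) -> ImportanceVector:
    """Count internal splits per feature across every tree of an ensemble.

    Accepts a fitted sklearn ensemble (``estimators_``) or any iterable of
    fitted trees. Features never used in a split get importance 0.
    """
    counts = np.zeros(len(feature_names), dtype=float)
    n_trees = 0
    for tree in _iter_trees(ensemble):
        split_features = tree.feature[tree.feature >= 0]
        counts += np.bincount(split_features, minlength=len(feature_names))
        n_trees += 1
    if n_trees == 0:
        raise ValueError("empty tree ensemble")
    return ImportanceVector(tuple(feature_names), counts, "tree_ensemble")


def importance_from_linear_coefficients(coefficients, feature_names) -> ImportanceVector:
    """Sum of absolute coefficients across class rows (binary models: one row)."""
    coef = np.atleast_2d(np.asarray(coefficients, dtype=float))
    if coef.shape[1] != len(feature_names):
        raise ValueError("coefficient columns != number of features")
    if not np.isfinite(coef).all():
        raise ValueError("non-finite coefficient")
    return ImportanceVector(
        tuple(feature_names), np.abs(coef).sum(axis=0), "linear"
    )


def rank_top_k(v: ImportanceVector, k: int, instance_id=("unknown", 0)) -> RankedList:
    """Top ``min(k, n)`` feature names by descending importance.

    Ties are broken by ascending feature name so the ranking is deterministic
    across runs and platforms.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(
        range(len(v.feature_names)),
        key=lambda i: (-v.importance[i], v.feature_names[i]),
    )
    top = tuple(v.feature_names[i] for i in order[: min(k, len(order))])
    return RankedList(top, tuple(instance_id))
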