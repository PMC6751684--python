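"""The eight-classifier roster and its hyperparameters.

Three tree-ensemble families (bagging, gradient boosting, random forest,
each defaulting to 300 predictors) and five linear families (logistic
regression, passive-aggressive, ridge, SGD, linear-kernel SVC). The linear
SVC is backed by liblinear (``LinearSVC``). Everything else keeps library
defaults.
"""

from __future__ import annotations

from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import (
    LogisticRegression,
    RidgeClassifier,
    SGDClassifier,
)
from sklearn.svm import LinearSVC

TREE_FAMILIES = ("bagging_trees", "gradient_boosting", "random_forest")
LINEAR_FAMILIES = (
    "logistic_regression",
    "passive_aggressive",
    "ridge",
    "sgd_linear",
    "svc_linear",
)
# enumeration order fixes the seed ladder; keep it stable
ALL_FAMILIES = (
    "gradient_boosting",
    "random_forest",
    "logistic_regression",
    "passive_aggressive",
    "sgd_linear",
    "svc_linear",
    "ridge",
    "bagging_trees",
)


def make_classifier(family: str, seed: int, n_estimators: int = 300, max_iter: int = 1000):
    """Instantiate one classifier of the roster with its own random state."""
    if family == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=n_estimators, random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    if family == "bagging_trees":
        return BaggingClassifier(n_estimators=n_estimators, random_state=seed)
    if family == "logistic_regression":
        return LogisticRegression(max_iter=max_iter, random_state=seed)
    if family == "passive_aggressive":
        # passive-aggressive updates expressed through the SGD machinery
        return SGDClassifier(
            loss="hinge", penalty=None, learning_rate="pa1", eta0=1.0,
            max_iter=max_iter, random_state=seed,
        )
    if family == "sgd_linear":
        return SGDClassifier(max_iter=max_iter, random_state=seed)
    if family == "svc_linear":
        return LinearSVC(max_iter=max(max_iter, 2000), random_state=seed)
    if family == "ridge":
        return RidgeClassifier(random_state=seed)
    raise ValueError(
        f"unknown classifier family {family!r}; supported: {', '.join(ALL_FAMILIES)}"
    )


def family_typology(family: str) -> str:
    if family in TREE_FAMILIES:
        return "tree_ensemble"
    if family in LINEAR_FAMILIES:
        return "linear"
    raise ValueError(
        f"unknown classifier family {family!r}; supported: {', '.join(ALL_FAMILIES)}"
    )
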