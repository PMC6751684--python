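"""Consensus feature selection across a heterogeneous classifier ensemble.

Each *classifier instance* is one (family, run) pair. A run draws a fresh
stratified fold partition, fits the classifier on each training partition
(with standardization learned on that partition only), averages the per-fold
importance vectors and emits a single ranked feature list. With the default
roster of 8 families run 10 times each, N_c = 80 instances contribute.

Every feature f is then scored by

    s_f = N_t / N_c

where N_t counts the instances whose top-k list contains f. The signature is
the k highest-scoring features. Weighted rank-aggregation alternatives exist,
but the plain appearance fraction needs no extra parameters and is what this
package implements.

The statsmodels-style surface is :class:`EnsembleFeatureSelection` (model)
and :class:`EnsembleSelectionResults` (estimates + summary); the functional
pieces (:func:`tally_top_k`, :func:`consensus_scores`,
:func:`select_signature`, :func:`run_ensemble_selection`) are usable on
their own.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._classifiers import ALL_FAMILIES, family_typology, make_classifier
from .importance import (
    ImportanceVector,
    RankedList,
    importance_from_linear_coefficients,
    importance_from_tree_ensemble,
    rank_top_k,
)
from .io import Standardizer, stratified_folds

__all__ = [
    "EnsembleConfig",
    "EnsembleFeatureSelection",
    "EnsembleSelectionResults",
    "tally_top_k",
    "consensus_scores",
    "select_signature",
    "run_ensemble_selection",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of one ensemble-selection run.

    Defaults mirror the study protocol: the full 8-family roster, 10 runs of
    10-fold stratified CV (N_c = 80 instances), top-100 tally and a
    100-feature signature, 300 predictors for the tree ensembles.
    """

    classifier_families: tuple = ALL_FAMILIES
    n_runs: int = 10
    n_folds: int = 10
    top_k_tally: int = 100
    signature_size: int = 100
    seed: int = 0
    n_estimators: int = 300
    max_iter: int = 1000

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.top_k_tally < 1:
            raise ValueError("top_k_tally must be >= 1")
        unknown = [f for f in self.classifier_families if f not in ALL_FAMILIES]
        if unknown:
            raise ValueError(
                f"unknown classifier families {unknown}; supported: {ALL_FAMILIES}"
            )
        object.__setattr__(
            self, "classifier_families", tuple(self.classifier_families)
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def instance_seed(self, family: str, run: int) -> int:
        """Sub-seed for one (family, run) instance, by fixed enumeration order.

        Derived from a SeedSequence so instances are independent regardless
        of execution order; kept below 2**31.
        """
        fam_idx = ALL_FAMILIES.index(family)
        ss = np.random.SeedSequence([self.seed, fam_idx, run])
        return int(ss.generate_state(1)[0] % (2**31))


def tally_top_k(lists, k: int, feature_names) -> pd.Series:
    """N_t per feature: in how many lists it appears among the first k entries."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tally = pd.Series(0, index=list(feature_names), dtype=int)
    names = set(feature_names)
    for rl in lists:
        feats = rl.features if isinstance(rl, RankedList) else tuple(rl)
        unknown = set(feats) - names
        if unknown:
            raise ValueError(f"ranked list contains unknown features: {sorted(unknown)}")
        for f in feats[: min(k, len(feats))]:
            tally[f] += 1
    return tally


def consensus_scores(N_t, N_c: int) -> pd.DataFrame:
    """Score table with s_f = N_t / N_c per feature.

    A feature appearing in the top-k lists of 73 of 100 instances scores
    exactly 0.73.
    """
    if N_c < 1:
        raise ValueError("N_c must be >= 1")
    tally = pd.Series(N_t).astype(int)
    if (tally < 0).any() or (tally > N_c).any():
        raise ValueError("tallies must satisfy 0 <= N_t <= N_c")
    table = pd.DataFrame({"N_t": tally, "s_f": tally / N_c})
    table.index.name = "feature"
    table.attrs["N_c"] = int(N_c)
    return table


def select_signature(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top ``min(k, n)`` features by descending s_f.

    Ties break by descending N_t (redundant when N_c is shared) then
    ascending feature name, so the signature is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = (
        table.assign(_name=table.index.astype(str))
        .sort_values(
            by=["s_f", "N_t", "_name"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        .drop(columns="_name")
    )
    sig = ordered.head(min(k, len(ordered))).copy()
    sig.insert(0, "rank", np.arange(1, len(sig) + 1))
    sig.attrs.update(table.attrs)
    return sig


class EnsembleFeatureSelection:
    """Consensus feature-selection model over labeled expression data.

    Parameters
    ----------
    X : DataFrame
        Samples × features expression matrix.
    y : array-like
        Per-sample class labels (tumor types); at least two classes.
    config : EnsembleConfig, optional
        Roster, CV protocol and signature size; defaults to the full
        8 × 10-run protocol.
    """

    def __init__(self, X: pd.DataFrame, y, config: EnsembleConfig | None = None):
        self.X = X
        self.y = np.asarray(y)
        if len(self.y) != len(X):
            raise ValueError("y length must equal the number of samples")
        if len(np.unique(self.y)) < 2:
            raise ValueError("need at least two classes")
        self.config = config or EnsembleConfig()

    @classmethod
    def from_dataframe(
        cls, X: pd.DataFrame, labels: pd.DataFrame, label_column: str = "tumor_type", **cfg
    ) -> "EnsembleFeatureSelection":
        y = labels.loc[X.index, label_column].to_numpy()
        return cls(X, y, EnsembleConfig(**cfg))

    # -- one classifier instance -------------------------------------------------

    def _instance_ranked_list(self, family: str, run: int) -> RankedList:
        cfg = self.config
        sub_seed = cfg.instance_seed(family, run)
        fold_index = stratified_folds(self.y, cfg.n_folds, sub_seed)
        values = self.X
        acc = np.zeros(values.shape[1])
        for fold in range(cfg.n_folds):
            train = values.iloc[fold_index != fold]
            scaler = Standardizer().fit(train)
            Xtr = scaler.transform(train).to_numpy()
            clf = make_classifier(
                family, sub_seed + fold, n_estimators=cfg.n_estimators, max_iter=cfg.max_iter
            )
            clf.fit(Xtr, self.y[fold_index != fold])
            if family_typology(family) == "tree_ensemble":
                iv = importance_from_tree_ensemble(clf, values.columns)
            else:
                iv = importance_from_linear_coefficients(clf.coef_, values.columns)
            acc += iv.importance
        avg = ImportanceVector(
            tuple(values.columns), acc / cfg.n_folds, family_typology(family)
        )
        return rank_top_k(avg, cfg.top_k_tally, instance_id=(family, run))

    def fit(self) -> "EnsembleSelectionResults":
        """Run every (family, run) instance and aggregate the consensus table."""
        cfg = self.config
        lists: list[RankedList] = []
        status: list[dict] = []
        for family in cfg.classifier_families:
            for run in range(cfg.n_runs):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        lists.append(self._instance_ranked_list(family, run))
                    status.append({"family": family, "run": run, "status": "ok"})
                except Exception as exc:  # convergence failure: skip, decrement N_c
                    warnings.warn(
                        f"instance ({family}, run {run}) failed and was skipped: {exc}",
                        UserWarning,
                        stacklevel=2,
                    )
                    status.append(
                        {"family": family, "run": run, "status": f"failed: {exc}"}
                    )
        if not lists:
            raise RuntimeError("every classifier instance failed")
        N_c = len(lists)
        tally = tally_top_k(lists, cfg.top_k_tally, self.X.columns)
        table = consensus_scores(tally, N_c)
        signature = select_signature(table, cfg.signature_size)
        return EnsembleSelectionResults(
            model=self,
            scores=table,
            signature=signature,
            n_instances=N_c,
            instance_status=status,
        )


@dataclass
class EnsembleSelectionResults:
    """Consensus score table and signature from a fitted ensemble selection."""

    model: EnsembleFeatureSelection
    scores: pd.DataFrame
    signature: pd.DataFrame
    n_instances: int
    instance_status: list = field(default_factory=list)

    @property
    def selected_features(self) -> list:
        return list(self.signature.index)

    def summary(self) -> str:
        cfg = self.model.config
        head = self.signature.head(10)
        lines = [
            "Ensemble feature selection",
            "=" * 60,
            f"families:        {', '.join(cfg.classifier_families)}",
            f"runs x folds:    {cfg.n_runs} x {cfg.n_folds}",
            f"instances (N_c): {self.n_instances}",
            f"tally k:         {cfg.top_k_tally}",
            f"signature size:  {len(self.signature)}",
            f"config digest:   {cfg.digest()}",
            "-" * 60,
            f"{'rank':>4}  {'feature':<24} {'N_t':>5} {'s_f':>7}",
        ]
        for name, row in head.iterrows():
            lines.append(
                f"{int(row['rank']):>4}  {name:<24} {int(row['N_t']):>5} {row['s_f']:>7.3f}"
            )
        if len(self.signature) > 10:
            lines.append(f"... ({len(self.signature) - 10} more)")
        return "\n".join(lines)

    # -- persistence (deterministic: no timestamps/timings) ---------------------

    def save_signature_tsv(self, path) -> None:
        out = self.signature.reset_index()[["rank", "feature", "N_t", "s_f"]]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# method=ensemble config={self.model.config.digest()} N_c={self.n_instances}\n")
            out.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    def save_scores_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# method=ensemble config={self.model.config.digest()} N_c={self.n_instances}\n")
            self.scores.reset_index().to_csv(fh, sep="\t", index=False, float_format="%.10g")

    def save_report_json(self, path) -> None:
        report = {
            "config": self.model.config.to_dict(),
            "config_digest": self.model.config.digest(),
            "n_instances": self.n_instances,
            "instances": self.instance_status,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_ensemble_selection(X: pd.DataFrame, y, config: EnsembleConfig | None = None):
    """Functional wrapper: returns ``(consensus score table, signature)``."""
    res = EnsembleFeatureSelection(X, y, config).fit()
    return res.scores, res.signature
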