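"""Expression/label tables, TSV round-trips, standardization and stratified folds.

The in-memory containers are plain pandas objects:

* an *expression matrix* is a ``DataFrame`` with sample IDs as the index and
  miRNA identifiers (e.g. ``hsa-mir-10b``) as columns, holding non-negative
  linear expression values (RPM for sequencing data, array intensity
  otherwise);
* a *label table* is a ``DataFrame`` indexed by sample ID with columns
  ``tumor_type``, ``tissue_status`` (``TT``/``NT``) and optionally
  ``subtype``, plus an integer ``class_code`` assigned by sorted category
  order.

Standardization (zero mean, unit variance per feature) is always learned on a
training partition only and then applied to held-out data, so test folds never
leak into the scaler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ExpressionFormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "assign_class_codes",
    "Standardizer",
    "standardize",
    "stratified_folds",
]


class ExpressionFormatError(ValueError):
    """Raised when an expression TSV violates the format contract."""


def _check_expression_frame(df: pd.DataFrame) -> None:
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ExpressionFormatError(f"duplicate feature name: {dup!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ExpressionFormatError(f"duplicate sample ID: {dup!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ExpressionFormatError(
            f"missing value at sample {row!r}, feature {col!r} (no imputation)"
        )
    arr = df.to_numpy()
    if not np.isfinite(arr).all():
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ExpressionFormatError(
            f"non-finite value at sample {df.index[i]!r}, feature {df.columns[j]!r}"
        )


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a samples × features expression matrix from TSV.

    The header row carries feature names; the first column carries sample
    IDs. Duplicate names, missing values and non-numeric cells are errors —
    the offending coordinate is reported, nothing is imputed.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    features = header[1:]
    seen: set[str] = set()
    for name in features:
        if name in seen:
            raise ExpressionFormatError(f"duplicate feature name: {name!r}")
        seen.add(name)

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ExpressionFormatError(
                f"non-numeric cell at sample {bad!r}, feature {col!r}: "
                f"{df.loc[bad, col]!r}"
            ) from None
    _check_expression_frame(out)
    return out


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    """Write an expression matrix as TSV (inverse of :func:`read_expression_tsv`)."""
    _check_expression_frame(df)
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


LABEL_COLUMNS = ("tumor_type", "tissue_status", "subtype")


def assign_class_codes(labels: pd.Series) -> pd.Series:
    """Integer class codes by sorted category order (a bijection with categories)."""
    cats = sorted(labels.astype(str).unique())
    mapping = {c: i for i, c in enumerate(cats)}
    return labels.astype(str).map(mapping).astype(int)


def read_labels_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    if "tumor_type" not in df.columns:
        raise ValueError("label table must have a 'tumor_type' column")
    if df["tumor_type"].isna().any():
        bad = df.index[df["tumor_type"].isna()][0]
        raise ValueError(f"sample {bad!r} has no tumor_type")
    df["class_code"] = assign_class_codes(df["tumor_type"])
    return df


def write_labels_tsv(df: pd.DataFrame, path) -> None:
    cols = [c for c in LABEL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class Standardizer:
    """Per-feature centering/scaling fitted on a training partition.

    Uses the population SD convention (divide by n). Constant features
    (sd = 0) receive a substitute sd of 1 so the transform stays defined;
    they are flagged in ``constant_features`` so selectors can ignore them.
    """

    mean: np.ndarray = field(default=None)
    sd: np.ndarray = field(default=None)
    feature_names: list = field(default=None)
    constant_features: np.ndarray = field(default=None)
    fitted_on: int = 0

    def fit(self, train: pd.DataFrame) -> "Standardizer":
        values = train.to_numpy(dtype=float)
        self.mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        self.constant_features = sd == 0.0
        self.sd = np.where(self.constant_features, 1.0, sd)
        self.feature_names = list(train.columns)
        self.fitted_on = len(train)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.columns) != self.feature_names:
            raise ValueError("feature names do not match the fitted standardizer")
        return (X - self.mean) / self.sd


def standardize(
    train: pd.DataFrame, others: list[pd.DataFrame] = ()
) -> tuple[Standardizer, pd.DataFrame, list[pd.DataFrame]]:
    """Fit a :class:`Standardizer` on ``train`` and apply it everywhere.

    ``others`` are transformed with the training mean/sd only — their values
    are never consulted when fitting.
    """
    model = Standardizer().fit(train)
    return model, model.transform(train), [model.transform(o) for o in others]


def stratified_folds(labels, n_folds: int, seed: int) -> np.ndarray:
    """Assign each sample to one of ``n_folds`` class-stratified folds.

    Per-fold class counts differ from exact proportionality by at most one
    sample per class. Deterministic given ``seed``. Classes with fewer
    samples than ``n_folds`` trigger a warning; their samples are still
    assigned (some folds simply lack the class).
    """
    y = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if (counts < n_folds).any():
        warnings.warn(
            f"{int((counts < n_folds).sum())} class(es) have fewer samples than "
            f"n_folds={n_folds}; some folds will lack them",
            UserWarning,
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_index = np.empty(len(y), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn repeats the small-class warning
        for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            fold_index[test_idx] = i
    return fold_index
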