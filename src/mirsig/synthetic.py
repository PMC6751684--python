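"""Synthetic labeled expression data with planted discriminative structure.

The generator emulates the structure of a pan-cancer bulk miRNA compendium:
many classes with highly unbalanced sizes, non-negative heavy-tailed
expression values (log-normal), and a small planted subset of
class-discriminative features. Expression is built in log space:

    log X[s, f] = b_f + shift[class(s), f] + eps,   eps ~ N(0, noise_sd)

with per-feature baselines b_f ~ N(base_loc, base_scale) and class-specific
shifts drawn as N(0, effect_size) on informative features only, so
``effect_size`` is the per-class mean shift in log-space units. A second
"platform" is simulated by inverting the z-score mapping with a known
per-feature scale, so the platform-map fit can be scored against the truth.

The default benchmark (600 samples, 8 unbalanced classes, 200 features, 20
informative, effect 1.5) is small enough for minutes-scale test runs; a
compendium-scale preset with 28 tumor classes and matching tumor/normal
counts is available for label-level experiments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import assign_class_codes, write_expression_tsv, write_labels_tsv

__all__ = [
    "SyntheticSpec",
    "generate_labeled_expression",
    "apply_platform_transform",
    "tcga_like_label_table",
    "write_synthetic_dataset",
    "PAN_CANCER_CLASS_COUNTS",
]

# per-class (tumor tissue, normal tissue) sample counts of the 28-class
# pan-cancer compendium the generator emulates; totals 8023 TT / 634 NT
PAN_CANCER_CLASS_COUNTS = {
    "ACC": (80, 0), "BLCA": (411, 19), "BRCA": (777, 87), "CESC": (306, 3),
    "CHOL": (36, 9), "DLBC": (47, 0), "ESCA": (187, 13), "HNSC": (487, 44),
    "KICH": (66, 25), "KIRC": (260, 71), "KIRP": (291, 34), "LGG": (528, 0),
    "LIHC": (374, 50), "LUAD": (458, 46), "LUSC": (341, 45), "MESO": (86, 0),
    "PAAD": (154, 4), "PCPG": (184, 3), "PRAD": (494, 52), "SARC": (260, 0),
    "SKCM": (450, 2), "STAD": (399, 45), "TGCT": (156, 0), "THCA": (513, 59),
    "THYM": (124, 2), "UCEC": (417, 21), "UCS": (57, 0), "UVM": (80, 0),
}

DEFAULT_PROPORTIONS = (0.3, 0.2, 0.15, 0.1, 0.1, 0.05, 0.05, 0.05)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset draw."""

    n_samples: int = 600
    n_classes: int = 8
    class_proportions: tuple = DEFAULT_PROPORTIONS
    n_features: int = 200
    n_informative: int = 20
    effect_size: float = 1.5
    base_loc: float = 2.0
    base_scale: float = 1.0
    noise_sd: float = 1.0
    normal_tissue_fraction: float = 0.0
    subtype_proportions: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if len(self.class_proportions) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if not np.isclose(sum(self.class_proportions), 1.0):
            raise ValueError("class_proportions must sum to 1")
        if min(self.class_proportions) <= 0:
            raise ValueError("all class proportions must be positive")
        for name in ("effect_size", "base_scale", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _counts_from_proportions(n: int, proportions, rng=None) -> np.ndarray:
    """Largest-remainder apportionment: counts match proportions within rounding."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    if (counts == 0).any():
        raise ValueError("infeasible proportions: a class received zero samples")
    return counts


def generate_labeled_expression(spec: SyntheticSpec):
    """Draw ``(expression matrix, label table, planted feature list)``.

    Only planted (informative) features carry class signal; everything else
    is exchangeable noise. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _counts_from_proportions(spec.n_samples, spec.class_proportions)
    class_names = [f"C{c:02d}" for c in range(spec.n_classes)]
    y = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(y)

    feature_names = [f"syn-mir-{i + 1:04d}" for i in range(spec.n_features)]
    planted_idx = np.sort(rng.choice(spec.n_features, spec.n_informative, replace=False))
    planted = [feature_names[i] for i in planted_idx]

    baselines = rng.normal(spec.base_loc, spec.base_scale, size=spec.n_features)
    shifts = np.zeros((spec.n_classes, spec.n_features))
    if spec.effect_size > 0 and spec.n_informative > 0:
        shifts[:, planted_idx] = rng.normal(
            0.0, spec.effect_size, size=(spec.n_classes, spec.n_informative)
        )

    log_x = baselines + shifts[y] + rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_features))

    tissue = np.array(["TT"] * spec.n_samples, dtype=object)
    if spec.normal_tissue_fraction > 0:
        n_nt = int(round(spec.normal_tissue_fraction * spec.n_samples))
        nt_idx = rng.choice(spec.n_samples, size=n_nt, replace=False)
        tissue[nt_idx] = "NT"
        # normal tissue loses the tumor-class shift and gains a shared one
        nt_shift = np.zeros(spec.n_features)
        nt_shift[planted_idx] = rng.normal(0.0, spec.effect_size, size=spec.n_informative)
        log_x[nt_idx] = (
            baselines
            + nt_shift
            + rng.normal(0.0, spec.noise_sd, size=(len(nt_idx), spec.n_features))
        )

    sample_ids = [f"S{i + 1:05d}" for i in range(spec.n_samples)]
    X = pd.DataFrame(np.exp(log_x), index=sample_ids, columns=feature_names)
    labels = pd.DataFrame(
        {
            "tumor_type": [class_names[c] for c in y],
            "tissue_status": tissue,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if spec.subtype_proportions is not None:
        subtype_names = ["TNBC", "LumA", "LumB", "Her2", "Normal"][: len(spec.subtype_proportions)]
        labels["subtype"] = ""
        host = class_names[0]
        host_idx = labels.index[labels["tumor_type"] == host]
        sub_counts = _counts_from_proportions(len(host_idx), spec.subtype_proportions)
        assigned = np.repeat(np.arange(len(sub_counts)), sub_counts)
        rng.shuffle(assigned)
        labels.loc[host_idx, "subtype"] = [subtype_names[i] for i in assigned]
    labels["class_code"] = assign_class_codes(labels["tumor_type"])
    return X, labels, planted


def tcga_like_label_table(seed: int = 0) -> pd.DataFrame:
    """Label table with the exact 28-class tumor/normal counts of the compendium.

    8657 samples: 8023 tumor tissue and 634 normal tissue, unbalanced across
    28 tumor types. Expression is not generated — this is for label-level
    experiments (stratification, binary task construction) at full scale.
    """
    rows = []
    for acronym, (tt, nt) in PAN_CANCER_CLASS_COUNTS.items():
        rows += [(acronym, "TT")] * tt + [(acronym, "NT")] * nt
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    labels = pd.DataFrame(
        [rows[i] for i in order],
        columns=["tumor_type", "tissue_status"],
        index=pd.Index([f"S{i + 1:05d}" for i in range(len(rows))], name="sample_id"),
    )
    labels["class_code"] = assign_class_codes(labels["tumor_type"])
    return labels


def apply_platform_transform(X_ref: pd.DataFrame, a_true, noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Fabricate a second platform's z-scores from reference intensities.

    Inverts the reference mapping: Z = ((X/a_true) − μ)/σ + noise, with μ, σ
    the per-feature mean and population SD of ``X_ref``. With ``a_true = 1``
    and no noise this returns exactly the reference z-scores.
    """
    a = pd.Series(np.broadcast_to(np.asarray(a_true, dtype=float), (X_ref.shape[1],)),
                  index=X_ref.columns)
    if (a <= 0).any():
        raise ValueError("a_true must be positive")
    mu = X_ref.mean(axis=0)
    sigma = X_ref.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = ((X_ref / a) - mu) / sigma
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        Z = Z + rng.normal(0.0, noise_sd, size=Z.shape)
    return Z


def write_synthetic_dataset(directory, X: pd.DataFrame, labels: pd.DataFrame, planted) -> dict:
    """Write expression/label/planted TSVs into ``directory``; returns the paths."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression": os.path.join(directory, "expression.tsv"),
        "labels": os.path.join(directory, "labels.tsv"),
        "planted": os.path.join(directory, "planted.tsv"),
    }
    write_expression_tsv(X, paths["expression"])
    write_labels_tsv(labels, paths["labels"])
    pd.Series(list(planted), name="feature").to_csv(paths["planted"], sep="\t", index=False)
    return paths
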