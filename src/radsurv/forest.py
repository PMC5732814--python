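"""Random-forest survival-group prediction.

Patients in a group are labeled *short* (imputed survival below the group
median) or *long* (at or above it) — a near-even split by construction —
and a bagged ensemble of randomized decision trees predicts the label from
feature vectors.  Three entry points:

* :func:`crossval_auc` — 10-fold cross-validated ROC/AUC of one feature set;
* :func:`compare_feature_sets` — paired comparison (identical folds) of the
  clinical baseline (age, T, N, M, stage) against the baseline combined
  with the 24 radiomic features;
* :func:`oob_importance` — Breiman-style out-of-bag permutation importance,
  normalized by the between-tree standard deviation and averaged over folds.

The ensemble is built tree-by-tree here (scikit-learn decision trees on
bootstrap resamples) rather than through a monolithic forest object so that
each tree's out-of-bag sample is available to the importance computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.tree import DecisionTreeClassifier

from .survival import impute_censored

__all__ = [
    "TNM_FEATURES",
    "STAGE_ORDER",
    "BaggedForest",
    "CVReport",
    "make_labels",
    "encode_clinical",
    "crossval_auc",
    "compare_feature_sets",
    "oob_importance",
]

#: Clinical baseline predictors: demographics plus TNM staging.
TNM_FEATURES = ("age", "T", "N", "M", "stage")

STAGE_ORDER = {"I": 1, "II": 2, "IIIa": 3, "IIIb": 4, "IV": 5}

FPR_GRID = np.linspace(0.0, 1.0, 101)


def make_labels(group: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Binary survival-group labels within one patient group.

    Censored times are imputed first; the group median of imputed times is
    the threshold.  Returns ``(labels, median)`` with label 1 = *long*
    survival (imputed time at or above the median) and 0 = *short*.
    """
    if len(group) < 10:
        raise ValueError("group too small for 10-fold cross-validation (need >= 10)")
    imputed = impute_censored(group["time"].to_numpy(), group["event"].to_numpy())
    median = float(np.median(imputed))
    labels = (imputed >= median).astype(int)
    if labels.min() == labels.max():
        warnings.warn("all patients fall in one survival class (degenerate group)")
    return labels, median


def encode_clinical(group: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the clinical baseline (age, T, N, M, stage)."""
    out = pd.DataFrame(index=group.index)
    out["age"] = group["age"].astype(float)
    for col in ("T", "N", "M"):
        out[col] = pd.to_numeric(group[col], errors="coerce")
    stage = group["stage"]
    if stage.dtype == object:
        out["stage"] = stage.map(STAGE_ORDER).astype(float)
    else:
        out["stage"] = stage.astype(float)
    return out


@dataclass
class BaggedForest:
    """Bootstrap-aggregated randomized decision trees.

    Each tree is fit on a bootstrap resample of the training set (same
    size, drawn with replacement) and examines ``floor(sqrt(p))`` candidate
    features per split.  Class-probability votes are averaged across trees.
    Out-of-bag row indices are retained per tree.
    """

    n_trees: int = 500
    trees: list = field(default_factory=list, repr=False)
    oob_indices: list = field(default_factory=list, repr=False)
    classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> "BaggedForest":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        n = len(y)
        self.classes_ = np.unique(y)
        self.trees = []
        self.oob_indices = []
        all_rows = np.arange(n)
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(
                max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees.append(tree)
            self.oob_indices.append(np.setdiff1d(all_rows, boot, assume_unique=False))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        proba = np.zeros((len(X), len(self.classes_)))
        for tree in self.trees:
            p = tree.predict_proba(X)
            for k, cls in enumerate(tree.classes_):
                col = int(np.searchsorted(self.classes_, cls))
                proba[:, col] += p[:, k]
        return proba / len(self.trees)


def _even_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into folds whose sizes differ by at most one."""
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, n_folds)]


@dataclass
class CVReport:
    """Cross-validated ROC/AUC summary for one feature set."""

    label: str
    fold_aucs: list[float]
    mean_auc: float
    mean_fpr: np.ndarray = field(repr=False)
    mean_tpr: np.ndarray = field(repr=False)
    n: int = 0
    seed: int | None = None
    n_excluded_folds: int = 0


def crossval_auc(
    X,
    y,
    n_trees: int = 500,
    n_folds: int = 10,
    seed: int = 0,
    label: str = "",
    folds: list[np.ndarray] | None = None,
) -> CVReport:
    """K-fold cross-validated AUC of a bagged forest.

    The cohort is randomly divided into ``n_folds`` even-sized folds (plain
    random split, not label-stratified); each fold is scored by a forest
    trained on the others and its ROC/AUC computed from the class-1
    probability votes.  The overall performance is the mean of the fold
    AUCs; the mean ROC curve averages fold TPRs on a fixed 101-point FPR
    grid.  A fold containing a single class has no defined AUC — it is
    excluded from the mean with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both survival classes present")
    rng = np.random.default_rng(seed)
    if folds is None:
        folds = _even_folds(len(y), n_folds, rng)
    fold_aucs: list[float] = []
    tprs: list[np.ndarray] = []
    n_excluded = 0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        if len(np.unique(y[test_idx])) < 2:
            warnings.warn("fold with a single class: AUC undefined, excluded from mean")
            n_excluded += 1
            continue
        forest = BaggedForest(n_trees=n_trees).fit(X[train_idx], y[train_idx], rng)
        score = forest.predict_proba(X[test_idx])[:, 1]
        fold_aucs.append(float(roc_auc_score(y[test_idx], score)))
        fpr, tpr, _ = roc_curve(y[test_idx], score)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
    if not fold_aucs:
        raise ValueError("every fold had a single class; AUC undefined")
    return CVReport(
        label=label,
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        mean_fpr=FPR_GRID.copy(),
        mean_tpr=np.mean(tprs, axis=0),
        n=len(y),
        seed=seed,
        n_excluded_folds=n_excluded,
    )


def compare_feature_sets(
    group: pd.DataFrame,
    feature_names: list[str],
    n_trees: int = 500,
    n_folds: int = 10,
    seed: int = 0,
    radiomics_only: bool = False,
) -> dict[str, CVReport]:
    """Paired TNM-vs-Combined cross-validation on identical folds.

    The *TNM* model uses age and staging only; the *Combined* model adds
    the 24 radiomic features to that baseline (set ``radiomics_only=True``
    to drop the clinical variables from the combined set).  Patients with
    missing staging fields are dropped before labeling.  Both models share
    one fold partition so their AUCs are directly comparable.
    """
    clin = encode_clinical(group)
    keep = clin.notna().all(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} patients with missing staging fields")
    group = group.loc[keep]
    clin = clin.loc[keep]
    y, _ = make_labels(group)
    X_tnm = clin.to_numpy(dtype=float)
    X_rad = group[list(feature_names)].to_numpy(dtype=float)
    X_comb = X_rad if radiomics_only else np.hstack([X_tnm, X_rad])
    rng = np.random.default_rng(seed)
    folds = _even_folds(len(y), n_folds, rng)
    return {
        "TNM": crossval_auc(X_tnm, y, n_trees, n_folds, seed, label="TNM", folds=folds),
        "Combined": crossval_auc(X_comb, y, n_trees, n_folds, seed, label="Combined", folds=folds),
    }


def oob_importance(
    X,
    y,
    feature_names: list[str] | None = None,
    n_trees: int = 500,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-bag permutation importance, normalized and fold-averaged.

    Per fold: a forest is trained on the fold's training set; for every
    tree and feature, the feature's values are permuted among that tree's
    out-of-bag rows and the increase in the tree's OOB misclassification
    error is recorded.  Per-feature increases are averaged over trees and
    divided by their standard deviation across trees (features the ensemble
    never splits on get importance 0); the normalized values are averaged
    over folds.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    folds = _even_folds(n, n_folds, rng)
    fold_scores = np.zeros((len(folds), p))
    for f_idx, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xt, yt = X[train_idx], y[train_idx]
        forest = BaggedForest(n_trees=n_trees).fit(Xt, yt, rng)
        increases = np.zeros((len(forest.trees), p))
        for t_idx, (tree, oob) in enumerate(zip(forest.trees, forest.oob_indices)):
            if len(oob) == 0:
                continue
            X_oob, y_oob = Xt[oob], yt[oob]
            base_err = float(np.mean(tree.predict(X_oob) != y_oob))
            for j in range(p):
                col = X_oob[:, j]
                if np.ptp(col) == 0:
                    continue  # constant within the fold: permuting changes nothing
                perm = rng.permutation(len(oob))
                X_perm = X_oob.copy()
                X_perm[:, j] = col[perm]
                increases[t_idx, j] = float(np.mean(tree.predict(X_perm) != y_oob)) - base_err
        mean_inc = increases.mean(axis=0)
        std_inc = increases.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            normed = np.where(std_inc > 0, mean_inc / std_inc, 0.0)
        fold_scores[f_idx] = normed
    result = pd.DataFrame(
        {"feature": feature_names, "importance": fold_scores.mean(axis=0)}
    )
    return result.sort_values("importance", ascending=False, ignore_index=True)
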