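"""Model evaluation: linear SVM, stratified 3-fold CV, mean ROC / AUC.

The protocol compares feature quadruples for their ability to separate
two cohorts.  Candidate quadruples are all 4-element subsets of 7 base
topological descriptors (number of intervals, length median, length
stdev, length sum, frac5%, signal to noise, persistent entropy)
combined with up to 2 of the 5 triangle descriptors — 420 models in
total: C(7,4) + C(7,3)*C(5,1) + C(7,2)*C(5,2).

Each model is assessed by stratified 3-fold cross-validation: per fold,
features are standardised with statistics of the training rows only, a
linear-kernel SVM is trained, and the test rows are scored with the
continuous decision value.  The three fold ROC curves are averaged
vertically on a common false-positive-rate grid; the summary is the
AUC of the mean curve together with mean +/- sd of the fold AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "BASE_TOPO_FEATURES",
    "TRIANGLE_FEATURES",
    "FeatureSet",
    "EvaluationResult",
    "enumerate_feature_sets",
    "evaluate_feature_set",
    "rank_models",
    "correlation_table",
]

#: the 7 base topological descriptors eligible for model quadruples
BASE_TOPO_FEATURES = (
    "number_of_intervals",
    "length_median",
    "length_stdev",
    "length_sum",
    "frac5",
    "signal_to_noise",
    "pers_entropy",
)

#: the 5 triangle descriptors (at most 2 per quadruple)
TRIANGLE_FEATURES = (
    "triangle_width",
    "triangle_height",
    "triangle_location",
    "triangle_proportion",
    "triangle_misalignment",
)

#: common FPR grid for vertical ROC averaging
FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class FeatureSet:
    """An ordered quadruple of feature-column names."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != 4 or len(set(self.names)) != 4:
            raise ValueError("a feature set must hold 4 distinct features")

    @property
    def n_triangle(self) -> int:
        return sum(1 for n in self.names if n in TRIANGLE_FEATURES)


@dataclass(frozen=True)
class EvaluationResult:
    """Per-fold and averaged ROC performance of one feature set."""

    fold_rocs: tuple[tuple[np.ndarray, np.ndarray], ...]
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    fold_aucs: tuple[float, ...]
    auc_mean_curve: float
    auc_mean: float
    auc_sd: float
    seed: int


def enumerate_feature_sets(
    base: Sequence[str] = BASE_TOPO_FEATURES,
    triangle: Sequence[str] = TRIANGLE_FEATURES,
    max_triangle: int = 2,
) -> list[FeatureSet]:
    """All 4-feature models with at most ``max_triangle`` triangle features.

    Deterministic ordering: by number of triangle features, then
    lexicographically by the combination indices.
    """
    sets: list[FeatureSet] = []
    for n_tri in range(0, max_triangle + 1):
        for tri in combinations(triangle, n_tri):
            for b in combinations(base, 4 - n_tri):
                sets.append(FeatureSet(tuple(b) + tri))
    return sets


def evaluate_feature_set(
    features: FeatureSet | Sequence[str],
    table: pd.DataFrame,
    labels: Sequence[int] | np.ndarray | str = "group",
    seed: int = 0,
    n_splits: int = 3,
    C: float = 1.0,
) -> EvaluationResult:
    """Cross-validated ROC evaluation of one feature quadruple.

    Parameters
    ----------
    features
        Feature column names (a :class:`FeatureSet` or plain sequence).
    table
        Feature table, one row per subject.
    labels
        Binary labels (array-like) or the name of a column of ``table``
        holding them.
    seed
        Seed of the stratified fold shuffler; identical inputs and seed
        reproduce the result exactly.
    """
    names = list(features.names if isinstance(features, FeatureSet) else features)
    X = table[names].to_numpy(dtype=float)
    if isinstance(labels, str):
        y = table[labels].to_numpy()
    else:
        y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("evaluation requires exactly two classes")
    y = (y == classes[1]).astype(int)
    bad = [n for n in names if not np.all(np.isfinite(X[:, names.index(n)]))]
    if bad:
        raise ValueError(f"missing values in feature(s): {', '.join(bad)}")

    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_rocs: list[tuple[np.ndarray, np.ndarray]] = []
    fold_aucs: list[float] = []
    tprs: list[np.ndarray] = []
    for train, test in cv.split(X, y):
        if np.unique(y[test]).size < 2 or np.unique(y[train]).size < 2:
            raise ValueError("stratification failed: a fold misses a class")
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel="linear", C=C)
        clf.fit(scaler.transform(X[train]), y[train])
        scores = clf.decision_function(scaler.transform(X[test]))
        fpr, tpr, _ = roc_curve(y[test], scores)
        fold_rocs.append((fpr, tpr))
        fold_aucs.append(float(auc(fpr, tpr)))
        interp = np.interp(FPR_GRID, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    return EvaluationResult(
        fold_rocs=tuple(fold_rocs),
        mean_fpr=FPR_GRID.copy(),
        mean_tpr=mean_tpr,
        fold_aucs=tuple(fold_aucs),
        auc_mean_curve=float(auc(FPR_GRID, mean_tpr)),
        auc_mean=float(np.mean(fold_aucs)),
        auc_sd=float(np.std(fold_aucs, ddof=1)),
        seed=seed,
    )


def search_models(
    table: pd.DataFrame,
    labels: Sequence[int] | np.ndarray | str = "group",
    feature_sets: Sequence[FeatureSet] | None = None,
    seed: int = 0,
    n_splits: int = 3,
    C: float = 1.0,
) -> tuple[list[tuple[FeatureSet, EvaluationResult]], list[FeatureSet]]:
    """Evaluate many feature sets, skipping those with undefined features.

    A feature column can be undefined (NaN) or infinite (the
    signal-to-noise sentinel) for some subjects; models using such a
    column cannot be standardised and are skipped rather than silently
    imputed.  Returns (evaluated results, skipped feature sets).
    """
    if feature_sets is None:
        feature_sets = enumerate_feature_sets()
    all_names = sorted({n for fs in feature_sets for n in fs.names})
    usable = {
        n for n in all_names
        if np.all(np.isfinite(table[n].to_numpy(dtype=float)))
    }
    results: list[tuple[FeatureSet, EvaluationResult]] = []
    skipped: list[FeatureSet] = []
    for fs in feature_sets:
        if not set(fs.names) <= usable:
            skipped.append(fs)
            continue
        results.append(
            (fs, evaluate_feature_set(fs, table, labels, seed=seed,
                                      n_splits=n_splits, C=C))
        )
    return results, skipped


def rank_models(
    results: Sequence[tuple[FeatureSet, EvaluationResult]],
) -> pd.DataFrame:
    """Ranked report of evaluated models, best mean AUC first.

    Ties are broken by fewer triangle features, then lexicographically
    by feature names.
    """
    rows = sorted(
        results,
        key=lambda fr: (-fr[1].auc_mean, fr[0].n_triangle, fr[0].names),
    )
    return pd.DataFrame(
        {
            "features": ["+".join(fs.names) for fs, _ in rows],
            "n_triangle": [fs.n_triangle for fs, _ in rows],
            "auc_mean": [r.auc_mean for _, r in rows],
            "auc_sd": [r.auc_sd for _, r in rows],
            "auc_mean_curve": [r.auc_mean_curve for _, r in rows],
        }
    )


def correlation_table(
    table: pd.DataFrame,
    row_features: Sequence[str],
    col_features: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between two feature groups.

    Returns a DataFrame of R values indexed by ``row_features`` with
    ``col_features`` columns; undefined entries (zero-variance column,
    too few finite pairs) are NaN.  Companion attributes
    ``.attrs["pvalues"]`` and ``.attrs["significant"]`` hold the
    p-value matrix and the significance flags at level ``alpha``.
    """
    if len(table) < 3:
        raise ValueError("correlation table needs at least 3 rows")
    r_mat = pd.DataFrame(index=list(row_features), columns=list(col_features),
                         dtype=float)
    p_mat = r_mat.copy()
    for rf in row_features:
        for cf in col_features:
            x = table[rf].to_numpy(dtype=float)
            y = table[cf].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            r_mat.loc[rf, cf] = r
            p_mat.loc[rf, cf] = p
    r_mat.attrs["pvalues"] = p_mat
    r_mat.attrs["significant"] = p_mat < alpha
    return r_mat
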