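"""Random-forest tumor/normal classification on DIR features.

The classifier follows the original protocol: 500 trees, 3 candidate
features per split (mtry), and repeated stratified 4-fold cross-validation
(100 repeats by default) whose out-of-fold class probabilities are pooled
across folds *and* repeats into a single AUC.  Folds are built over
tumor/normal pairs, never over individual samples, so both members of a
pair always share a fold and the evaluation cannot leak pairing structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve

__all__ = ["DiagnosticRun", "train_eval_cv", "feature_reduction_curve", "evaluate_holdout", "fit_full"]

N_TREES = 500
MTRY = 3


@dataclass
class DiagnosticRun:
    """Configuration + results of one cross-validated diagnostic run."""

    n_trees: int = N_TREES
    mtry: int = MTRY
    repeats: int = 100
    folds: int = 4
    seed: int = 0
    pooled_auc: Optional[float] = None
    per_repeat_aucs: List[float] = field(default_factory=list)
    roc: Optional[pd.DataFrame] = None
    confusion: Optional[np.ndarray] = None
    importances: Optional[pd.Series] = None


def _forest(run: DiagnosticRun, seed: int, n_features: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=run.n_trees,
        max_features=min(run.mtry, n_features),
        random_state=seed,
        n_jobs=1,
    )


def _check_xy(X: pd.DataFrame, y: pd.Series) -> None:
    if X.shape[0] == 0:
        raise ValueError("empty feature matrix")
    if y.nunique() < 2:
        raise ValueError("need both classes present")
    if X.isna().any().any():
        raise ValueError("feature matrix must be imputed (no missing cells)")


def train_eval_cv(
    X: pd.DataFrame,
    labels: pd.Series,
    pairs: pd.Series,
    run: Optional[DiagnosticRun] = None,
) -> DiagnosticRun:
    """Repeated pair-aware k-fold CV with pooled out-of-fold AUC.

    *X* is samples x features (imputed), *labels* "tumor"/"normal" (or
    1/0), *pairs* the pair id of each sample.  Probabilities of the
    positive (tumor) class from every out-of-fold prediction across all
    repeats are concatenated into one pooled AUC; the ROC points and the
    0.5-threshold confusion matrix of the first repeat are kept, as are
    the feature importances of a fit on the full data.
    """
    run = run or DiagnosticRun()
    y = labels.map({"tumor": 1, "normal": 0}).fillna(labels).astype(int) if labels.dtype == object else labels.astype(int)
    _check_xy(X, y)
    rng = np.random.default_rng(run.seed)
    uniq_pairs = np.array(sorted(pairs.unique()))
    pair_of = pairs.to_numpy()
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()

    pooled_prob, pooled_y = [], []
    first_prob = np.full(len(yv), np.nan)
    for rep in range(run.repeats):
        perm = rng.permutation(uniq_pairs)
        fold_of_pair = {p: i % run.folds for i, p in enumerate(perm)}
        fold = np.array([fold_of_pair[p] for p in pair_of])
        for f in range(run.folds):
            test = fold == f
            # pair-leakage guard: no pair id on both sides of the split
            assert not (set(pair_of[test]) & set(pair_of[~test]))
            clf = _forest(run, int(rng.integers(0, 2**31 - 1)), Xv.shape[1])
            clf.fit(Xv[~test], yv[~test])
            prob = clf.predict_proba(Xv[test])[:, list(clf.classes_).index(1)]
            pooled_prob.append(prob)
            pooled_y.append(yv[test])
            if rep == 0:
                first_prob[test] = prob
        run.per_repeat_aucs.append(
            float(roc_auc_score(np.concatenate(pooled_y[-run.folds:]), np.concatenate(pooled_prob[-run.folds:])))
        )
    pooled_prob = np.concatenate(pooled_prob)
    pooled_y = np.concatenate(pooled_y)
    run.pooled_auc = float(roc_auc_score(pooled_y, pooled_prob))
    fpr, tpr, thr = roc_curve(yv, first_prob)
    run.roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    run.confusion = confusion_matrix(yv, (first_prob >= 0.5).astype(int))
    full = _forest(run, run.seed, Xv.shape[1])
    full.fit(Xv, yv)
    run.importances = pd.Series(full.feature_importances_, index=X.columns).sort_values(ascending=False)
    return run


def feature_reduction_curve(
    X: pd.DataFrame,
    labels: pd.Series,
    importances: pd.Series,
    *,
    cv_folds: int = 5,
    step: float = 0.9,
    run: Optional[DiagnosticRun] = None,
) -> pd.DataFrame:
    """Cross-validated error for geometrically shrinking feature sets.

    Feature-set sizes follow n <- ceil(step * n); the recursion stops when
    the size would not decrease or would drop below 2.  At each size the
    top features by importance are kept and the misclassification rate is
    estimated by *cv_folds*-fold CV.
    """
    run = run or DiagnosticRun()
    y = labels.map({"tumor": 1, "normal": 0}).fillna(labels).astype(int) if labels.dtype == object else labels.astype(int)
    _check_xy(X, y)
    ranked = [f for f in importances.sort_values(ascending=False).index if f in X.columns]
    sizes = [len(ranked)]
    while True:
        m = math.ceil(step * sizes[-1])
        if m >= sizes[-1] or m < 2:
            break
        sizes.append(m)
    rng = np.random.default_rng(run.seed)
    rows = []
    for n in sizes:
        Xn = X[ranked[:n]].to_numpy(dtype=float)
        idx = rng.permutation(len(y))
        folds = np.array_split(idx, cv_folds)
        errs = []
        for f in folds:
            mask = np.zeros(len(y), dtype=bool)
            mask[f] = True
            clf = _forest(run, int(rng.integers(0, 2**31 - 1)), Xn.shape[1])
            clf.fit(Xn[~mask], y.to_numpy()[~mask])
            pred = clf.predict(Xn[mask])
            errs.append(np.mean(pred != y.to_numpy()[mask]))
        rows.append({"n_features": n, "cv_error": float(np.mean(errs))})
    return pd.DataFrame(rows)


def evaluate_holdout(
    model: RandomForestClassifier,
    X_val: pd.DataFrame,
    y_val: pd.Series,
) -> Tuple[float, pd.DataFrame, np.ndarray]:
    """AUC, ROC points and 0.5-threshold confusion matrix on a holdout."""
    if X_val.shape[0] == 0:
        raise ValueError("empty holdout")
    y = y_val.map({"tumor": 1, "normal": 0}).fillna(y_val).astype(int) if y_val.dtype == object else y_val.astype(int)
    if y.nunique() < 2:
        raise ValueError("holdout AUC undefined with a single class")
    prob = model.predict_proba(X_val.to_numpy(dtype=float))[:, list(model.classes_).index(1)]
    auc = float(roc_auc_score(y, prob))
    fpr, tpr, thr = roc_curve(y, prob)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    conf = confusion_matrix(y, (prob >= 0.5).astype(int))
    return auc, roc, conf


def fit_full(X: pd.DataFrame, labels: pd.Series, run: Optional[DiagnosticRun] = None) -> RandomForestClassifier:
    """Train one forest on the full training matrix (for holdout use)."""
    run = run or DiagnosticRun()
    y = labels.map({"tumor": 1, "normal": 0}).fillna(labels).astype(int) if labels.dtype == object else labels.astype(int)
    _check_xy(X, y)
    clf = _forest(run, run.seed, X.shape[1])
    clf.fit(X.to_numpy(dtype=float), y.to_numpy())
    return clf
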