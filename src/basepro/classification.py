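"""Random-forest prognosis classification and model comparison.

Samples are labelled by 10-year outcome (good: event-free through the
horizon; poor: event within the horizon; censored before the horizon:
excluded).  Feature blocks (signature scores, immune scores, clinical
covariates, comparator score) are evaluated with stratified 10-fold
cross-validation: out-of-fold class probabilities are pooled and scored
once for a single AUC.  Backward feature elimination repeatedly drops the
least important feature (Gini importance) and keeps the feature set with
the highest cross-validated AUC at the fewest features.  Correlated ROC
curves are compared with DeLong's test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .scoring import mann_whitney_auc, validate_signature, RocResult

logger = logging.getLogger("basepro.classification")

GOOD, POOR, EXCLUDED = "good", "poor", "excluded"

RF_PARAMS = dict(n_estimators=500, max_features="sqrt", max_depth=None)


@dataclass
class PrognosisLabels:
    labels: pd.Series  # good / poor / excluded
    horizon: float

    @property
    def included(self) -> pd.Index:
        return self.labels.index[self.labels != EXCLUDED]

    def binary(self) -> pd.Series:
        """1 = poor prognosis, 0 = good, excluded samples dropped."""
        kept = self.labels[self.labels != EXCLUDED]
        return (kept == POOR).astype(int)


@dataclass
class ClassifierReport:
    probabilities: pd.Series  # pooled out-of-fold P(poor)
    auc: float
    folds: pd.Series
    importance: pd.DataFrame | None
    seed: int


def label_prognosis(survival_table: pd.DataFrame, horizon: float = 10.0) -> PrognosisLabels:
    """Dichotomise time-to-event data at the follow-up horizon.

    Event at t <= horizon -> poor; followed to/beyond the horizon without an
    event within it -> good; censored before the horizon -> excluded.
    """
    time = survival_table["time"].astype(float)
    event = survival_table["event"].astype(int)
    if (time < 0).any():
        raise ValueError("negative survival time")
    labels = pd.Series(EXCLUDED, index=survival_table.index)
    labels[time >= horizon] = GOOD  # includes events after the horizon
    labels[(event == 1) & (time <= horizon)] = POOR  # horizon-day events are poor
    return PrognosisLabels(labels=labels, horizon=horizon)


def _prepare(features: pd.DataFrame, labels: PrognosisLabels | pd.Series):
    y = labels.binary() if isinstance(labels, PrognosisLabels) else pd.Series(labels).astype(int)
    shared = features.index.intersection(y.index)
    X = features.loc[shared]
    complete = X.notna().all(axis=1)
    if (~complete).any():
        logger.info("dropping %d sample(s) with missing feature values", int((~complete).sum()))
        X = X[complete]
    # canonical lexicographic ordering so fold assignment is order-invariant
    X = X.sort_index()
    y = y.loc[X.index]
    if y.nunique() < 2:
        raise ValueError("labels contain a single class")
    return X, y


def cross_validated_probabilities(
    features: pd.DataFrame,
    labels: PrognosisLabels | pd.Series,
    k: int = 10,
    seed: int = 0,
) -> ClassifierReport:
    """Pooled out-of-fold random-forest probabilities and a single AUC.

    Folds are stratified by class over a canonical (sorted) sample ordering;
    the pooled probabilities are scored once with the Mann-Whitney AUC.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = _prepare(features, labels)
    if y.value_counts().min() < k:
        raise ValueError(f"need >= {k} samples per class for {k}-fold stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    probs = pd.Series(np.nan, index=X.index)
    folds = pd.Series(-1, index=X.index)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(random_state=seed + fold, **RF_PARAMS)
        rf.fit(X.iloc[tr], y.iloc[tr])
        poor_col = list(rf.classes_).index(1)
        probs.iloc[te] = rf.predict_proba(X.iloc[te])[:, poor_col]
        folds.iloc[te] = fold
    auc = mann_whitney_auc(probs.to_numpy(), y.to_numpy())
    return ClassifierReport(probabilities=probs, auc=auc, folds=folds, importance=None, seed=seed)


def rf_importance(
    features: pd.DataFrame,
    labels: PrognosisLabels | pd.Series,
    seed: int = 0,
    importance: str = "gini",
) -> pd.DataFrame:
    """Feature importance from a forest on all included samples.

    Gini impurity decrease by default; ``importance='permutation'`` uses
    out-of-bag-free permutation importance on the training data.  Ranking
    ties are broken alphabetically.
    """
    X, y = _prepare(features, labels)
    rf = RandomForestClassifier(random_state=seed, **RF_PARAMS)
    rf.fit(X, y)
    if importance == "gini":
        imp = rf.feature_importances_
    elif importance == "permutation":
        from sklearn.inspection import permutation_importance

        imp = permutation_importance(rf, X, y, n_repeats=10, random_state=seed).importances_mean
    else:
        raise ValueError(f"unknown importance {importance!r}")
    table = pd.DataFrame({"feature": X.columns, "importance": imp})
    table = table.sort_values(["importance", "feature"], ascending=[False, True], kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def backward_selection(
    features: pd.DataFrame,
    labels: PrognosisLabels | pd.Series,
    k: int = 10,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Backward feature elimination on cross-validated AUC.

    Each step records the pooled k-fold AUC of the current feature set, then
    removes the single least-important feature, until one feature remains.
    Returns the feature set with the highest AUC (compared at 1e-4
    resolution, ties broken toward fewer features) and the full trajectory.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least two features")
    current = list(features.columns)
    rows = []
    best: tuple[float, int, list[str]] | None = None
    while current:
        auc = cross_validated_probabilities(features[current], labels, k=k, seed=seed).auc
        rows.append({"n_features": len(current), "auc": auc, "features": list(current)})
        key = (round(auc, 4), -len(current))
        if best is None or key >= best[0]:
            best = (key, len(current), list(current))
        if len(current) == 1:
            break
        imp = rf_importance(features[current], labels, seed=seed)
        current.remove(imp["feature"].iloc[-1])  # least important; ties alphabetical
    trajectory = pd.DataFrame(rows)
    return best[2], trajectory


def external_validation(
    train_features: pd.DataFrame,
    train_labels: PrognosisLabels | pd.Series,
    test_features: pd.DataFrame,
    test_labels: PrognosisLabels | pd.Series,
    feature_set: list[str] | None = None,
    seed: int = 0,
) -> tuple[float, RocResult, pd.Series]:
    """Train on one cohort, report AUC and ROC on another."""
    feature_set = list(feature_set or train_features.columns)
    for name in feature_set:
        if name not in test_features.columns:
            raise KeyError(f"feature {name!r} missing from the test cohort")
        if name not in train_features.columns:
            raise KeyError(f"feature {name!r} missing from the training cohort")
    Xtr, ytr = _prepare(train_features[feature_set], train_labels)
    Xte, yte = _prepare(test_features[feature_set], test_labels)
    rf = RandomForestClassifier(random_state=seed, **RF_PARAMS)
    rf.fit(Xtr, ytr)
    poor_col = list(rf.classes_).index(1)
    probs = pd.Series(rf.predict_proba(Xte)[:, poor_col], index=Xte.index)
    roc = validate_signature(probs.to_numpy(), yte.to_numpy())
    return roc.auc, roc, probs


# ---------------------------------------------------------------------------
# DeLong's test for two correlated ROC curves
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_test(probs_a, probs_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test of the paired AUC difference.

    Uses the structural-components estimate of the covariance of the two
    empirical AUCs on the same samples; returns (AUC_a - AUC_b, p).
    Identical predictors (zero estimated variance) give p = 1 with a warning.
    """
    y = np.asarray(labels).astype(bool)
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    aucs = []
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for idx, probs in enumerate((probs_a, probs_b)):
        x = np.asarray(probs, float)
        if x.shape != y.shape:
            raise ValueError("probability vector length does not match labels")
        pos, neg = x[y], x[~y]
        tx = _midrank(pos)
        ty = _midrank(neg)
        tz = _midrank(np.r_[pos, neg])
        auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        aucs.append(auc)
        v10[idx] = (tz[:m] - tx) / n
        v01[idx] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        if diff != 0:
            raise ValueError("zero DeLong variance with unequal AUCs")
        warnings.warn("identical predictors: DeLong variance is zero, p = 1")
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    return float(diff), float(2.0 * stats.norm.sf(abs(z)))
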