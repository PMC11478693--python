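"""Device-type classification audit from quality metrics alone.

If a random forest can tell Android from iOS using nothing but the eight
per-sensor quality metrics, then device type is a confounder for any
downstream behavioural model built on the same data.  The audit:

* builds a participant-level design (24 features combined across the three
  sensors, or 8 for a sensor-specific model), labels android=0 / ios=1;
* tunes tree count, max depth and min leaf size by stratified 12-fold CV on
  a stratified 70/30 training split, scoring each combination by the mean of
  accuracy (at the Youden-J threshold), AU-ROC and AU-PRC;
* reports held-out metrics at two operating points (Youden-J for
  ROC-derived metrics, max-F for precision/recall) with percentile 95% CIs
  from repeated re-shuffled CV on the training split;
* checks significance against a label-permutation null; and
* interprets the model with SHAP-style attributions: importance scores IS
  (normalized mean |attribution|, max 1) and signed impact levels IL in
  [-1, 1] (negative oriented to Android, positive to iOS).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._treeshap import forest_expected_value, forest_shap_values
from .cohort import DQM_COLUMNS

__all__ = [
    "DEFAULT_GRID",
    "FittedModel",
    "ClassifierReport",
    "ShapSummary",
    "make_design",
    "tune_and_fit",
    "evaluate",
    "permutation_null",
    "shap_summaries",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID = {
    "n_estimators": (100, 300, 500),
    "max_depth": (3, 5, 10, None),
    "min_samples_leaf": (1, 5, 10),
}

METRIC_NAMES = (
    "accuracy",
    "precision",
    "recall",
    "sensitivity",
    "specificity",
    "auroc",
    "auprc",
)


def make_design(
    table: pd.DataFrame, mode: str = "combined"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Participant-level feature matrix and binary labels (android=0, ios=1).

    ``mode`` is "combined" (all sensors present in the table, 8 metrics each)
    or a sensor name.  Participants missing a sensor in combined mode, or any
    feature value, are dropped with a log message.
    """
    metrics = list(DQM_COLUMNS)
    if mode == "combined":
        wide = table.pivot(
            index="participant_id", columns="sensor_type", values=metrics
        )
        wide.columns = [f"{sensor}_{metric}" for metric, sensor in wide.columns]
        wide = wide[sorted(wide.columns)]
    else:
        if mode not in set(table["sensor_type"]):
            raise ValueError(f"sensor {mode!r} not present in table")
        sub = table[table["sensor_type"] == mode]
        wide = sub.set_index("participant_id")[metrics]
        wide.columns = [f"{mode}_{m}" for m in metrics]
    labels = (
        table.drop_duplicates("participant_id")
        .set_index("participant_id")["device_type"]
        .reindex(wide.index)
    )
    complete = wide.notna().all(axis=1)
    if (~complete).any():
        logger.info("dropping %d participants with incomplete features", int((~complete).sum()))
    wide = wide[complete]
    labels = labels[complete]
    y = (labels == "ios").astype(int).to_numpy()
    return wide, y


def _youden_threshold(y: np.ndarray, prob: np.ndarray) -> float:
    fpr, tpr, thr = roc_curve(y, prob)
    j = tpr - fpr
    return float(thr[np.argmax(j)])


def _fscore_threshold(y: np.ndarray, prob: np.ndarray) -> float:
    prec, rec, thr = precision_recall_curve(y, prob)
    f1 = 2 * prec[:-1] * rec[:-1] / np.maximum(prec[:-1] + rec[:-1], 1e-12)
    return float(thr[np.argmax(f1)])


def _metrics_at(y: np.ndarray, prob: np.ndarray, thr_j: float, thr_f: float) -> dict:
    """The seven report metrics given the two operating thresholds."""
    pred_j = (prob >= thr_j).astype(int)
    pred_f = (prob >= thr_f).astype(int)
    tp = np.sum((pred_j == 1) & (y == 1))
    tn = np.sum((pred_j == 0) & (y == 0))
    fp = np.sum((pred_j == 1) & (y == 0))
    fn = np.sum((pred_j == 0) & (y == 1))
    tp_f = np.sum((pred_f == 1) & (y == 1))
    fp_f = np.sum((pred_f == 1) & (y == 0))
    fn_f = np.sum((pred_f == 0) & (y == 1))
    out = {
        "accuracy": float((tp + tn) / y.size),
        "precision": float(tp_f / max(tp_f + fp_f, 1)),
        "recall": float(tp_f / max(tp_f + fn_f, 1)),
        "sensitivity": float(tp / max(tp + fn, 1)),
        "specificity": float(tn / max(tn + fp, 1)),
    }
    if np.unique(y).size == 2:
        out["auroc"] = float(roc_auc_score(y, prob))
        out["auprc"] = float(average_precision_score(y, prob))
    else:  # degenerate fold
        out["auroc"] = np.nan
        out["auprc"] = np.nan
    return out


def _oof_probabilities(
    X: np.ndarray, y: np.ndarray, params: dict, n_splits: int, seed: int
) -> np.ndarray:
    """Out-of-fold positive-class probabilities from shuffled stratified CV."""
    n_splits = min(n_splits, int(np.bincount(y).min()))
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + attempt)
        prob = np.empty(y.size)
        ok = True
        for tr, te in skf.split(X, y):
            if np.unique(y[tr]).size < 2:
                ok = False
                logger.info("fold missing a class; reshuffling with seed+1")
                break
            clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
            clf.fit(X[tr], y[tr])
            prob[te] = clf.predict_proba(X[te])[:, 1]
        if ok:
            return prob
    raise RuntimeError("could not build class-complete CV folds")


@dataclass
class FittedModel:
    model: RandomForestClassifier
    params: dict
    threshold_youden: float
    threshold_fscore: float
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    feature_names: list[str]
    seed: int
    cv_splits: int


@dataclass
class ClassifierReport:
    params: dict
    thresholds: dict
    heldout: dict
    cv_median: dict
    cv_ci: dict
    n_train: int
    n_test: int
    permutation: dict = field(default_factory=dict)


def tune_and_fit(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    *,
    grid: dict | None = None,
    n_splits: int = 12,
    test_size: float = 0.3,
) -> FittedModel:
    """Stratified 70/30 split, grid-tuned random forest, two thresholds.

    Hyperparameters are selected by shuffled stratified ``n_splits``-fold CV
    on the training split, scoring each combination by the mean of accuracy
    at the Youden threshold, AU-ROC and AU-PRC on the pooled out-of-fold
    predictions.  The final model is refit on the full training split and
    both operating thresholds are chosen from its out-of-fold predictions.
    Deterministic given the seed.
    """
    names = (
        list(features.columns)
        if isinstance(features, pd.DataFrame)
        else [f"f{i}" for i in range(np.asarray(features).shape[1])]
    )
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2 or y.size < 24:
        raise ValueError("need both classes and at least 24 rows")
    grid = grid or DEFAULT_GRID
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed, shuffle=True
    )
    best_score, best_params = -np.inf, None
    for nt, md, ml in itertools.product(
        grid["n_estimators"], grid["max_depth"], grid["min_samples_leaf"]
    ):
        params = {"n_estimators": nt, "max_depth": md, "min_samples_leaf": ml}
        prob = _oof_probabilities(X_tr, y_tr, params, n_splits, seed)
        thr_j = _youden_threshold(y_tr, prob)
        thr_f = _fscore_threshold(y_tr, prob)
        m = _metrics_at(y_tr, prob, thr_j, thr_f)
        score = (m["accuracy"] + m["auroc"] + m["auprc"]) / 3.0
        if score > best_score:
            best_score, best_params = score, params
    prob = _oof_probabilities(X_tr, y_tr, best_params, n_splits, seed)
    thr_j = _youden_threshold(y_tr, prob)
    thr_f = _fscore_threshold(y_tr, prob)
    model = RandomForestClassifier(random_state=seed, n_jobs=1, **best_params)
    model.fit(X_tr, y_tr)
    return FittedModel(
        model=model,
        params=best_params,
        threshold_youden=thr_j,
        threshold_fscore=thr_f,
        X_train=X_tr,
        y_train=y_tr,
        X_test=X_te,
        y_test=y_te,
        feature_names=names,
        seed=seed,
        cv_splits=n_splits,
    )


def evaluate(fitted: FittedModel, repeats: int = 100) -> ClassifierReport:
    """Held-out metrics plus medians and percentile 95% CIs over ``repeats``
    re-shuffled stratified CV evaluations on the training split."""
    prob_te = fitted.model.predict_proba(fitted.X_test)[:, 1]
    heldout = _metrics_at(
        fitted.y_test, prob_te, fitted.threshold_youden, fitted.threshold_fscore
    )
    dist: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for rep in range(repeats):
        prob = _oof_probabilities(
            fitted.X_train,
            fitted.y_train,
            fitted.params,
            fitted.cv_splits,
            fitted.seed + 1000 + 7 * rep,
        )
        thr_j = _youden_threshold(fitted.y_train, prob)
        thr_f = _fscore_threshold(fitted.y_train, prob)
        m = _metrics_at(fitted.y_train, prob, thr_j, thr_f)
        for k in METRIC_NAMES:
            dist[k].append(m[k])
    cv_median = {k: float(np.median(v)) for k, v in dist.items()}
    cv_ci = {
        k: [float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))]
        for k, v in dist.items()
    }
    return ClassifierReport(
        params=fitted.params,
        thresholds={
            "youden": fitted.threshold_youden,
            "fscore": fitted.threshold_fscore,
        },
        heldout=heldout,
        cv_median=cv_median,
        cv_ci=cv_ci,
        n_train=int(fitted.y_train.size),
        n_test=int(fitted.y_test.size),
    )


def permutation_null(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    fitted: FittedModel,
    n_perm: int = 200,
    seed: int = 0,
    *,
    retune: bool = False,
    observed_accuracy: float | None = None,
) -> dict:
    """Label-permutation null for the classification accuracy.

    Labels are shuffled over the full design; per shuffle the 70/30 split,
    fit and held-out evaluation are re-run.  By default the already-tuned
    hyperparameters are reused (``retune=True`` re-runs the grid search per
    shuffle).  Returns the null distribution and the add-one empirical p of
    the observed held-out accuracy.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    null_acc = np.empty(n_perm)
    for i in range(n_perm):
        y_shuf = rng.permutation(y)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if retune:
            fm = tune_and_fit(X, y_shuf, seed=sub_seed)
            rep = evaluate(fm, repeats=1)
            null_acc[i] = rep.heldout["accuracy"]
        else:
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y_shuf, test_size=0.3, stratify=y_shuf, random_state=sub_seed
            )
            clf = RandomForestClassifier(
                random_state=sub_seed, n_jobs=1, **fitted.params
            )
            clf.fit(X_tr, y_tr)
            null_acc[i] = float(np.mean(clf.predict(X_te) == y_te))
    if observed_accuracy is None:
        prob_te = fitted.model.predict_proba(fitted.X_test)[:, 1]
        observed_accuracy = _metrics_at(
            fitted.y_test, prob_te, fitted.threshold_youden, fitted.threshold_fscore
        )["accuracy"]
    p = (1.0 + np.sum(null_acc >= observed_accuracy)) / (n_perm + 1.0)
    return {
        "null_accuracy": null_acc,
        "observed_accuracy": float(observed_accuracy),
        "p_value": float(p),
        "null_median": float(np.median(null_acc)),
        "null_q99": float(np.percentile(null_acc, 99)),
    }


@dataclass
class ShapSummary:
    feature_names: list[str]
    importance: np.ndarray  # IS per feature, max-normalized to 1
    impact: np.ndarray  # IL, per observation x feature, in [-1, 1]
    raw: np.ndarray  # unnormalized attributions
    base_value: float


def shap_summaries(
    model: RandomForestClassifier,
    features: pd.DataFrame | np.ndarray,
    feature_names: list[str] | None = None,
) -> ShapSummary:
    """Importance scores and impact levels from exact tree attributions.

    IS is the per-feature mean |attribution| of the iOS-class probability,
    normalized by its maximum (so the top feature scores 1); IL is the
    per-observation attribution normalized by the global max |attribution|,
    keeping its sign (negative = pushes toward Android, positive = iOS).
    """
    if feature_names is None:
        feature_names = (
            list(features.columns)
            if isinstance(features, pd.DataFrame)
            else [f"f{i}" for i in range(np.asarray(features).shape[1])]
        )
    X = np.asarray(features, dtype=float)
    phi = forest_shap_values(model, X)
    base = forest_expected_value(model)
    mean_abs = np.abs(phi).mean(axis=0)
    top = mean_abs.max()
    importance = mean_abs / top if top > 0 else mean_abs
    global_max = np.abs(phi).max()
    impact = phi / global_max if global_max > 0 else phi
    return ShapSummary(
        feature_names=list(feature_names),
        importance=importance,
        impact=impact,
        raw=phi,
        base_value=base,
    )
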