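"""Model zoo, repeated stratified evaluation, DeLong AUC comparison, SHAP report.

Eight classifier families are registered (CatBoost, XGBoost, logistic
regression, SVM, random forest, k-NN, naive Bayes, AdaBoost) with fixed
hyperparameters: 100 trees/iterations for the tree ensembles, 5 neighbours
for k-NN, probability-calibrated SVM, random_state 42 throughout, everything
else at library defaults. A registered backend whose library is not installed
is skipped with a warning and marked absent in the report.

Evaluation repeats a stratified 75/25 shuffle split (default 100 times),
reporting mean ± SD of AUC, accuracy, precision, recall, F1 and PR-AUC per
model. Class balancing by minority-class bootstrap oversampling is applied
inside the training fold by default; ``pre_split_oversample=True`` balances the whole
table before splitting instead, which leaks duplicated subjects between train
and test folds and is therefore optimistic — the evaluation report flags it.

The DeLong test compares two correlated ROC AUCs computed on the same test
labels, using per-positive/per-negative placement values for the
variance/covariance of the AUC difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .selection import bootstrap_oversample

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model registry

DEFAULT_MODELS = ("CatBoost", "XGBoost", "LR", "SVM", "RF", "KNN", "NB", "AdaBoost")


def _build_model(name: str, seed: int):
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "XGBoost":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=100, random_state=seed, verbosity=0,
                             eval_metric="logloss")
    if name == "CatBoost":
        from catboost import CatBoostClassifier  # optional backend

        return CatBoostClassifier(iterations=100, random_state=seed, verbose=0)
    if name == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "SVM":
        # RBF SVM with Platt-calibrated probabilities (ROC needs scores)
        return CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "NB":
        return GaussianNB()
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed)
    raise ModelError(f"unknown model {name!r}")


def fit_model_zoo(
    x: pd.DataFrame,
    y: np.ndarray,
    seed: int = 42,
    models: tuple[str, ...] = DEFAULT_MODELS,
) -> tuple[dict[str, object], list[str]]:
    """Fit every available registered classifier on the full table.

    Returns (fitted models, names skipped because their backend is missing).
    """
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ModelError("labels contain a single class")
    if x.shape[1] < 1:
        raise ModelError("no features to fit")
    fitted: dict[str, object] = {}
    skipped: list[str] = []
    for name in models:
        try:
            model = _build_model(name, seed)
        except ImportError:
            warnings.warn(f"model backend for {name!r} unavailable; skipping")
            skipped.append(name)
            continue
        model.fit(x.values, y)
        fitted[name] = model
    return fitted, skipped


# ---------------------------------------------------------------------------
# repeated stratified evaluation

METRICS = ("auc", "accuracy", "precision", "recall", "f1", "pr_auc")


@dataclass
class EvalReport:
    summary: pd.DataFrame  # rows: model; columns: <metric>_mean, <metric>_sd
    best_model: str
    n_splits: int
    train_fraction: float
    oversample_mode: str  # "fold_internal" | "pre_split" | "none"
    optimistic: bool  # True when duplicated subjects may leak across folds
    skipped_models: list[str] = field(default_factory=list)
    roc_curves: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    per_split: dict[str, pd.DataFrame] = field(default_factory=dict)
    delong: pd.DataFrame | None = None


def _scores(model, x: np.ndarray) -> np.ndarray:
    return model.predict_proba(x)[:, 1]


_ROC_GRID = np.linspace(0.0, 1.0, 101)


def evaluate_models(
    x: pd.DataFrame,
    y: np.ndarray,
    n_splits: int = 100,
    train_fraction: float = 0.75,
    seed: int = 42,
    models: tuple[str, ...] = DEFAULT_MODELS,
    oversample: bool = True,
    pre_split_oversample: bool = False,
    compute_delong: bool = False,
    max_redraws: int = 50,
) -> EvalReport:
    """Repeated stratified 75/25 evaluation of the model zoo.

    Each repetition draws a stratified split, optionally balances the training
    fold by bootstrap oversampling, fits every model, and scores the untouched
    test fold. ``pre_split_oversample`` instead balances the entire table once, before
    splitting (optimistic; flagged in the report). Splits whose test fold
    lacks a class are re-drawn, to a cap.
    """
    y = np.asarray(y, dtype=int)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ModelError("need at least 2 subjects per class")
    mode = "none"
    if oversample:
        mode = "pre_split" if pre_split_oversample else "fold_internal"
    if pre_split_oversample and oversample:
        x, y, _ = bootstrap_oversample(x, y, seed=seed)

    available: list[str] = []
    skipped: list[str] = []
    for name in models:
        try:
            _build_model(name, seed)
            available.append(name)
        except ImportError:
            warnings.warn(f"model backend for {name!r} unavailable; skipping")
            skipped.append(name)

    rows: dict[str, list[dict[str, float]]] = {m: [] for m in available}
    tprs: dict[str, list[np.ndarray]] = {m: [] for m in available}
    pooled_scores: dict[str, list[np.ndarray]] = {m: [] for m in available}
    pooled_labels: list[np.ndarray] = []

    rng = np.random.default_rng(seed)
    done = 0
    draws = 0
    while done < n_splits:
        draws += 1
        if draws > n_splits + max_redraws:
            raise ModelError("exceeded the re-draw cap for valid stratified splits")
        split_seed = int(rng.integers(2**31))
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=train_fraction, random_state=split_seed
        )
        train_idx, test_idx = next(splitter.split(x.values, y))
        y_tr, y_te = y[train_idx], y[test_idx]
        if np.unique(y_te).size < 2 or np.unique(y_tr).size < 2:
            logger.info("re-drawing split %d: a fold lost a class", done)
            continue
        x_tr = x.iloc[train_idx]
        if oversample and not pre_split_oversample:
            x_tr, y_tr, _ = bootstrap_oversample(x_tr, y_tr, seed=split_seed)
        x_te = x.iloc[test_idx].values
        pooled_labels.append(y_te)
        for name in available:
            model = _build_model(name, seed)
            model.fit(x_tr.values, y_tr)
            s = _scores(model, x_te)
            pred = (s >= 0.5).astype(int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows[name].append(
                    {
                        "auc": roc_auc_score(y_te, s),
                        "accuracy": accuracy_score(y_te, pred),
                        "precision": precision_score(y_te, pred, zero_division=0),
                        "recall": recall_score(y_te, pred, zero_division=0),
                        "f1": f1_score(y_te, pred, zero_division=0),
                        "pr_auc": average_precision_score(y_te, s),
                    }
                )
            fpr, tpr, _ = roc_curve(y_te, s)
            tprs[name].append(np.interp(_ROC_GRID, fpr, tpr))
            pooled_scores[name].append(s)
        done += 1

    per_split = {m: pd.DataFrame(rows[m]) for m in available}
    summary = pd.DataFrame(
        {
            **{f"{met}_mean": [per_split[m][met].mean() for m in available] for met in METRICS},
            **{f"{met}_sd": [per_split[m][met].std(ddof=1) for m in available] for met in METRICS},
        },
        index=list(available),
    )
    best = summary["auc_mean"].idxmax()
    roc_curves = {
        m: {
            "fpr": _ROC_GRID,
            "tpr_mean": np.mean(tprs[m], axis=0),
            "tpr_lo": np.percentile(tprs[m], 2.5, axis=0),
            "tpr_hi": np.percentile(tprs[m], 97.5, axis=0),
        }
        for m in available
    }
    delong = None
    if compute_delong:
        labels_cat = np.concatenate(pooled_labels)
        delong = pd.DataFrame(index=list(available), columns=list(available), dtype=float)
        for a in available:
            for b in available:
                if a == b:
                    delong.loc[a, b] = 1.0
                else:
                    _, p = delong_auc_test(
                        np.concatenate(pooled_scores[a]),
                        np.concatenate(pooled_scores[b]),
                        labels_cat,
                    )
                    delong.loc[a, b] = p
    return EvalReport(
        summary=summary,
        best_model=str(best),
        n_splits=n_splits,
        train_fraction=train_fraction,
        oversample_mode=mode,
        optimistic=(mode == "pre_split"),
        skipped_models=skipped,
        roc_curves=roc_curves,
        per_split=per_split,
        delong=delong,
    )


# ---------------------------------------------------------------------------
# DeLong test for correlated ROC AUCs


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (placement values)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # per-positive placement
    v01 = cmp.mean(axis=0)  # per-negative placement
    return float(v10.mean()), v10, v01


def delong_auc_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Two-sided DeLong test for a difference between two correlated AUCs.

    The AUCs come from the Mann–Whitney statistic; the variance of the AUC
    difference uses the empirical covariance of the placement values. Returns
    (z, p); identical score orderings give z=0, p=1 with a degeneracy warning.
    """
    labels = np.asarray(labels, dtype=int)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ModelError("scores and labels must share a shape")
    pos_mask = labels == 1
    if not pos_mask.any() or pos_mask.all():
        raise ModelError("both classes must be present")
    auc_a, v10_a, v01_a = _placements(scores_a[pos_mask], scores_a[~pos_mask])
    auc_b, v10_b, v01_b = _placements(scores_b[pos_mask], scores_b[~pos_mask])
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))  # 2x2 over positives
    s01 = np.cov(np.vstack([v01_a, v01_b]))  # 2x2 over negatives
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        if abs(delta) > 0:
            warnings.warn("DeLong variance is zero but AUCs differ; p set to 0")
            return np.inf if delta > 0 else -np.inf, 0.0
        warnings.warn("degenerate DeLong comparison (identical orderings); p = 1")
        return 0.0, 1.0
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via exhaustive pair counting (ties count half)."""
    labels = np.asarray(labels, dtype=int)
    pos = np.asarray(scores, dtype=float)[labels == 1]
    neg = np.asarray(scores, dtype=float)[labels == 0]
    auc, _, _ = _placements(pos, neg)
    return auc


# ---------------------------------------------------------------------------
# SHAP reporting contract


@dataclass
class ShapSummary:
    available: bool
    feature_names: list[str] = field(default_factory=list)
    values: np.ndarray | None = None  # (n_subjects, n_features), signed
    base_value: float = 0.0
    mean_abs: dict[str, float] = field(default_factory=dict)
    dominant_sign: dict[str, int] = field(default_factory=dict)
    ranking: list[str] = field(default_factory=list)
    message: str = ""


def shap_summary(model, x: pd.DataFrame) -> ShapSummary:
    """Signed per-feature attribution distribution for a fitted model.

    Attribution is delegated to the shap library (TreeExplainer for tree
    ensembles, model-agnostic Explainer otherwise). When the backend is not
    installed the report section is omitted with a warning rather than
    failing the pipeline.
    """
    try:
        import shap
    except ImportError:
        warnings.warn("shap backend unavailable; attribution section omitted")
        return ShapSummary(available=False, message="shap not installed; section omitted")
    try:
        explainer = shap.TreeExplainer(model)
        sv = explainer.shap_values(x.values)
    except Exception:
        explainer = shap.Explainer(model.predict_proba, x.values)
        sv = explainer(x.values).values[..., 1]
    if isinstance(sv, list):  # per-class list from tree explainers
        sv = sv[1]
    if sv.ndim == 3:
        sv = sv[..., 1]
    base = explainer.expected_value
    if np.ndim(base) > 0:
        base = np.asarray(base).ravel()[-1]
    mean_abs = {c: float(np.abs(sv[:, j]).mean()) for j, c in enumerate(x.columns)}
    dom = {c: int(np.sign(sv[:, j].mean()) or 1) for j, c in enumerate(x.columns)}
    ranking = sorted(x.columns, key=lambda c: -mean_abs[c])
    return ShapSummary(
        available=True,
        feature_names=list(x.columns),
        values=np.asarray(sv, dtype=float),
        base_value=float(base),
        mean_abs=mean_abs,
        dominant_sign=dom,
        ranking=ranking,
    )
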