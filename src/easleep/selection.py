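"""Responder labeling, class balancing, and multi-stage feature selection.

The prediction target is treatment response: a patient whose PSQI score drops
by at least half (configurable fraction; a strict ">" variant is available)
is a responder. Baseline microstate metrics are the candidate features.

Selection runs in configurable ordered stages (default: top-k ranking ->
bootstrap stability -> multi-method consensus -> collinearity pruning):

* three independent rankers each nominate their top-15 features — random
  forest (Gini importance), recursive feature elimination with logistic
  regression, and gradient-boosted trees (gain importance);
* stability: 100 bootstrap resamples of subjects per method, retaining
  features nominated in > 75% of resamples;
* consensus: features retained by every ranker (the full three-method
  intersection; ``min_methods`` relaxes this to an at-least-two rule —
  gradient boosting spreads split gain over nearly every feature, so its
  stable set barely filters and a two-method rule admits chance-correlated
  noise through boosting + one other method);
* pruning: drop features with variance inflation factor (VIF) > 10, then one
  member of any pair with |Pearson r| > 0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# responder labeling


def label_responders(
    psqi_pre: np.ndarray,
    psqi_post: np.ndarray,
    threshold_fraction: float = 0.5,
    strict: bool = False,
) -> tuple[np.ndarray, dict[str, float]]:
    """Binary responder labels from pre/post PSQI scores.

    label = 1 iff (pre - post)/pre >= threshold_fraction (``strict=True``
    switches the comparator to >). Returns labels and a count/percentage
    summary.
    """
    pre = np.asarray(psqi_pre, dtype=float)
    post = np.asarray(psqi_post, dtype=float)
    if pre.shape != post.shape:
        raise SelectionError("psqi_pre and psqi_post must have equal length")
    zero = np.nonzero(pre <= 0)[0]
    if zero.size:
        raise SelectionError(f"psqi_pre must be positive; offending subjects: {zero.tolist()}")
    reduction = (pre - post) / pre
    labels = (reduction > threshold_fraction) if strict else (reduction >= threshold_fraction)
    labels = labels.astype(int)
    n = labels.size
    summary = {
        "n": float(n),
        "n_responders": float(labels.sum()),
        "n_non_responders": float(n - labels.sum()),
        "pct_responders": 100.0 * labels.sum() / n,
        "pct_non_responders": 100.0 * (n - labels.sum()) / n,
        "threshold_fraction": threshold_fraction,
        "comparator": 1.0 if strict else 0.0,
    }
    return labels, summary


def bootstrap_oversample(
    x: pd.DataFrame, y: np.ndarray, seed: int = 42
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Resample the minority class with replacement until classes balance.

    Majority rows are untouched. Returns (x, y, provenance) where provenance
    marks duplicated (resampled) rows with 1.
    """
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise SelectionError("both classes must be present to oversample")
    if counts[0] == counts[1]:
        return x.reset_index(drop=True), y.copy(), np.zeros(y.size, dtype=int)
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    need = int(counts.max() - counts.min())
    min_idx = np.nonzero(y == minority)[0]
    extra = rng.choice(min_idx, size=need, replace=True)
    order = np.concatenate([np.arange(y.size), extra])
    provenance = np.concatenate([np.zeros(y.size, dtype=int), np.ones(need, dtype=int)])
    return x.iloc[order].reset_index(drop=True), y[order], provenance


# ---------------------------------------------------------------------------
# rankers


def rank_features_topk(
    x: pd.DataFrame, y: np.ndarray, method: str, k: int = 15, seed: int = 42
) -> list[str]:
    """Top-k features by one of the three rankers ('rf', 'rfe', 'xgb')."""
    if k > x.shape[1]:
        raise SelectionError(f"k={k} exceeds the {x.shape[1]} available features")
    y = np.asarray(y, dtype=int)
    if method == "rf":
        model = RandomForestClassifier(n_estimators=100, random_state=seed)
        model.fit(x.values, y)
        scores = model.feature_importances_
        order = np.argsort(-scores, kind="stable")[:k]
        return [x.columns[i] for i in order]
    if method == "xgb":
        model = XGBClassifier(
            n_estimators=100, random_state=seed, verbosity=0,
            importance_type="gain", eval_metric="logloss",
        )
        model.fit(x.values, y)
        scores = model.feature_importances_
        order = np.argsort(-scores, kind="stable")[:k]
        return [x.columns[i] for i in order]
    if method == "rfe":
        # RFE needs coef_ on the estimator itself, so standardize up front
        xs = StandardScaler().fit_transform(x.values)
        rfe = RFE(
            LogisticRegression(max_iter=1000, random_state=seed),
            n_features_to_select=k, step=1,
        )
        rfe.fit(xs, y)
        return [c for c, keep in zip(x.columns, rfe.support_) if keep]
    raise SelectionError(f"unknown ranking method {method!r}")


def stability_select(
    x: pd.DataFrame,
    y: np.ndarray,
    method: str,
    b: int = 100,
    freq_threshold: float = 0.75,
    k: int = 15,
    seed: int = 42,
) -> tuple[list[str], dict[str, float]]:
    """Bootstrap stability of a ranker: keep features in the top-k of
    > ``freq_threshold`` of ``b`` subject resamples."""
    if b < 10:
        raise SelectionError("need at least 10 bootstrap iterations")
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    freq = dict.fromkeys(x.columns, 0.0)
    done = 0
    attempts = 0
    while done < b:
        attempts += 1
        if attempts > 20 * b:
            raise SelectionError("could not draw enough two-class bootstrap samples")
        idx = rng.integers(n, size=n)
        if np.unique(y[idx]).size < 2:
            continue
        sub_seed = int(rng.integers(2**31))
        for f in rank_features_topk(x.iloc[idx], y[idx], method, k=k, seed=sub_seed):
            freq[f] += 1.0
        done += 1
    freq = {f: c / b for f, c in freq.items()}
    stable = [f for f in x.columns if freq[f] > freq_threshold]
    return stable, freq


def consensus_features(
    stable_sets: dict[str, list[str]], min_methods: int = 2
) -> tuple[list[str], dict[str, int]]:
    """Features retained by at least ``min_methods`` of the methods.

    Also returns the Venn region counts (keys like 'rf', 'rf&rfe',
    'rf&rfe&xgb') for reporting.
    """
    methods = sorted(stable_sets)
    universe: dict[str, set[str]] = {}
    for m in methods:
        for f in stable_sets[m]:
            universe.setdefault(f, set()).add(m)
    venn: dict[str, int] = {}
    for f, who in universe.items():
        key = "&".join(sorted(who))
        venn[key] = venn.get(key, 0) + 1
    # preserve a deterministic order: first appearance over methods
    seen: list[str] = []
    for m in methods:
        for f in stable_sets[m]:
            if f not in seen:
                seen.append(f)
    chosen = [f for f in seen if len(universe[f]) >= min_methods]
    return chosen, venn


# ---------------------------------------------------------------------------
# collinearity pruning


def compute_vif(x: pd.DataFrame) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2_j) from regressing feature j on the others."""
    cols = list(x.columns)
    vals = x.to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, col in enumerate(cols):
        yj = vals[:, j]
        others = np.delete(vals, j, axis=1)
        design = np.column_stack([np.ones(others.shape[0]), others])
        beta, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ beta
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class PruneRecord:
    feature: str
    reason: str  # "vif" | "correlation"
    value: float
    partner: str | None = None


def collinearity_prune(
    x: pd.DataFrame,
    vif_threshold: float = 10.0,
    corr_threshold: float = 0.8,
) -> tuple[list[str], list[PruneRecord]]:
    """Iteratively drop collinear candidates.

    First the largest-VIF feature while any VIF exceeds ``vif_threshold``
    (perfectly collinear features report VIF = inf); then, for any remaining
    pair with |Pearson r| > ``corr_threshold``, the member with the larger
    mean |r| to all other candidates. Every removal is logged with the
    offending value.
    """
    if x.shape[1] < 2:
        raise SelectionError("need at least 2 candidate features to prune")
    keep = list(x.columns)
    removed: list[PruneRecord] = []
    while len(keep) >= 2:
        vifs = compute_vif(x[keep])
        worst = max(keep, key=lambda c: vifs[c])
        if vifs[worst] > vif_threshold:
            removed.append(PruneRecord(worst, "vif", float(vifs[worst])))
            logger.info("pruned %s (VIF=%.3g)", worst, vifs[worst])
            keep.remove(worst)
        else:
            break
    while len(keep) >= 2:
        corr = x[keep].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        if abs(corr[i, j]) <= corr_threshold:
            break
        mean_abs = np.abs(corr).sum(axis=1) / (len(keep) - 1)
        drop, other = (i, j) if mean_abs[i] >= mean_abs[j] else (j, i)
        removed.append(
            PruneRecord(keep[drop], "correlation", float(abs(corr[i, j])), keep[other])
        )
        logger.info("pruned %s (|r|=%.3f with %s)", keep[drop], abs(corr[i, j]), keep[other])
        keep.pop(drop)
    return keep, removed


# ---------------------------------------------------------------------------
# the full selection pipeline


@dataclass
class SelectionReport:
    per_method_topk: dict[str, list[str]]
    stability_freq: dict[str, dict[str, float]]
    stable_sets: dict[str, list[str]]
    consensus: list[str]
    venn_counts: dict[str, int]
    pruned: list[PruneRecord]
    final_features: list[str]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        union_topk = {f for fs in self.per_method_topk.values() for f in fs}
        if not set(self.consensus) <= union_topk:
            raise SelectionError("consensus must be a subset of the top-k union")
        if not set(self.final_features) <= set(self.consensus):
            raise SelectionError("final features must be a subset of the consensus")


def select_features(
    x: pd.DataFrame,
    y: np.ndarray,
    methods: tuple[str, ...] = ("rf", "rfe", "xgb"),
    k: int = 15,
    b: int = 100,
    freq_threshold: float = 0.75,
    min_methods: int = 3,
    vif_threshold: float = 10.0,
    corr_threshold: float = 0.8,
    seed: int = 42,
    order: str = "stability_then_consensus",
) -> SelectionReport:
    """Run the multi-stage selection pipeline.

    ``order`` picks the stage ordering: ``"stability_then_consensus"``
    (default: per-method stability filtering, then the >=2-method consensus)
    or ``"consensus_then_stability"`` (consensus on raw top-k sets first, then
    keep consensus features stable for at least one method).
    """
    rng = np.random.default_rng(seed)
    per_method_topk = {
        m: rank_features_topk(x, y, m, k=k, seed=int(rng.integers(2**31))) for m in methods
    }
    stability_freq: dict[str, dict[str, float]] = {}
    stable_sets: dict[str, list[str]] = {}
    for m in methods:
        stable, freq = stability_select(
            x, y, m, b=b, freq_threshold=freq_threshold, k=k, seed=int(rng.integers(2**31))
        )
        stable_sets[m] = stable
        stability_freq[m] = freq
    if order == "stability_then_consensus":
        consensus, venn = consensus_features(stable_sets, min_methods=min_methods)
    elif order == "consensus_then_stability":
        consensus, venn = consensus_features(per_method_topk, min_methods=min_methods)
        consensus = [
            f for f in consensus if any(f in stable_sets[m] for m in methods)
        ]
    else:
        raise SelectionError(f"unknown stage order {order!r}")
    if len(consensus) >= 2:
        final, pruned = collinearity_prune(
            x[consensus], vif_threshold=vif_threshold, corr_threshold=corr_threshold
        )
    else:
        final, pruned = list(consensus), []
    return SelectionReport(
        per_method_topk=per_method_topk,
        stability_freq=stability_freq,
        stable_sets=stable_sets,
        consensus=consensus,
        venn_counts=venn,
        pruned=pruned,
        final_features=final,
        config={
            "methods": list(methods), "k": k, "b": b,
            "freq_threshold": freq_threshold, "min_methods": min_methods,
            "vif_threshold": vif_threshold, "corr_threshold": corr_threshold,
            "seed": seed, "order": order,
        },
    )
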