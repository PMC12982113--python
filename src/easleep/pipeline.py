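"""End-to-end orchestration with a single config and a reproducibility manifest.

A run is configured by one mapping (usually loaded from YAML) with stage
sub-sections; every stochastic stage derives its seed from the top-level seed,
and a RunManifest (config snapshot, seeds, input digests, outputs, warnings)
is written when a stage starts and finalized when it ends, so a run can be
reproduced bit-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .groupstats import (
    clinical_change_tests,
    metric_anova,
    results_table,
    tanova_by_class,
    transition_tests,
)
from .microstates import (
    CLASSES,
    assign_canonical_labels,
    backfit_peaks,
    compute_gfp,
    compute_metrics,
    find_gfp_peaks,
    modified_kmeans,
    two_level_templates,
)
from .models import EvalReport, evaluate_models, fit_model_zoo, shap_summary
from .preprocess import PreprocessConfig, microstate_prefilter, standard_preprocess
from .selection import SelectionReport, label_responders, select_features
from .synthgen import FEATURE_VOCABULARY, Cohort, CohortSpec, simulate_cohort


class ConfigSchemaError(ValueError):
    """Raised before any computation; the message carries the field path."""


@dataclass
class RunManifest:
    stage: str
    config: dict
    seeds: dict[str, int]
    package_version: str = __version__
    started: float = field(default_factory=time.time)
    finished: float | None = None
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    status: str = "running"

    def digest_input(self, name: str, path: Path) -> None:
        self.input_digests[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, outdir: Path) -> Path:
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"manifest_{self.stage}.json"
        blob = dataclasses.asdict(self)
        path.write_text(json.dumps(blob, indent=2, default=str))
        return path

    def finalize(self, outdir: Path) -> Path:
        self.finished = time.time()
        self.status = "ok"
        return self.write(outdir)


def _require(config: dict, path: str) -> Any:
    node: Any = config
    crumbs = []
    for key in path.split("."):
        crumbs.append(key)
        if not isinstance(node, dict) or key not in node:
            raise ConfigSchemaError(f"config missing required field: {'.'.join(crumbs)}")
        node = node[key]
    return node


def _get(config: dict, path: str, default: Any) -> Any:
    node: Any = config
    for key in path.split("."):
        if not isinstance(node, dict) or key not in node:
            return default
        node = node[key]
    return node


# ---------------------------------------------------------------------------
# microstate stage


def _subject_pipeline(rec, cfg: PreprocessConfig, k: int, restarts: int,
                      min_distance_ms: float, seed: int):
    pre = standard_preprocess(rec, cfg)
    ms = microstate_prefilter(pre, cfg)
    gfp = compute_gfp(ms)
    peaks = find_gfp_peaks(gfp, ms.rate, min_distance_ms)
    maps = ms.data[:, peaks].T
    res = modified_kmeans(
        maps, k=k, restarts=restarts, seed=seed,
        weights=gfp[peaks], channel_names=ms.channel_names,
    )
    return ms, res.templates


def run_microstate_stage(config: dict, outdir: str | Path | None = None
                         ) -> dict[str, Any]:
    """Simulate (or load) a cohort and run preprocessing, segmentation,
    metric extraction and the group statistics, writing tidy outputs.

    Returns a dict with the cohort, per-group metrics table, group templates,
    and statistics tables.
    """
    _require(config, "montage")
    seed = int(_require(config, "seed"))
    outdir = Path(outdir) if outdir is not None else None
    manifest = RunManifest(stage="microstates", config=config, seeds={"root": seed})
    if outdir:
        manifest.write(outdir)

    k = int(_get(config, "microstates.k", 4))
    restarts = int(_get(config, "microstates.restarts", 100))
    min_distance_ms = float(_get(config, "microstates.min_distance_ms", 10.0))
    cfg = PreprocessConfig(
        target_rate=float(_get(config, "preprocess.rate", 256.0)),
        band_hz=tuple(_get(config, "preprocess.band", (1.0, 45.0))),
        notch_hz=tuple(_get(config, "preprocess.notch", (48.0, 52.0))),
        ms_band_hz=tuple(_get(config, "preprocess.ms_band", (2.0, 20.0))),
    )
    spec = CohortSpec(
        n_hc=int(_get(config, "simulate.n_hc", 4)),
        n_ci=int(_get(config, "simulate.n_ci", 4)),
        n_responders=int(_get(config, "simulate.n_responders", 2)),
        snr=float(_get(config, "simulate.snr", 2.0)),
        duration_s=float(_get(config, "simulate.duration_s", 60.0)),
        rate=float(_get(config, "simulate.rate", 512.0)),
        emit_recordings=True,
        seed=seed,
    )
    cohort: Cohort = simulate_cohort(spec)
    rng = np.random.default_rng(seed)

    rows = []
    group_sets: dict[str, list] = {}
    group_recs: dict[str, list] = {}
    for sid, recs in cohort.recordings.items():
        group = "HC" if sid.startswith("HC") else "CI"
        for phase, rec in recs.items():
            key = group if group == "HC" else f"CI_{phase}"
            ms, tset = _subject_pipeline(
                rec, cfg, k, restarts, min_distance_ms, int(rng.integers(2**31))
            )
            group_sets.setdefault(key, []).append(tset)
            group_recs.setdefault(key, []).append((sid, ms))

    templates = {}
    metrics_rows = []
    orgtms: dict[str, list[np.ndarray]] = {}
    group_maps_by_class: dict[str, dict[str, np.ndarray]] = {c: {} for c in CLASSES}
    for key, sets in group_sets.items():
        grp = two_level_templates(sets, k=k, restarts=restarts, seed=int(rng.integers(2**31)))
        lab, match = assign_canonical_labels(grp.templates)
        templates[key] = lab
        aligned_sets = [assign_canonical_labels(ts)[0] for ts in sets]
        for c_i, c in enumerate(lab.labels):
            group_maps_by_class[c][key] = np.vstack([a.maps[c_i] for a in aligned_sets])
        for sid, ms in group_recs[key]:
            met = compute_metrics(backfit_peaks(ms, lab, min_distance_ms))
            orgtms.setdefault(key, []).append(met.orgtm)
            for name, value in met.to_dict().items():
                metrics_rows.append(
                    {"subject_id": sid, "condition": key, "name": name, "value": value}
                )
    metrics = pd.DataFrame(metrics_rows)

    stats_results = []
    anova_tables = []
    if "HC" in group_sets and "CI_pre" in group_sets:
        wide = metrics.pivot_table(index=["subject_id", "condition"], columns="name",
                                   values="value").reset_index()
        wide = wide[wide["condition"].isin(["HC", "CI_pre"])]
        for met_name in ("Duration", "Coverage", "Occurrence"):
            long = wide.melt(
                id_vars=["subject_id", "condition"],
                value_vars=[f"{met_name}_{c}" for c in CLASSES],
                var_name="class", value_name="value",
            )
            long["class"] = long["class"].str.split("_").str[-1]
            long = long.rename(columns={"condition": "group"})
            try:
                stats_results += metric_anova(long, met_name.lower(),
                                              group_col="group")
            except Exception as err:  # degenerate smoke cohorts
                anova_tables.append(f"{met_name}: {err}")
    if len(group_sets) >= 2:
        two_groups = {c: {g: m for g, m in gm.items() if g in ("HC", "CI_pre")}
                      for c, gm in group_maps_by_class.items()}
        if all(len(gm) == 2 for gm in two_groups.values()):
            stats_results += tanova_by_class(
                two_groups, n_perm=int(_get(config, "stats.n_perm", 500)),
                seed=int(rng.integers(2**31)),
            )
    if "CI_pre" in orgtms and "CI_post" in orgtms:
        stats_results += transition_tests(
            np.stack(orgtms["CI_pre"]), np.stack(orgtms["CI_post"]), paired=True
        )
    stats_results += clinical_change_tests(cohort.table)
    stats = results_table(stats_results)

    outputs: dict[str, Any] = {
        "cohort": cohort,
        "metrics": metrics,
        "templates": templates,
        "stats": stats,
    }
    manifest.warnings.extend(anova_tables)
    if outdir:
        metrics.to_csv(outdir / "metrics.csv", index=False)
        stats.to_csv(outdir / "stats.csv", index=False)
        for key, tset in templates.items():
            pd.DataFrame(tset.maps.T, index=tset.channel_names, columns=tset.labels
                         ).to_csv(outdir / f"templates_{key}.csv")
        cohort.table.to_csv(outdir / "cohort.csv", index=False)
        manifest.outputs = [str(p) for p in sorted(outdir.glob("*.csv"))]
        manifest.finalize(outdir)
    return outputs


# ---------------------------------------------------------------------------
# prediction stage


def run_prediction_stage(
    config: dict,
    feature_table: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> dict[str, Any]:
    """Responder labeling, feature selection, model zoo and evaluation.

    ``feature_table`` must carry PSQI_pre/PSQI_post plus baseline feature
    columns; when None, a cohort is simulated from the config. ``pre_split_oversample``
    toggles pre-split oversampling (optimistic, flagged).
    """
    seed = int(_require(config, "seed"))
    outdir = Path(outdir) if outdir is not None else None
    manifest = RunManifest(stage="predict", config=config, seeds={"root": seed})
    if outdir:
        manifest.write(outdir)

    if feature_table is None:
        spec = CohortSpec(
            n_hc=2,
            n_ci=int(_get(config, "simulate.n_ci", 41)),
            n_responders=int(_get(config, "simulate.n_responders", 14)),
            emit_recordings=False,
            seed=seed,
        )
        cohort = simulate_cohort(spec)
        feature_table = cohort.table[cohort.table["group"] == "CI"].reset_index(drop=True)

    for col in ("PSQI_pre", "PSQI_post"):
        if col not in feature_table.columns:
            raise ConfigSchemaError(f"feature table missing column: {col}")
    labels, label_summary = label_responders(
        feature_table["PSQI_pre"].to_numpy(),
        feature_table["PSQI_post"].to_numpy(),
        threshold_fraction=float(_get(config, "predict.threshold_fraction", 0.5)),
        strict=bool(_get(config, "predict.strict_threshold", False)),
    )
    feat_cols = [c for c in FEATURE_VOCABULARY if c in feature_table.columns]
    if not feat_cols:
        raise ConfigSchemaError("feature table carries no microstate feature columns")
    x = feature_table[feat_cols]

    report: SelectionReport = select_features(
        x,
        labels,
        k=int(_get(config, "predict.top_k", 15)),
        b=int(_get(config, "predict.stability_b", 100)),
        freq_threshold=float(_get(config, "predict.stability_threshold", 0.75)),
        min_methods=int(_get(config, "predict.min_methods", 3)),
        vif_threshold=float(_get(config, "predict.vif_threshold", 10.0)),
        corr_threshold=float(_get(config, "predict.corr_threshold", 0.8)),
        seed=seed,
        order=str(_get(config, "predict.stage_order", "stability_then_consensus")),
    )
    final = report.final_features if len(report.final_features) >= 2 else feat_cols
    eval_report: EvalReport = evaluate_models(
        x[final],
        labels,
        n_splits=int(_get(config, "predict.n_splits", 100)),
        train_fraction=float(_get(config, "predict.train_fraction", 0.75)),
        seed=int(_get(config, "predict.model_seed", 42)),
        pre_split_oversample=bool(_get(config, "predict.pre_split_oversample", False)),
    )
    fitted, _ = fit_model_zoo(x[final], labels, seed=int(_get(config, "predict.model_seed", 42)),
                              models=(eval_report.best_model,))
    shap_rep = shap_summary(fitted[eval_report.best_model], x[final])

    outputs = {
        "labels": labels,
        "label_summary": label_summary,
        "selection": report,
        "evaluation": eval_report,
        "shap": shap_rep,
    }
    if outdir:
        (outdir / "selection.json").write_text(json.dumps(
            {
                "per_method_topk": report.per_method_topk,
                "stable_sets": report.stable_sets,
                "consensus": report.consensus,
                "venn_counts": report.venn_counts,
                "pruned": [dataclasses.asdict(p) for p in report.pruned],
                "final_features": report.final_features,
                "config": report.config,
            }, indent=2))
        eval_report.summary.to_csv(outdir / "evaluation.csv")
        (outdir / "evaluation.json").write_text(json.dumps(
            {
                "best_model": eval_report.best_model,
                "oversample_mode": eval_report.oversample_mode,
                "optimistic": eval_report.optimistic,
                "skipped_models": eval_report.skipped_models,
                "n_splits": eval_report.n_splits,
                "summary": eval_report.summary.round(6).to_dict(),
            }, indent=2))
        manifest.outputs = [str(p) for p in sorted(outdir.iterdir())]
        if not shap_rep.available:
            manifest.warnings.append(shap_rep.message)
        manifest.finalize(outdir)
    return outputs
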