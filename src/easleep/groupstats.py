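"""Group-level statistics on microstate metrics, topographies and clinical scales.

The comparisons mirror a standard cohort design: healthy controls vs patients
at baseline (unpaired), and patients before vs after treatment (paired).
Normality is gated per variable with the Shapiro–Wilk test: normal data use
t-tests and are summarized as mean ± SD; non-normal data use Wilcoxon /
Mann–Whitney and are summarized as median (IQR). Family-wise error is
controlled with Bonferroni adjustment; the family size used is always emitted
with the adjusted value.

Topographic differences between groups are tested with a nonparametric
permutation TANOVA: the statistic is 1 - |Pearson r| between unit-norm
group-mean maps (the global map dissimilarity), with the null built by
permuting group membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .microstates import CLASSES, _demean_rows, _normalize_rows

SHAPIRO_ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass
class StatResult:
    test_name: str
    effect_name: str
    statistic: float
    df: float | None
    p_raw: float
    p_adjusted: float
    adjustment: str  # "bonferroni" | "none"
    family_size: int
    group_summaries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise StatsError("p values must lie in [0, 1]")
        if self.p_adjusted + 1e-12 < self.p_raw:
            raise StatsError("adjusted p cannot be below raw p")


def bonferroni(p: float, family_size: int) -> float:
    return float(min(1.0, p * family_size))


def _summary(x: np.ndarray, normal: bool) -> str:
    x = np.asarray(x, dtype=float)
    if normal:
        return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q3 - q1:.2f})"


def _is_normal(x: np.ndarray) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return True
    return stats.shapiro(x).pvalue > SHAPIRO_ALPHA


# ---------------------------------------------------------------------------
# TANOVA


def _global_polarity_align(maps: np.ndarray) -> np.ndarray:
    """Flip each map's sign to agree with the pooled principal orientation.

    Subject maps from polarity-invariant clustering carry arbitrary signs;
    aligning them once to the pooled first principal component (a
    permutation-invariant reference) makes plain group means well defined
    without destabilizing the permutation null.
    """
    m = _normalize_rows(_demean_rows(maps))
    _, vecs = np.linalg.eigh(m.T @ m)
    ref = vecs[:, -1]
    signs = np.sign(m @ ref)
    signs[signs == 0] = 1.0
    return signs[:, None] * m


def _group_mean(maps: np.ndarray) -> np.ndarray:
    mean = maps.mean(axis=0)
    n = np.linalg.norm(mean)
    return mean / n if n > 0 else mean


def _map_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    return 1.0 - abs(float(a @ b))


def tanova_permutation(
    group_maps: dict[str, np.ndarray],
    n_perm: int = 1000,
    seed: int | None = None,
    class_label: str = "",
) -> StatResult:
    """Permutation test for a topography difference between groups.

    ``group_maps`` maps group name -> (n_subjects, n_channels) subject maps of
    one microstate class. For two groups the statistic is the dissimilarity
    between polarity-aligned group means; for more, the mean pairwise
    dissimilarity. p = (1 + #{null >= observed}) / (1 + n_perm). Adjust over
    classes with :func:`bonferroni` at the call site (see
    :func:`tanova_by_class`).
    """
    names = sorted(group_maps)
    if len(names) < 2:
        raise StatsError("need at least 2 groups")
    sizes = []
    for g in names:
        if np.atleast_2d(group_maps[g]).shape[0] < 2:
            raise StatsError(f"group {g!r} has fewer than 2 subjects")
        sizes.append(np.atleast_2d(group_maps[g]).shape[0])
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse")
    pooled = _global_polarity_align(
        np.vstack([np.atleast_2d(group_maps[g]) for g in names])
    )
    bounds = np.cumsum([0] + sizes)

    def statistic(m: np.ndarray) -> float:
        means = [_group_mean(m[bounds[i]:bounds[i + 1]]) for i in range(len(names))]
        pairs = [
            _map_dissimilarity(means[i], means[j])
            for i in range(len(means)) for j in range(i + 1, len(means))
        ]
        return float(np.mean(pairs))

    observed = statistic(pooled)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        if statistic(pooled[perm]) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return StatResult(
        test_name="tanova_permutation",
        effect_name=f"topography[{class_label}]" if class_label else "topography",
        statistic=observed,
        df=None,
        p_raw=p,
        p_adjusted=p,
        adjustment="none",
        family_size=1,
        group_summaries={g: f"n={s}" for g, s in zip(names, sizes)},
    )


def tanova_by_class(
    group_maps_by_class: dict[str, dict[str, np.ndarray]],
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[StatResult]:
    """Per-class TANOVA, Bonferroni-adjusted over the classes."""
    family = len(group_maps_by_class)
    out = []
    rng = np.random.default_rng(seed)
    for label, gm in group_maps_by_class.items():
        r = tanova_permutation(gm, n_perm=n_perm, seed=int(rng.integers(2**31)), class_label=label)
        r.p_adjusted = bonferroni(r.p_raw, family)
        r.adjustment = "bonferroni"
        r.family_size = family
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# mixed-design ANOVA on metrics


def metric_anova(
    metrics: pd.DataFrame,
    metric: str,
    *,
    subject_col: str = "subject_id",
    group_col: str = "group",
    class_col: str = "class",
    value_col: str = "value",
) -> list[StatResult]:
    """Mixed two-way ANOVA: group (between) x microstate class (within).

    ``metrics`` is long-form with one row per subject x class. Returns the
    main effects and the interaction for the chosen metric. No sphericity
    correction is applied to the within factor (switch to pingouin's corrected
    p-values downstream if desired).
    """
    import pingouin as pg

    data = metrics.copy()
    counts = data.groupby([subject_col])[class_col].nunique()
    n_classes = data[class_col].nunique()
    bad = counts[counts != n_classes]
    if len(bad):
        raise StatsError(f"missing class cells for subjects: {list(bad.index)}")
    if data[value_col].std(ddof=0) == 0:
        # zero-variance degenerate input: no effect, not a crash
        return [
            StatResult("mixed_anova", f"{metric}:{eff}", 0.0, None, 1.0, 1.0,
                       "none", 1)
            for eff in ("group", "class", "interaction")
        ]
    aov = pg.mixed_anova(
        data=data, dv=value_col, within=class_col, subject=subject_col,
        between=group_col, correction=False,
    )
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    name_map = {group_col: "group", class_col: "class", "Interaction": "interaction"}
    out = []
    for _, row in aov.iterrows():
        eff = name_map.get(str(row["Source"]), str(row["Source"]))
        p = float(row[p_col]) if np.isfinite(row[p_col]) else 1.0
        out.append(
            StatResult(
                test_name="mixed_anova",
                effect_name=f"{metric}:{eff}",
                statistic=float(row["F"]) if np.isfinite(row["F"]) else 0.0,
                df=float(row["DF1"]),
                p_raw=p,
                p_adjusted=p,
                adjustment="none",
                family_size=1,
            )
        )
    return out


# ---------------------------------------------------------------------------
# pairwise post-hoc tests


def _gate_and_test(a: np.ndarray, b: np.ndarray, paired: bool) -> tuple[str, float, float | None, float, bool]:
    """Shapiro-gated parametric/rank test. Returns (name, stat, df, p, normal)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        diff = a - b
        normal = _is_normal(diff)
        if np.ptp(diff) == 0:
            return "paired_t", 0.0, float(a.size - 1), 1.0, True
        if normal:
            r = stats.ttest_rel(a, b)
            return "paired_t", float(r.statistic), float(a.size - 1), float(r.pvalue), True
        r = stats.wilcoxon(a, b)
        return "wilcoxon", float(r.statistic), None, float(r.pvalue), False
    normal = _is_normal(a) and _is_normal(b)
    if np.ptp(np.concatenate([a, b])) == 0:
        return "t", 0.0, float(a.size + b.size - 2), 1.0, True
    if normal:
        r = stats.ttest_ind(a, b)
        return "t", float(r.statistic), float(a.size + b.size - 2), float(r.pvalue), True
    r = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mann_whitney", float(r.statistic), None, float(r.pvalue), False


def posthoc_pairwise(
    data: dict[str, np.ndarray],
    contrasts: list[tuple[str, str]],
    paired: bool,
    family_size: int | None = None,
    backend: str = "gated",
) -> list[StatResult]:
    """Normality-gated pairwise comparisons, Bonferroni-adjusted.

    ``backend="dunn"`` uses the rank-based Dunn procedure on the pooled
    samples instead (an alternative to the gated parametric tests).
    """
    if family_size is None:
        family_size = len(contrasts)
    out = []
    if backend == "dunn":
        return _dunn_test(data, contrasts, family_size)
    for a_name, b_name in contrasts:
        a, b = np.asarray(data[a_name]), np.asarray(data[b_name])
        if a.size < 3 or b.size < 3:
            raise StatsError(f"contrast ({a_name}, {b_name}): need n >= 3 per sample")
        name, statv, df, p, normal = _gate_and_test(a, b, paired)
        out.append(
            StatResult(
                test_name=name,
                effect_name=f"{a_name} vs {b_name}",
                statistic=statv,
                df=df,
                p_raw=p,
                p_adjusted=bonferroni(p, family_size),
                adjustment="bonferroni",
                family_size=family_size,
                group_summaries={
                    a_name: _summary(a, normal),
                    b_name: _summary(b, normal),
                },
            )
        )
    return out


def _dunn_test(
    data: dict[str, np.ndarray], contrasts: list[tuple[str, str]], family_size: int
) -> list[StatResult]:
    """Dunn's rank-sum z test with tie correction over the pooled groups."""
    names = sorted({n for pair in contrasts for n in pair})
    pooled = np.concatenate([np.asarray(data[n], dtype=float) for n in names])
    sizes = {n: np.asarray(data[n]).size for n in names}
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    pos = 0
    for n in names:
        mean_rank[n] = ranks[pos:pos + sizes[n]].mean()
        pos += sizes[n]
    big_n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (big_n - 1))
    out = []
    for a_name, b_name in contrasts:
        se = np.sqrt(
            (big_n * (big_n + 1) / 12.0 - tie_term)
            * (1.0 / sizes[a_name] + 1.0 / sizes[b_name])
        )
        z = (mean_rank[a_name] - mean_rank[b_name]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        out.append(
            StatResult(
                test_name="dunn",
                effect_name=f"{a_name} vs {b_name}",
                statistic=float(z),
                df=None,
                p_raw=float(p),
                p_adjusted=bonferroni(p, family_size),
                adjustment="bonferroni",
                family_size=family_size,
            )
        )
    return out


# ---------------------------------------------------------------------------
# transitions and clinical scales


def transition_tests(
    orgtm_a: np.ndarray, orgtm_b: np.ndarray, paired: bool = True
) -> list[StatResult]:
    """One test per ordered off-diagonal class pair (family of 12).

    ``orgtm_a``/``orgtm_b`` are (n_subjects, K, K) stacks of per-subject
    OrgTM matrices for the two conditions/groups.
    """
    orgtm_a = np.asarray(orgtm_a, dtype=float)
    orgtm_b = np.asarray(orgtm_b, dtype=float)
    k = orgtm_a.shape[1]
    family = k * (k - 1)
    out = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            a, b = orgtm_a[:, i, j], orgtm_b[:, i, j]
            name, statv, df, p, normal = _gate_and_test(a, b, paired)
            out.append(
                StatResult(
                    test_name=name,
                    effect_name=f"OrgTM_{CLASSES[i]}->{CLASSES[j]}",
                    statistic=statv,
                    df=df,
                    p_raw=p,
                    p_adjusted=bonferroni(p, family),
                    adjustment="bonferroni",
                    family_size=family,
                    group_summaries={"a": _summary(a, normal), "b": _summary(b, normal)},
                )
            )
    return out


CLINICAL_SCALES = ("PSQI", "ISI", "HAS", "FSS", "HAMD", "HAMA")


def clinical_change_tests(cohort: pd.DataFrame,
                          scales: tuple[str, ...] = CLINICAL_SCALES) -> list[StatResult]:
    """Pre/post tests per clinical scale in the patient group, Shapiro-gated."""
    ci = cohort[cohort["group"] == "CI"]
    out = []
    for scale in scales:
        pre_col, post_col = f"{scale}_pre", f"{scale}_post"
        for col in (pre_col, post_col):
            if col not in cohort.columns:
                raise StatsError(f"missing clinical column {col!r}")
        pre = ci[pre_col].to_numpy(dtype=float)
        post = ci[post_col].to_numpy(dtype=float)
        name, statv, df, p, normal = _gate_and_test(pre, post, paired=True)
        out.append(
            StatResult(
                test_name=name,
                effect_name=f"{scale} pre vs post",
                statistic=statv,
                df=df,
                p_raw=p,
                p_adjusted=p,
                adjustment="none",
                family_size=1,
                group_summaries={"pre": _summary(pre, normal), "post": _summary(post, normal)},
            )
        )
    return out


def demographic_tests(cohort: pd.DataFrame) -> list[StatResult]:
    """Between-group demographics: chi-square for sex, t for continuous columns."""
    out = []
    if "sex" in cohort.columns:
        tab = pd.crosstab(cohort["group"], cohort["sex"])
        chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
        out.append(StatResult("chi_square", "sex", float(chi2), float(dof),
                              float(p), float(p), "none", 1))
    for col in ("age", "education_years"):
        if col in cohort.columns:
            a = cohort.loc[cohort["group"] == "HC", col].dropna().to_numpy(dtype=float)
            b = cohort.loc[cohort["group"] == "CI", col].dropna().to_numpy(dtype=float)
            r = stats.ttest_ind(a, b)
            out.append(StatResult("t", col, float(r.statistic),
                                  float(a.size + b.size - 2), float(r.pvalue),
                                  float(r.pvalue), "none", 1,
                                  {"HC": _summary(a, True), "CI": _summary(b, True)}))
    return out


def results_table(results: list[StatResult]) -> pd.DataFrame:
    """Tidy table of statistical results (one row per effect)."""
    return pd.DataFrame(
        [
            {
                "test": r.test_name,
                "effect": r.effect_name,
                "statistic": r.statistic,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "adjustment": r.adjustment,
                "family_size": r.family_size,
                **{f"summary[{k}]": v for k, v in r.group_summaries.items()},
            }
            for r in results
        ]
    )
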