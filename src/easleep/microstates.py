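"""EEG microstate segmentation and temporal statistics.

Resting EEG is modeled as a sequence of a few quasi-stable scalp topographies
("microstates", canonically four classes A–D). The analysis here follows the
standard two-level workflow:

1. compute global field power (GFP) and extract topographic maps at GFP peaks;
2. cluster peak maps with a polarity-invariant ("modified") K-means, per
   subject, then cluster all subject templates again to obtain group templates;
3. back-fit group templates to each subject's GFP peaks by maximum absolute
   spatial correlation, yielding a per-subject state sequence;
4. derive temporal metrics — Coverage (% of analyzed time), Duration (mean
   episode length, ms), Occurrence (episodes/s) — and the organizational
   transition matrix OrgTM (% of all observed between-class transitions).

Polarity invariance is fundamental: a map and its negation belong to the same
class, so all correlations are taken in absolute value and cluster centroids
are principal orientations (dominant eigenvectors) of the assigned maps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .recording import Recording

logger = logging.getLogger(__name__)

CLASSES = ("A", "B", "C", "D")


class MicrostateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass
class TemplateSet:
    """K unit-norm, zero-mean (average-referenced) topographies.

    A TemplateSet and its row-wise negation are equivalent under every
    operation in this module.
    """

    maps: np.ndarray  # (K, n_channels)
    labels: tuple[str, ...]
    channel_names: tuple[str, ...]
    level: str = "subject"  # "subject" | "group"

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.labels = tuple(self.labels)
        self.channel_names = tuple(self.channel_names)
        if self.maps.ndim != 2 or self.maps.shape[0] != len(self.labels):
            raise MicrostateError("maps must be (K, n_channels) with one label per row")
        if self.maps.shape[1] != len(self.channel_names):
            raise MicrostateError("channel_names length must match map columns")
        if np.abs(self.maps.mean(axis=1)).max() > 1e-9:
            raise MicrostateError("template rows must have zero channel-mean")
        if np.abs(np.linalg.norm(self.maps, axis=1) - 1.0).max() > 1e-9:
            raise MicrostateError("template rows must be unit L2 norm")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def reorder(self, order: list[int] | np.ndarray, labels: tuple[str, ...]) -> "TemplateSet":
        return replace(self, maps=self.maps[list(order)], labels=tuple(labels))


@dataclass
class PeakSequence:
    """Back-fitted state labels at GFP peaks (the per-subject time-state sequence)."""

    peak_samples: np.ndarray  # strictly increasing sample indices
    label_idx: np.ndarray  # index into `labels` per peak
    labels: tuple[str, ...]  # class tags (ordered as in the TemplateSet)
    abs_corr: np.ndarray  # |spatial correlation| per peak, in [0, 1]
    rate: float
    total_samples: int

    def __post_init__(self) -> None:
        self.peak_samples = np.asarray(self.peak_samples, dtype=int)
        self.label_idx = np.asarray(self.label_idx, dtype=int)
        self.abs_corr = np.asarray(self.abs_corr, dtype=float)
        if np.any(np.diff(self.peak_samples) <= 0):
            raise MicrostateError("peak samples must be strictly increasing")
        if self.abs_corr.size and (self.abs_corr.min() < -1e-12 or self.abs_corr.max() > 1 + 1e-12):
            raise MicrostateError("abs_corr must lie in [0, 1]")

    @property
    def n_peaks(self) -> int:
        return self.peak_samples.size


@dataclass
class MicrostateMetrics:
    """Per-subject temporal metrics over the microstate classes.

    coverage sums to 100 (all peaks assigned), orgtm entries sum to 100 over
    the off-diagonal, and per class coverage/100 == occurrence * duration/1000
    (time in state = episode rate x mean episode length).
    """

    labels: tuple[str, ...]
    coverage: np.ndarray  # per class, % of analyzed time
    duration: np.ndarray  # per class, mean episode length in ms
    occurrence: np.ndarray  # per class, episodes per second
    orgtm: np.ndarray  # (K, K) % of all transitions, zero diagonal
    n_transitions: int
    analyzed_s: float

    def to_dict(self) -> dict[str, float]:
        """Flatten to the Duration_X / Occurrence_X / Coverage_X / OrgTM_X->Y vocabulary."""
        out: dict[str, float] = {}
        for i, lab in enumerate(self.labels):
            out[f"Coverage_{lab}"] = float(self.coverage[i])
            out[f"Duration_{lab}"] = float(self.duration[i])
            out[f"Occurrence_{lab}"] = float(self.occurrence[i])
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i != j:
                    out[f"OrgTM_{a}->{b}"] = float(self.orgtm[i, j])
        return out


# ---------------------------------------------------------------------------
# GFP and peaks


def compute_gfp(rec: Recording, *, strict: bool = True) -> np.ndarray:
    """Global field power: per-sample population SD across channels.

    GFP(t) = sqrt(mean_c (v_c(t) - mean_c v(t))^2). For average-referenced
    data the inner mean is ~0 and GFP is the spatial RMS.
    """
    if strict and not rec.is_average_referenced(rel_tol=1e-6):
        raise MicrostateError("GFP expects an average-referenced recording")
    return rec.data.std(axis=0, ddof=0)


def gfp_of_maps(maps: np.ndarray) -> np.ndarray:
    """Population SD of each map row (the GFP of an instantaneous topography)."""
    return np.asarray(maps, dtype=float).std(axis=1, ddof=0)


def find_gfp_peaks(gfp: np.ndarray, rate: float, min_distance_ms: float = 10.0) -> np.ndarray:
    """Strict local maxima of the GFP series, separated by >= min_distance_ms.

    Endpoints are excluded; a constant series yields no peaks.
    """
    gfp = np.asarray(gfp, dtype=float)
    if gfp.size < 3:
        raise MicrostateError("GFP series must have at least 3 samples")
    distance = max(1, int(round(min_distance_ms / 1000.0 * rate)))
    peaks, _ = find_peaks(gfp, distance=distance)
    return peaks


# ---------------------------------------------------------------------------
# spatial correlation helpers


def _demean_rows(maps: np.ndarray) -> np.ndarray:
    maps = np.asarray(maps, dtype=float)
    return maps - maps.mean(axis=1, keepdims=True)


def _normalize_rows(maps: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms = np.where(norms > 0, norms, 1.0)
    return maps / norms


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels of average-referenced maps.

    ``a``: (n, C) or (C,); ``b``: (m, C) or (C,). Returns (n, m) (squeezed for
    1-D inputs). Signed; take ``abs`` for polarity-free comparisons.
    """
    a2 = _normalize_rows(_demean_rows(np.atleast_2d(a)))
    b2 = _normalize_rows(_demean_rows(np.atleast_2d(b)))
    out = a2 @ b2.T
    if np.ndim(a) == 1 and np.ndim(b) == 1:
        return out[0, 0]
    if np.ndim(a) == 1 or np.ndim(b) == 1:
        return out.ravel()
    return out


# ---------------------------------------------------------------------------
# modified (polarity-invariant) K-means


@dataclass
class ModKMeansResult:
    templates: TemplateSet
    assignment: np.ndarray  # cluster index per input map
    gev: float
    restart_gevs: np.ndarray = field(default_factory=lambda: np.empty(0))


def _gev_of(weights_sq: np.ndarray, abs_corr: np.ndarray) -> float:
    denom = weights_sq.sum()
    if denom == 0:
        return 0.0
    return float((weights_sq * abs_corr**2).sum() / denom)


def _principal_map(maps: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of sum_i v_i v_i^T — the principal orientation."""
    s = maps.T @ maps
    vals, vecs = np.linalg.eigh(s)
    v = vecs[:, -1]
    v = v - v.mean()
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def modified_kmeans(
    maps: np.ndarray,
    k: int = 4,
    restarts: int = 100,
    seed: int | None = None,
    *,
    weights: np.ndarray | None = None,
    channel_names: tuple[str, ...] | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
    level: str = "subject",
) -> ModKMeansResult:
    """Polarity-invariant K-means on topographic maps.

    Assignment maximizes squared spatial correlation; the centroid update is
    the dominant eigenvector of the assigned maps' outer-product sum, so a map
    and its negation are interchangeable. The best of ``restarts`` random
    initializations by GFP^2-weighted global explained variance (GEV) wins.

    Parameters
    ----------
    maps : (n, C) array of instantaneous topographies (any reference; rows are
        demeaned internally).
    weights : optional per-map GFP values used in the GEV criterion; defaults
        to each map's own GFP.
    """
    maps = _demean_rows(maps)
    n = maps.shape[0]
    if k > n:
        raise MicrostateError(f"k={k} exceeds the number of maps ({n})")
    if weights is None:
        weights = gfp_of_maps(maps)
    w_sq = np.asarray(weights, dtype=float) ** 2
    normed = _normalize_rows(maps)
    rng = np.random.default_rng(seed)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(maps.shape[1]))

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    restart_gevs = np.empty(restarts)
    for r in range(restarts):
        idx = rng.choice(n, size=k, replace=False)
        templates = _normalize_rows(maps[idx].copy())
        templates = templates - templates.mean(axis=1, keepdims=True)
        templates = _normalize_rows(templates)
        assignment = np.full(n, -1)
        gev_prev = -np.inf
        for _ in range(max_iter):
            corr = np.abs(normed @ templates.T)  # (n, k)
            new_assignment = corr.argmax(axis=1)
            fit = corr[np.arange(n), new_assignment]
            # re-seed empty clusters from the worst-fit map
            for c in range(k):
                if not np.any(new_assignment == c):
                    worst = int(np.argmin(fit))
                    logger.debug("restart %d: empty cluster %d re-seeded from map %d", r, c, worst)
                    new_assignment[worst] = c
                    fit[worst] = 1.0
            gev = _gev_of(w_sq, corr[np.arange(n), new_assignment])
            converged = np.array_equal(new_assignment, assignment) or (
                np.isfinite(gev_prev) and abs(gev - gev_prev) <= tol * max(gev_prev, 1e-30)
            )
            assignment = new_assignment
            gev_prev = gev
            for c in range(k):
                members = maps[assignment == c]
                if members.shape[0]:
                    templates[c] = _principal_map(members)
            if converged:
                break
        corr = np.abs(normed @ templates.T)
        assignment = corr.argmax(axis=1)
        gev = _gev_of(w_sq, corr[np.arange(n), assignment])
        restart_gevs[r] = gev
        if best is None or gev > best[0]:
            best = (gev, templates.copy(), assignment.copy())

    assert best is not None
    gev, templates, assignment = best
    tset = TemplateSet(
        maps=templates,
        labels=tuple(str(i) for i in range(k)),
        channel_names=channel_names,
        level=level,
    )
    return ModKMeansResult(tset, assignment, gev, restart_gevs)


def two_level_templates(
    subject_template_sets: list[TemplateSet],
    k: int = 4,
    restarts: int = 100,
    seed: int | None = None,
) -> ModKMeansResult:
    """Pool all subject templates and re-cluster them into group templates."""
    if len(subject_template_sets) < 2:
        raise MicrostateError("need at least 2 subjects for group-level clustering")
    ch = subject_template_sets[0].channel_names
    for ts in subject_template_sets[1:]:
        if ts.channel_names != ch:
            raise MicrostateError("subjects have mismatched channel sets")
    pooled = np.vstack([ts.maps for ts in subject_template_sets])
    res = modified_kmeans(
        pooled, k=k, restarts=restarts, seed=seed,
        weights=np.ones(pooled.shape[0]), channel_names=ch, level="group",
    )
    return res


def assign_canonical_labels(
    templates: TemplateSet, reference: TemplateSet | None = None
) -> tuple[TemplateSet, dict[str, float]]:
    """Relabel templates A–D by best match to a reference set (polarity-free).

    All 4! label permutations are evaluated; the one maximizing the total
    absolute spatial correlation wins (ties broken by lexicographic
    permutation order). Returns the relabeled set, rows reordered to the
    reference label order, plus per-class match values.
    """
    if reference is None:
        from .synthgen import make_template_set

        reference = make_template_set(montage=None, channel_names=templates.channel_names)
    if templates.k != reference.k:
        raise MicrostateError("template sets must have the same k")
    if templates.channel_names != reference.channel_names:
        raise MicrostateError("template sets must share the channel space")
    corr = np.abs(spatial_correlation(reference.maps, templates.maps))  # (k_ref, k)
    best_perm: tuple[int, ...] | None = None
    best_total = -np.inf
    for perm in itertools.permutations(range(templates.k)):
        total = sum(corr[i, p] for i, p in enumerate(perm))
        if total > best_total + 1e-9:
            best_total = total
            best_perm = perm
        elif abs(total - best_total) <= 1e-9 and best_perm is not None and perm < best_perm:
            logger.debug("canonical labeling tie at %.9f; lexicographic tie-break", total)
            best_perm = perm
    assert best_perm is not None
    relabeled = templates.reorder(list(best_perm), reference.labels)
    matches = {
        lab: float(corr[i, best_perm[i]]) for i, lab in enumerate(reference.labels)
    }
    return relabeled, matches


# ---------------------------------------------------------------------------
# back-fitting and metrics


def backfit_peaks(
    rec: Recording, templates: TemplateSet, min_distance_ms: float = 10.0
) -> PeakSequence:
    """Assign each GFP peak to the template with maximum |spatial correlation|."""
    gfp = compute_gfp(rec)
    peaks = find_gfp_peaks(gfp, rec.rate, min_distance_ms)
    maps = rec.data[:, peaks].T  # (n_peaks, C)
    variances = maps.std(axis=1)
    keep = variances > 0
    if not np.all(keep):
        logger.warning("dropping %d zero-variance peak maps", int((~keep).sum()))
        peaks, maps = peaks[keep], maps[keep]
    corr = np.abs(spatial_correlation(maps, templates.maps))
    label_idx = corr.argmax(axis=1)
    abs_corr = corr[np.arange(corr.shape[0]), label_idx]
    return PeakSequence(
        peak_samples=peaks,
        label_idx=label_idx,
        labels=templates.labels,
        abs_corr=np.clip(abs_corr, 0.0, 1.0),
        rate=rec.rate,
        total_samples=rec.n_samples,
    )


def compute_metrics(seq: PeakSequence) -> MicrostateMetrics:
    """Temporal metrics from a back-fitted peak sequence.

    Peak labels are expanded to continuous time by nearest-peak assignment:
    each peak owns the interval between the midpoints to its neighbours, and
    the first/last cells are extended outward by half the adjacent spacing.
    Maximal same-label runs define episodes.
    """
    if seq.n_peaks < 2:
        raise MicrostateError("need at least 2 peaks to compute metrics")
    k = len(seq.labels)
    t = seq.peak_samples / seq.rate  # seconds
    mid = (t[:-1] + t[1:]) / 2.0
    left = np.concatenate([[t[0] - (t[1] - t[0]) / 2.0], mid])
    right = np.concatenate([mid, [t[-1] + (t[-1] - t[-2]) / 2.0]])
    cell = right - left  # time owned by each peak
    total = float(cell.sum())

    # maximal same-label runs
    lab = seq.label_idx
    change = np.nonzero(np.diff(lab))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [lab.size - 1]])
    ep_label = lab[starts]
    ep_len = np.array([cell[s:e + 1].sum() for s, e in zip(starts, ends)])

    coverage = np.zeros(k)
    duration = np.zeros(k)
    occurrence = np.zeros(k)
    for c in range(k):
        m = ep_label == c
        if m.any():
            coverage[c] = 100.0 * ep_len[m].sum() / total
            duration[c] = 1000.0 * ep_len[m].mean()
            occurrence[c] = m.sum() / total

    orgtm = np.zeros((k, k))
    n_transitions = ep_label.size - 1
    if n_transitions > 0:
        np.add.at(orgtm, (ep_label[:-1], ep_label[1:]), 1.0)
        orgtm *= 100.0 / n_transitions
    else:
        logger.warning("single-episode sequence: OrgTM undefined (all zero)")
    return MicrostateMetrics(
        labels=seq.labels,
        coverage=coverage,
        duration=duration,
        occurrence=occurrence,
        orgtm=orgtm,
        n_transitions=int(n_transitions),
        analyzed_s=total,
    )


def compute_gev(seq: PeakSequence, gfp: np.ndarray, templates: TemplateSet) -> float:
    """GFP^2-weighted explained variance of the back-fit: sum gfp^2 r^2 / sum gfp^2."""
    w_sq = np.asarray(gfp, dtype=float)[seq.peak_samples] ** 2
    return _gev_of(w_sq, seq.abs_corr)
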