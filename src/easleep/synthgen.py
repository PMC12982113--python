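"""Synthetic EEG recordings and cohorts with known microstate ground truth.

Every downstream stage (preprocessing, segmentation, group statistics,
response prediction) is testable against this generator: it plants four
archetype topographies switched by a semi-Markov chain (gamma dwell times),
rides them on a 10 Hz carrier with additive white sensor noise, and emits a
cohort table with a planted pre-to-post PSQI improvement and planted
baseline-feature/response effects.

The default ground truths are calibrated to a published chronic-insomnia
dataset's group summaries: per-state mean dwell times are the group mean
durations, and the conditional transition matrix is the row-normalized
organizational transition matrix (OrgTM, % of all transitions). Healthy
controls (HC), patients before treatment (CI pre) and after treatment
(CI post) each get their own calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .microstates import CLASSES, TemplateSet, spatial_correlation
from .montage import Montage, standard_montage
from .recording import Recording

__all__ = [
    "GroundTruth",
    "GroupEffects",
    "CohortSpec",
    "Cohort",
    "make_template_set",
    "simulate_state_sequence",
    "synthesize_recording",
    "simulate_recordings",
    "simulate_cohort",
    "synthesize_feature_table",
    "default_truth",
    "FEATURE_VOCABULARY",
]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# group calibrations (per-state mean durations in ms; OrgTM as % of all
# transitions, rows = source state A..D, zero diagonal)

_CAL = {
    "hc": {
        "duration_ms": [58.38, 66.85, 66.52, 75.97],
        "orgtm": [
            [0.0, 6.13, 5.57, 8.19],
            [6.06, 0.0, 7.88, 12.65],
            [5.71, 7.82, 0.0, 9.58],
            [8.08, 12.59, 9.74, 0.0],
        ],
    },
    "ci_pre": {
        "duration_ms": [62.01, 59.75, 69.04, 67.19],
        "orgtm": [
            [0.0, 6.52, 8.01, 9.29],
            [6.65, 0.0, 7.56, 8.60],
            [7.98, 7.58, 0.0, 10.02],
            [9.16, 8.67, 9.97, 0.0],
        ],
    },
    "ci_post": {
        "duration_ms": [57.67, 66.08, 76.36, 51.14],
        "orgtm": [
            [0.0, 6.79, 9.69, 5.56],
            [6.94, 0.0, 13.82, 6.76],
            [9.56, 13.93, 0.0, 7.33],
            [5.52, 6.80, 7.31, 0.0],
        ],
    },
}

#: The 28-name feature vocabulary of the baseline microstate feature table.
FEATURE_VOCABULARY: tuple[str, ...] = tuple(
    [f"Duration_{c}" for c in CLASSES]
    + [f"Occurrence_{c}" for c in CLASSES]
    + [f"Coverage_{c}" for c in CLASSES]
    + [f"OrgTM_{a}->{b}" for a in CLASSES for b in CLASSES if a != b]
)


def _row_normalize(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float).copy()
    np.fill_diagonal(m, 0.0)
    sums = m.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ConfigError("degenerate transition row (all zero)")
    return m / sums


# ---------------------------------------------------------------------------
# archetype templates


def make_template_set(
    n_channels: int = 26,
    montage: Montage | None = None,
    seed: int = 0,
    *,
    channel_names: tuple[str, ...] | None = None,
    jitter: float = 0.0,
) -> TemplateSet:
    """Build the four canonical microstate archetypes A–D over a montage.

    The maps are smooth spatial gradients over projected electrode positions:
    A runs left-posterior to right-anterior, B is its left/right mirror, C is
    a left/right-symmetric fronto-occipital gradient, and D peaks over the
    fronto-central midline. All maps are average-referenced (zero channel
    mean) and unit L2 norm. ``jitter`` adds a small seeded smooth perturbation
    (0 = pure analytic archetypes).
    """
    if montage is None:
        if channel_names is not None:
            montage = standard_montage(channel_names)
        else:
            montage = standard_montage()
            if n_channels != montage.n_channels:
                raise ConfigError(
                    f"default montage has {montage.n_channels} channels, requested {n_channels}"
                )
    if montage.n_channels < 4:
        raise ConfigError("need at least 4 channels to build 4 archetypes")
    xy = montage.xy
    xy = xy - xy.mean(axis=0)
    scale = np.abs(xy).max()
    x, y = (xy / scale).T  # x: left(-) to right(+); y: posterior(-) to anterior(+)

    a = (x + y) / np.sqrt(2.0)  # left-occipital -> right-frontal
    b = (-x + y) / np.sqrt(2.0)  # right-occipital -> left-frontal
    c = y  # symmetric fronto-occipital gradient
    d = np.exp(-((x**2 + (y - 0.35) ** 2) / (2 * 0.45**2)))  # fronto-central max
    maps = np.vstack([a, b, c, d])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        rough = rng.standard_normal(maps.shape)
        # smooth the perturbation over neighbouring electrodes
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1) / scale**2
        kernel = np.exp(-d2 / (2 * 0.3**2))
        kernel /= kernel.sum(axis=1, keepdims=True)
        smooth = rough @ kernel.T
        smooth /= np.linalg.norm(smooth, axis=1, keepdims=True)
        maps = maps / np.linalg.norm(maps, axis=1, keepdims=True) + jitter * smooth
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
    return TemplateSet(maps=maps, labels=CLASSES, channel_names=montage.names, level="group")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Generative parameters for one group's recordings.

    ``transition_matrix`` holds conditional next-state probabilities (rows sum
    to 1, zero diagonal); ``mean_dwell_ms`` the per-state mean dwell times;
    ``snr`` the ratio of microstate-signal RMS to sensor-noise RMS;
    ``carrier_hz`` the oscillation frequency riding the templates.
    """

    templates: TemplateSet
    transition_matrix: np.ndarray
    mean_dwell_ms: np.ndarray
    snr: float = 2.0
    carrier_hz: float = 10.0
    seed: int = 0
    occurrence_target: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.mean_dwell_ms = np.asarray(self.mean_dwell_ms, dtype=float)
        k = self.templates.k
        if self.transition_matrix.shape != (k, k):
            raise ConfigError("transition_matrix must be K x K")
        if np.abs(np.diag(self.transition_matrix)).max() > 0:
            raise ConfigError("transition_matrix diagonal must be exactly 0")
        if np.abs(self.transition_matrix.sum(axis=1) - 1.0).max() > 1e-12:
            raise ConfigError("transition_matrix rows must sum to 1")
        if np.any(self.mean_dwell_ms <= 0):
            raise ConfigError("mean_dwell_ms must be positive")
        if not self.snr > 0:
            raise ConfigError("snr must be positive")
        pair = np.abs(spatial_correlation(self.templates.maps, self.templates.maps))
        np.fill_diagonal(pair, 0.0)
        if pair.max() >= 0.9:
            raise ConfigError("templates not mutually distinct (max |r| >= 0.9)")
        if self.occurrence_target is None:
            self.occurrence_target = self.expected_metrics()["occurrence"]

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the embedded (episode-level) chain."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def expected_metrics(self) -> dict[str, np.ndarray]:
        """Closed-form expectations of the temporal metrics under this truth.

        With episode-level stationary weights pi and dwell means d, mean cycle
        time is T = sum pi_x d_x; Occurrence_X = pi_x / T, Coverage_X =
        100 pi_x d_x / T, OrgTM_X->Y = 100 pi_x P_xy.
        """
        pi = self.stationary()
        d_s = self.mean_dwell_ms / 1000.0
        t_bar = float(pi @ d_s)
        return {
            "duration": self.mean_dwell_ms.copy(),
            "occurrence": pi / t_bar,
            "coverage": 100.0 * pi * d_s / t_bar,
            "orgtm": 100.0 * pi[:, None] * self.transition_matrix,
        }

    def expected_feature_dict(self) -> dict[str, float]:
        m = self.expected_metrics()
        out: dict[str, float] = {}
        for i, c in enumerate(CLASSES):
            out[f"Duration_{c}"] = float(m["duration"][i])
            out[f"Occurrence_{c}"] = float(m["occurrence"][i])
            out[f"Coverage_{c}"] = float(m["coverage"][i])
        for i, a in enumerate(CLASSES):
            for j, b in enumerate(CLASSES):
                if i != j:
                    out[f"OrgTM_{a}->{b}"] = float(m["orgtm"][i, j])
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": list(self.templates.labels),
                "channel_names": list(self.templates.channel_names),
                "templates": self.templates.maps.tolist(),
                "transition_matrix": self.transition_matrix.tolist(),
                "mean_dwell_ms": self.mean_dwell_ms.tolist(),
                "snr": self.snr,
                "carrier_hz": self.carrier_hz,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        tset = TemplateSet(
            maps=np.asarray(obj["templates"]),
            labels=tuple(obj["labels"]),
            channel_names=tuple(obj["channel_names"]),
            level="group",
        )
        return cls(
            templates=tset,
            transition_matrix=np.asarray(obj["transition_matrix"]),
            mean_dwell_ms=np.asarray(obj["mean_dwell_ms"]),
            snr=obj["snr"],
            carrier_hz=obj["carrier_hz"],
            seed=obj["seed"],
        )


def default_truth(
    group: str = "hc",
    *,
    snr: float = 2.0,
    carrier_hz: float = 10.0,
    seed: int = 0,
    montage: Montage | None = None,
) -> GroundTruth:
    """Calibrated ground truth for ``group`` in {'hc', 'ci_pre', 'ci_post'}."""
    if group not in _CAL:
        raise ConfigError(f"unknown group {group!r}; expected one of {sorted(_CAL)}")
    cal = _CAL[group]
    return GroundTruth(
        templates=make_template_set(montage=montage),
        transition_matrix=_row_normalize(np.asarray(cal["orgtm"])),
        mean_dwell_ms=np.asarray(cal["duration_ms"]),
        snr=snr,
        carrier_hz=carrier_hz,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sequence and recording synthesis


_DWELL_SHAPE = 2.0  # gamma shape of the underlying dwell-time law


def _calibrate_gamma_mean(target_s: float, half_cycle_s: float) -> float:
    """Gamma mean m such that quantized dwells average ``target_s``.

    Dwell times are drawn from gamma(shape=2, scale=m/2) and quantized to a
    whole number of carrier half-cycles by stochastic rounding with a floor of
    one; the floor inflates the mean by h * P(round hits zero), so the gamma
    mean is solved (fixed point) to keep the realized mean on target.
    """
    from scipy.stats import gamma as gamma_dist

    h = half_cycle_s
    if target_s <= h:
        raise ConfigError(
            f"mean dwell {target_s*1000:.1f} ms not reachable: it must exceed one "
            f"carrier half-cycle ({h*1000:.1f} ms)"
        )
    m = target_s
    for _ in range(200):
        theta = m / _DWELL_SHAPE
        # P(quantized count = 0) = E[(1 - L/h)^+]
        p0 = gamma_dist.cdf(h, _DWELL_SHAPE, scale=theta) - (
            _DWELL_SHAPE * theta / h
        ) * gamma_dist.cdf(h, _DWELL_SHAPE + 1, scale=theta)
        m_new = target_s - h * p0
        if m_new <= 0:
            m_new = m / 2.0
        if abs(m_new - m) < 1e-12:
            m = m_new
            break
        m = 0.5 * (m + m_new)  # damped fixed point
    if m <= 0:
        raise ConfigError(f"dwell calibration failed for target {target_s*1000:.1f} ms")
    return m


def simulate_state_sequence(
    truth: GroundTruth,
    duration_s: float,
    rate: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Piecewise-constant per-sample state labels from the semi-Markov truth.

    Dwell times follow a gamma law (shape 2, per-state mean ``mean_dwell_ms``)
    quantized to a whole number of carrier half-cycles, so that topography
    switches fall at GFP minima — the quasi-stability that makes microstates
    observable at GFP peaks in real EEG. The quantization is stochastic
    rounding with the gamma mean calibrated so realized dwells average
    ``mean_dwell_ms`` exactly. Successors follow ``transition_matrix`` (zero
    diagonal: no two consecutive segments share a label); the initial state is
    drawn from the embedded chain's stationary distribution.
    """
    if duration_s < 1:
        raise ConfigError("duration_s must be >= 1 s")
    if rate < 100:
        raise ConfigError("rate must be >= 100 Hz")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    k = truth.templates.k
    h = 1.0 / (2.0 * truth.carrier_hz)  # half-cycle (one GFP arch) in seconds
    cal_mean = np.array(
        [_calibrate_gamma_mean(d / 1000.0, h) for d in truth.mean_dwell_ms]
    )
    n = int(round(duration_s * rate))
    n_arches = int(np.ceil(duration_s / h)) + 1
    arch_state = np.empty(n_arches, dtype=int)
    state = int(rng.choice(k, p=truth.stationary()))
    pos = 0
    while pos < n_arches:
        dwell = rng.gamma(_DWELL_SHAPE, cal_mean[state] / _DWELL_SHAPE)
        frac, whole = np.modf(dwell / h)
        arches = int(whole) + int(rng.random() < frac)
        arches = max(1, arches)
        arch_state[pos:pos + arches] = state
        pos += arches
        state = int(rng.choice(k, p=truth.transition_matrix[state]))
    t = np.arange(n) / rate
    return arch_state[np.minimum((t / h).astype(int), n_arches - 1)]


def synthesize_recording(
    truth: GroundTruth,
    state_seq: np.ndarray,
    rate: float,
    rng: np.random.Generator | None = None,
    *,
    target_rms_uv: float = 5.0,
    line_noise_uv: float = 0.0,
    line_hz: float = 50.0,
) -> Recording:
    """Recording = (carrier x active template) + white sensor noise at ``snr``.

    The carrier is a sinusoid at ``carrier_hz`` whose zeros coincide with the
    segment boundaries produced by :func:`simulate_state_sequence`; each
    segment gets a log-normal amplitude and a random polarity (the map's sign
    is unobservable anyway), so GFP peaks arrive at about twice the carrier
    frequency, one per half-cycle arch. ``line_noise_uv`` optionally adds a
    mains sinusoid for notch-filter tests.
    """
    state_seq = np.asarray(state_seq, dtype=int)
    if state_seq.size == 0:
        raise ConfigError("state sequence is empty")
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1)
    n = state_seq.size
    t = np.arange(n) / rate
    change = np.nonzero(np.diff(state_seq))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [n]])
    base = np.sin(2 * np.pi * truth.carrier_hz * t)
    carrier = np.empty(n)
    for s, e in zip(starts, ends):
        amp = rng.lognormal(mean=0.0, sigma=0.3)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        carrier[s:e] = amp * sign * base[s:e]
    signal = truth.templates.maps[state_seq].T * carrier  # (C, n)
    rms = float(np.sqrt(np.mean(signal**2)))
    if rms > 0:
        signal *= target_rms_uv / rms
    data = signal
    if np.isfinite(truth.snr):
        noise = rng.standard_normal(signal.shape) * (target_rms_uv / truth.snr)
        data = signal + noise
    if line_noise_uv > 0:
        data = data + line_noise_uv * np.sin(2 * np.pi * line_hz * t)
    return Recording(
        data=data,
        rate=rate,
        channel_names=truth.templates.channel_names,
        reference="recorded",
        history=(f"synthesized(snr={truth.snr}, carrier_hz={truth.carrier_hz})",),
    )


def simulate_recordings(
    truth: GroundTruth,
    n_subjects: int,
    duration_s: float = 150.0,
    rate: float = 256.0,
    seed: int | None = None,
) -> list[Recording]:
    """Independent recordings for ``n_subjects`` drawn from one ground truth."""
    root = np.random.default_rng(truth.seed if seed is None else seed)
    out = []
    for _ in range(n_subjects):
        rng = np.random.default_rng(root.integers(2**31))
        seq = simulate_state_sequence(truth, duration_s, rate, rng)
        out.append(synthesize_recording(truth, seq, rate, rng))
    return out


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class GroupEffects:
    """Additive offsets turning one group's truth into another's.

    Offsets act on dwell means (ms) and on the conditional transition matrix
    (rows re-normalized after the shift); templates are untouched — group
    topographies did not differ in the calibration dataset.
    """

    dwell_offset_ms: np.ndarray = field(default_factory=lambda: np.zeros(4))
    transition_offset: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))

    def apply(self, truth: GroundTruth) -> GroundTruth:
        dwell = truth.mean_dwell_ms + np.asarray(self.dwell_offset_ms, dtype=float)
        if np.any(dwell <= 0):
            raise ConfigError("group effect drives a dwell mean non-positive")
        p = truth.transition_matrix + np.asarray(self.transition_offset, dtype=float)
        np.fill_diagonal(p, 0.0)
        if np.any(p < 0):
            p = np.clip(p, 1e-3, None)
            np.fill_diagonal(p, 0.0)
        return replace(truth, mean_dwell_ms=dwell, transition_matrix=_row_normalize(p))

    @classmethod
    def between(cls, base: GroundTruth, target: GroundTruth) -> "GroupEffects":
        return cls(
            dwell_offset_ms=target.mean_dwell_ms - base.mean_dwell_ms,
            transition_offset=target.transition_matrix - base.transition_matrix,
        )


#: Planted responder/non-responder baseline shifts, in feature units,
#: following the reported predictor directions (responders: longer Duration_A,
#: shorter Duration_B, more D->B and C->B transitions).
DEFAULT_RESPONDER_EFFECTS: dict[str, float] = {
    "Duration_A": 6.0,
    "Duration_B": -6.0,
    "OrgTM_D->B": 2.5,
    "OrgTM_C->B": 2.5,
}

_SCALES = {  # pre-treatment mean, SD, and planted mean improvement
    "ISI": (16.93, 4.74, 5.86),
    "HAS": (40.71, 9.03, 4.42),
    "FSS": (47.05, 9.63, 6.93),
    "HAMD": (10.20, 3.00, 3.25),
    "HAMA": (9.68, 2.54, 2.83),
}


@dataclass
class CohortSpec:
    """Design of a synthetic cohort (healthy controls + patients)."""

    n_hc: int = 19
    n_ci: int = 41
    n_responders: int = 14
    group_effects: GroupEffects | None = None  # None -> calibrated HC->CI-pre offsets
    responder_feature_effects: dict[str, float] | None = None
    psqi_pre_mean: float = 13.0
    psqi_pre_sd: float = 1.5
    psqi_bounds: tuple[int, int] = (5, 16)  # patient inclusion range
    hc_psqi_mean: float = 4.0
    snr: float = 2.0
    duration_s: float = 150.0
    rate: float = 256.0
    subject_dwell_sigma: float = 0.10  # log-normal between-subject dwell spread
    subject_transition_sigma: float = 0.15  # logit-space transition spread
    emit_recordings: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_ci < 2:
            raise ConfigError("n_hc and n_ci must both be >= 2")
        if not 0 <= self.n_responders <= self.n_ci:
            raise ConfigError("n_responders must lie in [0, n_ci]")
        lo, hi = self.psqi_bounds
        if not (0 < lo < hi):
            raise ConfigError("invalid psqi_bounds")


@dataclass
class Cohort:
    """Simulated cohort: clinical table, planted truths, optional recordings."""

    table: pd.DataFrame  # one row per subject; baseline features + scales
    truths: dict[str, GroundTruth]  # group-level truths (hc, ci_pre, ci_post)
    metrics_post: pd.DataFrame  # per-CI-subject post-treatment feature dicts
    recordings: dict[str, dict[str, Recording]] = field(default_factory=dict)


def _jitter_truth(truth: GroundTruth, spec: CohortSpec, rng: np.random.Generator) -> GroundTruth:
    dwell = truth.mean_dwell_ms * rng.lognormal(0.0, spec.subject_dwell_sigma, size=truth.mean_dwell_ms.size)
    # dwell means must stay above one carrier half-cycle (the arch floor)
    dwell = np.maximum(dwell, 1.05 * 1000.0 / (2.0 * truth.carrier_hz))
    p = truth.transition_matrix.copy()
    off = ~np.eye(p.shape[0], dtype=bool)
    logit = np.log(np.clip(p[off], 1e-6, None))
    logit += rng.normal(0.0, spec.subject_transition_sigma, size=logit.size)
    p[off] = np.exp(logit)
    return replace(truth, mean_dwell_ms=dwell, transition_matrix=_row_normalize(p))


def _plant_feature_effects(truth: GroundTruth, effects: dict[str, float]) -> GroundTruth:
    """Shift a truth so its expected features move by ``effects``.

    Duration_X shifts act on the dwell mean; OrgTM_X->Y shifts (percentage
    points of all transitions) are mapped onto the conditional row via the
    stationary weight. Occurrence/Coverage are emergent and not directly
    plantable.
    """
    dwell = truth.mean_dwell_ms.copy()
    p = truth.transition_matrix.copy()
    pi = truth.stationary()
    idx = {c: i for i, c in enumerate(CLASSES)}
    for name, shift in effects.items():
        if name.startswith("Duration_"):
            i = idx[name.split("_")[1]]
            dwell[i] += shift
            if dwell[i] <= 0:
                raise ConfigError(f"effect on {name} drives dwell non-positive")
        elif name.startswith("OrgTM_"):
            a, b = name[len("OrgTM_"):].split("->")
            i, j = idx[a], idx[b]
            p[i, j] = max(1e-2, p[i, j] + shift / (100.0 * pi[i]))
        else:
            raise ConfigError(
                f"unsupported responder feature effect {name!r} "
                "(only Duration_X and OrgTM_X->Y are plantable)"
            )
    return replace(truth, mean_dwell_ms=dwell, transition_matrix=_row_normalize(p))


_MEAS_NOISE = {"Duration": 3.0, "Occurrence": 0.15, "Coverage": 1.0, "OrgTM": 0.5}


def _noisy_features(truth: GroundTruth, rng: np.random.Generator) -> dict[str, float]:
    feats = truth.expected_feature_dict()
    out = {}
    for name, val in feats.items():
        sd = _MEAS_NOISE[name.split("_")[0]]
        v = val + rng.normal(0.0, sd)
        if name.split("_")[0] in ("Duration", "Occurrence", "Coverage", "OrgTM"):
            v = max(v, 0.0)
        out[name] = v
    return out


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the full cohort with planted group, treatment and responder effects.

    Healthy controls come from the HC calibration; patients pre-treatment from
    HC truth + ``group_effects`` (default: calibrated offsets); post-treatment
    truths have the effects reversed toward the post-treatment calibration for
    planted responders and stay at the pre-treatment truth for non-responders.
    The emitted PSQI columns are constructed so the responder rule recovers the
    planted labels exactly.
    """
    rng = np.random.default_rng(spec.seed)
    hc_truth = default_truth("hc", snr=spec.snr, seed=spec.seed)
    if spec.group_effects is None:
        ci_pre_truth = default_truth("ci_pre", snr=spec.snr, seed=spec.seed)
    else:
        ci_pre_truth = spec.group_effects.apply(hc_truth)
    ci_post_truth = default_truth("ci_post", snr=spec.snr, seed=spec.seed)
    effects = (
        DEFAULT_RESPONDER_EFFECTS
        if spec.responder_feature_effects is None
        else spec.responder_feature_effects
    )

    responder = np.zeros(spec.n_ci, dtype=bool)
    responder[rng.permutation(spec.n_ci)[: spec.n_responders]] = True

    rows: list[dict] = []
    post_rows: list[dict] = []
    recordings: dict[str, dict[str, Recording]] = {}
    lo, hi = spec.psqi_bounds

    for i in range(spec.n_hc):
        sid = f"HC{i+1:02d}"
        sub_truth = _jitter_truth(hc_truth, spec, rng)
        row = {"subject_id": sid, "group": "HC", "responder": np.nan}
        row["PSQI_pre"] = int(np.clip(round(rng.normal(spec.hc_psqi_mean, 1.5)), 0, lo - 1))
        row["PSQI_post"] = np.nan
        for s in _SCALES:
            row[f"{s}_pre"] = np.nan
            row[f"{s}_post"] = np.nan
        row.update(_noisy_features(sub_truth, rng))
        rows.append(row)
        if spec.emit_recordings:
            sub_rng = np.random.default_rng(rng.integers(2**31))
            seq = simulate_state_sequence(sub_truth, spec.duration_s, spec.rate, sub_rng)
            recordings[sid] = {"pre": synthesize_recording(sub_truth, seq, spec.rate, sub_rng)}

    for i in range(spec.n_ci):
        sid = f"CI{i+1:02d}"
        is_resp = bool(responder[i])
        base = ci_pre_truth
        if is_resp:
            base = _plant_feature_effects(base, effects)
        pre_truth = _jitter_truth(base, spec, rng)
        post_truth = _jitter_truth(ci_post_truth if is_resp else ci_pre_truth, spec, rng)

        pre = int(np.clip(round(rng.normal(spec.psqi_pre_mean, spec.psqi_pre_sd)), lo, hi))
        if is_resp:
            frac = rng.uniform(0.55, 0.80)
            post = int(np.floor(pre * (1.0 - frac)))
        else:
            frac = rng.uniform(0.10, 0.42)
            post = int(np.ceil(pre * (1.0 - frac)))
            if (pre - post) / pre >= 0.5:  # integer rounding guard
                post = int(np.ceil(pre / 2.0)) + (0 if pre % 2 else 1)
                post = min(post, pre)
        row = {"subject_id": sid, "group": "CI", "responder": float(is_resp)}
        row["PSQI_pre"] = pre
        row["PSQI_post"] = post
        for s, (mu, sd, delta) in _SCALES.items():
            v_pre = rng.normal(mu, sd)
            v_post = max(0.0, v_pre - rng.normal(delta, 2.0))
            row[f"{s}_pre"] = v_pre
            row[f"{s}_post"] = v_post
        row.update(_noisy_features(pre_truth, rng))
        rows.append(row)
        post_feats = _noisy_features(post_truth, rng)
        post_feats["subject_id"] = sid
        post_rows.append(post_feats)
        if spec.emit_recordings:
            sub_rng = np.random.default_rng(rng.integers(2**31))
            seq = simulate_state_sequence(pre_truth, spec.duration_s, spec.rate, sub_rng)
            rec_pre = synthesize_recording(pre_truth, seq, spec.rate, sub_rng)
            seq2 = simulate_state_sequence(post_truth, spec.duration_s, spec.rate, sub_rng)
            rec_post = synthesize_recording(post_truth, seq2, spec.rate, sub_rng)
            recordings[sid] = {"pre": rec_pre, "post": rec_post}

    table = pd.DataFrame(rows)
    metrics_post = pd.DataFrame(post_rows).set_index("subject_id")
    return Cohort(
        table=table,
        truths={"hc": hc_truth, "ci_pre": ci_pre_truth, "ci_post": ci_post_truth},
        metrics_post=metrics_post,
        recordings=recordings,
    )


# ---------------------------------------------------------------------------
# feature-table test bed


def synthesize_feature_table(
    n_pos: int,
    n_neg: int,
    effect_sizes: dict[str, float],
    n_noise_features: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian feature matrix with planted class separations.

    Informative features are N(0,1) for the negative class and N(d,1) for the
    positive class (d = the standardized mean difference); noise features are
    N(0,1) independent of the label. Column names reuse the microstate feature
    vocabulary.
    """
    if n_pos < 2 or n_neg < 2:
        raise ConfigError("need at least 2 subjects per class")
    for name, d in effect_sizes.items():
        if not np.isfinite(d):
            raise ConfigError(f"effect size for {name!r} is not finite")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    cols: dict[str, np.ndarray] = {}
    for name, d in effect_sizes.items():
        cols[name] = rng.standard_normal(n) + d * labels
    spare = [v for v in FEATURE_VOCABULARY if v not in cols]
    for j in range(n_noise_features):
        name = spare[j] if j < len(spare) else f"noise_{j}"
        cols[name] = rng.standard_normal(n)
    x = pd.DataFrame(cols)
    perm = rng.permutation(n)
    return x.iloc[perm].reset_index(drop=True), labels[perm]
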