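"""The resting-state preprocessing chain.

Order of operations (each step appends to the recording's history):
resample to 256 Hz -> zero-phase band-pass 1–45 Hz -> band-stop 48–52 Hz
(mains) -> optional amplitude-based epoch screening on 2-s windows ->
re-concatenation. A second stage narrows the band to 2–20 Hz and re-references
to the common average before microstate analysis.

Filters are 4th-order Butterworth applied forward-backward (zero phase), the
conventional choice where no filter family is prescribed. Artifact-component
removal on real data is a manual, decomposition-based step outside this
package's scope; ``artifact_stage`` is the pluggable hook for it and defaults
to a no-op (synthetic data is artifact-free).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .recording import Recording


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    target_rate: float = 256.0
    band_hz: tuple[float, float] = (1.0, 45.0)
    notch_hz: tuple[float, float] = (48.0, 52.0)
    epoch_s: float = 2.0
    reject_peak_to_peak_uv: float | None = None  # None = screening disabled
    ms_band_hz: tuple[float, float] = (2.0, 20.0)
    filter_order: int = 4


def _sos_filtfilt(data: np.ndarray, rate: float, lo: float, hi: float,
                  order: int, btype: str) -> np.ndarray:
    nyq = rate / 2.0
    if hi >= nyq:
        raise PreprocessError(
            f"band edge {hi} Hz infeasible at rate {rate} Hz (Nyquist {nyq} Hz)"
        )
    sos = butter(order, [lo / nyq, hi / nyq], btype=btype, output="sos")
    return sosfiltfilt(sos, data, axis=1)


def _resample(data: np.ndarray, rate: float, target: float) -> np.ndarray:
    frac = Fraction(target / rate).limit_denominator(1000)
    return resample_poly(data, frac.numerator, frac.denominator, axis=1)


def artifact_stage(rec: Recording,
                   hook: Callable[[Recording], Recording] | None = None) -> Recording:
    """Pluggable artifact-removal stage; identity when no hook is given."""
    if hook is None:
        return rec.with_data(rec.data, "artifact_stage(noop)")
    return hook(rec)


def standard_preprocess(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Resample, band-pass, notch, and (optionally) screen epochs by amplitude."""
    if rec.rate < 2.0 * cfg.band_hz[1]:
        raise PreprocessError(
            f"rate {rec.rate} Hz below 2x band upper edge {cfg.band_hz[1]} Hz"
        )
    data, rate = rec.data, rec.rate
    steps = []
    if abs(rate - cfg.target_rate) > 1e-9:
        data = _resample(data, rate, cfg.target_rate)
        rate = cfg.target_rate
        steps.append(f"resample(to={cfg.target_rate})")
    data = _sos_filtfilt(data, rate, *cfg.band_hz, cfg.filter_order, "bandpass")
    steps.append(f"bandpass({cfg.band_hz[0]}-{cfg.band_hz[1]}Hz,order={cfg.filter_order},zero-phase)")
    if cfg.notch_hz is not None:
        data = _sos_filtfilt(data, rate, *cfg.notch_hz, cfg.filter_order, "bandstop")
        steps.append(f"notch({cfg.notch_hz[0]}-{cfg.notch_hz[1]}Hz)")
    if cfg.reject_peak_to_peak_uv is not None:
        n_ep = int(data.shape[1] // (cfg.epoch_s * rate))
        ep_len = int(cfg.epoch_s * rate)
        kept = []
        for e in range(n_ep):
            seg = data[:, e * ep_len:(e + 1) * ep_len]
            if (seg.max(axis=1) - seg.min(axis=1)).max() <= cfg.reject_peak_to_peak_uv:
                kept.append(seg)
        if not kept:
            raise PreprocessError("epoch screening rejected every epoch")
        data = np.concatenate(kept, axis=1)
        steps.append(
            f"epoch_screen(p2p<={cfg.reject_peak_to_peak_uv}uV,kept={len(kept)}/{n_ep})"
        )
    out = rec
    for s in steps:
        out = out.with_data(data, s, rate=rate)
    return out


def microstate_prefilter(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Narrow-band (2–20 Hz) + common-average reference for microstate analysis."""
    if rec.n_channels < 2:
        raise PreprocessError("average reference undefined for a single channel")
    data = _sos_filtfilt(rec.data, rec.rate, *cfg.ms_band_hz, cfg.filter_order, "bandpass")
    data = data - data.mean(axis=0, keepdims=True)
    out = rec.with_data(
        data,
        f"ms_prefilter({cfg.ms_band_hz[0]}-{cfg.ms_band_hz[1]}Hz)+avg_reference",
        reference="average",
    )
    return out
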