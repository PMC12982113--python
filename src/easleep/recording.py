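"""The in-memory EEG container passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class RecordingError(ValueError):
    pass


@dataclass
class Recording:
    """A multichannel EEG recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    rate : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Ordered 10–20 labels, one per row of ``data``.
    reference : str
        ``"recorded"`` (as acquired) or ``"average"`` (common average).
    history : tuple of str
        Append-only log of processing steps with their parameters.
    """

    data: np.ndarray
    rate: float
    channel_names: tuple[str, ...]
    reference: str = "recorded"
    history: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise RecordingError("data must be a channels x samples matrix")
        if self.rate <= 0:
            raise RecordingError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise RecordingError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise RecordingError("duplicate channel names")
        if not np.all(np.isfinite(self.data)):
            raise RecordingError("data contains NaN or Inf")
        if self.reference not in ("recorded", "average"):
            raise RecordingError(f"unknown reference tag {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def with_data(self, data: np.ndarray, step: str, *, rate: float | None = None,
                  reference: str | None = None) -> "Recording":
        """Return a copy with new data and the step appended to history."""
        return replace(
            self,
            data=data,
            rate=self.rate if rate is None else rate,
            reference=self.reference if reference is None else reference,
            history=self.history + (step,),
        )

    def is_average_referenced(self, rel_tol: float = 1e-9) -> bool:
        rms = float(np.sqrt(np.mean(self.data**2)))
        if rms == 0.0:
            return True
        return float(np.max(np.abs(self.data.mean(axis=0)))) < rel_tol * rms
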