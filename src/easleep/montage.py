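"""Electrode montage handling for the 26-channel 10–20 layout.

Positions come from MNE's standard 10–20 montage. Downstream code needs 2-D
positions (for building archetype topographies) and the left/right mirror
pairing of channels (for symmetry checks), both derived here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Default 26-channel eyes-closed resting-state layout (10–20 names).
STANDARD_26 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FCz", "FC4", "T7", "C3", "Cz", "C4", "T8",
    "CP3", "CPz", "CP4", "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)


class MontageError(ValueError):
    """A channel has no known scalp position."""


@dataclass(frozen=True)
class Montage:
    """Named scalp positions.

    Attributes
    ----------
    names : tuple of str
        Channel names, ordered as in the recordings.
    xyz : ndarray, shape (n_channels, 3)
        3-D positions in meters (head frame: +x right, +y anterior, +z up).
    """

    names: tuple[str, ...]
    xyz: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise MontageError("duplicate channel names in montage")
        if self.xyz.shape != (len(self.names), 3):
            raise MontageError("xyz must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    @property
    def xy(self) -> np.ndarray:
        """2-D positions: azimuthal-equidistant projection onto the scalp plane."""
        x, y, z = self.xyz.T
        r = np.linalg.norm(self.xyz, axis=1)
        # polar angle from vertex; points farther from Cz project farther out
        theta = np.arccos(np.clip(z / np.where(r > 0, r, 1.0), -1.0, 1.0))
        phi = np.arctan2(y, x)
        return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])

    def mirror_index(self) -> np.ndarray:
        """Index array mapping each channel to its left/right mirror.

        Pairs odd/even 10–20 suffixes (Fp1<->Fp2, C3<->C4, ...); midline
        channels (z suffix) map to themselves.
        """
        lookup = {n.lower(): i for i, n in enumerate(self.names)}
        idx = np.empty(self.n_channels, dtype=int)
        for i, name in enumerate(self.names):
            head = name.rstrip("0123456789")
            digits = name[len(head):]
            if not digits:  # midline names like Fz carry no digits
                idx[i] = i
                continue
            num = int(digits)
            partner = head + str(num + 1 if num % 2 == 1 else num - 1)
            j = lookup.get(partner.lower())
            if j is None:
                raise MontageError(f"no mirror partner for channel {name!r}")
            idx[i] = j
        return idx


def standard_montage(names: tuple[str, ...] | list[str] = STANDARD_26) -> Montage:
    """Build a :class:`Montage` from MNE's standard 10–20 positions.

    Raises
    ------
    MontageError
        If a requested channel has no position in the standard layout,
        the error names the offending channel.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mon = mne.channels.make_standard_montage("standard_1020")
    pos = mon.get_positions()["ch_pos"]
    lower = {k.lower(): v for k, v in pos.items()}
    xyz = []
    for n in names:
        p = lower.get(n.lower())
        if p is None or not np.all(np.isfinite(p)):
            raise MontageError(f"montage has no position for channel {n!r}")
        xyz.append(p)
    return Montage(names=tuple(names), xyz=np.asarray(xyz, dtype=float))
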