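"""Reading and writing EEG recordings.

Two dialects:

* ``edf`` — European Data Format, read through MNE (read-only here; EDF
  export is not wired in).
* ``matrix`` — a ``.npz`` array (keys ``data`` in microvolts, ``rate``) with a
  ``<stem>.channels.tsv`` sidecar (columns: name, unit, x, y, z). This is the
  writable dialect and what the synthetic generator emits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .montage import standard_montage
from .recording import Recording, RecordingError


class FormatError(ValueError):
    pass


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".channels.tsv")


def read_recording(path: str | Path, dialect: str = "matrix") -> Recording:
    """Read a recording; voltages are returned in microvolts.

    Raises
    ------
    FileNotFoundError / FormatError
        Missing files or channel-name mismatches; the message names the field.
    """
    path = Path(path)
    if dialect == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        return Recording(
            data=data,
            rate=float(raw.info["sfreq"]),
            channel_names=tuple(raw.ch_names),
            history=(f"read_edf({path.name})",),
        )
    if dialect == "matrix":
        if not path.exists():
            raise FileNotFoundError(f"matrix file not found: {path}")
        side = _sidecar(path)
        if not side.exists():
            raise FileNotFoundError(f"channels sidecar not found: {side}")
        with np.load(path) as npz:
            if "data" not in npz or "rate" not in npz:
                raise FormatError("matrix file must contain 'data' and 'rate'")
            data = npz["data"]
            rate = float(npz["rate"])
        tsv = pd.read_csv(side, sep="\t")
        if "name" not in tsv.columns:
            raise FormatError("channels.tsv lacks a 'name' column")
        names = tuple(tsv["name"].astype(str))
        if len(names) != data.shape[0]:
            raise FormatError(
                f"channels.tsv lists {len(names)} names for {data.shape[0]} data rows"
            )
        try:
            return Recording(
                data=data, rate=rate, channel_names=names,
                history=(f"read_matrix({path.name})",),
            )
        except RecordingError as err:
            raise FormatError(str(err)) from err
    raise FormatError(f"unknown dialect {dialect!r}; expected 'edf' or 'matrix'")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording in the matrix dialect (npz + channels.tsv sidecar)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, data=rec.data, rate=rec.rate)
    try:
        mon = standard_montage(rec.channel_names)
        xyz = mon.xyz
    except Exception:
        xyz = np.full((rec.n_channels, 3), np.nan)
    pd.DataFrame(
        {
            "name": rec.channel_names,
            "unit": ["uV"] * rec.n_channels,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    ).to_csv(_sidecar(path), sep="\t", index=False)
    return path
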