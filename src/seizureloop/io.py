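"""Reading and writing recordings, annotations and epoch archives.

Recordings are exchanged as single-channel EDF or as two-column CSV
(``time_s, amplitude``) with a ``# fs=<Hz>`` header line. Seizure-interval
annotations travel in a separate two-column CSV (``onset_s, offset_s``).
Epoch collections are stored as NumPy ``.npz`` archives with per-epoch
labels and start times.

EDF writing is implemented here directly (plain EDF, one channel, 16-bit
samples, one-second data records); EDF reading is delegated to ``mne``,
which also serves as an independent round-trip check in the test suite.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Epoch, Recording

_EDF_EPOCH = datetime.datetime(1985, 1, 1, 0, 0, 0)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as a plain single-channel EDF file.

    Samples are stored as 16-bit integers in one-second data records with
    the physical dimension µV; the trailing partial second, if any, is
    zero-padded (EDF records have fixed length). Annotations are not
    embedded — they are written separately with :func:`write_annotations`.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    x = recording.samples
    n_rec = int(np.ceil(x.size / spr)) if x.size else 0
    padded = np.zeros(n_rec * spr)
    padded[: x.size] = x

    pmin, pmax = float(padded.min()), float(padded.max())
    if pmax <= pmin:  # constant signal: widen to keep the gain finite
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin) / gain + dmin).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-1985 X X X", 80),
        _pad(_EDF_EPOCH.strftime("%d.%m.%y"), 8),
        _pad(_EDF_EPOCH.strftime("%H.%M.%S"), 8),
        _pad(str(256 + 256), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad("1", 4),
    ])
    sig_header = b"".join([
        _pad(recording.channel_label, 16),
        _pad("", 80),
        _pad("uV", 8),
        _pad(f"{pmin:.6g}", 8),
        _pad(f"{pmax:.6g}", 8),
        _pad(str(dmin), 8),
        _pad(str(dmax), 8),
        _pad("", 80),
        _pad(str(spr), 8),
        _pad("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.tobytes())


def read_edf(path: str | Path, annotations_path: str | Path | None = None) -> Recording:
    """Read a single-channel EDF recording via mne.

    If ``annotations_path`` points to an annotation CSV, the seizure
    intervals are attached to the returned recording.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[0] * 1e6  # mne returns volts for µV channels
    ann = read_annotations(annotations_path) if annotations_path else []
    return Recording(samples=data, fs=float(raw.info["sfreq"]),
                     annotations=ann, channel_label=raw.ch_names[0])


def write_csv(recording: Recording, path: str | Path) -> None:
    """Write a recording as CSV: a ``# fs=<Hz>`` header line, then
    ``time_s,amplitude`` rows."""
    t = np.arange(recording.n_samples) / recording.fs
    with open(path, "w") as fh:
        fh.write(f"# fs={recording.fs}\n")
        pd.DataFrame({"time_s": t, "amplitude": recording.samples}).to_csv(
            fh, index=False)


def read_csv(path: str | Path, annotations_path: str | Path | None = None) -> Recording:
    """Read a recording written by :func:`write_csv`."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' sampling-rate header")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    ann = read_annotations(annotations_path) if annotations_path else []
    return Recording(samples=df["amplitude"].to_numpy(), fs=fs, annotations=ann)


def write_annotations(annotations: list[tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(annotations, columns=["onset_s", "offset_s"]).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return [(float(a), float(b)) for a, b in zip(df["onset_s"], df["offset_s"])]


def save_epochs(epochs: list[Epoch], path: str | Path) -> None:
    """Save an epoch collection as a ``.npz`` archive (X, fs, labels, t0)."""
    if not epochs:
        raise ValueError("cannot save an empty epoch collection")
    lengths = {e.n for e in epochs}
    if len(lengths) != 1:
        raise ValueError("all epochs must have the same length")
    np.savez(
        path,
        X=np.stack([e.x for e in epochs]),
        fs=np.array([epochs[0].fs]),
        labels=np.array([e.label for e in epochs]),
        t0=np.array([e.t0 for e in epochs]),
    )


def load_epochs(path: str | Path) -> list[Epoch]:
    with np.load(path, allow_pickle=False) as z:
        fs = float(z["fs"][0])
        return [
            Epoch(x=row, fs=fs, label=str(lab), t0=float(t0))
            for row, lab, t0 in zip(z["X"], z["labels"], z["t0"])
        ]
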