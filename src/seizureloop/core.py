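"""Core containers: recordings, epochs, and seizure-interval annotations.

A :class:`Recording` is a single-channel EEG trace with a sampling rate and
a list of annotated seizure intervals (onset/offset in seconds, as a human
scorer would mark them). An :class:`Epoch` is one fixed-length analysis
window cut from a recording, optionally carrying a class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Class labels used throughout the package.
SEIZURE = "seizure"
NON_SEIZURE = "non-seizure"
UNKNOWN = "unknown"

LABELS = (SEIZURE, NON_SEIZURE, UNKNOWN)


def validate_annotations(
    annotations: list[tuple[float, float]], duration_s: float
) -> list[tuple[float, float]]:
    """Check that seizure intervals are sorted, disjoint and inside the record.

    Returns the annotations as a list of ``(onset_s, offset_s)`` float tuples.
    Raises ``ValueError`` on any violation.
    """
    out: list[tuple[float, float]] = []
    prev_off = 0.0
    for onset, offset in annotations:
        onset, offset = float(onset), float(offset)
        if offset <= onset:
            raise ValueError(f"annotation offset {offset} <= onset {onset}")
        if onset < prev_off:
            raise ValueError(
                "annotations must be sorted and non-overlapping "
                f"(interval starting at {onset} overlaps or precedes {prev_off})"
            )
        if onset < 0 or offset > duration_s + 1e-9:
            raise ValueError(
                f"annotation ({onset}, {offset}) outside recording [0, {duration_s}]"
            )
        out.append((onset, offset))
        prev_off = offset
    return out


@dataclass
class Recording:
    """Single-channel EEG time series with seizure-interval annotations.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence in microvolts.
    fs : float
        Sampling rate in Hz (125 Hz for the online path, 500 Hz offline).
    annotations : list of (onset_s, offset_s)
        Sorted, non-overlapping seizure intervals in seconds.
    channel_label : str
        Free-text channel name.
    """

    samples: np.ndarray
    fs: float
    annotations: list[tuple[float, float]] = field(default_factory=list)
    channel_label: str = "EEG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Recording.samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.annotations = validate_annotations(self.annotations, self.duration_s)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def seizure_mask(self) -> np.ndarray:
        """Boolean per-sample mask: True inside any annotated interval."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for onset, offset in self.annotations:
            i0 = int(round(onset * self.fs))
            i1 = int(round(offset * self.fs))
            mask[i0:i1] = True
        return mask


@dataclass(frozen=True)
class Epoch:
    """One fixed-length analysis window.

    ``label`` is immutable after construction (the dataclass is frozen).
    ``t0`` is the window start time within its source recording.
    """

    x: np.ndarray
    fs: float
    label: str = UNKNOWN
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def duration_s(self) -> float:
        return self.x.size / self.fs
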