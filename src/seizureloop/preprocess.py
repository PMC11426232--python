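"""Filtering, segmentation and dataset assembly.

The online path applies a causal third-order Butterworth band-pass (the
controller must not look ahead); an optional zero-phase mode exists for
offline analysis. Recordings are cut into consecutive non-overlapping
fixed-length windows; an epoch is labeled seizure when at least half of its
samples fall inside an annotated interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import NON_SEIZURE, SEIZURE, Epoch, Recording

DEFAULT_BAND = (0.5, 45.0)
DEFAULT_ORDER = 3
#: Fraction of in-annotation samples required to label an epoch seizure.
SEIZURE_OVERLAP_FRACTION = 0.5


def design_bandpass(order: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Butterworth band-pass in second-order sections; errors if a band
    edge reaches Nyquist."""
    low, high = band
    if not (0 < low < high):
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    if high >= fs / 2:
        raise ValueError(f"high band edge {high} Hz >= Nyquist {fs / 2} Hz")
    return signal.butter(order, band, btype="bandpass", fs=fs, output="sos")


def iir_filter(
    recording: Recording,
    order: int = DEFAULT_ORDER,
    band: tuple[float, float] = DEFAULT_BAND,
    zero_phase: bool = False,
) -> Recording:
    """Band-pass the recording; annotations and sampling rate are preserved.

    ``zero_phase=False`` (default) is the causal single-pass realization used
    online; ``zero_phase=True`` applies forward-backward filtering for
    offline analysis.
    """
    sos = design_bandpass(order, band, recording.fs)
    if zero_phase:
        y = signal.sosfiltfilt(sos, recording.samples)
    else:
        y = signal.sosfilt(sos, recording.samples)
    return Recording(samples=y, fs=recording.fs,
                     annotations=list(recording.annotations),
                     channel_label=recording.channel_label)


def decimate_recording(recording: Recording, factor: int = 4) -> Recording:
    """Integer decimation with an anti-alias filter (500 Hz -> 125 Hz at
    the default factor). Annotations are unchanged (they are in seconds)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    y = signal.decimate(recording.samples, factor, ftype="fir", zero_phase=True)
    return Recording(samples=y, fs=recording.fs / factor,
                     annotations=list(recording.annotations),
                     channel_label=recording.channel_label)


def segment(
    recording: Recording,
    window_s: float = 3.0,
    seizure_overlap: float = SEIZURE_OVERLAP_FRACTION,
) -> list[Epoch]:
    """Cut consecutive non-overlapping windows; the trailing partial window
    is discarded. Epoch k starts exactly at ``k * window_s``.

    Labels: seizure iff at least ``seizure_overlap`` of the window's samples
    lie inside an annotated interval, else non-seizure.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_win = int(round(window_s * recording.fs))
    n_epochs = recording.n_samples // n_win
    mask = recording.seizure_mask()
    out = []
    for k in range(n_epochs):
        s = k * n_win
        frac = mask[s:s + n_win].mean()
        label = SEIZURE if frac >= seizure_overlap else NON_SEIZURE
        out.append(Epoch(recording.samples[s:s + n_win], recording.fs,
                         label, s / recording.fs))
    return out


@dataclass
class DatasetSplit:
    """A train/test partition of an epoch collection."""

    train: list[Epoch]
    test: list[Epoch]
    ratio: float
    seed: int


def balanced_subsample_and_split(
    epochs: list[Epoch],
    n_per_class: int,
    ratio: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Class-stratified subsample of ``n_per_class`` epochs per class,
    then a stratified random split at ``ratio`` (train fraction).

    With 100 per class at ratio 0.8 this yields 160 training and 40 test
    epochs, 80 of each class in training. Sampling is without replacement
    and reproducible under ``seed``.
    """
    if not 0 <= ratio <= 1:
        raise ValueError("ratio must be in [0, 1]")
    pools = {SEIZURE: [], NON_SEIZURE: []}
    for e in epochs:
        if e.label in pools:
            pools[e.label].append(e)
    short = {k: len(v) for k, v in pools.items() if len(v) < n_per_class}
    if short:
        raise ValueError(
            f"insufficient epochs for n_per_class={n_per_class}: available "
            + ", ".join(f"{k}={len(v)}" for k, v in pools.items())
        )
    rng = np.random.default_rng(seed)
    train: list[Epoch] = []
    test: list[Epoch] = []
    n_train = int(round(n_per_class * ratio))
    for label in (SEIZURE, NON_SEIZURE):
        idx = rng.choice(len(pools[label]), size=n_per_class, replace=False)
        chosen = [pools[label][i] for i in idx]
        train.extend(chosen[:n_train])
        test.extend(chosen[n_train:])
    rng.shuffle(train)
    rng.shuffle(test)
    return DatasetSplit(train=train, test=test, ratio=ratio, seed=seed)
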