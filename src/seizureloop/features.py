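"""Per-epoch EEG features and range normalization.

Six statistics are computed for each analysis window x(i), i = 1..N:

* coastline (line length)          CL   = sum |x(i+1) - x(i)|
* sample standard deviation        STD  (N-1 denominator)
* log-energy entropy               Elog = sum log(x(i)^2 + eps)
* Euclidean norm                   ||x||_2
* mean instantaneous frequency     time-averaged spectral centroid (Hz)
* mean spectral entropy            time-averaged normalized Shannon entropy
                                   of the power spectrum, in [0, 1]

The two spectral features share one short-time Fourier decomposition: Hann
slices of min(N, 4*fs) samples with 50% overlap. The spectral entropy
additionally averages adjacent frequency-bin pairs before normalizing,
which removes most of the negative bias raw periodogram fluctuations
impose on the entropy of broadband signals.

Range normalization is the affine per-feature map (v - min) / (max - min)
fitted on a reference (training) dataset; streaming values outside the
fitted range are NOT clipped, since an online system cannot know future
extrema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import Epoch

FEATURE_NAMES = ("cl", "std", "e_log", "eucl", "mif", "mse")
#: The subset the multi-level threshold detector operates on.
THRESHOLD_FEATURES = ("cl", "std", "e_log")

#: Guard added to squared amplitudes (µV²) so zero samples stay finite.
DEFAULT_ELOG_EPS = 1e-12


def coastline(x: np.ndarray) -> float:
    """Line length: sum of absolute successive-sample differences."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("coastline requires at least 2 samples")
    return float(np.abs(np.diff(x)).sum())


def std_dev(x: np.ndarray) -> float:
    """Sample standard deviation (N-1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("std_dev requires at least 2 samples")
    return float(np.std(x, ddof=1))


def log_energy_entropy(x: np.ndarray, eps: float = DEFAULT_ELOG_EPS) -> float:
    """Shannon log-energy entropy: sum_i log(x(i)^2 + eps), natural log."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("log_energy_entropy requires a non-empty epoch")
    if eps <= 0:
        raise ValueError("eps must be positive")
    return float(np.log(x**2 + eps).sum())


def euclidean_norm(x: np.ndarray) -> float:
    """sqrt(sum x(i)^2)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("euclidean_norm requires a non-empty epoch")
    return float(np.linalg.norm(x))


def _stft_power(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann short-time power spectrum; slices of min(N, 4*fs), 50% overlap.

    Returns (frequencies, power[freq, slice])."""
    nperseg = int(min(x.size, round(4 * fs)))
    f, _, S = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    return f, S


def mean_instantaneous_frequency(x: np.ndarray, fs: float) -> float:
    """Time average of the spectrogram first-moment (centroid) frequency.

    An all-zero epoch is defined as 0 Hz, with a warning."""
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("mean_instantaneous_frequency requires >= 16 samples")
    if not np.any(x):
        warnings.warn("all-zero epoch: mean instantaneous frequency set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    f, S = _stft_power(x, fs)
    tot = S.sum(axis=0)
    good = tot > 0
    if not good.any():
        return 0.0
    centroid = (f[:, None] * S[:, good]).sum(axis=0) / tot[good]
    return float(centroid.mean())


def mean_spectral_entropy(x: np.ndarray, fs: float) -> float:
    """Time average of the normalized Shannon spectral entropy, in [0, 1].

    Per slice, adjacent frequency bins of the power spectrum are pair-
    averaged, the result is normalized to a probability distribution, and
    its entropy is divided by log(number of bins). An all-zero epoch is
    defined as 0, with a warning."""
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("mean_spectral_entropy requires >= 16 samples")
    if not np.any(x):
        warnings.warn("all-zero epoch: mean spectral entropy set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    f, S = _stft_power(x, fs)
    # average adjacent bin pairs to tame periodogram fluctuations
    n2 = (len(f) // 2) * 2
    S = S[:n2].reshape(len(f) // 2, 2, -1).mean(axis=1)
    tot = S.sum(axis=0)
    vals = []
    for j in np.nonzero(tot > 0)[0]:
        p = S[:, j] / tot[j]
        p = p[p > 0]
        vals.append(-(p * np.log(p)).sum() / np.log(S.shape[0]))
    return float(np.mean(vals)) if vals else 0.0


@dataclass(frozen=True)
class FeatureVector:
    """The six per-epoch statistics."""

    cl: float
    std: float
    e_log: float
    eucl: float
    mif: float
    mse: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def feature_vector(x: np.ndarray, fs: float,
                   eps: float = DEFAULT_ELOG_EPS) -> FeatureVector:
    """Compute all six features for one epoch."""
    return FeatureVector(
        cl=coastline(x),
        std=std_dev(x),
        e_log=log_energy_entropy(x, eps=eps),
        eucl=euclidean_norm(x),
        mif=mean_instantaneous_frequency(x, fs),
        mse=mean_spectral_entropy(x, fs),
    )


def feature_table(epochs: list[Epoch], eps: float = DEFAULT_ELOG_EPS) -> pd.DataFrame:
    """One row per epoch: the six feature columns plus ``label`` and ``t0``."""
    rows = []
    for e in epochs:
        fv = feature_vector(e.x, e.fs, eps=eps)
        rows.append({**{n: getattr(fv, n) for n in FEATURE_NAMES},
                     "label": e.label, "t0": e.t0})
    return pd.DataFrame(rows)


@dataclass
class NormalizationParams:
    """Per-feature (min, max) fitted on a reference dataset.

    Features with max == min are flagged degenerate and map to 0."""

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    degenerate: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
            "degenerate": list(self.degenerate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(names=tuple(d["names"]), mins=np.array(d["mins"]),
                   maxs=np.array(d["maxs"]), degenerate=tuple(d["degenerate"]))


def fit_normalization(table: pd.DataFrame,
                      names: tuple[str, ...] = FEATURE_NAMES) -> NormalizationParams:
    """Fit per-feature min/max on a reference feature table (>= 2 rows)."""
    if len(table) < 2:
        raise ValueError("normalization requires at least 2 rows")
    mins = table.loc[:, list(names)].min().to_numpy(dtype=float)
    maxs = table.loc[:, list(names)].max().to_numpy(dtype=float)
    degenerate = tuple(n for n, lo, hi in zip(names, mins, maxs) if hi <= lo)
    return NormalizationParams(names=tuple(names), mins=mins, maxs=maxs,
                               degenerate=degenerate)


def apply_normalization(table: pd.DataFrame,
                        params: NormalizationParams) -> pd.DataFrame:
    """Map each feature through (v - min)/(max - min); degenerate features
    map to 0. Values outside the fitted range are not clipped."""
    out = table.copy()
    for name, lo, hi in zip(params.names, params.mins, params.maxs):
        if name in params.degenerate:
            out[name] = 0.0
        else:
            out[name] = (table[name] - lo) / (hi - lo)
    return out
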