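"""Synthetic spike-wave EEG generator.

Emulates the statistical structure of rat EEG in an acute chemoconvulsant
seizure model: a low-amplitude 1/f-shaped baseline and, within a 30-minute
observation window, discrete seizure events of 21-60 s consisting of a
~3 Hz spike-wave train riding on elevated broadband noise. The generator
claims no physiological fidelity; it reproduces the high line-length, high
variance, high log-energy signature that threshold detectors key on, so the
downstream pipeline is testable without animal data.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` stream; identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core import NON_SEIZURE, SEIZURE, Epoch, Recording


class InfeasiblePlacementError(ValueError):
    """Requested seizure events cannot be placed without overlap."""


class InsufficientDataError(ValueError):
    """Requested epoch counts exceed what the generated signal contains."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic EEG generator.

    Defaults describe the acute-model study conditions: a 30-minute
    post-injection window sampled at 125 Hz, with seizure events of 21-60 s
    whose peak amplitude is at least ten times the baseline sigma.

    Attributes
    ----------
    duration_s : recording length (s).
    fs : sampling rate (Hz); 125 online, 500 offline.
    baseline_sigma : baseline noise standard deviation (µV, nominal).
    seizure_amplitude_ratio : peak seizure amplitude / baseline sigma (> 1).
    spike_rate_hz : spike-wave repetition rate inside seizures.
    n_seizures : number of discrete events to inject.
    seizure_duration_range_s : (low, high) of per-event duration draw.
    band : acquisition band (Hz) the baseline noise is limited to.
    min_gap_s : minimum baseline gap between events and at the edges.
    seed : master seed for the generator stream.
    """

    duration_s: float = 1800.0
    fs: float = 125.0
    baseline_sigma: float = 20.0
    seizure_amplitude_ratio: float = 12.0
    spike_rate_hz: float = 3.0
    n_seizures: int = 5
    seizure_duration_range_s: tuple[float, float] = (21.0, 60.0)
    band: tuple[float, float] = (0.5, 45.0)
    min_gap_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.seizure_duration_range_s
        if not (0 < lo <= hi < self.duration_s):
            raise ValueError(
                "seizure_duration_range_s must satisfy 0 < low <= high < duration_s"
            )
        if self.seizure_amplitude_ratio <= 1:
            raise ValueError("seizure_amplitude_ratio must exceed 1")
        if self.n_seizures < 0:
            raise ValueError("n_seizures must be non-negative")
        if not (0 < self.band[0] < self.band[1] < self.fs / 2):
            raise ValueError("band must lie strictly inside (0, fs/2)")


#: Composition of the pre-collected statistics set: 3000 three-second
#: epochs, 131 seizure and 2869 non-seizure.
THRESHOLD_STATS_PRESET = {"n_seizure": 131, "n_nonseizure": 2869, "epoch_s": 3.0}

#: Composition of the pooled training set: 4200 three-second epochs from
#: seven 30-minute recordings, 100 seizure and 4100 non-seizure.
TRAINING_POOL_PRESET = {"n_seizure": 100, "n_nonseizure": 4100, "epoch_s": 3.0}


def _one_over_f_noise(n: int, fs: float, band: tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise with 1/f power shaping, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    # 1/f power => 1/sqrt(f) amplitude, flattened below a 1 Hz knee
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec * shaping, n=n)
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_process(n: int, fs: float, scale_s: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean unit-variance Gaussian process (Gaussian-smoothed
    white noise with the given correlation time)."""
    from scipy.ndimage import gaussian_filter1d

    z = rng.standard_normal(n)
    width = max(1, int(round(scale_s * fs)))
    out = gaussian_filter1d(z, width, mode="reflect")
    sd = out.std()
    return out / sd if sd > 0 else out - out.mean()


#: Waveform-shaping constants of the ictal discharge model: threshold (in
#: envelope-process standard deviations), depth and correlation time of the
#: brief waxing-waning attenuations; slow-wave amplitude relative to spike
#: peak; in-seizure broadband noise level relative to baseline sigma.
DIP_RATE = 2.0
DIP_DEPTH = 0.55
DIP_SCALE_S = 1.0
WAVE_REL = 0.6
SEIZURE_NOISE_FACTOR = 2.0


def _dip_envelope(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Mostly-at-ceiling amplitude envelope with rare brief attenuations.

    The envelope sits at 1 except where a smooth Gaussian process exceeds
    ``DIP_RATE`` standard deviations, where it drops by ``DIP_DEPTH`` —
    discharges hold near their ceiling amplitude with occasional short
    dips rather than fading smoothly."""
    g = _slow_process(n, fs, DIP_SCALE_S, rng)
    return 1.0 - DIP_DEPTH / (1.0 + np.exp(-4.0 * (g - DIP_RATE)))


def _spike_wave(n: int, fs: float, rate_hz: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Ictal discharge of exactly n samples, in units of the nominal spike
    peak (realized event peak is therefore >= ~1).

    A stereotyped spike train (sharp biphasic spikes at ``rate_hz`` with
    small timing/amplitude jitter) plus a slow wave, each component under
    its own independent waxing-waning envelope: spike sharpness, slow-wave
    amplitude and background activation fluctuate separately in real
    discharges, so a brief attenuation of one component does not silence
    the others. Returns the discharge and a third independent envelope for
    the in-seizure broadband noise."""
    duration_s = n / fs
    t = np.arange(n) / fs
    # biphasic spike: derivative of a 12 ms Gaussian (sharp, so spikes set
    # the line length while the slow wave carries most of the power)
    sigma = 0.012
    half = int(round(4 * sigma * fs))
    ts = (np.arange(2 * half + 1) - half) / fs
    spike = -ts / sigma**2 * np.exp(-(ts**2) / (2 * sigma**2))
    spike /= np.abs(spike).max()

    train = np.zeros(n)
    period = 1.0 / rate_hz
    t_next = period * rng.uniform(0.2, 0.8)
    while t_next < duration_s:
        i = int(round(t_next * fs))
        amp = rng.uniform(0.95, 1.05)
        lo, hi = i - half, i + half + 1
        s0 = max(0, -lo)
        s1 = len(spike) - max(0, hi - n)
        train[max(0, lo):min(n, hi)] += amp * spike[s0:s1]
        t_next += period * rng.uniform(0.98, 1.02)

    # slow wave at half the spike rate, detuned so the spike/wave phase
    # alignment averages out within an analysis window instead of acting
    # as a hidden per-epoch amplitude factor
    wave = np.sin(2 * np.pi * 0.5 * rate_hz * t + rng.uniform(0, 2 * np.pi))
    env_spike = _dip_envelope(n, fs, rng)
    env_wave = _dip_envelope(n, fs, rng)
    env_noise = _dip_envelope(n, fs, rng)
    # fixed nominal scaling: spike peak ~1 defines the unit, so event
    # amplitude does not depend on one extreme sample
    x = env_spike * train + WAVE_REL * env_wave * wave
    return x, env_noise


def _place_events(config: GeneratorConfig, rng: np.random.Generator
                  ) -> list[tuple[float, float]]:
    """Draw event durations and place them with at least min_gap_s spacing."""
    if config.n_seizures == 0:
        return []
    lo, hi = config.seizure_duration_range_s
    durations = rng.uniform(lo, hi, size=config.n_seizures)
    free = config.duration_s - durations.sum() - config.min_gap_s * (config.n_seizures + 1)
    if free < 0:
        raise InfeasiblePlacementError(
            f"{config.n_seizures} events totalling {durations.sum():.1f}s plus "
            f"{config.min_gap_s}s gaps do not fit in {config.duration_s}s"
        )
    w = rng.random(config.n_seizures + 1)
    gaps = config.min_gap_s + free * w / w.sum()
    annotations = []
    t = 0.0
    for gap, dur in zip(gaps, durations):
        t += gap
        annotations.append((round(t, 3), round(t + dur, 3)))
        t += dur
    return annotations


def generate_recording(config: GeneratorConfig) -> Recording:
    """Generate one synthetic EEG recording with annotated seizure events.

    Baseline segments are 1/f-shaped band-limited Gaussian noise of standard
    deviation ``baseline_sigma``. Each annotated segment adds a spike-wave
    train (peak ``seizure_amplitude_ratio * baseline_sigma``) plus doubled
    broadband noise, with half-second cosine on/off ramps. Annotations match
    the injected events exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    annotations = _place_events(config, rng)

    x = config.baseline_sigma * _one_over_f_noise(n, config.fs, config.band, rng)
    peak = config.seizure_amplitude_ratio * config.baseline_sigma
    for onset, offset in annotations:
        i0 = int(round(onset * config.fs))
        i1 = int(round(offset * config.fs))
        seg_len = i1 - i0
        sw, env_noise = _spike_wave(seg_len, config.fs, config.spike_rate_hz, rng)
        extra = env_noise * rng.standard_normal(seg_len)
        ramp = np.ones(seg_len)
        nr = min(int(round(0.5 * config.fs)), seg_len // 2)
        if nr > 0:
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
            ramp[:nr] = edge
            ramp[-nr:] = edge[::-1]
        x[i0:i1] += ramp * (peak * sw
                            + SEIZURE_NOISE_FACTOR * config.baseline_sigma * extra)

    return Recording(samples=x, fs=config.fs, annotations=annotations,
                     channel_label="synthetic-EEG")


#: Length of the cosine on/off amplitude ramp at each event edge (s).
EDGE_RAMP_S = 0.5


def _epochs_from_recording(rec: Recording, epoch_s: float
                           ) -> tuple[list[Epoch], list[Epoch]]:
    """Cut clean class epochs: seizure epochs from the steady ictal interior
    of each annotated event (the on/off amplitude ramps at the event edges
    are transition zones, not steady seizure activity, and are excluded);
    non-seizure epochs from the regular window grid with zero annotation
    overlap."""
    n_win = int(round(epoch_s * rec.fs))
    seiz: list[Epoch] = []
    for onset, offset in rec.annotations:
        i0 = int(round((onset + EDGE_RAMP_S) * rec.fs))
        i1 = int(round((offset - EDGE_RAMP_S) * rec.fs))
        k = 0
        while i0 + (k + 1) * n_win <= i1:
            s = i0 + k * n_win
            seiz.append(Epoch(rec.samples[s:s + n_win], rec.fs, SEIZURE, s / rec.fs))
            k += 1
    mask = rec.seizure_mask()
    base: list[Epoch] = []
    for k in range(rec.n_samples // n_win):
        s = k * n_win
        if not mask[s:s + n_win].any():
            base.append(Epoch(rec.samples[s:s + n_win], rec.fs, NON_SEIZURE, s / rec.fs))
    return seiz, base


def generate_epoch_dataset(
    n_seizure: int,
    n_nonseizure: int,
    epoch_s: float = 3.0,
    fs: float | None = None,
    config: GeneratorConfig | None = None,
    max_recordings: int = 50,
) -> list[Epoch]:
    """Generate a labeled epoch dataset of exact class counts.

    Epochs are pooled from as many independently seeded recordings as
    needed (mirroring pooling across animals), each recording drawn from
    ``config`` with a seed derived from ``config.seed`` and the recording
    index. Seizure epochs are cut fully inside annotated events; non-seizure
    epochs come from baseline windows with zero annotation overlap.

    Raises
    ------
    InsufficientDataError
        If ``max_recordings`` recordings cannot supply the requested counts.
    """
    if n_seizure < 0 or n_nonseizure < 0:
        raise ValueError("epoch counts must be non-negative")
    config = config or GeneratorConfig()
    if fs is not None and fs != config.fs:
        config = replace(config, fs=fs)

    seiz: list[Epoch] = []
    base: list[Epoch] = []
    for i in range(max_recordings):
        if len(seiz) >= n_seizure and len(base) >= n_nonseizure:
            break
        sub_seed = int((config.seed + 7919 * (i + 1)) % 2**31)
        rec = generate_recording(replace(config, seed=sub_seed))
        s, b = _epochs_from_recording(rec, epoch_s)
        seiz.extend(s)
        base.extend(b)
    if len(seiz) < n_seizure or len(base) < n_nonseizure:
        raise InsufficientDataError(
            f"after {max_recordings} recordings only {len(seiz)} seizure and "
            f"{len(base)} non-seizure epochs are available "
            f"(requested {n_seizure}/{n_nonseizure})"
        )
    return seiz[:n_seizure] + base[:n_nonseizure]
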