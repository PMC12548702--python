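"""Acoustic novelty functions and adaptive-threshold onset detection.

Three complementary change detectors are computed from the raw waveform --
local energy flux, spectral flux, and complex-domain (phase) prediction
error -- normalized to [0, 1], averaged, and peak-picked against a local
median threshold.  Detected onset times feed the IOI analyses.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from ._types import (
    AudioSignal,
    FeatureMatrix,
    NoveltyConfig,
    NoveltyFunction,
    OnsetEvents,
    PeakPickConfig,
)

__all__ = [
    "AudioSignal",
    "NoveltyConfig",
    "NoveltyFunction",
    "PeakPickConfig",
    "OnsetEvents",
    "energy_novelty",
    "spectral_novelty",
    "complex_novelty",
    "combine_novelty",
    "pick_onsets",
    "encode_onset_vector",
]


def _check_audio(audio: AudioSignal, cfg: NoveltyConfig) -> None:
    if len(audio.samples) == 0:
        raise ValueError("audio must be non-empty")
    if audio.fs < 2 * cfg.target_fs:
        raise ValueError(
            f"audio rate {audio.fs} Hz too low for target rate {cfg.target_fs} Hz"
        )


def _n_target(audio: AudioSignal, cfg: NoveltyConfig) -> int:
    return max(1, int(round(len(audio.samples) / audio.fs * cfg.target_fs)))


def _resample_to_target(values: np.ndarray, times: np.ndarray,
                        audio: AudioSignal, cfg: NoveltyConfig) -> np.ndarray:
    """Linear interpolation of a frame-rate signal onto the target grid."""
    n_out = _n_target(audio, cfg)
    t_out = np.arange(n_out) / cfg.target_fs
    if len(values) == 1:
        return np.full(n_out, values[0])
    return np.interp(t_out, times, values)


def _local_average_subtract(x: np.ndarray, fs: float, win_s: float) -> np.ndarray:
    """x - centered moving average, clipped at zero."""
    win = max(1, int(round(win_s * fs)))
    kernel = np.ones(win) / win
    local = ndimage.convolve1d(x, kernel, mode="nearest")
    return np.clip(x - local, 0.0, None)


def energy_novelty(audio: AudioSignal, cfg: NoveltyConfig | None = None) -> NoveltyFunction:
    """Half-wave-rectified derivative of the log-compressed local energy.

    Steps: square -> Hann smoothing -> downsample to ``cfg.target_fs`` ->
    ``log(1 + gamma * x)`` -> first difference -> half-wave rectify.
    """
    cfg = cfg or NoveltyConfig()
    _check_audio(audio, cfg)
    x = audio.samples
    win_len = cfg.resolved_energy_win(audio.fs)
    window = signal.windows.hann(win_len)
    window = window / window.sum()
    energy = signal.fftconvolve(x * x, window, mode="same")
    energy = np.clip(energy, 0.0, None)  # fft round-off can dip below zero
    t_frames = np.arange(len(energy)) / audio.fs
    energy_ds = _resample_to_target(energy, t_frames, audio, cfg)
    compressed = np.log1p(cfg.gamma * energy_ds)
    nov = np.diff(compressed, prepend=compressed[:1])
    nov = np.clip(nov, 0.0, None)
    return NoveltyFunction(values=nov, fs=cfg.target_fs, kind="energy")


def _stft_frames(audio: AudioSignal, cfg: NoveltyConfig):
    """Onesided STFT magnitudes/coefficients and their frame-center times."""
    win_len = cfg.resolved_stft_win(audio.fs)
    hop = cfg.resolved_stft_hop(audio.fs)
    window = signal.windows.hann(win_len)
    sft = signal.ShortTimeFFT(window, hop=hop, fs=audio.fs, fft_mode="onesided")
    X = sft.stft(audio.samples)
    times = sft.t(len(audio.samples))
    return X, times


def spectral_novelty(audio: AudioSignal, cfg: NoveltyConfig | None = None) -> NoveltyFunction:
    """Log-compressed spectral flux with local-average subtraction."""
    cfg = cfg or NoveltyConfig()
    _check_audio(audio, cfg)
    X, times = _stft_frames(audio, cfg)
    Y = np.log1p(cfg.gamma * np.abs(X))
    flux = np.diff(Y, axis=1, prepend=Y[:, :1])
    flux = np.clip(flux, 0.0, None)
    nov_frames = flux.sum(axis=0)
    nov = _resample_to_target(nov_frames, times, audio, cfg)
    nov = _local_average_subtract(nov, cfg.target_fs, cfg.local_avg_win)
    return NoveltyFunction(values=nov, fs=cfg.target_fs, kind="spectral")


def complex_novelty(audio: AudioSignal, cfg: NoveltyConfig | None = None) -> NoveltyFunction:
    """Magnitude-weighted phase-prediction error.

    Each STFT frame is predicted from the previous frame's magnitude, phase
    and phase rate (local stationarity); the per-band error magnitude is
    decrease-suppressed, summed over bands, locally averaged and rectified.
    """
    cfg = cfg or NoveltyConfig()
    _check_audio(audio, cfg)
    X, times = _stft_frames(audio, cfg)
    n_freq, n_frames = X.shape
    if n_frames < 3:
        nov = np.zeros(_n_target(audio, cfg))
        return NoveltyFunction(values=nov, fs=cfg.target_fs, kind="complex")
    phi = np.angle(X) / (2 * np.pi)
    dphi = np.diff(phi, axis=1, prepend=phi[:, :1])
    # prediction of frame n+1 from frame n
    predicted = np.abs(X[:, :-1]) * np.exp(2j * np.pi * (phi[:, :-1] + dphi[:, :-1]))
    err = np.abs(X[:, 1:] - predicted)  # error at frames 1..n-1
    err = np.concatenate([np.zeros((n_freq, 1)), err], axis=1)
    # suppress per-band decreases (keep only growing novelty)
    dec = np.diff(err, axis=1) < 0
    err[:, 1:][dec] = 0.0
    nov_frames = err.sum(axis=0)
    nov = _resample_to_target(nov_frames, times, audio, cfg)
    nov = _local_average_subtract(nov, cfg.target_fs, cfg.local_avg_win)
    return NoveltyFunction(values=nov, fs=cfg.target_fs, kind="complex")


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        # a constant function carries no event information
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def combine_novelty(funcs: list[NoveltyFunction]) -> NoveltyFunction:
    """Min-max normalize each function to [0, 1] and average pointwise."""
    if not funcs:
        raise ValueError("need at least one novelty function")
    n = len(funcs[0].values)
    fs = funcs[0].fs
    for f in funcs:
        if len(f.values) != n:
            raise ValueError("novelty functions must have equal length")
        if f.fs != fs:
            raise ValueError("novelty functions must share a rate")
    stacked = np.stack([_minmax(f.values) for f in funcs])
    return NoveltyFunction(values=stacked.mean(axis=0), fs=fs, kind="combined")


def adaptive_threshold(nov: NoveltyFunction, cfg: PeakPickConfig | None = None):
    """Return (smoothed novelty, local threshold) for peak picking."""
    cfg = cfg or PeakPickConfig()
    if len(nov.values) == 0:
        raise ValueError("novelty must be non-empty")
    smoothed = ndimage.gaussian_filter1d(nov.values, cfg.gauss_sigma, mode="nearest")
    win = min(cfg.median_win, len(smoothed))
    local = ndimage.median_filter(smoothed, size=win, mode="nearest")
    threshold = local + nov.values.mean() + cfg.offset
    return smoothed, threshold


def pick_onsets(nov: NoveltyFunction, cfg: PeakPickConfig | None = None) -> OnsetEvents:
    """Detect onsets as strict local maxima of the smoothed combined novelty
    that exceed the local median threshold."""
    cfg = cfg or PeakPickConfig()
    smoothed, threshold = adaptive_threshold(nov, cfg)
    if len(smoothed) < 3:
        return OnsetEvents(times=np.array([]))
    prev = smoothed[:-2]
    cur = smoothed[1:-1]
    nxt = smoothed[2:]
    is_peak = (cur > prev) & (cur > nxt)
    above = cur > threshold[1:-1]
    idx = np.flatnonzero(is_peak & above) + 1
    times = idx / nov.fs
    guard = cfg.edge_guard
    total = len(smoothed) / nov.fs
    keep = (times >= guard) & (times <= total - guard)
    return OnsetEvents(times=times[keep])


def encode_onset_vector(onsets: OnsetEvents, fs: float, n_samples: int) -> FeatureMatrix:
    """Binary single-feature vector; sample index = floor(time * fs)."""
    if len(onsets) and onsets.times.min() < 0:
        raise ValueError("onset times must be nonnegative")
    vec = np.zeros(n_samples)
    idx = np.floor(onsets.times * fs).astype(int)
    idx = idx[idx < n_samples]
    vec[idx] = 1.0
    return FeatureMatrix(values=vec[:, None], fs=fs, feature_labels=["onset"])
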