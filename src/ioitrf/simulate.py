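"""Synthetic onset trains, tone-burst audio, and multichannel EEG with a
known IOI-dependent response amplitude.

The generator provides ground truth for every pipeline stage: a
right-skewed IOI law, bursts of varying level/rise time over a noise floor,
and EEG built by convolving the onset train with a biphasic kernel whose
per-event gain saturates with the preceding IOI, projected through a
fronto-central channel profile plus 1/f noise.
"""

from __future__ import annotations

import numpy as np

from ._types import AudioSignal, EEGRecording, OnsetEvents, RecoveryParams, SimConfig
from .features import compute_ioi

__all__ = [
    "SimConfig",
    "RecoveryParams",
    "simulate_onset_train",
    "simulate_audio",
    "simulate_eeg",
    "biphasic_kernel",
    "simulate_subject",
]

#: Don't place onsets closer than this to the recording end (room for the
#: evoked response).
_TAIL_GUARD = 0.7


def _draw_iois(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    name = law[0]
    if name == "lognormal":
        _, mu, sigma = law
        return rng.lognormal(mu, sigma, size)
    if name == "exponential":
        _, rate = law
        return rng.exponential(1.0 / rate, size)
    raise ValueError(f"unknown ioi_law {name!r}")


def simulate_onset_train(cfg: SimConfig) -> OnsetEvents:
    """I.i.d. IOIs from ``cfg.ioi_law`` cumulated into onset times."""
    rng = np.random.default_rng(cfg.seed)
    horizon = cfg.duration - _TAIL_GUARD
    times = []
    t = 0.0
    while True:
        block = _draw_iois(rng, cfg.ioi_law, 256)
        for ioi in block:
            t += ioi
            if t >= horizon:
                break
            times.append(t)
        if t >= horizon:
            break
    return compute_ioi(OnsetEvents(times=np.array(times)))


def biphasic_kernel(cfg: SimConfig, rec: RecoveryParams) -> np.ndarray:
    """Negative (N1) plus positive (P2) Gaussian at the EEG rate, lag 0..600 ms."""
    t = np.arange(0, 0.6, 1.0 / cfg.fs_eeg)
    n1 = np.exp(-0.5 * ((t - cfg.n1_latency) / cfg.n1_width) ** 2)
    p2 = np.exp(-0.5 * ((t - cfg.p2_latency) / cfg.p2_width) ** 2)
    return -rec.a_inf_n1 * n1 + rec.a_inf_p2 * p2


def simulate_audio(onsets: OnsetEvents, cfg: SimConfig) -> AudioSignal:
    """Tone bursts (random carrier 300-3000 Hz, varying level and rise
    time) over a pink-ish noise floor ``cfg.noise_floor_db`` below the mean
    burst RMS."""
    rng = np.random.default_rng(cfg.seed + 1)
    fs = cfg.fs_audio
    n = int(round(cfg.duration * fs))
    floor_amp = cfg.burst_rms * 10.0 ** (cfg.noise_floor_db / 20.0)
    # white floor: broadband spectral fluctuations average out across bands,
    # keeping the combined novelty of event-free stretches sub-threshold
    audio = rng.standard_normal(n) * floor_amp

    n_burst = int(round(cfg.burst_duration * fs))
    t_burst = np.arange(n_burst) / fs
    for time in onsets.times:
        lo = int(np.floor(time * fs))
        if lo + n_burst > n:
            break
        carrier = rng.uniform(300.0, 3000.0)
        rise = rng.uniform(0.002, 0.015)
        level = cfg.burst_rms * rng.lognormal(0.0, cfg.burst_level_sd)
        env = np.minimum(t_burst / rise, 1.0)
        env = env * np.exp(-np.maximum(t_burst - rise, 0.0) / 0.06)
        tone = np.sin(2 * np.pi * carrier * t_burst) * env
        rms = np.sqrt(np.mean(tone * tone))
        audio[lo:lo + n_burst] += tone * (level / rms)
    return AudioSignal(samples=audio, fs=fs)


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, int],
                      exponent: float, sd: float, fs: float) -> np.ndarray:
    """Channel-independent 1/f^exponent noise with unit-free SD scaling."""
    n_ch, n = shape
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal((n_ch, len(freqs)))
            + 1j * rng.standard_normal((n_ch, len(freqs)))) * scale
    noise = np.fft.irfft(spec, n=n, axis=1)
    std = noise.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std * sd


def simulate_eeg(onsets: OnsetEvents, rec: RecoveryParams, cfg: SimConfig,
                 ioi_coupling: bool = True) -> EEGRecording:
    """Convolve the gain-scaled onset train with the biphasic kernel and
    project through the channel mixing profile plus 1/f noise.

    ``ioi_coupling=False`` permutes the per-event gains across events: the
    marginal amplitude distribution is preserved but the IOI-amplitude link
    is broken (null generator for type-I checks).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    fs = cfg.fs_eeg
    n = int(round(cfg.duration * fs))
    if len(onsets) and np.all(np.isnan(onsets.ioi)) and len(onsets) > 1:
        onsets = compute_ioi(onsets)
    gains = rec.gain(onsets.ioi)
    if not ioi_coupling:
        gains = rng.permutation(gains)
    kern = biphasic_kernel(cfg, rec)
    train = np.zeros(n)
    idx = np.floor(onsets.times * fs).astype(int)
    keep = idx < n
    np.add.at(train, idx[keep], gains[keep])
    source = np.convolve(train, kern)[:n]
    data = cfg.mixing[:, None] * source[None, :]
    if cfg.noise_sd > 0:
        data = data + _one_over_f_noise(rng, (cfg.n_channels, n),
                                        cfg.noise_exponent, cfg.noise_sd, fs)
    return EEGRecording(data=data, fs=fs, channel_labels=cfg.channel_labels())


def simulate_subject(cfg: SimConfig, rec: RecoveryParams | None = None,
                     with_audio: bool = False, ioi_coupling: bool = True):
    """Convenience bundle: (onsets, eeg[, audio]) for one synthetic subject."""
    rec = rec or RecoveryParams()
    onsets = simulate_onset_train(cfg)
    eeg = simulate_eeg(onsets, rec, cfg, ioi_coupling=ioi_coupling)
    if with_audio:
        return onsets, eeg, simulate_audio(onsets, cfg)
    return onsets, eeg
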