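"""Shared domain containers.

These dataclasses are defined here once and re-exported from the domain
modules that own them conceptually (``novelty``, ``features``, ``trf`` ...)
so that the modules can depend on each other without import cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AudioSignal",
    "NoveltyConfig",
    "NoveltyFunction",
    "PeakPickConfig",
    "OnsetEvents",
    "BinSpec",
    "FeatureMatrix",
    "EEGRecording",
    "LaggedDesignMatrix",
    "TRFModel",
    "CVConfig",
    "PeakWindows",
    "FitResult",
    "PermutationResult",
    "ComparisonResult",
    "RecoveryParams",
    "SimConfig",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class AudioSignal:
    """Mono waveform plus sampling rate. Multichannel input is averaged."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim == 2:
            # collapse channels (axis with the fewer entries) by averaging
            axis = 0 if arr.shape[0] < arr.shape[1] else 1
            arr = arr.mean(axis=axis)
        if arr.ndim != 1:
            raise ValueError("samples must be 1-D (or 2-D multichannel)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.samples = arr
        self.fs = float(self.fs)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class NoveltyConfig:
    """Parameters of the acoustic novelty functions.

    ``stft_win``/``stft_hop``/``energy_win`` default to ``None`` meaning
    "derive from the audio rate": the STFT window is 2048 samples at
    44.1 kHz and scaled (to the nearest power of two) for other rates, the
    hop is ``fs / target_fs``, and the energy window spans 100 ms.
    """

    target_fs: float = 100.0
    gamma: float = 10.0
    stft_win: int | None = None
    stft_hop: int | None = None
    energy_win: int | None = None
    local_avg_win: float = 1.0

    def __post_init__(self):
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not self.target_fs > 0:
            raise ValueError("target_fs must be positive")
        if self.stft_win is not None and self.stft_hop is not None:
            if self.stft_hop > self.stft_win:
                raise ValueError("stft_hop must not exceed stft_win")

    def resolved_stft_win(self, fs: float) -> int:
        if self.stft_win is not None:
            return int(self.stft_win)
        n = 2048 * fs / 44100.0
        return int(2 ** max(5, round(np.log2(n))))

    def resolved_stft_hop(self, fs: float) -> int:
        if self.stft_hop is not None:
            return int(self.stft_hop)
        return max(1, int(round(fs / self.target_fs)))

    def resolved_energy_win(self, fs: float) -> int:
        if self.energy_win is not None:
            return int(self.energy_win)
        return max(3, int(round(0.1 * fs)))


@dataclass
class NoveltyFunction:
    """Nonnegative change signal sampled at ``fs``."""

    values: np.ndarray
    fs: float
    kind: str = "combined"

    _KINDS = ("energy", "spectral", "complex", "combined")

    def __post_init__(self):
        self.values = _as_float_array(self.values, "novelty values")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.values.ndim != 1:
            raise ValueError("novelty values must be 1-D")
        if len(self.values) and self.values.min() < -1e-12:
            raise ValueError("novelty values must be nonnegative")


@dataclass
class PeakPickConfig:
    """Adaptive-threshold peak picking parameters."""

    gauss_sigma: float = 4.0
    offset: float = 0.05
    median_win: int = 1024
    #: peaks this close (s) to either end are discarded: the smoothing and
    #: local-median context is incomplete there and produces edge artifacts
    edge_guard: float = 0.5

    def __post_init__(self):
        if not self.gauss_sigma > 0:
            raise ValueError("gauss_sigma must be positive")
        if self.median_win < 1:
            raise ValueError("median_win must be >= 1")


@dataclass
class OnsetEvents:
    """Detected (or simulated) sound-event onsets.

    ``ioi[i]`` is the interval preceding onset ``i`` (NaN for the first).
    ``bin`` is -1 until assigned; ``eligible`` marks onsets that enter the
    binned analyses (IOI defined and below the exclusion cutoff).
    """

    times: np.ndarray
    ioi: np.ndarray | None = None
    intensity: np.ndarray | None = None
    sharpness: np.ndarray | None = None
    bin: np.ndarray | None = None
    eligible: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("times must be 1-D")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        self.times = t
        n = len(t)

        def _opt(x, fill, dtype=float):
            if x is None:
                return np.full(n, fill, dtype=dtype)
            arr = np.asarray(x, dtype=dtype)
            if arr.shape != (n,):
                raise ValueError("per-event arrays must match times")
            return arr

        self.ioi = _opt(self.ioi, np.nan)
        self.intensity = _opt(self.intensity, np.nan)
        self.sharpness = _opt(self.sharpness, np.nan)
        self.bin = _opt(self.bin, -1, dtype=int)
        if self.eligible is None:
            self.eligible = np.zeros(n, dtype=bool)
        else:
            self.eligible = np.asarray(self.eligible, dtype=bool)
            if self.eligible.shape != (n,):
                raise ValueError("eligible must match times")

    def __len__(self) -> int:
        return len(self.times)

    def replace(self, **kw) -> "OnsetEvents":
        return replace(self, **kw)


@dataclass
class BinSpec:
    """Uniform-count IOI binning: ``edges`` has ``n_bins + 1`` entries."""

    n_bins: int
    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.edges = _as_float_array(self.edges, "edges")
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.edges) != self.n_bins + 1:
            raise ValueError("edges must have n_bins + 1 entries")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("edges must be strictly increasing")
        if len(self.counts) != self.n_bins:
            raise ValueError("counts must have n_bins entries")

    @property
    def upper_edges(self) -> np.ndarray:
        return self.edges[1:]

    def assign(self, iois: np.ndarray) -> np.ndarray:
        """Bin index per IOI; ties on an inner edge go to the lower bin."""
        iois = np.asarray(iois, dtype=float)
        idx = np.searchsorted(self.edges[1:-1], iois, side="left")
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class FeatureMatrix:
    """time x feature stimulus representation at the EEG rate."""

    values: np.ndarray
    fs: float
    feature_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ValueError("values must be 2-D (time x feature)")
        self.values = arr
        if not self.feature_labels:
            self.feature_labels = [f"f{i}" for i in range(arr.shape[1])]
        if len(self.feature_labels) != arr.shape[1]:
            raise ValueError("feature_labels must match feature count")
        self.fs = float(self.fs)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class EEGRecording:
    """channel x time multichannel recording."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("data must be 2-D (channel x time)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("data must be finite")
        self.data = arr
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(arr.shape[0])]
        if len(self.channel_labels) != arr.shape[0]:
            raise ValueError("channel_labels must match channel count")
        self.fs = float(self.fs)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]


@dataclass
class LaggedDesignMatrix:
    """time x (feature * lag) design with zero-filled shifts."""

    values: np.ndarray
    lag_axis: np.ndarray  # lag times in ms
    feature_labels: list[str]
    fs: float

    @property
    def n_lags(self) -> int:
        return len(self.lag_axis)

    @property
    def n_features(self) -> int:
        return len(self.feature_labels)


@dataclass
class TRFModel:
    """Lagged forward-model weights: feature x lag x channel."""

    weights: np.ndarray
    lam: float
    lag_window: tuple[float, float]
    fs: float
    feature_labels: list[str] = field(default_factory=list)
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError("weights must be feature x lag x channel")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not self.feature_labels:
            self.feature_labels = [f"f{i}" for i in range(self.weights.shape[0])]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.weights.shape[2])]

    @property
    def lag_axis(self) -> np.ndarray:
        """Lag times in ms."""
        t_min, t_max = self.lag_window
        n = self.weights.shape[1]
        step = 1000.0 / self.fs
        return np.round(t_min / step) * step + step * np.arange(n)


@dataclass
class CVConfig:
    """Segmented cross-validation settings."""

    n_segments: int = 6
    lambda_grid: Sequence[float] = field(
        default_factory=lambda: tuple(10.0 ** k for k in range(-4, 5))
    )
    lag_window: tuple[float, float] = (-100.0, 500.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda values must be positive")


@dataclass
class PeakWindows:
    """Component search windows (ms) and the channels averaged over."""

    n1_window: tuple[float, float] = (70.0, 160.0)
    p2_window: tuple[float, float] = (160.0, 300.0)
    channel_set: Sequence[str] | None = (
        "F3", "Fz", "F4", "FC1", "FC2", "C3", "Cz", "C4",
    )

    def __post_init__(self):
        if self.n1_window[0] >= self.n1_window[1]:
            raise ValueError("n1_window must be an increasing interval")
        if self.p2_window[0] >= self.p2_window[1]:
            raise ValueError("p2_window must be an increasing interval")


@dataclass
class FitResult:
    family: str
    params: dict
    r_squared: float


@dataclass
class PermutationResult:
    observed: float
    null_scores: np.ndarray
    p_value: float
    p_fdr: float | None = None


@dataclass
class ComparisonResult:
    model_pair: tuple[str, str]
    w: float
    z: float
    p: float
    rho: float
    n: int


@dataclass
class RecoveryParams:
    """Saturating amplitude-recovery law a(IOI) for the generator.

    a(ioi) = floor + (1 - floor) * (1 - exp(-ioi / tau_rec)), scaled by the
    asymptotic component amplitudes.
    """

    a_inf_n1: float = 4.0
    a_inf_p2: float = 3.5
    tau_rec: float = 1.5
    floor: float = 0.3

    def __post_init__(self):
        if not self.tau_rec > 0:
            raise ValueError("tau_rec must be positive")
        if not (0 <= self.floor < 1):
            raise ValueError("floor must be in [0, 1)")

    def gain(self, ioi: np.ndarray) -> np.ndarray:
        """Relative amplitude in [floor, 1]; NaN IOI (first event) -> 1."""
        ioi = np.asarray(ioi, dtype=float)
        g = self.floor + (1.0 - self.floor) * (1.0 - np.exp(-ioi / self.tau_rec))
        return np.where(np.isnan(ioi), 1.0, g)


#: Default 22-channel montage with a fronto-central weighting.
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P3", "P4",
]

DEFAULT_MIXING = np.array([
    0.35, 0.35, 0.30, 0.75, 1.00, 0.75, 0.30,
    0.55, 0.90, 0.90, 0.55,
    0.25, 0.70, 0.95, 0.70, 0.25,
    0.40, 0.60, 0.60, 0.40, 0.35, 0.35,
])


@dataclass
class SimConfig:
    """Synthetic-recording settings; everything is a pure function of
    (config, seed)."""

    duration: float = 300.0
    ioi_law: tuple = ("lognormal", 0.53, 0.9)
    fs_eeg: float = 100.0
    fs_audio: float = 8000.0
    n_channels: int = 22
    mixing: np.ndarray | None = None
    noise_exponent: float = 1.0
    noise_sd: float = 1.5
    n1_latency: float = 0.110
    n1_width: float = 0.020
    p2_latency: float = 0.220
    p2_width: float = 0.030
    burst_rms: float = 0.15
    burst_level_sd: float = 0.2
    burst_duration: float = 0.15
    noise_floor_db: float = -20.0
    seed: int = 0

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.mixing is None:
            if self.n_channels == len(DEFAULT_MIXING):
                self.mixing = DEFAULT_MIXING.copy()
            else:
                # fall back to a smooth gain profile of the requested size
                x = np.linspace(0, np.pi, self.n_channels)
                self.mixing = 0.3 + 0.7 * np.sin(x) ** 2
        self.mixing = np.asarray(self.mixing, dtype=float)
        if len(self.mixing) != self.n_channels:
            raise ValueError("mixing length must equal n_channels")

    def channel_labels(self) -> list[str]:
        if self.n_channels == len(DEFAULT_CHANNELS):
            return list(DEFAULT_CHANNELS)
        return [f"ch{i}" for i in range(self.n_channels)]
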