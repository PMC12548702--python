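"""Per-event acoustic covariates (intensity, envelope sharpness) and their
mixed-effects relation to the IOI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import ndimage, stats

from ._types import AudioSignal, OnsetEvents

__all__ = [
    "event_intensity",
    "envelope_sharpness",
    "event_covariates",
    "lme_ioi",
    "LMEResult",
]


def event_intensity(audio: AudioSignal, onsets: OnsetEvents,
                    win: float = 0.05) -> np.ndarray:
    """RMS of the waveform in [t, t + win) per onset."""
    n_win = max(1, int(round(win * audio.fs)))
    x = audio.samples
    out = np.empty(len(onsets))
    for i, t in enumerate(onsets.times):
        lo = int(np.floor(t * audio.fs))
        seg = x[lo:lo + n_win]
        out[i] = np.sqrt(np.mean(seg * seg)) if len(seg) else 0.0
    return out


def _envelope(x: np.ndarray, fs: float, smooth: float = 0.010) -> np.ndarray:
    """Rectified waveform with a causal 10 ms moving average.

    Causal smoothing keeps the envelope at zero right up to an onset, so
    the post-onset gradient is not diluted by pre-onset leakage.
    """
    win = max(1, int(round(smooth * fs)))
    kernel = np.ones(win) / win
    return np.convolve(np.abs(x), kernel)[: len(x)]


def envelope_sharpness(audio: AudioSignal, onsets: OnsetEvents,
                       win: float = 0.05) -> np.ndarray:
    """Mean gradient of the amplitude envelope over the first ``win``
    seconds following each onset (amplitude per second).

    The mean of the pointwise gradient telescopes to the net envelope
    change across the window divided by the window length; an
    instantaneous-rise event therefore scores high while a slow ramp
    scores its ramp slope.
    """
    env = _envelope(audio.samples, audio.fs)
    n_win = max(2, int(round(win * audio.fs)))
    out = np.empty(len(onsets))
    for i, t in enumerate(onsets.times):
        lo = int(np.floor(t * audio.fs))
        hi = min(lo + n_win - 1, len(env) - 1)
        if hi <= lo:
            out[i] = 0.0
            continue
        out[i] = (env[hi] - env[lo]) / ((hi - lo) / audio.fs)
    return out


def event_covariates(audio: AudioSignal, onsets: OnsetEvents,
                     participant: str | int = 0,
                     win: float = 0.05) -> pd.DataFrame:
    """Table of IOI-eligible events with intensity and sharpness columns."""
    intensity = event_intensity(audio, onsets, win)
    sharpness = envelope_sharpness(audio, onsets, win)
    mask = onsets.eligible
    return pd.DataFrame({
        "participant": participant,
        "time_s": onsets.times[mask],
        "ioi": onsets.ioi[mask],
        "intensity": intensity[mask],
        "sharpness": sharpness[mask],
    })


@dataclass
class LMEResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    random_intercept_var: float
    loglik: float
    predictor_correlations: dict[str, tuple[float, float]]


def lme_ioi(cov: pd.DataFrame) -> LMEResult:
    """IOI ~ sharpness * intensity with participant random intercepts (ML).

    Also reports pairwise Pearson correlations among ioi/intensity/sharpness
    as a collinearity check.
    """
    required = {"ioi", "intensity", "sharpness", "participant"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    model = smf.mixedlm("ioi ~ sharpness * intensity", data=cov,
                        groups=cov["participant"])
    fit = model.fit(reml=False)
    corrs = {}
    for x, y in (("ioi", "intensity"), ("ioi", "sharpness"),
                 ("sharpness", "intensity")):
        r, p = stats.pearsonr(cov[x], cov[y])
        corrs[f"{x}~{y}"] = (float(r), float(p))
    fixed = [name for name in fit.params.index if name != "Group Var"]
    return LMEResult(
        params=fit.params[fixed],
        bse=fit.bse[fixed],
        tvalues=fit.tvalues[fixed],
        pvalues=fit.pvalues[fixed],
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        loglik=float(fit.llf),
        predictor_correlations=corrs,
    )
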