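"""Paired model comparisons: signed-rank tests, onset-count-matched
subsampling, merged-condition training, and generic leave-one-out models.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._types import ComparisonResult, CVConfig, EEGRecording, FeatureMatrix, OnsetEvents
from .novelty import encode_onset_vector
from .trf import crossval_fit, predict, select_lambda, lag_matrix, ridge_fit

__all__ = [
    "ComparisonResult",
    "wilcoxon_compare",
    "signed_rank_distribution",
    "matched_onset_subsample",
    "merged_condition_training",
    "generic_lopo",
]


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of |d| (zeros already dropped) and the sign vector."""
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(len(d))
    sorted_abs = absd[order]
    i = 0
    while i < len(d):
        j = i
        while j < len(d) and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
        i = j
    return ranks, np.sign(d)


def signed_rank_distribution(ranks: np.ndarray) -> np.ndarray:
    """Exact null distribution of W+ by enumerating all sign assignments."""
    n = len(ranks)
    ws = np.empty(2 ** n)
    for k, signs in enumerate(itertools.product((0, 1), repeat=n)):
        ws[k] = np.dot(signs, ranks)
    return ws


def wilcoxon_compare(a: np.ndarray, b: np.ndarray, n_comparisons: int = 1,
                     model_pair: tuple[str, str] = ("a", "b")) -> ComparisonResult:
    """Paired two-sided Wilcoxon signed-rank test on per-participant scores.

    ``W`` is the rank sum of positive differences ``a - b`` (zeros dropped,
    ties mid-ranked).  For fewer than 10 non-zero pairs the p-value is exact
    (full sign-assignment enumeration); otherwise it uses the normal
    approximation with continuity and tie corrections.  The effect size is
    ``rho = |Z| / sqrt(N)`` with N the number of pairs entering the test,
    and the p-value is Bonferroni-multiplied by ``n_comparisons`` (capped
    at 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return ComparisonResult(model_pair, w=0.0, z=0.0, p=1.0, rho=0.0, n=0)
    ranks, signs = _signed_ranks(d)
    w = float(ranks[signs > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie correction for the variance
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts ** 3 - tie_counts) / 48.0
    sigma = float(np.sqrt(sigma2))
    if sigma == 0:
        z = 0.0
    else:
        cc = 0.5 * np.sign(w - mu)  # continuity correction toward the mean
        z = (w - mu - cc) / sigma
    if n < 10:
        dist = signed_rank_distribution(ranks)
        p_raw = float(np.mean(np.abs(dist - mu) >= abs(w - mu) - 1e-12))
    else:
        p_raw = float(2 * norm.sf(abs(z)))
    p = min(1.0, p_raw * n_comparisons)
    rho = abs(z) / np.sqrt(n)
    return ComparisonResult(model_pair, w=w, z=float(z), p=p, rho=float(rho), n=n)


def matched_onset_subsample(onsets: OnsetEvents, n_keep: int, fs: float,
                            n_samples: int, n_reps: int = 100,
                            seed: int = 0) -> list[FeatureMatrix]:
    """Single-onset vectors keeping ``n_keep`` uniformly sampled onsets
    (without replacement), one per replicate."""
    n = len(onsets)
    if not (0 < n_keep <= n):
        raise ValueError("n_keep must be in (0, n_onsets]")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        keep = np.sort(rng.choice(n, size=n_keep, replace=False))
        sub = OnsetEvents(times=onsets.times[keep])
        out.append(encode_onset_vector(sub, fs, n_samples))
    return out


def _concat(datasets: list[tuple[FeatureMatrix, EEGRecording]]):
    fs = datasets[0][0].fs
    labels = datasets[0][0].feature_labels
    ch = datasets[0][1].channel_labels
    for f, e in datasets:
        if f.fs != fs or e.fs != fs:
            raise ValueError("all datasets must share the sampling rate")
        if f.n_samples != e.n_times:
            raise ValueError("feature matrix and EEG must be time-aligned")
    values = np.concatenate([f.values for f, _ in datasets], axis=0)
    data = np.concatenate([e.data for _, e in datasets], axis=1)
    feats = FeatureMatrix(values=values, fs=fs, feature_labels=list(labels))
    eeg = EEGRecording(data=data, fs=fs, channel_labels=list(ch))
    return feats, eeg


def merged_condition_training(datasets: list[tuple[FeatureMatrix, EEGRecording]],
                              cfg: CVConfig | None = None,
                              n_segments: int = 12):
    """Concatenate one participant's condition datasets along time and run
    the segmented cross-validation with ``n_segments`` rotations."""
    cfg = cfg or CVConfig()
    if cfg.n_segments != n_segments:
        cfg = CVConfig(n_segments=n_segments, lambda_grid=cfg.lambda_grid,
                       lag_window=cfg.lag_window, seed=cfg.seed)
    feats, eeg = _concat(datasets)
    return crossval_fit(feats, eeg, cfg)


def generic_lopo(datasets: list[tuple[FeatureMatrix, EEGRecording]],
                 cfg: CVConfig | None = None) -> pd.DataFrame:
    """Leave-one-participant-out generic models.

    For each participant, a model is trained on everyone else's concatenated
    data (ridge parameter from a single-level segment rotation on the
    training pool) and evaluated on the held-out participant.
    """
    cfg = cfg or CVConfig()
    rows = []
    for held in range(len(datasets)):
        train = [d for i, d in enumerate(datasets) if i != held]
        feats, eeg = _concat(train)
        lam = select_lambda(feats, eeg, cfg)
        design = lag_matrix(feats, cfg.lag_window, feats.fs)
        model = ridge_fit(design, eeg, lam)
        f_test, e_test = datasets[held]
        _, r_mean = predict(model, f_test, e_test)
        rows.append({"participant": held, "r_mean": r_mean, "lambda": lam})
    return pd.DataFrame(rows)
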