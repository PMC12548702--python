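"""Lagged ridge forward models (TRFs) with segment-based cross-validation.

The design matrix stacks zero-padded time-shifted copies of each stimulus
feature; weights solve the penalized normal equations per channel.  For
binary onset features an exact sparse Gram path (:class:`OnsetDesignCache`)
produces identical normal equations from onset sample indices alone, which
makes the 100-fold permutation refits cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from ._types import (
    CVConfig,
    EEGRecording,
    FeatureMatrix,
    LaggedDesignMatrix,
    TRFModel,
)

__all__ = [
    "EEGRecording",
    "LaggedDesignMatrix",
    "TRFModel",
    "CVConfig",
    "lag_samples",
    "lag_matrix",
    "ridge_fit",
    "predict",
    "crossval_fit",
    "select_lambda",
    "segment_bounds",
    "OnsetDesignCache",
]


def lag_samples(lag_window: tuple[float, float], fs: float) -> np.ndarray:
    """Integer sample shifts covering [t_min, t_max] ms inclusive."""
    t_min, t_max = lag_window
    lo = int(round(t_min * fs / 1000.0))
    hi = int(round(t_max * fs / 1000.0))
    if hi < lo:
        raise ValueError("lag window must be increasing")
    return np.arange(lo, hi + 1)


def lag_matrix(feats: FeatureMatrix, lag_window: tuple[float, float],
               fs: float | None = None) -> LaggedDesignMatrix:
    """time x (feature * lag) design; shifted-out samples are zero.

    Column (f, tau) holds feature f delayed by tau samples, i.e.
    ``S[t, (f, tau)] = feats[t - tau, f]`` with zero padding.
    """
    fs = fs if fs is not None else feats.fs
    lags = lag_samples(lag_window, fs)
    T, F = feats.values.shape
    L = len(lags)
    out = np.zeros((T, F * L))
    for fi in range(F):
        x = feats.values[:, fi]
        for li, lag in enumerate(lags):
            col = out[:, fi * L + li]
            if lag >= 0:
                col[lag:] = x[: T - lag] if lag < T else 0.0
            else:
                col[:lag] = x[-lag:]
    lag_ms = lags * 1000.0 / fs
    return LaggedDesignMatrix(values=out, lag_axis=lag_ms,
                              feature_labels=list(feats.feature_labels), fs=fs)


def _solve_normal_eqs(xtx: np.ndarray, xty: np.ndarray, lam: float) -> np.ndarray:
    k = xtx.shape[0]
    if lam == 0:
        # surface rank deficiency instead of silently pseudo-inverting
        rank = np.linalg.matrix_rank(xtx, hermitian=True)
        if rank < k:
            raise np.linalg.LinAlgError(
                f"design is rank deficient (rank {rank} < {k}); "
                "use a positive ridge parameter"
            )
        return np.linalg.solve(xtx, xty)
    a = xtx + lam * np.eye(k)
    return linalg.solve(a, xty, assume_a="pos")


def ridge_fit(design: LaggedDesignMatrix, eeg: EEGRecording,
              lam: float) -> TRFModel:
    """Penalized least squares ``w = (S'S + lam I)^-1 S'r`` per channel."""
    X = design.values
    if X.shape[0] != eeg.n_times:
        raise ValueError("design and EEG must be time-aligned")
    xtx = X.T @ X
    xty = X.T @ eeg.data.T
    w = _solve_normal_eqs(xtx, xty, lam)
    F, L = design.n_features, design.n_lags
    weights = w.reshape(F, L, eeg.n_channels)
    lag_window = (design.lag_axis[0], design.lag_axis[-1])
    return TRFModel(weights=weights, lam=lam, lag_window=lag_window,
                    fs=design.fs, feature_labels=list(design.feature_labels),
                    channel_labels=list(eeg.channel_labels))


def _safe_corr(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Pearson r per channel (columns); zero-variance inputs give r = 0."""
    p = pred - pred.mean(axis=0)
    a = actual - actual.mean(axis=0)
    sp = np.sqrt((p * p).sum(axis=0))
    sa = np.sqrt((a * a).sum(axis=0))
    denom = sp * sa
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (p * a).sum(axis=0) / denom
    r[denom == 0] = 0.0
    return r


def predict(model: TRFModel, feats: FeatureMatrix,
            eeg: EEGRecording) -> tuple[np.ndarray, float]:
    """Forward prediction and per-channel Pearson r; returns (r, mean r)."""
    design = lag_matrix(feats, model.lag_window, model.fs)
    F, L, C = model.weights.shape
    pred = design.values @ model.weights.reshape(F * L, C)
    r = _safe_corr(pred, eeg.data.T)
    return r, float(r.mean())


def segment_bounds(n_times: int, n_segments: int) -> list[tuple[int, int]]:
    """Contiguous near-equal segments tiling [0, n_times)."""
    edges = np.linspace(0, n_times, n_segments + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_segments)]


@dataclass
class _GramCV:
    """Per-segment sufficient statistics for fast segmented ridge CV."""

    xtx: list[np.ndarray]        # per-segment S'S
    xty: list[np.ndarray]        # per-segment S'r
    colsum: list[np.ndarray]     # per-segment column sums of S
    ysum: list[np.ndarray]       # per-segment channel sums of r
    yss: list[np.ndarray]        # per-segment channel sums of squares
    nseg: list[int]

    @classmethod
    def build(cls, X: np.ndarray, Y: np.ndarray, bounds) -> "_GramCV":
        xtx, xty, colsum, ysum, yss, nseg = [], [], [], [], [], []
        for lo, hi in bounds:
            Xs, Ys = X[lo:hi], Y[lo:hi]
            xtx.append(Xs.T @ Xs)
            xty.append(Xs.T @ Ys)
            colsum.append(Xs.sum(axis=0))
            ysum.append(Ys.sum(axis=0))
            yss.append((Ys * Ys).sum(axis=0))
            nseg.append(hi - lo)
        return cls(xtx, xty, colsum, ysum, yss, nseg)

    def fit(self, segments: list[int], lam: float) -> np.ndarray:
        xtx = sum(self.xtx[s] for s in segments)
        xty = sum(self.xty[s] for s in segments)
        return _solve_normal_eqs(xtx, xty, lam)

    def score(self, w: np.ndarray, seg: int) -> np.ndarray:
        """Per-channel Pearson r of the prediction on one segment, computed
        from the segment's sufficient statistics (no design rebuild)."""
        n = self.nseg[seg]
        s_py = (w * self.xty[seg]).sum(axis=0)
        s_p = self.colsum[seg] @ w
        s_pp = (w * (self.xtx[seg] @ w)).sum(axis=0)
        s_y = self.ysum[seg]
        s_yy = self.yss[seg]
        cov = s_py - s_p * s_y / n
        var_p = s_pp - s_p * s_p / n
        var_y = s_yy - s_y * s_y / n
        denom = np.sqrt(np.clip(var_p, 0, None) * np.clip(var_y, 0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / denom
        r = np.asarray(r)
        r[~np.isfinite(r)] = 0.0
        return r


def _pick_lambda(scores: dict[float, float]) -> float:
    """Highest mean validation r; ties resolved to the smaller lambda."""
    best = max(scores.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def crossval_fit(feats: FeatureMatrix, eeg: EEGRecording,
                 cfg: CVConfig | None = None) -> tuple[TRFModel, pd.DataFrame]:
    """Nested segmented cross-validation.

    The recording is split into ``cfg.n_segments`` contiguous segments.
    Each segment is held out once; within the remaining training segments an
    inner rotation selects the ridge parameter maximizing mean validation
    correlation, the model is refit on all training segments at that value,
    and the held-out correlation is recorded.  The returned model is refit
    on the full recording at the most frequently selected lambda (ties to
    the smallest).
    """
    cfg = cfg or CVConfig()
    design = lag_matrix(feats, cfg.lag_window, feats.fs)
    T = design.values.shape[0]
    if eeg.n_times != T:
        raise ValueError("feature matrix and EEG must be time-aligned")
    span = design.n_lags
    if T < cfg.n_segments * span:
        raise ValueError("recording too short for the requested segmentation")
    bounds = segment_bounds(T, cfg.n_segments)
    gram = _GramCV.build(design.values, eeg.data.T, bounds)

    rows = []
    chosen = []
    for test_seg in range(cfg.n_segments):
        train = [s for s in range(cfg.n_segments) if s != test_seg]
        scores = {}
        for lam in cfg.lambda_grid:
            vals = []
            for val_seg in train:
                inner = [s for s in train if s != val_seg]
                w = gram.fit(inner, lam)
                vals.append(gram.score(w, val_seg).mean())
            scores[lam] = float(np.mean(vals))
        lam_star = _pick_lambda(scores)
        chosen.append(lam_star)
        w = gram.fit(train, lam_star)
        r = gram.score(w, test_seg)
        rows.append({"segment": test_seg, "lambda": lam_star,
                     "r_mean": float(r.mean()),
                     "r_channels": r})
    perf = pd.DataFrame(rows)

    vals, counts = np.unique(chosen, return_counts=True)
    lam_final = float(vals[np.lexsort((vals, -counts))[0]])
    w_full = gram.fit(list(range(cfg.n_segments)), lam_final)
    F, L = design.n_features, design.n_lags
    model = TRFModel(weights=w_full.reshape(F, L, eeg.n_channels),
                     lam=lam_final,
                     lag_window=(design.lag_axis[0], design.lag_axis[-1]),
                     fs=design.fs,
                     feature_labels=list(design.feature_labels),
                     channel_labels=list(eeg.channel_labels))
    return model, perf


def select_lambda(feats: FeatureMatrix, eeg: EEGRecording,
                  cfg: CVConfig | None = None) -> float:
    """Single-level rotation: each segment validates once per lambda."""
    cfg = cfg or CVConfig()
    design = lag_matrix(feats, cfg.lag_window, feats.fs)
    bounds = segment_bounds(design.values.shape[0], cfg.n_segments)
    gram = _GramCV.build(design.values, eeg.data.T, bounds)
    scores = {}
    for lam in cfg.lambda_grid:
        vals = []
        for val_seg in range(cfg.n_segments):
            train = [s for s in range(cfg.n_segments) if s != val_seg]
            w = gram.fit(train, lam)
            vals.append(gram.score(w, val_seg).mean())
        scores[lam] = float(np.mean(vals))
    return _pick_lambda(scores)


class OnsetDesignCache:
    """Exact normal equations for binary onset designs, from onset indices.

    For features that are sums of unit impulses, every entry of ``S'S`` is a
    count of aligned onset pairs and ``S'r`` is a sum of per-onset EEG
    slices.  Pair geometry and EEG slices are computed once; refitting under
    a new onset->feature allocation only regroups counts, so a permutation
    refit costs one small linear solve.
    """

    def __init__(self, onset_idx: np.ndarray, eeg: EEGRecording,
                 lag_window: tuple[float, float]):
        self.eeg = eeg
        self.lags = lag_samples(lag_window, eeg.fs)
        self.L = len(self.lags)
        self.T = eeg.n_times
        idx = np.asarray(onset_idx, dtype=int)
        if np.any(idx < 0) or np.any(idx >= self.T):
            raise ValueError("onset sample indices out of range")
        if np.any(np.diff(idx) < 0):
            order = np.argsort(idx, kind="stable")
            idx = idx[order]
            self._order = order
        else:
            self._order = np.arange(len(idx))
        self.idx = idx
        self.n = len(idx)
        self.lag_window = lag_window
        self._build_pairs()
        self._build_slices()

    # -- construction -----------------------------------------------------
    def _build_pairs(self):
        idx, L = self.idx, self.L
        span = L - 1
        pi, pj = [], []
        for i in range(self.n):
            lo = np.searchsorted(idx, idx[i] - span, side="left")
            hi = np.searchsorted(idx, idx[i] + span, side="right")
            js = np.arange(lo, hi)
            pi.append(np.full(len(js), i))
            pj.append(js)
        self.pair_i = np.concatenate(pi) if pi else np.zeros(0, int)
        self.pair_j = np.concatenate(pj) if pj else np.zeros(0, int)
        self.pair_d = idx[self.pair_i] - idx[self.pair_j]
        # an onset is "edge" when some lag falls outside the recording
        l0, l1 = self.lags[0], self.lags[-1]
        edge_onset = (idx + l0 < 0) | (idx + l1 >= self.T)
        is_edge_pair = edge_onset[self.pair_i] | edge_onset[self.pair_j]
        self.int_i = self.pair_i[~is_edge_pair]
        self.int_j = self.pair_j[~is_edge_pair]
        self.int_d = self.pair_d[~is_edge_pair]
        # for edge pairs, enumerate the valid (m, m + d) diagonal positions
        self.edge_entries = []  # (i, j, m_valid, m_valid + d)
        for i, j, d in zip(self.pair_i[is_edge_pair],
                           self.pair_j[is_edge_pair],
                           self.pair_d[is_edge_pair]):
            # m indexes the lag of onset i's column; t = idx[i] + lags[m]
            m = np.arange(max(0, -d), min(L, L - d))
            t = self.idx[i] + self.lags[m]
            m = m[(t >= 0) & (t < self.T)]
            self.edge_entries.append((i, j, m, m + d))
        # lag-offset lookup table for Toeplitz assembly
        mm = np.arange(L)
        self._doff = mm[None, :] - mm[:, None] + span  # (L, L) in [0, 2span]

    def _build_slices(self):
        """Per-onset lagged EEG slices E[i, m, c] = r[c, idx[i] + lags[m]]."""
        t = self.idx[:, None] + self.lags[None, :]
        valid = (t >= 0) & (t < self.T)
        tc = np.clip(t, 0, self.T - 1)
        E = self.eeg.data.T[tc]          # (n, L, C)
        E[~valid] = 0.0
        self.slices = E

    # -- fitting ----------------------------------------------------------
    def normal_equations(self, labels: np.ndarray, n_features: int):
        """(S'S, S'r) for the design where onset i feeds feature labels[i].

        Onsets labelled < 0 are excluded from the design entirely.
        """
        labels = np.asarray(labels, dtype=int)[self._order]
        if len(labels) != self.n:
            raise ValueError("labels must match onset count")
        F, L = n_features, self.L
        span = L - 1
        counts = np.zeros((F, F, 2 * span + 1))
        fi = labels[self.int_i]
        fj = labels[self.int_j]
        keep = (fi >= 0) & (fj >= 0)
        np.add.at(counts, (fi[keep], fj[keep], self.int_d[keep] + span), 1.0)
        # banded Toeplitz blocks from the pair counts
        xtx = counts[:, :, self._doff]            # (F, F, L, L)
        xtx = xtx.transpose(0, 2, 1, 3).reshape(F * L, F * L)
        for i, j, mi, mj in self.edge_entries:
            a, b = labels[i], labels[j]
            if a < 0 or b < 0:
                continue
            xtx[a * L + mi, b * L + mj] += 1.0
        C = self.eeg.n_channels
        xty = np.zeros((F, L, C))
        keep = labels >= 0
        np.add.at(xty, labels[keep], self.slices[keep])
        return xtx, xty.reshape(F * L, C)

    def fit(self, labels: np.ndarray, n_features: int, lam: float,
            feature_labels: list[str] | None = None) -> TRFModel:
        xtx, xty = self.normal_equations(labels, n_features)
        w = _solve_normal_eqs(xtx, xty, lam)
        weights = w.reshape(n_features, self.L, self.eeg.n_channels)
        lag_ms = self.lags * 1000.0 / self.eeg.fs
        return TRFModel(weights=weights, lam=lam,
                        lag_window=(lag_ms[0], lag_ms[-1]), fs=self.eeg.fs,
                        feature_labels=feature_labels or [],
                        channel_labels=list(self.eeg.channel_labels))
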