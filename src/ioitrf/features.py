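"""IOI computation, uniform-count binning, and stimulus feature matrices.

Onsets become (a) a single binary onset vector, (b) one binary column per
IOI bin, (c) a permuted-allocation null with identical per-bin counts, or
(d) a single vector weighted by the min-max-normalized IOI.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._types import BinSpec, FeatureMatrix, OnsetEvents

__all__ = [
    "BinSpec",
    "FeatureMatrix",
    "compute_ioi",
    "make_uniform_bins",
    "assign_bins",
    "binned_onset_matrix",
    "permute_bin_allocation",
    "permute_matrix_labels",
    "weighted_onset_vector",
]

#: IOIs longer than this are excluded from binned analyses (seconds).
MAX_IOI = 10.0


def compute_ioi(onsets: OnsetEvents, max_ioi: float = MAX_IOI) -> OnsetEvents:
    """Set per-onset IOIs and mark bin-eligible events.

    The first onset (no preceding interval) and onsets whose IOI exceeds
    ``max_ioi`` are excluded from the binned analyses.
    """
    t = onsets.times
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("onset times must be strictly increasing")
    ioi = np.full(len(t), np.nan)
    if len(t) > 1:
        ioi[1:] = np.diff(t)
    eligible = np.isfinite(ioi) & (ioi <= max_ioi)
    return onsets.replace(ioi=ioi, eligible=eligible)


def make_uniform_bins(iois: np.ndarray, n_bins: int) -> BinSpec:
    """Quantile edges such that per-bin onset counts differ by at most one.

    Deterministic: the sorted IOIs are split into ``n_bins`` contiguous
    chunks (larger chunks first) and inner edges are placed midway between
    adjacent chunk boundary values.
    """
    iois = np.sort(np.asarray(iois, dtype=float))
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > len(iois):
        raise ValueError(f"n_bins={n_bins} exceeds number of IOIs ({len(iois)})")
    chunks = np.array_split(iois, n_bins)
    inner = np.array([(a[-1] + b[0]) / 2 for a, b in zip(chunks[:-1], chunks[1:])])
    edges = np.concatenate([[iois[0]], inner, [iois[-1]]])
    if not np.all(np.diff(edges) > 0):
        raise ValueError("duplicate IOI values collapse bin edges; reduce n_bins")
    spec = BinSpec(n_bins=n_bins, edges=edges,
                   counts=np.zeros(n_bins, dtype=int))
    counts = np.bincount(spec.assign(iois), minlength=n_bins)
    spec.counts = counts
    if counts.max() - counts.min() > 1:
        warnings.warn("tied IOI values produce uneven bin counts", stacklevel=2)
    return spec


def assign_bins(onsets: OnsetEvents, spec: BinSpec) -> OnsetEvents:
    """Label eligible onsets with their bin index (-1 for ineligible)."""
    labels = np.full(len(onsets), -1, dtype=int)
    mask = onsets.eligible
    labels[mask] = spec.assign(onsets.ioi[mask])
    return onsets.replace(bin=labels)


def _onset_sample_indices(times: np.ndarray, fs: float, n_samples: int) -> np.ndarray:
    idx = np.floor(times * fs).astype(int)
    return idx


def _matrix_from_labels(times: np.ndarray, labels: np.ndarray, n_bins: int,
                        spec: BinSpec, fs: float, n_samples: int) -> FeatureMatrix:
    values = np.zeros((n_samples, n_bins))
    idx = _onset_sample_indices(times, fs, n_samples)
    keep = idx < n_samples
    values[idx[keep], labels[keep]] = 1.0
    feature_labels = [f"{e:.3f}" for e in spec.upper_edges]
    return FeatureMatrix(values=values, fs=fs, feature_labels=feature_labels)


def binned_onset_matrix(onsets: OnsetEvents, spec: BinSpec, fs: float,
                        n_samples: int) -> FeatureMatrix:
    """One binary column per IOI bin; each eligible onset appears once."""
    onsets = assign_bins(onsets, spec)
    mask = onsets.eligible
    return _matrix_from_labels(onsets.times[mask], onsets.bin[mask],
                               spec.n_bins, spec, fs, n_samples)


def permute_bin_allocation(onsets: OnsetEvents, spec: BinSpec, fs: float,
                           n_samples: int, seed: int) -> FeatureMatrix:
    """Binned matrix with the onset->bin allocation uniformly permuted.

    Onset times and per-bin counts are preserved; only the pairing of
    onsets with bin labels is shuffled.
    """
    onsets = assign_bins(onsets, spec)
    mask = onsets.eligible
    labels = onsets.bin[mask]
    rng = np.random.default_rng(seed)
    permuted = rng.permutation(labels)
    return _matrix_from_labels(onsets.times[mask], permuted,
                               spec.n_bins, spec, fs, n_samples)


def permute_matrix_labels(feats: FeatureMatrix, rng: np.random.Generator) -> FeatureMatrix:
    """Shuffle the column allocation of a binary binned matrix in place
    semantics-free: rows keep their single 1, columns are permuted among
    rows."""
    rows, cols = np.nonzero(feats.values)
    permuted = rng.permutation(cols)
    values = np.zeros_like(feats.values)
    values[rows, permuted] = 1.0
    return FeatureMatrix(values=values, fs=feats.fs,
                         feature_labels=list(feats.feature_labels))


def weighted_onset_vector(onsets: OnsetEvents, fs: float,
                          n_samples: int) -> FeatureMatrix:
    """Single feature whose onset samples carry the min-max-normalized IOI."""
    mask = onsets.eligible
    iois = onsets.ioi[mask]
    vec = np.zeros(n_samples)
    if len(iois):
        lo, hi = iois.min(), iois.max()
        if hi == lo:
            warnings.warn("all IOIs equal; weighted vector is all-zero",
                          stacklevel=2)
            weights = np.zeros_like(iois)
        else:
            weights = (iois - lo) / (hi - lo)
        idx = _onset_sample_indices(onsets.times[mask], fs, n_samples)
        keep = idx < n_samples
        vec[idx[keep]] = weights[keep]
    return FeatureMatrix(values=vec[:, None], fs=fs, feature_labels=["weighted"])
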