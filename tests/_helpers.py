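"""Shared experiment routines for the heavier simulation-based tests."""

from __future__ import annotations

import numpy as np

from ioitrf import CVConfig, RecoveryParams, SimConfig
from ioitrf.features import binned_onset_matrix, make_uniform_bins
from ioitrf.novelty import encode_onset_vector
from ioitrf.peaks import extract_peaks, permutation_test
from ioitrf.simulate import simulate_subject
from ioitrf.trf import _GramCV, crossval_fit, lag_matrix, segment_bounds


def run_binned_subject(seed: int, duration: float = 900.0, n_bins: int = 5,
                       n_perm: int = 100, tau_rec: float = 1.5,
                       floor: float = 0.3, ioi_coupling: bool = True,
                       lam: float | None = None, with_cv: bool = True):
    """Simulate one subject, fit the n-bin model, extract peaks, permute.

    Returns a dict with peak amplitude vectors and permutation p-values.
    """
    cfg = SimConfig(duration=duration, seed=seed)
    rec = RecoveryParams(tau_rec=tau_rec, floor=floor)
    onsets, eeg = simulate_subject(cfg, rec, ioi_coupling=ioi_coupling)
    spec = make_uniform_bins(onsets.ioi[onsets.eligible], n_bins)
    feats = binned_onset_matrix(onsets, spec, eeg.fs, eeg.n_times)
    if with_cv:
        model, perf = crossval_fit(feats, eeg, CVConfig())
        lam_used = model.lam
        r_mean = float(perf["r_mean"].mean())
    else:
        lam_used = 1.0 if lam is None else lam
        model = None
        r_mean = np.nan
    perm = permutation_test(feats, eeg, n_perm=n_perm, seed=seed + 7,
                            lam=lam_used)
    if model is not None:
        table = extract_peaks(model)
    else:
        # cheap path: reuse the cached fit from the permutation's lambda
        from ioitrf.trf import OnsetDesignCache
        from ioitrf.peaks import _binary_matrix_to_events
        idx, labels = _binary_matrix_to_events(feats)
        cache = OnsetDesignCache(idx, eeg, CVConfig().lag_window)
        m = cache.fit(labels, n_bins, lam_used,
                      feature_labels=list(feats.feature_labels))
        table = extract_peaks(m)
    return {
        "n1": -table["n1_amplitude"].to_numpy(),   # magnitudes
        "p2": table["p2_amplitude"].to_numpy(),
        "p_n1": perm["N1"].p_value,
        "p_p2": perm["P2"].p_value,
        "r_mean": r_mean,
        "onsets": onsets,
        "eeg": eeg,
        "feats": feats,
        "lam": lam_used,
    }


def rotation_score(feats, eeg, lam: float, n_segments: int = 6) -> float:
    """Mean held-out r over segment rotations at a fixed ridge parameter."""
    cfg = CVConfig(n_segments=n_segments)
    design = lag_matrix(feats, cfg.lag_window, feats.fs)
    bounds = segment_bounds(design.values.shape[0], n_segments)
    gram = _GramCV.build(design.values, eeg.data.T, bounds)
    rs = []
    for test_seg in range(n_segments):
        train = [s for s in range(n_segments) if s != test_seg]
        w = gram.fit(train, lam)
        rs.append(gram.score(w, test_seg).mean())
    return float(np.mean(rs))


def single_onset_feats(onsets, eeg):
    return encode_onset_vector(onsets, eeg.fs, eeg.n_times)
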