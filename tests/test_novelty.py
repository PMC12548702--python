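import numpy as np
import pytest
from scipy import signal as sg

from ioitrf import AudioSignal, NoveltyConfig, NoveltyFunction, PeakPickConfig
from ioitrf.novelty import (
    combine_novelty,
    complex_novelty,
    encode_onset_vector,
    energy_novelty,
    pick_onsets,
    spectral_novelty,
)
from ioitrf._types import OnsetEvents


def _sine(freq, duration, fs, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# energy novelty
# ---------------------------------------------------------------------------

def test_energy_zero_signal_gives_zeros():
    audio = AudioSignal(samples=np.zeros(5 * 1000), fs=1000.0)
    nov = energy_novelty(audio)
    assert nov.kind == "energy"
    assert np.allclose(nov.values, 0.0)


def test_energy_stationary_sine_near_zero_after_transient():
    audio = AudioSignal(samples=_sine(50, 4.0, 1000.0), fs=1000.0)
    nov = energy_novelty(audio)
    # skip the initial window transient
    assert np.all(nov.values[30:] < 1e-5)


def _energy_novelty_oracle(x, fs, cfg):
    """Sample-by-sample direct-loop version of the energy novelty chain."""
    win_len = cfg.resolved_energy_win(fs)
    w = sg.windows.hann(win_len)
    w = w / w.sum()
    half = (len(w) - 1) // 2
    x2 = x * x
    energy = np.zeros(len(x))
    for i in range(len(x)):
        acc = 0.0
        for k in range(len(w)):
            j = i + half - k
            if 0 <= j < len(x):
                acc += w[k] * x2[j]
        energy[i] = acc
    n_out = int(round(len(x) / fs * cfg.target_fs))
    t_out = np.arange(n_out) / cfg.target_fs
    e_ds = np.interp(t_out, np.arange(len(x)) / fs, energy)
    comp = np.log1p(cfg.gamma * e_ds)
    nov = np.diff(comp, prepend=comp[:1])
    return np.clip(nov, 0.0, None)


def test_energy_step_matches_direct_loop_oracle():
    fs = 1000.0
    rng = np.random.default_rng(3)
    x = _sine(80, 3.0, fs) * 0.02
    x[int(1.0 * fs):] += _sine(120, 2.0, fs)[: len(x) - int(1.0 * fs)]
    audio = AudioSignal(samples=x, fs=fs)
    cfg = NoveltyConfig()
    nov = energy_novelty(audio, cfg)
    oracle = _energy_novelty_oracle(x, fs, cfg)
    assert nov.values.shape == oracle.shape
    np.testing.assert_allclose(nov.values, oracle, atol=1e-8)
    # dominant peak within one energy window (100 ms) of the step at 1.0 s
    peak_t = np.argmax(nov.values) / cfg.target_fs
    assert abs(peak_t - 1.0) <= 0.1


def test_energy_rejects_empty_and_low_rate():
    with pytest.raises(ValueError):
        energy_novelty(AudioSignal(samples=np.zeros(0), fs=1000.0))
    with pytest.raises(ValueError):
        energy_novelty(AudioSignal(samples=np.zeros(100), fs=150.0),
                       NoveltyConfig(target_fs=100.0))


# ---------------------------------------------------------------------------
# spectral novelty
# ---------------------------------------------------------------------------

def test_spectral_zero_signal_gives_zeros():
    audio = AudioSignal(samples=np.zeros(4 * 8000), fs=8000.0)
    nov = spectral_novelty(audio)
    assert np.allclose(nov.values, 0.0)


def _naive_flux_peak_time(x, fs, gamma=10.0, win=512, hop=80):
    """Independent framing + FFT flux; returns the time of the peak frame."""
    n_frames = (len(x) - win) // hop
    prev = None
    flux = np.zeros(n_frames)
    w = sg.windows.hann(win)
    for k in range(n_frames):
        frame = x[k * hop:k * hop + win] * w
        mag = np.log1p(gamma * np.abs(np.fft.rfft(frame)))
        if prev is not None:
            d = mag - prev
            flux[k] = d[d > 0].sum()
        prev = mag
    return (np.argmax(flux) * hop + win / 2) / fs


def test_spectral_detects_frequency_switch_where_energy_is_silent():
    fs = 8000.0
    x = np.concatenate([_sine(440, 2.0, fs), _sine(880, 2.0, fs)])
    audio = AudioSignal(samples=x, fs=fs)
    nov_s = spectral_novelty(audio)
    nov_e = energy_novelty(audio)
    t_peak = np.argmax(nov_s.values) / nov_s.fs
    assert abs(t_peak - 2.0) <= 0.1
    # independent-framing oracle agrees on the switch location
    t_oracle = _naive_flux_peak_time(x, fs)
    assert abs(t_peak - t_oracle) <= 0.1
    # equal-RMS switch: energy novelty near the switch stays at noise level
    window = slice(int(1.9 * nov_e.fs), int(2.1 * nov_e.fs))
    assert nov_e.values[window].max() <= 1e-3 * np.log1p(10.0)


def test_spectral_flat_novelty_zeroed_by_local_average():
    # constant pre-subtraction novelty: x - mean(x) <= 0, clipped to zero
    from ioitrf.novelty import _local_average_subtract
    flat = np.full(500, 0.7)
    out = _local_average_subtract(flat, 100.0, 1.0)
    np.testing.assert_allclose(out, 0.0)


# ---------------------------------------------------------------------------
# complex novelty
# ---------------------------------------------------------------------------

def test_complex_zero_signal_gives_zeros():
    audio = AudioSignal(samples=np.zeros(4 * 8000), fs=8000.0)
    nov = complex_novelty(audio)
    assert np.allclose(nov.values, 0.0)


def test_complex_stationary_sine_near_zero():
    audio = AudioSignal(samples=_sine(440, 4.0, 8000.0), fs=8000.0)
    nov = complex_novelty(audio)
    jump = _phase_jump_signal()
    nov_jump = complex_novelty(jump)
    # stationary prediction error is tiny relative to a phase-jump signal
    assert nov.values[100:-100].max() < 0.01 * nov_jump.values.max()


def _phase_jump_signal(fs=8000.0):
    t1 = np.arange(int(1.0 * fs)) / fs
    t2 = np.arange(int(1.0 * fs)) / fs + 1.0
    x = np.concatenate([np.sin(2 * np.pi * 440 * t1),
                        np.sin(2 * np.pi * 440 * t2 + np.pi)])
    return AudioSignal(samples=x, fs=fs)


def _naive_prediction_error_peak(x, fs, win=512, hop=80):
    """Direct-loop phase-prediction oracle with independent framing."""
    n_frames = (len(x) - win) // hop
    w = sg.windows.hann(win)
    frames = [np.fft.rfft(x[k * hop:k * hop + win] * w) for k in range(n_frames)]
    err = np.zeros(n_frames)
    for k in range(2, n_frames):
        prev, cur = frames[k - 1], frames[k]
        phi_prev = np.angle(prev)
        dphi = np.angle(prev) - np.angle(frames[k - 2])
        pred = np.abs(prev) * np.exp(1j * (phi_prev + dphi))
        err[k] = np.abs(cur - pred).sum()
    return (np.argmax(err) * hop + win / 2) / fs


def test_complex_phase_jump_peak_matches_oracle():
    audio = _phase_jump_signal()
    nov = complex_novelty(audio)
    t_peak = np.argmax(nov.values) / nov.fs
    assert abs(t_peak - 1.0) <= 0.1
    t_oracle = _naive_prediction_error_peak(audio.samples, audio.fs)
    assert abs(t_peak - t_oracle) <= 0.1


# ---------------------------------------------------------------------------
# combination and peak picking
# ---------------------------------------------------------------------------

def _nf(values, kind="energy"):
    return NoveltyFunction(values=np.asarray(values, float), fs=100.0, kind=kind)


def test_combine_identical_equals_scaled_input():
    vals = np.array([0.0, 1.0, 4.0, 2.0, 0.0])
    combined = combine_novelty([_nf(vals), _nf(vals), _nf(vals)])
    np.testing.assert_allclose(combined.values, vals / 4.0)


def test_combine_zero_plus_scaled_halves():
    vals = np.array([0.0, 0.5, 1.0, 0.25])
    combined = combine_novelty([_nf(np.zeros(4)), _nf(vals)])
    np.testing.assert_allclose(combined.values, vals / 2.0)


def test_combine_disjoint_unit_peaks_are_third_height():
    a = np.zeros(9); a[1] = 1.0
    b = np.zeros(9); b[4] = 1.0
    c = np.zeros(9); c[7] = 1.0
    combined = combine_novelty([_nf(a), _nf(b), _nf(c)])
    expected = (a + b + c) / 3.0
    np.testing.assert_allclose(combined.values, expected)
    assert combined.values.max() == pytest.approx(1 / 3)


def test_combine_length_mismatch_raises():
    with pytest.raises(ValueError):
        combine_novelty([_nf(np.zeros(5)), _nf(np.zeros(6))])


def test_combine_constant_input_maps_to_zero():
    combined = combine_novelty([_nf(np.full(8, 3.0)), _nf(np.arange(8.0))])
    np.testing.assert_allclose(combined.values, np.arange(8.0) / 7.0 / 2.0)


def test_pick_onsets_constant_novelty_yields_none():
    nov = NoveltyFunction(values=np.full(4000, 0.3), fs=100.0, kind="combined")
    assert len(pick_onsets(nov)) == 0


def test_pick_onsets_single_triangle_at_apex():
    vals = np.full(4000, 0.1)
    apex = 2000
    tri = np.concatenate([np.linspace(0, 0.9, 8), np.linspace(0.9, 0, 8)[1:]])
    vals[apex - 7:apex + 8] += tri
    nov = NoveltyFunction(values=vals, fs=100.0, kind="combined")
    onsets = pick_onsets(nov)
    assert len(onsets) == 1
    assert onsets.times[0] == pytest.approx(apex / 100.0, abs=0.01)


def test_pick_onsets_two_separated_peaks():
    vals = np.full(4000, 0.1)
    tri = np.concatenate([np.linspace(0, 0.9, 8), np.linspace(0.9, 0, 8)[1:]])
    for apex in (1000, 3000):
        vals[apex - 7:apex + 8] += tri
    nov = NoveltyFunction(values=vals, fs=100.0, kind="combined")
    onsets = pick_onsets(nov)
    assert len(onsets) == 2
    assert np.all(np.diff(onsets.times) > 0)
    np.testing.assert_allclose(onsets.times, [10.0, 30.0], atol=0.01)


def test_pick_onsets_empty_raises():
    with pytest.raises(ValueError):
        pick_onsets(NoveltyFunction(values=np.zeros(0), fs=100.0,
                                    kind="combined"))


def test_amplitude_scaling_preserves_peak_locations():
    fs = 8000.0
    rng = np.random.default_rng(0)
    x = rng.standard_normal(int(2 * fs)) * 0.01
    x[int(0.9 * fs):int(1.0 * fs)] += _sine(700, 0.1, fs)
    for fn in (spectral_novelty, complex_novelty):
        n1 = fn(AudioSignal(samples=x, fs=fs))
        n2 = fn(AudioSignal(samples=5.0 * x, fs=fs))
        assert np.argmax(n1.values) == np.argmax(n2.values)


# ---------------------------------------------------------------------------
# onset vector encoding
# ---------------------------------------------------------------------------

def test_encode_onset_vector_examples():
    onsets = OnsetEvents(times=np.array([1.0, 2.5]))
    fm = encode_onset_vector(onsets, 100.0, 400)
    assert fm.values[100, 0] == 1.0 and fm.values[250, 0] == 1.0
    assert fm.values.sum() == 2.0

    empty = encode_onset_vector(OnsetEvents(times=np.array([])), 100.0, 50)
    assert empty.values.sum() == 0.0

    frac = encode_onset_vector(OnsetEvents(times=np.array([1.234])), 100.0, 200)
    assert frac.values[123, 0] == 1.0  # floor convention


def test_encode_negative_times_raise():
    with pytest.raises(ValueError):
        encode_onset_vector(OnsetEvents(times=np.array([-0.5, 1.0])), 100.0, 200)


def test_encode_sum_equals_detected_onsets():
    vals = np.full(4000, 0.1)
    tri = np.concatenate([np.linspace(0, 0.9, 8), np.linspace(0.9, 0, 8)[1:]])
    for apex in (700, 1500, 2600, 3300):
        vals[apex - 7:apex + 8] += tri
    nov = NoveltyFunction(values=vals, fs=100.0, kind="combined")
    onsets = pick_onsets(nov)
    fm = encode_onset_vector(onsets, 100.0, 4000)
    assert fm.values.sum() == len(onsets)


def test_novelty_outputs_length_consistent(small_subject):
    from ioitrf.simulate import simulate_audio
    from ioitrf import SimConfig
    onsets, _ = small_subject
    cfg = SimConfig(duration=20.0, seed=2)
    from ioitrf.simulate import simulate_onset_train
    ons = simulate_onset_train(cfg)
    audio = simulate_audio(ons, cfg)
    funcs = [energy_novelty(audio), spectral_novelty(audio),
             complex_novelty(audio)]
    lengths = {len(f.values) for f in funcs}
    assert len(lengths) == 1
    assert all(f.values.min() >= 0 for f in funcs)
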