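# ioitrf

Inter-onset-interval (IOI) binned temporal response functions (TRFs) for
continuous-soundscape EEG.

The package implements an end-to-end analysis showing that auditory N1/P2
responses to sound events in a continuous soundscape attenuate when the
preceding inter-onset interval is short:

1. **Onset detection** — energy, spectral-flux, and complex-domain novelty
   functions are computed from the raw audio, normalized, averaged, and
   peak-picked against a local adaptive (median) threshold.
2. **IOI features** — intervals between successive onsets (10 s exclusion),
   uniform-count quantile binning (2–8 bins), binary binned onset matrices,
   random-allocation nulls, and distance-weighted onset vectors.
3. **TRF estimation** — lagged ridge regression ([−100, 500] ms window)
   with 6-segment nested cross-validation over a λ grid of 10⁻⁴…10⁴.
4. **Peak statistics** — per-bin N1/P2 extraction from channel-averaged
   weights, logistic/exponential/quadratic amplitude-vs-IOI curve fits, and
   a gradient-score permutation test (100 permutations, BH-FDR corrected).
5. **Model comparison** — Wilcoxon signed-rank tests with effect sizes,
   onset-count-matched single-onset subsampling, merged 12-segment
   training, and generic leave-one-participant-out models.
6. **Covariates** — per-event intensity (50 ms RMS) and envelope sharpness
   (50 ms envelope gradient), related to IOI with a linear mixed-effects
   model (participant random intercepts).
7. **Synthetic data** — tone-burst audio and multichannel EEG generated by
   convolving onset trains with a biphasic N1/P2 kernel whose amplitude
   saturates with the preceding IOI, so every stage has ground truth.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including the
20-subject parameter-recovery run and the 200-simulation type-I check
(a few minutes each).

## CLI

```bash
ioitrf simulate --duration 300 --seed 7 --out sim/      # synthetic subject
ioitrf onsets sim/audio.wav --out onsets.tsv            # detect onsets
ioitrf features onsets.tsv --bins 5 --duration 300 --out feats.f32
ioitrf fit feats.f32 sim/eeg.f32 --out model.f32        # cross-validated TRF
ioitrf peaks model.f32 --out peaks.tsv                  # N1/P2 per bin
ioitrf permtest feats.f32 sim/eeg.f32 --n-perm 100 --seed 7
ioitrf covariates sim/audio.wav onsets.tsv --out cov.tsv
ioitrf run --out out/ --seed 7 --duration 300 --bins 3 --bins 5
```

EEG and feature matrices are stored as raw float32 plus a JSON sidecar
(`<file>.json` with rate, labels and shape); audio as WAV; tables as TSV.

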