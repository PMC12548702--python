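"""File formats: WAV audio, float32 raw + JSON sidecar for EEG / feature
matrices / TRF weights, TSV onset and peak tables, JSON results.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from ._types import AudioSignal, EEGRecording, FeatureMatrix, OnsetEvents, TRFModel

__all__ = [
    "read_wav", "write_wav",
    "read_eeg", "write_eeg",
    "read_onsets_tsv", "write_onsets_tsv",
    "read_feature_matrix", "write_feature_matrix",
    "read_trf_model", "write_trf_model",
    "write_json", "read_json",
]

_PCM_SCALE = {np.dtype("int16"): 2 ** 15, np.dtype("int32"): 2 ** 31,
              np.dtype("uint8"): 2 ** 7}


def read_wav(path) -> AudioSignal:
    """Read PCM8/16/24/32 or float WAV as a mono float signal in [-1, 1]."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype in _PCM_SCALE:
        offset = 128 if data.dtype == np.dtype("uint8") else 0
        data = (data.astype(float) - offset) / _PCM_SCALE[data.dtype]
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioSignal(samples=data, fs=float(fs))


def write_wav(path, audio: AudioSignal) -> None:
    wavfile.write(path, int(round(audio.fs)), audio.samples.astype(np.float32))


def _write_raw(path: Path, array: np.ndarray, sidecar: dict) -> None:
    path = Path(path)
    array.astype(np.float32).tofile(path)
    sidecar = dict(sidecar, shape=list(array.shape), dtype="float32")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def _read_raw(path: Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr = np.fromfile(path, dtype=np.float32).reshape(meta["shape"])
    return arr, meta


def write_eeg(path, eeg: EEGRecording) -> None:
    _write_raw(Path(path), eeg.data,
               {"fs": eeg.fs, "channel_labels": eeg.channel_labels,
                "layout": "channel x time"})


def read_eeg(path) -> EEGRecording:
    arr, meta = _read_raw(Path(path))
    return EEGRecording(data=arr.astype(float), fs=meta["fs"],
                        channel_labels=list(meta["channel_labels"]))


ONSET_COLUMNS = ["time_s", "ioi_s", "intensity", "sharpness", "bin"]


def write_onsets_tsv(path, onsets: OnsetEvents) -> None:
    df = pd.DataFrame({
        "time_s": onsets.times,
        "ioi_s": onsets.ioi,
        "intensity": onsets.intensity,
        "sharpness": onsets.sharpness,
        "bin": onsets.bin,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_onsets_tsv(path) -> OnsetEvents:
    df = pd.read_csv(path, sep="\t")
    missing = set(ONSET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"onset table missing columns: {sorted(missing)}")
    ioi = df["ioi_s"].to_numpy(dtype=float)
    eligible = np.isfinite(ioi) & (ioi <= 10.0)
    return OnsetEvents(times=df["time_s"].to_numpy(dtype=float),
                       ioi=ioi,
                       intensity=df["intensity"].to_numpy(dtype=float),
                       sharpness=df["sharpness"].to_numpy(dtype=float),
                       bin=df["bin"].to_numpy(dtype=int),
                       eligible=eligible)


def write_feature_matrix(path, feats: FeatureMatrix) -> None:
    _write_raw(Path(path), feats.values,
               {"fs": feats.fs, "feature_labels": feats.feature_labels,
                "layout": "time x feature"})


def read_feature_matrix(path) -> FeatureMatrix:
    arr, meta = _read_raw(Path(path))
    return FeatureMatrix(values=arr.astype(float), fs=meta["fs"],
                         feature_labels=list(meta["feature_labels"]))


def write_trf_model(path, model: TRFModel) -> None:
    _write_raw(Path(path), model.weights,
               {"lambda": model.lam, "lag_window": list(model.lag_window),
                "fs": model.fs, "feature_labels": model.feature_labels,
                "channel_labels": model.channel_labels,
                "layout": "feature x lag x channel"})


def read_trf_model(path) -> TRFModel:
    arr, meta = _read_raw(Path(path))
    return TRFModel(weights=arr.astype(float), lam=meta["lambda"],
                    lag_window=tuple(meta["lag_window"]), fs=meta["fs"],
                    feature_labels=list(meta["feature_labels"]),
                    channel_labels=list(meta["channel_labels"]))


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
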