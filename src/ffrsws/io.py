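"""File I/O for the pipeline's standard formats.

Audio goes through WAV (scipy); continuous EEG is stored as delimited text
(time_s, amplitude_uV) or read from EDF via mne when available; event tables
and analysis results are delimited text; run metadata is JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile


def write_wav(path, waveform: np.ndarray, fs: float) -> None:
    """Write mono float32 WAV."""
    wavfile.write(str(path), int(fs), np.asarray(waveform, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read mono WAV as float64 in [-1, 1] (integer formats rescaled)."""
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        raise ValueError("expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    return data, float(fs)


def read_eeg(path) -> tuple[np.ndarray, float]:
    """Read single-channel continuous EEG from text TSV or EDF.

    Text files need ``time_s`` and ``amplitude_uV`` columns.  EDF reading
    uses mne (first channel, converted from volts to µV).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading EDF requires mne") from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data()[0] * 1e6
        return data, float(raw.info["sfreq"])
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 0.0
    return df["amplitude_uV"].to_numpy(dtype=float), float(round(fs))


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_sample", "token", "polarity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    return df
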