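"""EEG preprocessing: filter, epoch, clean, average.

The pipeline order is fixed: bandpass the continuous recording, epoch around
event onsets (correcting for the insert-earphone transducer delay), then per
epoch linearly detrend, flag artifacts beyond ±50 µV, and baseline-correct.
Accepted sweeps are averaged per token into four views: polarity A, polarity
B, added (A+B)/2 (accentuates rectified/envelope-like components), and
subtracted (A−B)/2 (accentuates spectral fine structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = ["SweepEpochs", "AveragedFFR", "bandpass", "epoch", "clean", "average"]


@dataclass
class SweepEpochs:
    """Per-sweep epoched EEG segments with accept/reject flags."""

    data: np.ndarray  # sweeps x samples, µV
    fs: float
    window_ms: tuple[float, float]
    labels: np.ndarray  # token per sweep
    polarity: np.ndarray  # 'A' / 'B' per sweep
    accepted: np.ndarray  # bool per sweep
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.size == 0:
            self.data = self.data.reshape(0, self.n_window_samples)
        self.labels = np.asarray(self.labels)
        self.polarity = np.asarray(self.polarity)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        n = self.data.shape[0]
        for name in ("labels", "polarity", "accepted"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.phase is not None:
            self.phase = np.asarray(self.phase)
            if len(self.phase) != n:
                raise ValueError("phase length mismatch")

    @property
    def n_window_samples(self) -> int:
        lo, hi = self.window_ms
        return int(round((hi - lo) / 1000 * self.fs))

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        lo, _ = self.window_ms
        return lo + np.arange(self.data.shape[1]) / self.fs * 1000.0

    def select(self, **criteria) -> "SweepEpochs":
        """Subset by equality on labels/polarity/phase columns."""
        mask = np.ones(self.n_sweeps, dtype=bool)
        for key, val in criteria.items():
            mask &= np.asarray(getattr(self, key if key != "token" else "labels")) == val
        return SweepEpochs(
            data=self.data[mask],
            fs=self.fs,
            window_ms=self.window_ms,
            labels=self.labels[mask],
            polarity=self.polarity[mask],
            accepted=self.accepted[mask],
            phase=None if self.phase is None else self.phase[mask],
        )


@dataclass
class AveragedFFR:
    """Grand averages for one token in the four standard views."""

    token: str
    a_mean: np.ndarray
    b_mean: np.ndarray
    added: np.ndarray
    subtracted: np.ndarray
    n_accepted: dict
    fs: float
    window_ms: tuple[float, float] = (-50.0, 550.0)
    participant: str | int | None = None
    phase: str | None = None
    group: str | None = None

    @classmethod
    def from_polarity_means(
        cls, token: str, a_mean: np.ndarray, b_mean: np.ndarray, n_accepted: dict, fs: float, **meta
    ) -> "AveragedFFR":
        a_mean = np.asarray(a_mean, dtype=float)
        b_mean = np.asarray(b_mean, dtype=float)
        return cls(
            token=token,
            a_mean=a_mean,
            b_mean=b_mean,
            added=(a_mean + b_mean) / 2.0,
            subtracted=(a_mean - b_mean) / 2.0,
            n_accepted=n_accepted,
            fs=fs,
            **meta,
        )

    @property
    def times_ms(self) -> np.ndarray:
        return self.window_ms[0] + np.arange(len(self.a_mean)) / self.fs * 1000.0

    def view(self, name: str) -> np.ndarray:
        views = {"A": self.a_mean, "B": self.b_mean, "added": self.added, "subtracted": self.subtracted}
        if name not in views:
            raise KeyError(f"unknown view {name!r}; choose from {sorted(views)}")
        return views[name]

    def slice_ms(self, view: str, start_ms: float, stop_ms: float) -> np.ndarray:
        """Half-open [start, stop) slice of a view, times re token onset."""
        i0 = int(round((start_ms - self.window_ms[0]) / 1000 * self.fs))
        i1 = int(round((stop_ms - self.window_ms[0]) / 1000 * self.fs))
        x = self.view(view)
        if i0 < 0 or i1 > len(x) or i1 <= i0:
            raise ValueError(f"window [{start_ms}, {stop_ms}) ms outside epoch {self.window_ms}")
        return x[i0:i1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "a": self.a_mean,
                "b": self.b_mean,
                "added": self.added,
                "subtracted": self.subtracted,
            }
        )

    @classmethod
    def from_tsv(cls, path, token: str, **meta) -> "AveragedFFR":
        """Load an average written by :meth:`to_frame` (n_accepted unknown)."""
        df = pd.read_csv(path, sep="\t")
        t = df["time_ms"].to_numpy()
        fs = float(round(1000.0 / np.median(np.diff(t))))
        return cls.from_polarity_means(
            token=token,
            a_mean=df["a"].to_numpy(),
            b_mean=df["b"].to_numpy(),
            n_accepted={},
            fs=fs,
            window_ms=(float(t[0]), float(t[0]) + len(t) / fs * 1000.0),
            **meta,
        )


def bandpass(continuous: np.ndarray, fs: float, lo: float = 100.0, hi: float = 2400.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward–backward).

    Zero-phase filtering is used so that latency measurements downstream are
    not biased by filter group delay.
    """
    if hi >= fs / 2:
        raise ValueError("upper edge must be below Nyquist")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(continuous, dtype=float))


def epoch(
    continuous: np.ndarray,
    events: pd.DataFrame,
    fs: float = 5000.0,
    window_ms: tuple[float, float] = (-50.0, 550.0),
    transducer_delay_ms: float = 1.0,
) -> SweepEpochs:
    """Cut sweeps around event onsets.

    Epoch time zero is aligned to the *acoustic* arrival (trigger onset plus
    the transducer delay).  Windows are half-open [start, end): at 5,000 Hz
    the default window gives exactly 3,000 samples.  Events whose window
    would run past either edge of the recording are dropped and counted.
    """
    continuous = np.asarray(continuous, dtype=float)
    n_samp = int(round((window_ms[1] - window_ms[0]) / 1000 * fs))
    d = int(round(transducer_delay_ms / 1000 * fs))
    w0 = int(round(window_ms[0] / 1000 * fs))

    data, labels, pols, phases = [], [], [], []
    n_dropped = 0
    has_phase = "phase" in events.columns
    for row in events.itertuples(index=False):
        start = int(row.onset_sample) + d + w0
        if start < 0 or start + n_samp > len(continuous):
            n_dropped += 1
            continue
        data.append(continuous[start : start + n_samp])
        labels.append(row.token)
        pols.append(row.polarity)
        if has_phase:
            phases.append(row.phase)
    if n_dropped:
        logger.warning("dropped %d events too close to the recording edge", n_dropped)
    data_arr = np.asarray(data, dtype=float).reshape(len(data), n_samp)
    return SweepEpochs(
        data=data_arr,
        fs=fs,
        window_ms=window_ms,
        labels=np.asarray(labels),
        polarity=np.asarray(pols),
        accepted=np.ones(len(data), dtype=bool),
        phase=np.asarray(phases) if has_phase else None,
    )


def clean(
    epochs: SweepEpochs,
    reject_uv: float = 50.0,
    baseline_ms: tuple[float, float] = (-50.0, 0.0),
) -> SweepEpochs:
    """Detrend, artifact-reject (flag only), and baseline-correct each epoch.

    Per epoch, in order: linear detrend over the whole epoch; flag as
    rejected if any sample exceeds ±``reject_uv``; subtract the mean of the
    baseline window.  Rejected sweeps keep their data but are excluded from
    every average.
    """
    if reject_uv <= 0:
        raise ValueError("reject_uv must be positive")
    lo, hi = epochs.window_ms
    if baseline_ms[0] < lo or baseline_ms[1] > hi:
        raise ValueError("baseline window outside the epoch window")
    if epochs.n_sweeps == 0:
        return epochs
    data = signal.detrend(epochs.data, axis=1, type="linear")
    accepted = np.max(np.abs(data), axis=1) <= reject_uv
    b0 = int(round((baseline_ms[0] - lo) / 1000 * epochs.fs))
    b1 = int(round((baseline_ms[1] - lo) / 1000 * epochs.fs))
    data = data - data[:, b0:b1].mean(axis=1, keepdims=True)
    if not accepted.any():
        logger.warning("all %d sweeps rejected at ±%g µV", epochs.n_sweeps, reject_uv)
    return SweepEpochs(
        data=data,
        fs=epochs.fs,
        window_ms=epochs.window_ms,
        labels=epochs.labels,
        polarity=epochs.polarity,
        accepted=epochs.accepted & accepted,
        phase=epochs.phase,
    )


def average(epochs: SweepEpochs, **meta) -> list[AveragedFFR]:
    """Grand-average accepted sweeps per token into the four views."""
    out = []
    for token in sorted(set(epochs.labels.tolist())):
        means = {}
        ns = {}
        for pol in ("A", "B"):
            mask = (epochs.labels == token) & (epochs.polarity == pol) & epochs.accepted
            n = int(mask.sum())
            if n == 0:
                raise ValueError(f"no accepted sweeps for token {token!r} polarity {pol}")
            means[pol] = epochs.data[mask].mean(axis=0)
            ns[pol] = n
        out.append(
            AveragedFFR.from_polarity_means(
                token=token,
                a_mean=means["A"],
                b_mean=means["B"],
                n_accepted=ns,
                fs=epochs.fs,
                window_ms=epochs.window_ms,
                **meta,
            )
        )
    return out
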