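"""Sine-wave speech construction.

Sine-wave speech (SWS) replaces the formants of a natural utterance with
time-varying pure tones that follow the formant center-frequency and
amplitude trajectories; all other speech content is discarded.  This module
estimates two-formant tracks from natural audio by linear predictive coding
(LPC) over a sliding window, or accepts parametric tracks directly, and
resynthesizes them as phase-continuous sinusoids with a cosine-squared
offset ramp and RMS normalization so that every token in a set plays at the
same level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.linalg import solve_toeplitz

logger = logging.getLogger(__name__)

__all__ = [
    "FormantTrackSet",
    "SWSStimulus",
    "lpc_formant_tracks",
    "tracks_to_sws",
    "apply_offset_ramp",
    "rms_normalize",
]


@dataclass
class FormantTrackSet:
    """Time-varying F1/F2 center-frequency and amplitude trajectories.

    All arrays are sample-aligned at rate ``fs``.  Frequencies are in Hz,
    amplitudes linear (arbitrary units).
    """

    times: np.ndarray
    f1_hz: np.ndarray
    f2_hz: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    fs: float
    token: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f1_hz = np.asarray(self.f1_hz, dtype=float)
        self.f2_hz = np.asarray(self.f2_hz, dtype=float)
        self.a1 = np.asarray(self.a1, dtype=float)
        self.a2 = np.asarray(self.a2, dtype=float)
        n = len(self.times)
        for name in ("f1_hz", "f2_hz", "a1", "a2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != times length {n}")
        if n == 0:
            raise ValueError("empty track set")
        for name in ("f1_hz", "f2_hz"):
            f = getattr(self, name)
            if np.any(f <= 0) or np.any(f >= self.fs / 2):
                raise ValueError(f"{name} must lie in (0, fs/2)")
        if np.any(self.a1 < 0) or np.any(self.a2 < 0):
            raise ValueError("amplitudes must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def resample(self, fs_new: float) -> "FormantTrackSet":
        """Linearly interpolate all trajectories to a new sample rate."""
        n_new = int(round(self.n_samples * fs_new / self.fs))
        t_new = np.arange(n_new) / fs_new
        interp = lambda y: np.interp(t_new, self.times, y)
        return FormantTrackSet(
            times=t_new,
            f1_hz=interp(self.f1_hz),
            f2_hz=interp(self.f2_hz),
            a1=interp(self.a1),
            a2=interp(self.a2),
            fs=fs_new,
            token=self.token,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "f1_hz": self.f1_hz,
                "a1": self.a1,
                "f2_hz": self.f2_hz,
                "a2": self.a2,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, token: str = "") -> "FormantTrackSet":
        df = pd.read_csv(path, sep="\t")
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("track file needs at least two samples")
        fs = float(round(1.0 / np.median(np.diff(t))))
        return cls(
            times=t,
            f1_hz=df["f1_hz"].to_numpy(),
            f2_hz=df["f2_hz"].to_numpy(),
            a1=df["a1"].to_numpy(),
            a2=df["a2"].to_numpy(),
            fs=fs,
            token=token,
        )


@dataclass
class SWSStimulus:
    """Synthesized SWS waveform together with its generating tracks."""

    waveform: np.ndarray
    fs: float
    tracks: FormantTrackSet
    token: str = ""
    ramp_ms: float = 0.0  # duration of the applied cosine-squared offset ramp

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if len(self.waveform) != self.tracks.n_samples:
            raise ValueError("waveform and tracks must have the same length")
        if not self.token:
            self.token = self.tracks.token

    @property
    def duration_ms(self) -> float:
        return len(self.waveform) / self.fs * 1000.0

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.waveform**2)))


def _lpc_coefficients(frame: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Autocorrelation-method LPC via the Toeplitz normal equations.

    Returns the prediction polynomial ``a`` (a[0] = 1) and the model gain
    (square root of the residual power).
    """
    r = np.correlate(frame, frame, mode="full")[len(frame) - 1 :][: order + 1]
    if r[0] <= 0:
        raise np.linalg.LinAlgError("silent frame")
    r = r / r[0]
    coefs = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    a = np.concatenate(([1.0], -coefs))
    err = r[0] - coefs @ r[1:]
    gain = float(np.sqrt(max(err, 1e-12) * np.dot(frame, frame) / len(frame)))
    return a, gain


def _frame_formants(
    a: np.ndarray, gain: float, fs: float, n_formants: int, floor_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Formant candidates from LPC polynomial roots.

    Roots with positive imaginary part are candidate resonances; candidates
    below ``floor_hz``, with bandwidth >= 400 Hz, or whose spectral-envelope
    amplitude falls under 10% of the strongest candidate (spurious fill-in
    poles between true resonances) are discarded, and the lowest
    ``n_formants`` remaining are kept.  Amplitudes are the envelope
    magnitude ``gain / |A(e^{jw})|`` at each retained frequency.
    """
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 1e-8]
    freqs = np.angle(roots) * fs / (2 * np.pi)
    bws = -fs / np.pi * np.log(np.clip(np.abs(roots), 1e-12, None))
    keep = (freqs > floor_hz) & (freqs < fs / 2 - 50) & (bws < 400)
    freqs = freqs[keep]
    if len(freqs) < n_formants:
        raise np.linalg.LinAlgError("too few formant candidates")
    env_all = gain / np.abs(np.polyval(a[::-1], np.exp(1j * 2 * np.pi * freqs / fs)))
    strong = env_all >= 0.1 * env_all.max()
    freqs, env_all = freqs[strong], env_all[strong]
    if len(freqs) < n_formants:
        raise np.linalg.LinAlgError("too few formant candidates")
    order_idx = np.argsort(freqs)[:n_formants]
    return freqs[order_idx], env_all[order_idx]


def lpc_formant_tracks(
    audio: np.ndarray,
    fs: float,
    order: int = 12,
    win_ms: float = 25.0,
    hop_ms: float = 10.0,
    n_formants: int = 2,
    floor_hz: float = 90.0,
    analysis_fs: float = 10_000.0,
    token: str = "",
) -> FormantTrackSet:
    """Estimate two formant tracks from mono audio by sliding-window LPC.

    The audio is downsampled to ``analysis_fs`` for formant estimation
    (resonances of interest sit well below 5 kHz), analyzed in Hamming
    windows with pre-emphasis, and the per-frame estimates are linearly
    interpolated back to the input sample rate.  An unstable or silent
    frame reuses the previous frame's estimate (logged).
    """
    audio = np.asarray(audio, dtype=float).squeeze()
    if audio.ndim != 1:
        raise ValueError("audio must be mono")
    if audio.size == 0:
        raise ValueError("empty audio")
    if order < 2 * n_formants + 2:
        raise ValueError(f"LPC order must be >= {2 * n_formants + 2}")

    from fractions import Fraction

    frac = Fraction(int(analysis_fs), int(fs)).limit_denominator(1000)
    x = signal.resample_poly(audio, frac.numerator, frac.denominator)
    fs_a = fs * frac.numerator / frac.denominator

    win = int(round(win_ms / 1000 * fs_a))
    hop = int(round(hop_ms / 1000 * fs_a))
    if win > len(x):
        raise ValueError("analysis window longer than audio")
    x = np.append(x[0], x[1:] - 0.97 * x[:-1])  # pre-emphasis
    window = np.hamming(win)

    centers, f_frames, a_frames = [], [], []
    prev: tuple[np.ndarray, np.ndarray] | None = None
    n_bad = 0
    for start in range(0, len(x) - win + 1, hop):
        frame = x[start : start + win] * window
        try:
            a, gain = _lpc_coefficients(frame, order)
            freqs, amps = _frame_formants(a, gain, fs_a, n_formants, floor_hz)
            prev = (freqs, amps)
        except np.linalg.LinAlgError:
            n_bad += 1
            if prev is None:
                continue
            freqs, amps = prev
        centers.append((start + win / 2) / fs_a)
        f_frames.append(freqs)
        a_frames.append(amps)
    if n_bad:
        logger.warning("%d unstable LPC frames reused the previous estimate", n_bad)
    if not centers:
        raise ValueError("no analyzable frames (audio silent?)")

    centers = np.asarray(centers)
    f_frames = np.asarray(f_frames)
    a_frames = np.asarray(a_frames)
    t_full = np.arange(len(audio)) / fs
    return FormantTrackSet(
        times=t_full,
        f1_hz=np.interp(t_full, centers, f_frames[:, 0]),
        f2_hz=np.interp(t_full, centers, f_frames[:, 1]),
        a1=np.interp(t_full, centers, a_frames[:, 0]),
        a2=np.interp(t_full, centers, a_frames[:, 1]),
        fs=fs,
        token=token,
    )


def phase_from_frequency(freq_hz: np.ndarray, fs: float) -> np.ndarray:
    """Phase in radians from an instantaneous-frequency series.

    phi[n] = 2*pi/fs * sum_{k<=n} f[k], offset so phi[0] = 0; cumulative
    summation keeps the phase continuous for arbitrary frequency tracks.
    """
    freq_hz = np.asarray(freq_hz, dtype=float)
    return 2 * np.pi * (np.cumsum(freq_hz) - freq_hz[0]) / fs


def tracks_to_sws(tracks: FormantTrackSet) -> SWSStimulus:
    """Resynthesize formant tracks as a sum of phase-continuous sinusoids.

    waveform(t) = a1(t) cos(phi1(t)) + a2(t) cos(phi2(t)) with each phase the
    cumulative integral of the corresponding frequency track.
    """
    for name in ("f1_hz", "f2_hz"):
        if np.any(getattr(tracks, name) >= tracks.fs / 2):
            raise ValueError(f"{name} reaches Nyquist; aliasing")
    w = tracks.a1 * np.cos(phase_from_frequency(tracks.f1_hz, tracks.fs)) + tracks.a2 * np.cos(
        phase_from_frequency(tracks.f2_hz, tracks.fs)
    )
    return SWSStimulus(waveform=w, fs=tracks.fs, tracks=tracks, token=tracks.token)


def apply_offset_ramp(stimulus: SWSStimulus, ramp_ms: float = 50.0) -> SWSStimulus:
    """Apply a cosine-squared fall (1 -> 0) to the last ``ramp_ms``.

    The first ramp sample keeps its full value, the final sample is exactly
    zero, and samples before the ramp are untouched.  The track amplitude
    envelopes are ramped identically so the stimulus object stays
    self-consistent.
    """
    n = int(round(ramp_ms / 1000 * stimulus.fs))
    if n >= len(stimulus.waveform):
        raise ValueError("ramp duration must be shorter than the stimulus")
    j = np.arange(n)
    ramp = np.cos(np.pi / 2 * j / (n - 1)) ** 2 if n > 1 else np.zeros(1)
    ramp[-1] = 0.0  # exact zero at the final sample
    gain = np.ones(len(stimulus.waveform))
    gain[-n:] = ramp
    tracks = replace(stimulus.tracks, a1=stimulus.tracks.a1 * gain, a2=stimulus.tracks.a2 * gain)
    return SWSStimulus(
        waveform=stimulus.waveform * gain,
        fs=stimulus.fs,
        tracks=tracks,
        token=stimulus.token,
        ramp_ms=ramp_ms,
    )


def rms_normalize(stimuli: list[SWSStimulus], target_rms: float) -> list[SWSStimulus]:
    """Scale every stimulus to a common RMS so presentation level is equal."""
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    out = []
    for s in stimuli:
        r = s.rms
        if r == 0:
            raise ValueError(f"cannot normalize all-zero waveform ({s.token!r})")
        g = target_rms / r
        tracks = replace(s.tracks, a1=s.tracks.a1 * g, a2=s.tracks.a2 * g)
        out.append(
            SWSStimulus(
                waveform=s.waveform * g, fs=s.fs, tracks=tracks, token=s.token, ramp_ms=s.ramp_ms
            )
        )
    return out
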