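"""Synthetic FFR sessions.

Generates SWS-like stimuli and synthetic continuous-EEG recordings so that
every downstream analysis stage (preprocessing, cross-correlation, Fourier
analyzer, decoding) can be exercised and validated without recorded data.

The generative model per sweep: the neural response is a delayed sum of
phase-locked components that follow the stimulus's own frequency tracks —
F1, F2, and the F2−F1 cochlear distortion product (a difference tone created
mechanically on the basilar membrane, to which the auditory system phase
locks as it would to an acoustic input).  Each component is half-wave
rectified per stimulus polarity (a hallmark of auditory-nerve transduction:
responses to opposite polarities are not exact negations, and their sum
carries energy at twice the stimulus frequency).  White noise and an
optional zero-lag stimulus-artifact term complete the sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .synth import FormantTrackSet, SWSStimulus, apply_offset_ramp, phase_from_frequency, tracks_to_sws

__all__ = [
    "TOKEN_PRESETS",
    "NeuralResponseModel",
    "SessionProtocol",
    "Session",
    "make_token_tracks",
    "make_token_stimulus",
    "default_stimuli",
    "synthesize_sweep",
    "simulate_events",
    "simulate_session",
]

#: Preset two-formant trajectories for the three CV tokens.  Each entry gives
#: (F1 start, F1 target, F2 start, F2 target) in Hz; trajectories follow a
#: raised-cosine transition over the first 120 ms then hold, mimicking the
#: consonant-vowel formant transition.  F1 spans ~300–675 Hz and carries most
#: of the between-token contrast; F2 stays within ~1,100–1,300 Hz.
TOKEN_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "baw": (325.0, 640.0, 1180.0, 1120.0),
    "boo": (310.0, 350.0, 1240.0, 1150.0),
    "bow": (315.0, 480.0, 1270.0, 1190.0),
}

_ALIASES = {"tok1": "baw", "tok2": "boo", "tok3": "bow"}

_TRANSITION_MS = 120.0
_A2_RELATIVE = 0.4  # F2 sinusoid amplitude relative to F1


def _resolve_token(label: str) -> str:
    key = _ALIASES.get(label, label)
    if key not in TOKEN_PRESETS:
        valid = sorted(TOKEN_PRESETS) + sorted(_ALIASES)
        raise ValueError(f"unknown token {label!r}; valid presets: {valid}")
    return key


def make_token_tracks(token_label: str, duration_ms: float = 335.0, fs: float = 44_100.0) -> FormantTrackSet:
    """Parametric formant tracks for one of the three preset tokens."""
    key = _resolve_token(token_label)
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if fs < 8_000:
        raise ValueError("fs must be >= 8000 Hz")
    f1a, f1b, f2a, f2b = TOKEN_PRESETS[key]
    n = int(round(duration_ms / 1000 * fs))
    t = np.arange(n) / fs
    trans = min(_TRANSITION_MS, duration_ms) / 1000.0
    s = np.where(t < trans, 0.5 * (1 - np.cos(np.pi * t / trans)), 1.0)
    return FormantTrackSet(
        times=t,
        f1_hz=f1a + (f1b - f1a) * s,
        f2_hz=f2a + (f2b - f2a) * s,
        a1=np.ones(n),
        a2=np.full(n, _A2_RELATIVE),
        fs=fs,
        token=key,
    )


def make_token_stimulus(
    token_label: str, duration_ms: float = 335.0, fs: float = 44_100.0, ramp_ms: float = 50.0
) -> SWSStimulus:
    """Preset tracks -> phase-continuous SWS waveform with the offset ramp."""
    stim = tracks_to_sws(make_token_tracks(token_label, duration_ms, fs))
    return apply_offset_ramp(stim, ramp_ms)


def default_stimuli(fs: float = 44_100.0) -> list[SWSStimulus]:
    """The three preset SWS tokens at equal RMS."""
    from .synth import rms_normalize

    stims = [make_token_stimulus(tok, fs=fs) for tok in sorted(TOKEN_PRESETS)]
    return rms_normalize(stims, 0.05)


@dataclass
class NeuralResponseModel:
    """Parameters of the synthetic sweep-level response.

    delay_ms
        Latency of the neural response re stimulus onset (brainstem FFRs
        arrive ~3–10 ms after the acoustic input; default 6).
    rectification_gain
        Fraction of half-wave rectification applied per polarity, in [0, 1].
        0 gives a linear (polarity-antisymmetric) response; 1 gives full
        rectification and hence frequency doubling in the added average.
    f1_gain, f2_gain, dp_gain
        Peak amplitudes (µV) of the F1-following, F2-following, and F2−F1
        distortion-product components.  Scalp FFR components are of order
        0.1 µV.
    noise_rms
        Additive white-noise level (µV RMS) before the analysis bandpass.
        In-band scalp background during passive FFR recording is of order
        1–3 µV RMS; the ±50 µV rejection threshold targets transient
        movement artifacts, which this stationary background does not reach.
    artifact_gain
        Amplitude of zero-lag stimulus-artifact contamination (µV per unit
        stimulus; default 0).
    """

    delay_ms: float = 6.0
    rectification_gain: float = 0.5
    f1_gain: float = 0.10
    f2_gain: float = 0.03
    dp_gain: float = 0.05
    noise_rms: float = 2.0
    artifact_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.delay_ms < 0:
            raise ValueError("delay_ms must be >= 0")
        if not 0.0 <= self.rectification_gain <= 1.0:
            raise ValueError("rectification_gain must be in [0, 1]")
        for name in ("f1_gain", "f2_gain", "dp_gain", "noise_rms", "artifact_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SessionProtocol:
    """Presentation protocol for one recording session."""

    tokens: tuple[str, ...] = ("baw", "boo", "bow")
    reps_per_polarity: int = 1000
    iti_ms: float = 600.0
    fs_eeg: float = 5000.0
    phases: tuple[str, ...] = ("pre", "post")
    training_gain: float = 1.0
    transducer_delay_ms: float = 1.0  # insert-earphone acoustic travel time

    def __post_init__(self) -> None:
        if self.reps_per_polarity < 1:
            raise ValueError("reps_per_polarity must be >= 1")
        if self.training_gain <= 0:
            raise ValueError("training_gain must be > 0")
        if self.fs_eeg <= 2 * 1300:
            raise ValueError("fs_eeg must exceed twice the highest track frequency")
        self.tokens = tuple(self.tokens)
        self.phases = tuple(self.phases)

    @property
    def sweeps_per_phase(self) -> int:
        return len(self.tokens) * 2 * self.reps_per_polarity


def _component_bank(stimulus: SWSStimulus, fs_eeg: float, rectification_gain: float) -> dict:
    """Phase-locked response components for one stimulus at the EEG rate.

    Returns, per polarity, the list of (name, waveform) components with unit
    peak amplitude before the per-component gains.  Rectification blends the
    full sinusoid with its positive half-wave by ``rectification_gain`` so
    that amplitude is continuous in the parameter.
    """
    tr = stimulus.tracks.resample(fs_eeg)
    e1 = tr.a1 / max(tr.a1.max(), 1e-300)
    e2 = tr.a2 / max(tr.a2.max(), 1e-300)
    comps = {
        "f1": e1 * np.cos(phase_from_frequency(tr.f1_hz, fs_eeg)),
        "f2": e2 * np.cos(phase_from_frequency(tr.f2_hz, fs_eeg)),
        "dp": np.sqrt(e1 * e2) * np.cos(phase_from_frequency(tr.f2_hz - tr.f1_hz, fs_eeg)),
    }
    g = rectification_gain
    bank = {}
    for pol, sign in (("A", 1.0), ("B", -1.0)):
        bank[pol] = {
            name: (1 - g) * sign * x + g * np.maximum(sign * x, 0.0) for name, x in comps.items()
        }
    return bank


def synthesize_sweep(
    stimulus: SWSStimulus,
    polarity: str,
    model: NeuralResponseModel,
    seed: int,
    fs_eeg: float = 5000.0,
    pad_ms: float = 50.0,
) -> np.ndarray:
    """One synthetic sweep (µV) at the EEG rate.

    The waveform covers the stimulus duration plus ``pad_ms`` of tail so the
    delayed response fits; identical seeds give bit-identical output.
    """
    if polarity not in ("A", "B"):
        raise ValueError("polarity must be 'A' or 'B'")
    bank = _component_bank(stimulus, fs_eeg, model.rectification_gain)[polarity]
    n_stim = len(bank["f1"])
    n = n_stim + int(round(pad_ms / 1000 * fs_eeg))
    out = np.zeros(n)
    shift = int(round(model.delay_ms / 1000 * fs_eeg))
    gains = {"f1": model.f1_gain, "f2": model.f2_gain, "dp": model.dp_gain}
    for name, comp in bank.items():
        seg = comp[: n - shift]
        out[shift : shift + len(seg)] += gains[name] * seg
    if model.artifact_gain > 0:
        from scipy.signal import resample_poly
        from fractions import Fraction

        frac = Fraction(int(fs_eeg), int(stimulus.fs)).limit_denominator(1000)
        stim_ds = resample_poly(stimulus.waveform, frac.numerator, frac.denominator)
        sign = 1.0 if polarity == "A" else -1.0
        seg = stim_ds[:n]
        out[: len(seg)] += model.artifact_gain * sign * seg
    if model.noise_rms > 0:
        rng = np.random.default_rng(seed)
        out += model.noise_rms * rng.standard_normal(n)
    return out


def simulate_events(protocol: SessionProtocol, seed: int) -> pd.DataFrame:
    """Event table for a full session: one row per sweep.

    Sweep order within each phase is a uniform random permutation of the
    token x polarity x repetition grid.  Onset samples assume a fixed
    stimulus slot of 335 ms plus the intertrial interval, with a 1 s lead-in
    per phase.
    """
    rng = np.random.default_rng(seed)
    slot = int(round((335.0 + protocol.iti_ms) / 1000 * protocol.fs_eeg))
    lead = int(round(1.0 * protocol.fs_eeg))
    rows = []
    onset = lead
    for phase in protocol.phases:
        grid = [
            (tok, pol)
            for tok in protocol.tokens
            for pol in ("A", "B")
            for _ in range(protocol.reps_per_polarity)
        ]
        order = rng.permutation(len(grid))
        for idx in order:
            tok, pol = grid[idx]
            rows.append((onset, tok, pol, phase))
            onset += slot
        onset += lead
    return pd.DataFrame(rows, columns=["onset_sample", "token", "polarity", "phase"])


@dataclass
class Session:
    """A simulated continuous recording plus its event table and ground truth."""

    eeg: np.ndarray
    fs: float
    events: pd.DataFrame
    protocol: SessionProtocol
    model: NeuralResponseModel
    seed: int

    def save(self, outdir) -> None:
        """Write EEG (delimited text), events, and a ground-truth sidecar."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        t = np.arange(len(self.eeg)) / self.fs
        pd.DataFrame({"time_s": t, "amplitude_uV": self.eeg}).to_csv(
            outdir / "eeg.tsv", sep="\t", index=False, float_format="%.6g"
        )
        self.events.to_csv(outdir / "events.tsv", sep="\t", index=False)
        truth = {
            "seed": self.seed,
            "fs_eeg": self.fs,
            "protocol": asdict(self.protocol),
            "model": asdict(self.model),
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))


def simulate_session(
    stimuli: list[SWSStimulus],
    protocol: SessionProtocol,
    model: NeuralResponseModel,
    seed: int,
) -> Session:
    """Render a full continuous EEG session with event markers.

    Event onsets mark the electrical trigger; the acoustic input arrives
    ``transducer_delay_ms`` later and the neural components a further
    ``delay_ms`` after that.  The "post" phase scales all neural component
    gains by ``training_gain``.  Noise is white over the whole recording.
    """
    if not stimuli:
        raise ValueError("at least one stimulus is required")
    by_token = {s.token: s for s in stimuli}
    missing = [t for t in protocol.tokens if t not in by_token]
    if missing:
        raise ValueError(f"no stimulus provided for tokens {missing}")

    rng = np.random.default_rng(seed)
    events = simulate_events(protocol, seed)
    slot = int(round((335.0 + protocol.iti_ms) / 1000 * protocol.fs_eeg))
    n_total = int(events["onset_sample"].max()) + slot + int(round(protocol.fs_eeg))
    eeg = np.zeros(n_total)

    banks = {
        tok: _component_bank(by_token[tok], protocol.fs_eeg, model.rectification_gain)
        for tok in protocol.tokens
    }
    gains = {"f1": model.f1_gain, "f2": model.f2_gain, "dp": model.dp_gain}
    t_shift = int(round(protocol.transducer_delay_ms / 1000 * protocol.fs_eeg))
    n_shift = int(round(model.delay_ms / 1000 * protocol.fs_eeg))

    # Precompute the summed neural response per (token, polarity, phase-gain).
    responses: dict[tuple[str, str, str], np.ndarray] = {}
    for phase in protocol.phases:
        pg = protocol.training_gain if phase == "post" else 1.0
        for tok in protocol.tokens:
            for pol in ("A", "B"):
                comp = banks[tok][pol]
                responses[(tok, pol, phase)] = pg * sum(
                    gains[name] * comp[name] for name in comp
                )

    if model.artifact_gain > 0:
        from scipy.signal import resample_poly
        from fractions import Fraction

        artifacts = {}
        for tok in protocol.tokens:
            s = by_token[tok]
            frac = Fraction(int(protocol.fs_eeg), int(s.fs)).limit_denominator(1000)
            artifacts[tok] = resample_poly(s.waveform, frac.numerator, frac.denominator)

    for onset, tok, pol, phase in events.itertuples(index=False):
        start = int(onset) + t_shift + n_shift
        resp = responses[(tok, pol, phase)]
        eeg[start : start + len(resp)] += resp
        if model.artifact_gain > 0:
            a = artifacts[tok] * (1.0 if pol == "A" else -1.0) * model.artifact_gain
            s0 = int(onset) + t_shift
            eeg[s0 : s0 + len(a)] += a
    if model.noise_rms > 0:
        eeg += model.noise_rms * rng.standard_normal(n_total)
    return Session(eeg=eeg, fs=protocol.fs_eeg, events=events, protocol=protocol, model=model, seed=seed)
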