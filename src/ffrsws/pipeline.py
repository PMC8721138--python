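"""End-to-end orchestration: simulate -> preprocess -> xcorr -> FA -> decode.

A single YAML config drives all stages; one master seed deterministically
derives a seed per stage/participant (stage-name hashing), so a rerun with
the same config reproduces every stochastic output bit-exactly and any
stage can be rerun independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decode import compare_phases, extract_features, null_distribution, ovo_cv, permutation_p
from .fourier import build_reference, fa_presence, instantaneous_frequency
from .preprocess import average, bandpass, clean, epoch
from .simulate import NeuralResponseModel, SessionProtocol, default_stimuli, simulate_session
from .synth import phase_from_frequency
from .xcorr import analyze as xcorr_analyze

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "default_config", "validate_config", "run_pipeline", "derive_seed"]


def derive_seed(master_seed: int, *names) -> int:
    """Stable per-stage seed below 2**31 from the master seed and a path."""
    tag = "/".join(str(n) for n in names)
    return (int(master_seed) * 2_654_435_761 + zlib.crc32(tag.encode())) % (2**31)


@dataclass
class RunConfig:
    """All pipeline parameters; analysis defaults follow the study protocol."""

    out_dir: str = "ffrsws_run"
    seed: int = 11
    simulate: bool = True
    eeg_path: str | None = None
    events_path: str | None = None
    # synthetic-session block
    n_participants: int = 9
    groups: dict = field(default_factory=lambda: {"test": 1.5, "control": 1.0})  # group -> training_gain
    protocol: dict = field(default_factory=dict)  # overrides for SessionProtocol
    model: dict = field(default_factory=dict)  # overrides for NeuralResponseModel
    # cohort block: per-participant random effects (0 disables)
    amplitude_sigma: float = 0.25  # lognormal sigma of a per-participant gain scale
    latency_jitter_ms: float = 0.3  # s.d. of per-participant neural-delay offset
    # analysis block
    filter_lo_hz: float = 100.0
    filter_hi_hz: float = 2400.0
    epoch_window_ms: tuple = (-50.0, 550.0)
    transducer_delay_ms: float = 1.0
    reject_uv: float = 50.0
    baseline_ms: tuple = (-50.0, 0.0)
    max_lag_ms: float = 20.0
    ref_override: dict = field(default_factory=dict)  # token -> 'envelope'
    fa_window_ms: tuple = (50.0, 335.0)
    fa_shift_ms: float = -6.0
    fa_noise_offset_hz: float = 5.0
    feature_window_ms: tuple = (0.0, 380.0)
    n_folds: int = 3
    n_iterations: int = 2500

    def make_protocol(self, training_gain: float = 1.0) -> SessionProtocol:
        kwargs = dict(self.protocol)
        kwargs.setdefault("transducer_delay_ms", self.transducer_delay_ms)
        return SessionProtocol(training_gain=training_gain, **kwargs)

    def make_model(self) -> NeuralResponseModel:
        return NeuralResponseModel(**self.model)

    def participant_model(self, base: NeuralResponseModel, rng: np.random.Generator) -> NeuralResponseModel:
        """Sample one participant's response model around the cohort base.

        Amplitudes scale by a shared lognormal factor (individual response
        strength) and the neural delay shifts by a Gaussian offset
        (individual conduction time).
        """
        from dataclasses import replace

        scale = float(np.exp(rng.normal(0.0, self.amplitude_sigma))) if self.amplitude_sigma > 0 else 1.0
        jitter = float(rng.normal(0.0, self.latency_jitter_ms)) if self.latency_jitter_ms > 0 else 0.0
        return replace(
            base,
            delay_ms=max(base.delay_ms + jitter, 0.0),
            f1_gain=base.f1_gain * scale,
            f2_gain=base.f2_gain * scale,
            dp_gain=base.dp_gain * scale,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ValueError(f"unparseable config: {exc}") from exc
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping of sections/keys")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("epoch_window_ms", "baseline_ms", "fa_window_ms", "feature_window_ms"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self) -> str:
        d = asdict(self)
        for name in ("epoch_window_ms", "baseline_ms", "fa_window_ms", "feature_window_ms"):
            d[name] = list(d[name])
        return yaml.safe_dump(d, sort_keys=False)


def default_config() -> RunConfig:
    return RunConfig()


def validate_config(config: RunConfig) -> tuple[bool, list[str]]:
    """Range and cross-field consistency checks; returns (ok, messages)."""
    msgs: list[str] = []
    try:
        proto = config.make_protocol()
        config.make_model()
    except (TypeError, ValueError) as exc:
        return False, [f"invalid protocol/model block: {exc}"]
    fs = proto.fs_eeg
    if config.reject_uv <= 0:
        msgs.append("reject_uv must be positive")
    if not config.filter_lo_hz < config.filter_hi_hz < fs / 2:
        msgs.append("filter edges must satisfy lo < hi < fs/2")
    w0, w1 = config.epoch_window_ms
    if w1 <= w0:
        msgs.append("epoch window must be nonempty")
    if not (w0 <= config.baseline_ms[0] < config.baseline_ms[1] <= w1):
        msgs.append("baseline window must lie inside the epoch window")
    if not (w0 <= config.fa_window_ms[0] < config.fa_window_ms[1] <= w1):
        msgs.append("FA window must lie inside the epoch window")
    if not (w0 <= config.feature_window_ms[0] < config.feature_window_ms[1] <= w1):
        msgs.append("feature window must lie inside the epoch window")
    grid_ms = 1000.0 / fs
    if abs(config.max_lag_ms / grid_ms - round(config.max_lag_ms / grid_ms)) > 1e-9:
        msgs.append(f"max_lag_ms must sit on the {grid_ms:g} ms lag grid")
    if config.n_iterations < 1 or config.n_folds < 2:
        msgs.append("n_iterations must be >= 1 and n_folds >= 2")
    if not config.simulate and (config.eeg_path is None or config.events_path is None):
        msgs.append("missing input: eeg_path and events_path are required when simulate is off")
    if config.simulate and config.n_participants < config.n_folds:
        msgs.append("n_participants must be >= n_folds")
    return (len(msgs) == 0), msgs


def _fa_references(stimulus, fs_eeg: float) -> dict:
    """F1 / F2 / F2−F1 reference tracks for one stimulus at the EEG rate.

    Each single-component sinusoid is rendered at the EEG rate, its
    instantaneous frequency recovered from the analytic phase and smoothed,
    and the reference phase re-integrated from the smoothed track.
    """
    tr = stimulus.tracks.resample(fs_eeg)
    refs = {}
    for label, freq in (("F1", tr.f1_hz), ("F2", tr.f2_hz), ("F2_minus_F1", tr.f2_hz - tr.f1_hz)):
        wave = np.cos(phase_from_frequency(freq, fs_eeg))
        inst = instantaneous_frequency(wave, fs_eeg)
        refs[label] = build_reference(inst, fs_eeg, label=label)
    return refs


def _preprocess_session(session, config: RunConfig):
    """Filter -> epoch -> clean -> per-phase averages for one session."""
    filtered = bandpass(session.eeg, session.fs, config.filter_lo_hz, config.filter_hi_hz)
    ep = epoch(
        filtered,
        session.events,
        fs=session.fs,
        window_ms=config.epoch_window_ms,
        transducer_delay_ms=config.transducer_delay_ms,
    )
    ep = clean(ep, reject_uv=config.reject_uv, baseline_ms=config.baseline_ms)
    return ep


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute all stages and return results plus a manifest.

    With ``simulate`` on, one session is generated per participant per group
    ("post"-phase neural gains scaled by the group's training gain); with it
    off, the provided recording is analyzed as a single participant.
    Stage failures abort with the stage name; partial outputs are kept with
    a FAILED marker.
    """
    ok, msgs = validate_config(config)
    if not ok:
        raise ValueError("invalid config: " + "; ".join(msgs))
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": yaml.safe_load(config.to_yaml()),
        "seeds": {},
        "counts": {},
    }
    stage = "setup"
    try:
        stimuli = default_stimuli()
        model = config.make_model()
        averages = []
        stage = "simulate/preprocess"
        if config.simulate:
            for group, gain in config.groups.items():
                proto = config.make_protocol(training_gain=float(gain))
                for p in range(config.n_participants):
                    s = derive_seed(config.seed, "session", group, p)
                    manifest["seeds"][f"session/{group}/{p}"] = s
                    p_rng = np.random.default_rng(derive_seed(config.seed, "participant", group, p))
                    p_model = config.participant_model(model, p_rng)
                    session = simulate_session(stimuli, proto, p_model, seed=s)
                    ep = _preprocess_session(session, config)
                    manifest["counts"][f"sweeps/{group}/{p}"] = {
                        "total": int(ep.n_sweeps),
                        "accepted": int(ep.accepted.sum()),
                        "rejected": int((~ep.accepted).sum()),
                    }
                    for phase in proto.phases:
                        sub = ep.select(phase=phase)
                        averages.extend(
                            average(sub, participant=f"{group}{p}", phase=phase, group=group)
                        )
        else:
            from .io import read_eeg, read_events

            eeg, fs = read_eeg(config.eeg_path)
            events = read_events(config.events_path)
            proto = config.make_protocol()

            class _S:  # minimal session shim for recorded data
                pass

            session = _S()
            session.eeg, session.fs, session.events = eeg, fs, events
            ep = _preprocess_session(session, config)
            manifest["counts"]["sweeps/recorded"] = {
                "total": int(ep.n_sweeps),
                "accepted": int(ep.accepted.sum()),
            }
            phases = sorted(set(ep.phase.tolist())) if ep.phase is not None else [None]
            for phase in phases:
                sub = ep.select(phase=phase) if phase is not None else ep
                averages.extend(average(sub, participant=0, phase=phase or "pre", group="test"))

        stage = "xcorr"
        xcorr_table = xcorr_analyze(
            averages, stimuli, ref_override=config.ref_override, max_lag_ms=config.max_lag_ms
        )
        manifest["counts"]["xcorr_neural"] = int((xcorr_table["origin"] == "neural").sum())
        manifest["counts"]["xcorr_rows"] = int(len(xcorr_table))

        stage = "fourier_analyzer"
        refs = {s.token: _fa_references(s, averages[0].fs) for s in stimuli}
        fa_rows = []
        for avg in averages:
            for label, ref in refs[avg.token].items():
                resp = avg.slice_ms("subtracted", 0.0, avg.window_ms[1])
                res = fa_presence(
                    resp, ref, window_ms=config.fa_window_ms, shift_ms=config.fa_shift_ms
                )
                fa_rows.append(
                    {
                        "token": avg.token,
                        "participant": avg.participant,
                        "phase": avg.phase,
                        "group": avg.group,
                        "track_label": label,
                        "amplitude_uV": res.amplitude,
                        "phase_rad": res.phase_rad,
                        "noise_floor_uV": res.noise_floor,
                        "present": res.present,
                    }
                )
        fa_table = pd.DataFrame(fa_rows)

        stage = "decode"
        decoding: dict = {}
        by_group: dict[str, dict[str, list]] = {}
        for avg in averages:
            by_group.setdefault(avg.group, {}).setdefault(avg.phase, []).append(avg)
        for group, phases in by_group.items():
            decoding[group] = {}
            dists = {}
            for phase, avgs in phases.items():
                feats = extract_features(avgs, window_ms=config.feature_window_ms)
                s_true = derive_seed(config.seed, "decode", group, phase)
                s_null = derive_seed(config.seed, "null", group, phase)
                manifest["seeds"][f"decode/{group}/{phase}"] = s_true
                res = ovo_cv(feats, n_folds=config.n_folds, n_iterations=config.n_iterations, seed=s_true)
                null = null_distribution(
                    feats, n_iterations=config.n_iterations, seed=s_null, n_folds=config.n_folds
                )
                res.null_accuracies = null
                res.p_vs_null = permutation_p(res.iteration_accuracies, null)
                decoding[group][phase] = res
                dists[phase] = res.iteration_accuracies
            if "pre" in dists and "post" in dists:
                decoding[group]["p_pre_vs_post"] = compare_phases(dists["pre"], dists["post"])

        stage = "write"
        results = {
            "averages": averages,
            "xcorr": xcorr_table,
            "fa": fa_table,
            "decoding": decoding,
            "manifest": manifest,
        }
        if write_outputs:
            xcorr_table.to_csv(out / "xcorr.tsv", sep="\t", index=False)
            fa_table.to_csv(out / "fa.tsv", sep="\t", index=False)
            dec_json = {}
            for group, phases in decoding.items():
                dec_json[group] = {}
                for phase, res in phases.items():
                    if phase == "p_pre_vs_post":
                        dec_json[group][phase] = res
                        continue
                    dec_json[group][phase] = {
                        "median_accuracy": res.median_accuracy,
                        "p_vs_null": res.p_vs_null,
                        "confusion": res.confusion.tolist(),
                        "classes": [str(c) for c in res.classes],
                        "iteration_accuracies": res.iteration_accuracies.tolist(),
                        "null_accuracies": res.null_accuracies.tolist(),
                    }
            (out / "decoding.json").write_text(json.dumps(dec_json, indent=2))
            digest = hashlib.md5()
            for avg in averages:
                digest.update(np.ascontiguousarray(avg.subtracted).tobytes())
            manifest["averages_md5"] = digest.hexdigest()
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return results
    except Exception:
        if write_outputs:
            (out / "FAILED").write_text(f"pipeline failed during stage: {stage}\n")
        logger.exception("pipeline failed during stage %s", stage)
        raise
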