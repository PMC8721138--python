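"""Sine-wave speech synthesis: tracks, resynthesis, ramps, normalization."""

import numpy as np
import pytest
from scipy import signal

from ffrsws.fourier import instantaneous_frequency
from ffrsws.simulate import TOKEN_PRESETS, make_token_tracks
from ffrsws.synth import (
    FormantTrackSet,
    SWSStimulus,
    apply_offset_ramp,
    lpc_formant_tracks,
    rms_normalize,
    tracks_to_sws,
)


def constant_tracks(f1=500.0, f2=1200.0, a1=1.0, a2=0.0, dur_s=1.0, fs=44100.0, token="t"):
    n = int(round(dur_s * fs))
    return FormantTrackSet(
        times=np.arange(n) / fs,
        f1_hz=np.full(n, f1),
        f2_hz=np.full(n, f2),
        a1=np.full(n, a1),
        a2=np.full(n, a2),
        fs=fs,
        token=token,
    )


class TestTokenPresets:
    @pytest.mark.parametrize("token", sorted(TOKEN_PRESETS) + ["tok1", "tok2", "tok3"])
    def test_tracks_stay_in_formant_ranges(self, token):
        tr = make_token_tracks(token, 335, 44100)
        assert np.all((tr.f1_hz >= 300) & (tr.f1_hz <= 675))
        assert np.all((tr.f2_hz >= 1100) & (tr.f2_hz <= 1300))
        assert tr.n_samples == round(0.335 * 44100)

    def test_presets_distinct_primarily_in_f1(self):
        tracks = {t: make_token_tracks(t) for t in TOKEN_PRESETS}
        names = sorted(tracks)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                df1 = np.max(np.abs(tracks[a].f1_hz - tracks[b].f1_hz))
                df2 = np.max(np.abs(tracks[a].f2_hz - tracks[b].f2_hz))
                assert df1 > 0
                assert df1 > df2  # contrast concentrated in F1

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            make_token_tracks("tok1", 0, 44100)

    def test_unknown_token_names_valid_presets(self):
        with pytest.raises(ValueError, match="baw"):
            make_token_tracks("nope")


class TestTracksToSWS:
    def test_constant_track_spectrum_peaks_at_track_frequency(self):
        stim = tracks_to_sws(constant_tracks(f1=500.0, dur_s=1.0))
        freqs = np.fft.rfftfreq(len(stim.waveform), 1 / stim.fs)
        mag = np.abs(np.fft.rfft(stim.waveform))
        assert abs(freqs[np.argmax(mag)] - 500.0) <= 1.0

    def test_zero_amplitudes_give_zero_waveform(self):
        stim = tracks_to_sws(constant_tracks(a1=0.0, a2=0.0))
        assert np.all(stim.waveform == 0)

    def test_chirp_instantaneous_frequency_recovers_track(self):
        fs = 44100.0
        tr = constant_tracks(dur_s=0.335)
        n = tr.n_samples
        tr.f1_hz = np.linspace(300.0, 675.0, n)
        stim = tracks_to_sws(tr)
        inst = instantaneous_frequency(stim.waveform, fs)
        sl = slice(int(0.05 * n), int(0.95 * n))  # away from edges
        assert np.max(np.abs(inst[sl] - tr.f1_hz[sl])) < 5.0

    def test_nyquist_violation_rejected(self):
        tr = constant_tracks(fs=9000.0, f2=4000.0)
        tr.f2_hz[10] = 4500.0  # mutate past construction-time validation
        with pytest.raises(ValueError, match="[Aa]lias|Nyquist"):
            tracks_to_sws(tr)

    def test_phase_continuity_bounds_first_difference(self):
        # no phase-reset clicks: |x[n+1]-x[n]| <= 2*pi*f_max/fs * total amplitude
        tr = make_token_tracks("baw")
        stim = tracks_to_sws(tr)
        bound = 2 * np.pi * 1300.0 / tr.fs * (tr.a1.max() + tr.a2.max()) * 1.05
        assert np.max(np.abs(np.diff(stim.waveform))) <= bound


class TestOffsetRamp:
    @pytest.fixture()
    def unit_stim(self):
        tr = constant_tracks(dur_s=0.335)
        stim = tracks_to_sws(tr)
        return SWSStimulus(np.ones_like(stim.waveform), stim.fs, tr, "t")

    def test_ramp_endpoints_and_midpoint(self, unit_stim):
        out = apply_offset_ramp(unit_stim, 50.0)
        fs = out.fs
        assert out.waveform[-1] == 0.0
        assert out.waveform[int(round(0.285 * fs))] == pytest.approx(1.0, abs=1e-3)
        # ramp midpoint: cos^2(pi/4) = 0.5
        assert out.waveform[int(round(0.310 * fs))] == pytest.approx(0.5, abs=1e-3)
        # samples before the ramp untouched
        assert np.all(out.waveform[: int(0.28 * fs)] == 1.0)

    def test_ramp_longer_than_stimulus_rejected(self, unit_stim):
        with pytest.raises(ValueError):
            apply_offset_ramp(unit_stim, 400.0)


class TestRMSNormalize:
    def test_identity_and_scaling(self):
        stim = tracks_to_sws(constant_tracks(dur_s=0.1))
        r = stim.rms
        same = rms_normalize([stim], r)[0]
        np.testing.assert_allclose(same.waveform, stim.waveform, rtol=1e-12)
        doubled = SWSStimulus(2 * stim.waveform, stim.fs, stim.tracks, "t")
        np.testing.assert_allclose(rms_normalize([doubled], r)[0].waveform, stim.waveform, rtol=1e-12)

    def test_three_tokens_share_target_rms(self, stimuli):
        out = rms_normalize(stimuli, 0.05)
        for s in out:
            assert s.rms == pytest.approx(0.05, abs=5e-8)

    def test_zero_waveform_rejected(self):
        stim = tracks_to_sws(constant_tracks(a1=0.0, dur_s=0.1))
        with pytest.raises(ValueError, match="zero"):
            rms_normalize([stim], 0.05)


class TestLPCFormantTracks:
    def test_two_resonance_signal_recovered(self):
        # oracle input: pulse train through two known resonators
        fs = 10000.0
        n = int(0.5 * fs)
        pulses = np.zeros(n)
        pulses[:: int(fs / 100)] = 1.0  # 100 Hz glottal-like source
        x = pulses
        for f0, bw in ((400.0, 80.0), (1200.0, 120.0)):
            r = np.exp(-np.pi * bw / fs)
            poles = [1.0, -2 * r * np.cos(2 * np.pi * f0 / fs), r * r]
            x = signal.lfilter([1.0], poles, x)
        tr = lpc_formant_tracks(x, fs, order=12, win_ms=25, hop_ms=10)
        assert abs(np.median(tr.f1_hz) - 400.0) <= 25.0
        assert abs(np.median(tr.f2_hz) - 1200.0) <= 50.0

    def test_pure_tone_tracks_its_frequency(self):
        fs = 10000.0
        t = np.arange(int(0.3 * fs)) / fs
        tr = lpc_formant_tracks(np.sin(2 * np.pi * 500 * t), fs, order=12)
        assert abs(np.median(tr.f1_hz) - 500.0) <= 10.0

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lpc_formant_tracks(np.array([]), 44100.0)

    def test_window_longer_than_audio_rejected(self):
        with pytest.raises(ValueError, match="window"):
            lpc_formant_tracks(np.ones(50), 44100.0, win_ms=25)

    def test_round_trip_synthesis_then_lpc(self, stimulus):
        # resynthesized SWS analyzed by LPC recovers its own center frequencies
        tr = lpc_formant_tracks(stimulus.waveform, stimulus.fs)
        sl = slice(int(0.05 * len(tr.f1_hz)), int(0.8 * len(tr.f1_hz)))
        rel1 = np.abs(np.median(tr.f1_hz[sl]) - np.median(stimulus.tracks.f1_hz[sl])) / np.median(
            stimulus.tracks.f1_hz[sl]
        )
        rel2 = np.abs(np.median(tr.f2_hz[sl]) - np.median(stimulus.tracks.f2_hz[sl])) / np.median(
            stimulus.tracks.f2_hz[sl]
        )
        assert rel1 < 0.05
        assert rel2 < 0.05
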