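"""Fourier analyzer: references, noise tracks, amplitude/phase, presence."""

import numpy as np
import pytest

from ffrsws.fourier import (
    build_reference,
    fa_measure,
    fa_presence,
    instantaneous_frequency,
    make_noise_tracks,
)
from ffrsws.simulate import make_token_tracks

FS = 5000.0


@pytest.fixture(scope="module")
def chirp_reference():
    """Reference following the 'baw' preset F1 glide at the EEG rate."""
    tr = make_token_tracks("baw", 335, 44100).resample(FS)
    return build_reference(tr.f1_hz, FS, label="F1")


class TestInstantaneousFrequency:
    def test_constant_tone(self):
        t = np.arange(int(FS)) / FS
        inst = instantaneous_frequency(np.cos(2 * np.pi * 500 * t), FS)
        interior = inst[100:-100]  # away from 50-sample edge effects
        assert np.max(np.abs(interior - 500.0)) < 0.5

    def test_linear_chirp(self):
        n = int(0.335 * FS)
        t = np.arange(n) / FS
        f0, f1 = 300.0, 675.0
        k = (f1 - f0) / (0.335)
        x = np.cos(2 * np.pi * (f0 * t + 0.5 * k * t**2))
        inst = instantaneous_frequency(x, FS)
        truth = f0 + k * t
        central = slice(int(0.1 * n), int(0.9 * n))
        assert np.max(np.abs(inst[central] - truth[central])) < 5.0

    def test_zero_waveform_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_frequency(np.zeros(1000), FS)

    def test_short_waveform_rejected(self):
        with pytest.raises(ValueError, match="150"):
            instantaneous_frequency(np.ones(100), FS)


class TestBuildReference:
    def test_final_phase_of_constant_track(self):
        freq = np.full(int(FS), 100.0)  # 1 s at 100 Hz
        ref = build_reference(freq, FS)
        assert ref.phase_rad[-1] == pytest.approx(2 * np.pi * 100 * (1 - 1 / FS), abs=2 * np.pi / FS)

    def test_zero_frequency_constant_phase(self):
        ref = build_reference(np.zeros(500), FS)
        assert np.all(ref.phase_rad == 0.0)

    def test_round_trip_with_instantaneous_frequency(self):
        t = np.arange(int(FS)) / FS
        tone = np.cos(2 * np.pi * 440 * t)
        inst = instantaneous_frequency(tone, FS)
        ref = build_reference(inst, FS)
        rebuilt = np.cos(ref.phase_rad)
        r = np.corrcoef(tone[200:-200], rebuilt[200:-200])[0, 1]
        assert abs(r) > 0.99


class TestNoiseTracks:
    def test_exactly_ten_tracks_at_stated_offsets(self, chirp_reference):
        tracks = make_noise_tracks(chirp_reference)
        assert len(tracks) == 10
        offs = sorted(round(float(t.freq_hz[0] - chirp_reference.freq_hz[0])) for t in tracks)
        assert offs == [-9, -8, -7, -6, -5, 5, 6, 7, 8, 9]

    def test_constant_reference_offset_frequencies(self):
        ref = build_reference(np.full(1000, 500.0), FS)
        freqs = {round(float(t.freq_hz[0])) for t in make_noise_tracks(ref)}
        assert freqs == {491, 492, 493, 494, 495, 505, 506, 507, 508, 509}

    def test_low_frequency_reference_rejected(self):
        ref = build_reference(np.full(1000, 4.0), FS)
        with pytest.raises(ValueError, match="zero"):
            make_noise_tracks(ref)


class TestFAMeasure:
    def test_tracked_cosine_amplitude_is_half(self, chirp_reference):
        resp = 1.0 * np.cos(chirp_reference.phase_rad)
        amp, _ = fa_measure(resp, chirp_reference, shift_ms=0.0)
        assert amp == pytest.approx(0.5, rel=0.01)

    def test_amplitude_linear_in_response_scale(self, chirp_reference):
        resp = np.cos(chirp_reference.phase_rad)
        a1 = fa_measure(resp, chirp_reference, shift_ms=0.0)[0]
        a2 = fa_measure(3.25 * resp, chirp_reference, shift_ms=0.0)[0]
        assert a2 == pytest.approx(3.25 * a1, rel=1e-12)

    def test_zero_response_zero_amplitude(self, chirp_reference):
        amp, _ = fa_measure(np.zeros(len(chirp_reference)), chirp_reference, shift_ms=0.0)
        assert amp == 0.0

    def test_phase_convention_response_minus_reference(self, chirp_reference):
        resp = np.cos(chirp_reference.phase_rad + np.pi / 3)
        _, ph = fa_measure(resp, chirp_reference, shift_ms=0.0)
        assert ph == pytest.approx(np.pi / 3, abs=0.02)
        _, ph_flip = fa_measure(resp, chirp_reference, shift_ms=0.0, conjugate_reference=False)
        assert ph_flip == pytest.approx(-np.pi / 3, abs=0.02)

    def test_shift_realigns_delayed_response(self, chirp_reference):
        # a 6 ms-delayed tracked cosine measured with the -6 ms shift
        resp = np.cos(chirp_reference.phase_rad)
        delayed = np.concatenate([np.zeros(30), resp])
        amp, _ = fa_measure(delayed, chirp_reference, shift_ms=-6.0)
        assert amp == pytest.approx(0.5, rel=0.01)

    def test_window_outside_response_rejected(self, chirp_reference):
        with pytest.raises(ValueError):
            fa_measure(np.zeros(200), chirp_reference, window_ms=(50.0, 335.0))

    def test_off_track_leakage_matches_sinc_envelope(self, chirp_reference):
        # a noise track differs from the reference by a constant offset, so
        # the FA product beats at exactly that offset: leakage relative to
        # on-track is |sinc(offset * T)| for the T = 285 ms window
        resp = np.cos(chirp_reference.phase_rad)
        on = fa_measure(resp, chirp_reference, shift_ms=0.0)[0]
        T = 0.285
        for track in make_noise_tracks(chirp_reference):
            off = float(track.freq_hz[0] - chirp_reference.freq_hz[0])
            expected = abs(np.sinc(off * T))
            measured = fa_measure(resp, track, shift_ms=0.0)[0] / on
            assert measured == pytest.approx(expected, abs=0.02)


class TestFAPresence:
    def test_high_snr_component_present(self, chirp_reference):
        rng = np.random.default_rng(11)
        resp = np.cos(chirp_reference.phase_rad) + 0.1 * rng.standard_normal(len(chirp_reference))
        res = fa_presence(resp, chirp_reference, shift_ms=0.0)
        assert res.present
        assert len(res.noise_amplitudes) == 10
        assert res.amplitude > res.noise_floor

    def test_null_presence_rate_near_half(self, chirp_reference):
        # the mean-exceedance rule is lenient by design: ~50% under pure noise
        rng = np.random.default_rng(13)
        hits = sum(
            fa_presence(rng.standard_normal(len(chirp_reference)), chirp_reference, shift_ms=0.0).present
            for _ in range(20)
        )
        assert 0.25 <= hits / 20 <= 0.75

    def test_zero_response_absent(self, chirp_reference):
        res = fa_presence(np.zeros(len(chirp_reference)), chirp_reference, shift_ms=0.0)
        assert res.amplitude == 0.0
        assert res.noise_floor == 0.0
        assert not res.present  # strict inequality
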