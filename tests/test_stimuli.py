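"""Stimulus synthesis: levels, spectra, periodicity, filters, noises."""

import numpy as np
import pytest
from scipy.signal import correlate, hilbert, welch

from pitchsim.audio import AudioError, P_REF, Waveform, mix_at_snr, set_level
from pitchsim.stimuli import (
    HarmonicSpec,
    MOORE_ENVELOPES,
    bandpass_translate,
    frequency_shift_complex,
    harmonic_complex,
    make_harmonic_complex,
    masking_noise,
    mistuned_complex,
    moore_envelope_value,
    translated_filter_magnitude,
    transposed_tone,
)

from conftest import tone_component_level


def autocorr_peak_lag(x, sr, lo_ms, hi_ms):
    r = correlate(x, x, mode="full")[len(x) - 1:]
    k0, k1 = int(lo_ms * sr / 1000), int(hi_ms * sr / 1000)
    return (np.argmax(r[k0:k1]) + k0) / sr * 1000.0


class TestHarmonicComplex:
    def test_periodicity_200hz(self):
        """Harmonics 1-10 of 200 Hz give a 5 ms waveform period."""
        spec = HarmonicSpec(200.0, np.arange(1, 11), 60.0, "sine")
        w = make_harmonic_complex(spec, 0.1)
        assert autocorr_peak_lag(w.samples, w.sample_rate, 2, 8) == pytest.approx(5.0, abs=0.05)

    def test_alternating_phase_envelope_doubling(self):
        """Alternating-phase high harmonics double the envelope peak rate:
        first major envelope-autocorrelation peak at half the F0 period."""
        spec = HarmonicSpec(125.0, np.arange(12, 17), 60.0, "alternating")
        w = make_harmonic_complex(spec, 0.2)
        env = np.abs(hilbert(w.samples))
        env -= env.mean()
        lag = autocorr_peak_lag(env, w.sample_rate, 2, 6)
        assert lag == pytest.approx(4.0, abs=0.15)  # 8 ms F0 period / 2

    def test_component_level_convention(self):
        """A single harmonic at 60 dB SPL measures 60 +- 0.01 dB."""
        spec = HarmonicSpec(500.0, [1], 60.0, "sine")
        w = make_harmonic_complex(spec, 0.1)
        assert w.level_db_spl() == pytest.approx(60.0, abs=0.01)

    def test_phase_invariance_of_magnitude_spectrum(self, rng):
        """Sine, random and alternating phase leave the magnitude spectrum
        unchanged for identical component amplitudes."""
        mags = []
        for mode in ("sine", "random", "alternating"):
            spec = HarmonicSpec(200.0, np.arange(1, 11), 55.0, mode)
            w = make_harmonic_complex(spec, 0.25, rng=rng)
            mags.append(np.abs(np.fft.rfft(w.samples)))
        # compare at the component bins (leakage elsewhere is tiny at 0.25 s)
        bins = (np.arange(1, 11) * 200 * 0.25).astype(int)
        for m in mags[1:]:
            assert np.allclose(m[bins], mags[0][bins], rtol=1e-3)

    def test_errors(self):
        with pytest.raises(AudioError):
            HarmonicSpec(200.0, [], 60.0, "sine")
        with pytest.raises(AudioError):
            make_harmonic_complex(HarmonicSpec(200.0, [100], 60.0, "sine"), 0.05)


class TestMooreEnvelope:
    @pytest.mark.parametrize("x_expected, freq_offset", [
        (1.0, 0.0),           # at the passband edge
        ((10 ** 0.5 - 1) / 9, 0.75),  # x = 0.5 on the slope (0.75 = 0.5*1.5 F0)
        (0.0, 1.5),           # x <= 0 beyond the slope
    ])
    def test_slope_values(self, x_expected, freq_offset):
        env = MOORE_ENVELOPES["low_harmonics"]
        f0 = 100.0
        edge_hi = (env.center + env.width / 2) * f0
        v = moore_envelope_value(edge_hi + freq_offset * f0, env, f0)
        assert v == pytest.approx(x_expected, abs=1e-9)

    def test_flat_inside_passband(self):
        env = MOORE_ENVELOPES["mid_harmonics"]
        assert moore_envelope_value(11 * 100.0, env, 100.0) == 1.0


class TestFrequencyShiftComplex:
    def test_shifted_component_frequencies(self):
        """+8% shift of the low-harmonics envelope at F0=100 Hz puts energy
        at 208, 308, ..., 708 Hz and nowhere else."""
        w = frequency_shift_complex(100.0, "low_harmonics", 8.0)
        present = [f for f in (208, 308, 408, 508, 608, 708)]
        absent = [108, 808]  # outside the envelope's support
        for f in present:
            assert tone_component_level(w, f) > 10.0
        loudest = max(tone_component_level(w, f) for f in present)
        for f in absent:
            assert tone_component_level(w, f) < loudest - 40.0

    def test_zero_shift_is_harmonic(self):
        w = frequency_shift_complex(100.0, "low_harmonics", 0.0)
        assert tone_component_level(w, 500.0) > 10
        assert tone_component_level(w, 550.0) < -20

    def test_affine_component_grid(self):
        """Component frequencies are n*f0 + shift*f0/100 (affine in n)."""
        spec_freqs = (np.arange(2, 8) + 0.12) * 150.0
        w = frequency_shift_complex(150.0, "low_harmonics", 12.0)
        levels = [tone_component_level(w, f) for f in spec_freqs]
        assert max(levels) > 10

    def test_overall_level(self):
        w = frequency_shift_complex(200.0, "mid_harmonics", 4.0, level=70.0)
        assert w.level_db_spl() == pytest.approx(70.0, abs=0.01)

    def test_unknown_envelope(self):
        with pytest.raises(AudioError):
            frequency_shift_complex(100.0, "no_such_envelope", 0.0)


class TestMistunedComplex:
    def test_mistuned_component_position(self):
        """Harmonic 3 of 200 Hz shifted +4% sits at 624 Hz."""
        w = mistuned_complex(200.0, 3, 4.0)
        assert tone_component_level(w, 624.0) == pytest.approx(60.0, abs=0.5)
        assert tone_component_level(w, 600.0) < 30.0
        for n in (1, 2, 4, 5):
            assert tone_component_level(w, 200.0 * n) == pytest.approx(60.0, abs=0.5)

    def test_zero_shift_identity(self):
        a = mistuned_complex(200.0, 5, 0.0)
        b = make_harmonic_complex(
            HarmonicSpec(200.0, np.arange(1, 13), 60.0, "sine"), 0.150)
        assert np.allclose(a.samples, b.samples)

    def test_harmonic_12_at_400(self):
        w = mistuned_complex(400.0, 12, 8.0)
        assert tone_component_level(w, 5184.0) == pytest.approx(60.0, abs=0.5)

    def test_out_of_range_harmonic(self):
        with pytest.raises(AudioError):
            mistuned_complex(200.0, 13, 2.0)


class TestTransposedTone:
    def test_spectrum_near_carrier(self):
        """Energy concentrates near the carrier; < -40 dB re peak below 2 kHz."""
        w = transposed_tone(4000.0, 160.0)
        X = np.abs(np.fft.rfft(w.samples))
        f = np.fft.rfftfreq(w.n_samples, 1 / w.sample_rate)
        assert X[f < 2000].max() < X.max() * 10 ** (-40 / 20)

    def test_envelope_period(self):
        """160 Hz envelope shows a 6.25 ms Hilbert-envelope periodicity."""
        w = transposed_tone(6350.0, 160.0, duration=0.2)
        env = np.abs(hilbert(w.samples))
        env -= env.mean()
        lag = autocorr_peak_lag(env, w.sample_rate, 4, 9)
        assert lag == pytest.approx(6.25, abs=0.1)

    def test_envelope_above_cutoff_rejected(self):
        with pytest.raises(AudioError):
            transposed_tone(4000.0, 900.0)  # cutoff is 800 Hz


class TestMaskingNoise:
    def test_modified_uniform_spectrum_levels(self, rng):
        """15 dB/Hz below 600 Hz, then -2 dB/octave: 13 at 1200, 11 at 2400."""
        w = masking_noise("modified_uniform", 4.0, 32000, rng)
        f, P = welch(w.samples, 32000, nperseg=2048)
        lev = lambda fq: 10 * np.log10(
            P[np.abs(f - fq) < 80].mean() / P_REF**2)
        assert lev(300) == pytest.approx(15.0, abs=1.0)
        assert lev(1200) == pytest.approx(13.0, abs=1.0)
        assert lev(2400) == pytest.approx(11.0, abs=1.0)

    def test_threshold_equalizing_noise_equal_erb_power(self, rng):
        """TEN has (approximately) constant power per ERB across frequency."""
        from pitchsim.stimuli import erb_hz

        w = masking_noise("threshold_equalizing", 4.0, 32000, rng)
        f, P = welch(w.samples, 32000, nperseg=2048)
        powers = []
        for fc in (500.0, 1000.0, 2000.0, 4000.0):
            bw = erb_hz(fc)
            sel = (f > fc - bw / 2) & (f < fc + bw / 2)
            powers.append(10 * np.log10(np.trapezoid(P[sel], f[sel]) / P_REF**2))
        assert np.ptp(powers) < 1.5
        assert np.mean(powers) == pytest.approx(10.0, abs=1.0)

    def test_unknown_kind(self, rng):
        with pytest.raises(AudioError):
            masking_noise("pink", 0.1, 32000, rng)


class TestBandpassTranslate:
    def test_passband_center_unattenuated(self):
        """After translating the low edge to 2000 Hz, a tone at the (translated)
        passband center passes within 0.1 dB."""
        freqs = np.linspace(0, 16000, 4001)
        mag = translated_filter_magnitude(freqs, 2000.0)
        center = freqs[np.argmax(mag)]
        w = harmonic_complex(center, 0.15, max_freq=center * 1.01)
        w = set_level(w, 60.0)
        out = bandpass_translate(w, 2000.0)
        assert out.level_db_spl() == pytest.approx(60.0, abs=0.1)

    def test_edge_attenuation_is_15db(self):
        edge = 2000.0
        mag = translated_filter_magnitude(np.array([edge]), edge)
        assert 20 * np.log10(mag[0]) == pytest.approx(-15.0, abs=0.5)

    def test_silence_passthrough(self):
        w = Waveform(np.zeros(4800), 32000)
        assert np.allclose(bandpass_translate(w, 1000.0).samples, 0.0)

    def test_out_of_range_translation(self):
        w = Waveform(np.zeros(4800), 32000)
        with pytest.raises(AudioError):
            bandpass_translate(w, 15500.0)


class TestLevelsAndSnr:
    def test_snr_zero_equalizes_rms(self, rng):
        s = harmonic_complex(200.0, 0.1, component_level=60)
        n = masking_noise("modified_uniform", 0.1, 32000, rng)
        mixed = mix_at_snr(s, n, 0.0)
        noise_part = mixed.samples - s.samples
        assert 20 * np.log10(s.rms() / np.sqrt(np.mean(noise_part**2))) == \
            pytest.approx(0.0, abs=0.01)

    def test_snr_20db_is_10x_amplitude(self, rng):
        s = harmonic_complex(200.0, 0.1, component_level=60)
        n = masking_noise("modified_uniform", 0.1, 32000, rng)
        mixed = mix_at_snr(s, n, 20.0)
        noise_part = mixed.samples - s.samples
        assert s.rms() / np.sqrt(np.mean(noise_part**2)) == pytest.approx(10.0, rel=0.01)

    @pytest.mark.parametrize("level", [30.0, 70.0, 90.0])
    def test_set_level_round_trip(self, level, rng):
        w = Waveform(rng.standard_normal(3200), 32000)
        assert set_level(w, level).level_db_spl() == pytest.approx(level, abs=0.01)

    def test_zero_noise_rejected(self):
        s = harmonic_complex(200.0, 0.1)
        z = Waveform(np.zeros(s.n_samples), 32000)
        with pytest.raises(AudioError):
            mix_at_snr(s, z, 0.0)


class TestWavRoundTrip:
    def test_write_read(self, tmp_path, rng):
        from pitchsim.audio import read_wav, write_wav

        w = set_level(Waveform(rng.standard_normal(1600), 32000), 65.0)
        w.meta["seed"] = 7
        write_wav(tmp_path / "x.wav", w)
        back = read_wav(tmp_path / "x.wav")
        assert back.sample_rate == 32000
        assert back.meta["seed"] == 7
        assert np.allclose(back.samples, w.samples, atol=1e-6)
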