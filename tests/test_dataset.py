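"""Synthetic dataset generator: bin grid, screens, cepstral Gaussians."""

import numpy as np
import pytest
from scipy.stats import kstest

from pitchsim.audio import AudioError, Waveform
from pitchsim.dataset import (
    DatasetConfig,
    antimatch,
    assign_bin,
    build_dataset,
    envelope_coeffs,
    f0_bin_grid,
    fit_envelope_gaussian,
    periodicity_screen,
    profile_gaussian,
    random_filter_variant,
    sample_matched_tone,
    total_examples,
)
from pitchsim.stimuli import harmonic_complex


class TestF0BinGrid:
    def test_700_bins_full_grid(self):
        g = f0_bin_grid(80.0, 1000.0, 1.0 / 16.0)
        assert g.n_bins == 700
        assert g.bin_width_pct == pytest.approx(0.36, abs=0.005)

    def test_one_bin_grid_ratio(self):
        g = f0_bin_grid(80.0, 80.0 * 2 ** (1 / 192), 1.0 / 16.0)
        assert g.n_bins == 1
        assert g.edges[1] / g.edges[0] == pytest.approx(2 ** (1 / 192))

    def test_edges_geometric(self):
        g = f0_bin_grid()
        ratios = g.edges[1:] / g.edges[:-1]
        assert np.allclose(ratios, 2 ** (1 / 192))

    def test_assign_bin_conventions(self, rng):
        g = f0_bin_grid()
        assert assign_bin(80.0, g) == 0
        for k in rng.integers(0, 700, 20):
            assert assign_bin(g.centers[k], g) == k
            # just below the upper edge still belongs to bin k (half-open)
            assert assign_bin(g.edges[k + 1] * (1 - 1e-12), g) == k
        with pytest.raises(AudioError):
            assign_bin(1500.0, g)


class TestPeriodicityScreen:
    def test_pure_tones_rejected(self):
        for f0 in (200.0, 50.0):
            tone = harmonic_complex(f0, 0.05, max_freq=f0 * 1.2)
            assert periodicity_screen(tone) is False

    def test_broadband_noise_accepted(self, rng):
        n_accept = sum(
            periodicity_screen(Waveform(rng.standard_normal(1600), 32000))
            for _ in range(300))
        assert n_accept / 300 > 0.99

    def test_zero_energy_rejected(self):
        with pytest.raises(AudioError):
            periodicity_screen(Waveform(np.zeros(1600), 32000))


class TestEnvelopeGaussian:
    FREQS = np.logspace(np.log10(50), np.log10(16000), 128)

    def test_identical_envelopes_zero_covariance(self):
        env = np.tile(np.linspace(1.0, 0.1, 128), (20, 1))
        g = fit_envelope_gaussian(env, self.FREQS)
        assert np.allclose(g.cov, 0.0)
        assert np.allclose(g.mean, envelope_coeffs(env[:1], self.FREQS)[0])

    def test_permutation_invariance(self, rng):
        env = rng.uniform(0.1, 1.0, (30, 128))
        g1 = fit_envelope_gaussian(env, self.FREQS)
        g2 = fit_envelope_gaussian(env[::-1], self.FREQS)
        assert np.allclose(g1.mean, g2.mean)
        assert np.allclose(g1.cov, g2.cov)

    def test_rank_deficiency_flag(self, rng):
        env = rng.uniform(0.1, 1.0, (5, 128))
        assert fit_envelope_gaussian(env, self.FREQS).rank_deficient

    def test_parameter_recovery(self, rng):
        """Fitting n=2000 envelopes drawn from a known cepstral Gaussian
        recovers its mean within 3.5 standard errors coordinate-wise.

        The recovery target is the deterministic coefficient round-trip of
        the source mean (inverting 13 coefficients to an envelope and
        re-measuring them smooths through the mel filterbank, a small fixed
        bias shared by every sample); the round-trip itself must track the
        source mean almost perfectly."""
        src = profile_gaussian("speech_like")
        target = envelope_coeffs(
            src.envelope_from_coeffs(src.mean, self.FREQS), self.FREQS)[0]
        assert np.corrcoef(target, src.mean)[0, 1] > 0.99
        n = 2000
        coeffs = src.sample_coeffs(rng, n)
        env = np.stack([src.envelope_from_coeffs(c, self.FREQS)
                        for c in coeffs])
        fit = fit_envelope_gaussian(env, self.FREQS)
        se = np.sqrt(np.diag(src.cov) / n)
        assert np.all(np.abs(fit.mean - target) < 3.5 * se + 1e-6)

    def test_antimatch(self):
        g = profile_gaussian("speech_like")
        a = antimatch(g)
        assert np.array_equal(a.mean, -g.mean)
        assert np.array_equal(a.cov, g.cov)

    def test_antimatch_inverts_tilt(self):
        """A lowpass (decreasing) mean envelope maps to a highpass one."""
        freqs = self.FREQS
        env = np.tile(10 ** (-np.linspace(0, 3, 128)), (20, 1))
        g = fit_envelope_gaussian(env, freqs)
        lo, hi = slice(10, 30), slice(90, 110)
        mean_env = g.envelope_from_coeffs(g.mean, freqs)
        anti_env = antimatch(g).envelope_from_coeffs(-g.mean, freqs)
        assert mean_env[lo].mean() > mean_env[hi].mean()
        assert anti_env[lo].mean() < anti_env[hi].mean()


class TestMatchedTones:
    def test_component_grid(self, rng):
        """f0=100 tones contain components at exactly 100*n up to 16 kHz."""
        from conftest import tone_component_level

        g = profile_gaussian("music_like")
        w = sample_matched_tone(g, 100.0, rng)
        assert tone_component_level(w, 100.0) > -20
        assert tone_component_level(w, 15900.0) > -90
        assert tone_component_level(w, 150.0) < tone_component_level(w, 100.0) - 30

    def test_zero_covariance_reproducible_spectrum(self, rng):
        g = profile_gaussian("speech_like")
        g0 = antimatch(antimatch(g))
        g0.cov = np.zeros((13, 13))
        w1 = sample_matched_tone(g0, 200.0, rng)
        w2 = sample_matched_tone(g0, 200.0, rng)
        assert np.allclose(w1.samples, w2.samples)

    def test_matched_vs_antimatched_negative_correlation(self, rng):
        """Average log-spectral envelopes of matched and anti-matched tone
        sets are negatively correlated when the source mean is lowpass."""
        freqs = np.logspace(np.log10(200), np.log10(8000), 64)
        env = np.tile(10 ** (-np.linspace(0, 2.5, 64)), (20, 1)) \
            * np.exp(0.1 * np.random.default_rng(0).standard_normal((20, 64)))
        g = fit_envelope_gaussian(env, freqs)
        a = antimatch(g)
        m_env = np.log10(np.maximum(
            np.mean([g.sample_envelope(rng, freqs) for _ in range(40)], axis=0),
            1e-12))
        a_env = np.log10(np.maximum(
            np.mean([a.sample_envelope(rng, freqs) for _ in range(40)], axis=0),
            1e-12))
        r = np.corrcoef(m_env, a_env)[0, 1]
        assert r < -0.5


class TestRandomFilters:
    def test_zero_phase(self, rng):
        w = harmonic_complex(300.0, 0.1, max_freq=400)
        out = random_filter_variant(w, "lowpass", rng)
        xc = np.correlate(out.samples, w.samples, mode="full")
        assert np.argmax(np.abs(xc)) == len(w.samples) - 1

    def test_cutoffs_log_uniform(self, rng):
        w = Waveform(rng.standard_normal(64), 32000)
        cuts = [random_filter_variant(w, "lowpass", rng).meta["filter_cutoff"]
                for _ in range(3000)]
        stat = kstest(np.log(cuts),
                      lambda x: (x - np.log(500)) / (np.log(5000) - np.log(500)))
        assert stat.pvalue > 0.01

    def test_attenuation_beyond_cutoff(self, rng):
        """The realized forward-backward Butterworth attenuates at least
        2*(12n) - 9 dB two octaves above its cutoff (evaluated on the
        designed response, squared for the two passes)."""
        from scipy.signal import butter, sosfreqz

        for _ in range(10):
            w = Waveform(rng.standard_normal(64), 32000)
            out = random_filter_variant(w, "lowpass", rng)
            c, n = out.meta["filter_cutoff"], out.meta["filter_order"]
            probe = 4 * c
            if probe >= 16000:
                continue
            sos = butter(n, c, btype="low", fs=32000, output="sos")
            _, h = sosfreqz(sos, worN=[probe], fs=32000)
            att_two_pass = -2 * 20 * np.log10(np.abs(h[0]))
            assert att_two_pass >= 2 * (12 * n) - 9

    def test_unknown_mode(self, rng):
        with pytest.raises(AudioError):
            random_filter_variant(Waveform(np.zeros(16), 32000), "bandstop", rng)


class TestBuildDataset:
    def test_counts_exact_and_labels_correct(self, rng):
        cfg = DatasetConfig(n_bins=6, exemplars_per_bin=4)
        ds = build_dataset(cfg, rng)
        assert len(ds.examples) == 24
        counts = np.bincount([e.bin_index for e in ds.examples], minlength=6)
        assert (counts == 4).all()
        for e in ds.examples:
            assert assign_bin(e.f0, ds.grid) == e.bin_index

    def test_full_scale_total_is_2_1_million(self):
        assert total_examples(DatasetConfig.full_scale()) == 2_100_000

    def test_noiseless_mode(self, rng):
        cfg = DatasetConfig(n_bins=2, exemplars_per_bin=1, snr_range=None)
        ds = build_dataset(cfg, rng)
        assert all(e.snr is None for e in ds.examples)

    def test_seed_determinism(self):
        cfg = DatasetConfig(n_bins=3, exemplars_per_bin=2)
        m1 = build_dataset(cfg, np.random.default_rng(11)).manifest()
        m2 = build_dataset(cfg, np.random.default_rng(11)).manifest()
        assert m1.equals(m2)

    def test_snr_and_level_uniform(self, rng):
        cfg = DatasetConfig(n_bins=4, exemplars_per_bin=60, duration=0.02)
        ds = build_dataset(cfg, rng)
        snrs = np.array([e.snr for e in ds.examples])
        levels = np.array([e.level for e in ds.examples])
        assert kstest(snrs, lambda x: (x + 10) / 20).pvalue > 0.01
        assert kstest(levels, lambda x: (x - 30) / 60).pvalue > 0.01
        # levels realized on the waveforms themselves
        for e in ds.examples[:5]:
            assert e.input.level_db_spl() == pytest.approx(e.level, abs=0.01)
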