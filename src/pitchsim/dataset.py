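"""Synthetic labeled training corpora.

The real speech/music corpora behind the original training set are replaced
by a generator that reproduces their *statistical* structure:

* the label grid: 700 log-spaced F0 bins between 80 and 1000 Hz, 1/16
  semitone (0.36% F0) wide, with half-open geometric bins;
* per-example signal-to-noise ratios drawn uniformly (default -10..+10 dB)
  and overall levels drawn uniformly (30..90 dB SPL);
* component spectra drawn from a 13-coefficient cepstral (mel-frequency
  cepstral coefficient) multivariate Gaussian fitted to a family of spectral
  envelopes, imposed on equal-amplitude cosine-phase harmonic complexes with
  harmonics up to 16 kHz;
* background noise spectrally matched via the same cepstral machinery (fit to
  power spectra), with an autocorrelation periodicity screen;
* dataset variants: spectrally anti-matched (negated cepstral mean),
  lowpass/highpass randomly filtered, low-noise / noiseless, and
  speech-like / music-like envelope profiles (synthetic stand-ins for the
  corpus differences; they capture envelope tilt and variance only).

All sampling is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import dct, idct

from .audio import AudioError, Waveform, mix_at_snr, set_level
from .stimuli import HarmonicSpec, make_harmonic_complex, masking_noise

__all__ = [
    "F0BinGrid",
    "EnvelopeGaussian",
    "LabeledExample",
    "DatasetConfig",
    "f0_bin_grid",
    "assign_bin",
    "periodicity_screen",
    "mel_filterbank",
    "fit_envelope_gaussian",
    "sample_matched_tone",
    "antimatch",
    "random_filter_variant",
    "profile_gaussian",
    "build_dataset",
    "total_examples",
]


# ---------------------------------------------------------------------------
# F0 bin grid
# ---------------------------------------------------------------------------

@dataclass
class F0BinGrid:
    """Geometric F0 class grid.

    Edges form a geometric sequence with ratio ``2**(bin_width/12)``
    (``bin_width`` in semitones); bins are half-open ``[edge_k, edge_{k+1})``.
    """

    f_min: float
    f_max: float
    bin_width: float  # semitones
    n_bins: int = field(init=False)
    edges: np.ndarray = field(init=False)
    centers: np.ndarray = field(init=False)

    def __post_init__(self):
        if not (self.f_min < self.f_max and self.bin_width > 0):
            raise AudioError("need f_min < f_max and positive bin width")
        self.n_bins = int(round(np.log2(self.f_max / self.f_min) * 12.0 / self.bin_width))
        ratio = 2.0 ** (self.bin_width / 12.0)
        self.edges = self.f_min * ratio ** np.arange(self.n_bins + 1)
        self.centers = self.edges[:-1] * np.sqrt(ratio)

    @property
    def bin_width_pct(self) -> float:
        """Bin width as % F0 (ratio minus one)."""
        return (2.0 ** (self.bin_width / 12.0) - 1.0) * 100.0


def f0_bin_grid(f_min: float = 80.0, f_max: float = 1000.0,
                bin_width: float = 1.0 / 16.0) -> F0BinGrid:
    return F0BinGrid(f_min, f_max, bin_width)


def assign_bin(f0: np.ndarray | float, grid: F0BinGrid) -> np.ndarray | int:
    f = np.asarray(f0, dtype=float)
    if np.any(f < grid.edges[0]) or np.any(f >= grid.edges[-1]):
        raise AudioError("f0 outside the bin grid")
    idx = np.searchsorted(grid.edges, f, side="right") - 1
    return idx if idx.ndim else int(idx)


# ---------------------------------------------------------------------------
# Periodicity screen for background noise
# ---------------------------------------------------------------------------

def periodicity_screen(noise: Waveform, threshold: float = 0.8,
                       min_lag: float = 0.001) -> bool:
    """True (accept) unless the unbiased normalized autocorrelation exceeds
    ``threshold`` at any lag above ``min_lag`` (lags up to half the duration)."""
    x = noise.samples - noise.samples.mean()
    n = len(x)
    if np.all(x == 0):
        raise AudioError("zero-energy input")
    r = sps.correlate(x, x, mode="full")[n - 1:]
    counts = n - np.arange(n)
    r_unbiased = r / counts
    r_norm = r_unbiased / r_unbiased[0]
    k0 = int(np.ceil(min_lag * noise.sample_rate))
    k1 = n // 2
    return bool(np.max(r_norm[k0:k1 + 1]) <= threshold)


# ---------------------------------------------------------------------------
# Mel / cepstral envelope machinery
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, freqs: np.ndarray,
                   f_lo: float = 50.0, f_hi: float = 16000.0):
    """Triangular mel filterbank sampled on ``freqs``; returns (M, centers)."""
    mel_pts = np.linspace(_hz_to_mel(f_lo), _hz_to_mel(f_hi), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    M = np.zeros((n_mels, len(freqs)))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (freqs - lo) / (ctr - lo)
        down = (hi - freqs) / (hi - ctr)
        M[i] = np.clip(np.minimum(up, down), 0.0, None)
    return M, hz_pts[1:-1]


@dataclass
class EnvelopeGaussian:
    """Multivariate Gaussian over the first 13 mel-frequency cepstral
    coefficients of a spectral envelope (c0/log-energy excluded)."""

    mean: np.ndarray
    cov: np.ndarray
    n_mels: int = 40
    f_lo: float = 50.0
    f_hi: float = 16000.0
    rank_deficient: bool = False

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (13,) or self.cov.shape != (13, 13):
            raise AudioError("EnvelopeGaussian needs 13 coefficients")
        if not np.allclose(self.cov, self.cov.T):
            raise AudioError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(self.cov)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise AudioError("covariance must be positive semidefinite")

    def sample_coeffs(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        eigval, eigvec = np.linalg.eigh(self.cov)
        root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
        z = rng.standard_normal((n, 13))
        return self.mean + z @ root.T

    def envelope_from_coeffs(self, coeffs: np.ndarray,
                             freqs: np.ndarray) -> np.ndarray:
        """Invert cepstral coefficients to an amplitude envelope on ``freqs``."""
        full = np.zeros(self.n_mels)
        full[1:14] = coeffs
        log_mel_power = idct(full, type=2, norm="ortho")
        _, centers = mel_filterbank(self.n_mels, np.array([0.0]),
                                    self.f_lo, self.f_hi)
        logf = np.log(np.maximum(np.asarray(freqs, dtype=float), 1.0))
        interp = np.interp(logf, np.log(centers), log_mel_power,
                           left=log_mel_power[0], right=log_mel_power[-1])
        return 10.0 ** (interp / 2.0)  # amplitude from log10 power

    def sample_envelope(self, rng: np.random.Generator,
                        freqs: np.ndarray) -> np.ndarray:
        return self.envelope_from_coeffs(self.sample_coeffs(rng, 1)[0], freqs)


def envelope_coeffs(envelopes: np.ndarray, freqs: np.ndarray,
                    n_mels: int = 40, f_lo: float = 50.0,
                    f_hi: float = 16000.0, power: bool = False) -> np.ndarray:
    """Cepstral coefficients (c1..c13) of amplitude (or power) envelopes."""
    env = np.atleast_2d(np.asarray(envelopes, dtype=float))
    M, _ = mel_filterbank(n_mels, freqs, f_lo, f_hi)
    p = env if power else env**2
    mel_e = np.maximum(p @ M.T, 1e-20)
    cep = dct(np.log10(mel_e), type=2, norm="ortho", axis=-1)
    return cep[:, 1:14]


def fit_envelope_gaussian(envelopes: np.ndarray, freqs: np.ndarray,
                          power: bool = False, **kw) -> EnvelopeGaussian:
    """Fit the 13-coefficient cepstral Gaussian to a family of envelopes.

    Flags the covariance as rank deficient when fewer envelopes than
    coefficients are supplied (the Gaussian is still usable for sampling).
    """
    cep = envelope_coeffs(envelopes, freqs, power=power, **kw)
    n = cep.shape[0]
    mean = cep.mean(axis=0)
    if n < 2:
        cov = np.zeros((13, 13))
    else:
        cov = np.cov(cep, rowvar=False)
    g = EnvelopeGaussian(mean, cov, **kw)
    g.rank_deficient = n < 14
    return g


def antimatch(g: EnvelopeGaussian) -> EnvelopeGaussian:
    """Negate the cepstral mean (inverting the mean envelope); covariance kept."""
    return replace(g, mean=-g.mean, cov=g.cov.copy())


def sample_matched_tone(
    g: EnvelopeGaussian,
    f0: float,
    rng: np.random.Generator,
    duration: float = 0.150,
    sample_rate: float = 32000,
    max_freq: float = 16000.0,
) -> Waveform:
    """Harmonic complex whose spectrum follows an envelope drawn from ``g``.

    The base tone has all harmonics up to ``max_freq`` in cosine phase with
    equal amplitudes; the sampled envelope is imposed multiplicatively on the
    component amplitudes.
    """
    n_max = int(np.floor(min(max_freq, sample_rate / 2 * 0.999) / f0))
    if n_max < 1:
        raise AudioError("f0 above the maximum harmonic frequency")
    harmonics = np.arange(1, n_max + 1)
    freqs = harmonics * f0
    env = g.sample_envelope(rng, freqs)
    levels = 60.0 + 20.0 * np.log10(np.maximum(env, 1e-8))
    spec = HarmonicSpec(f0=f0, harmonic_numbers=harmonics,
                        component_levels=levels, phase_mode="cosine")
    w = make_harmonic_complex(spec, duration, sample_rate)
    w.meta.update(f0=f0, profile="matched_tone")
    return w


# ---------------------------------------------------------------------------
# Random filter variants (lowpass/highpass training sets)
# ---------------------------------------------------------------------------

_FILTER_CUTOFFS = {"lowpass": (500.0, 5000.0), "highpass": (1000.0, 10000.0)}


def random_filter_variant(w: Waveform, mode: str, rng: np.random.Generator) -> Waveform:
    """Apply a random Butterworth filter forward and backward (zero phase).

    Cutoffs are drawn log-uniformly (lowpass 500-5000 Hz, highpass
    1000-10000 Hz); the order is drawn uniformly from 1 to 5.
    """
    if mode not in _FILTER_CUTOFFS:
        raise AudioError(f"unknown filter mode {mode!r}")
    lo, hi = _FILTER_CUTOFFS[mode]
    cutoff = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if cutoff >= w.sample_rate / 2:
        raise AudioError("cutoff at or above Nyquist")
    order = int(rng.integers(1, 6))
    sos = sps.butter(order, cutoff, btype="low" if mode == "lowpass" else "high",
                     fs=w.sample_rate, output="sos")
    out = Waveform(sps.sosfiltfilt(sos, w.samples), w.sample_rate, dict(w.meta))
    out.meta.update(filter_mode=mode, filter_cutoff=cutoff, filter_order=order)
    return out


# ---------------------------------------------------------------------------
# Envelope-profile stand-ins for the speech/music corpora
# ---------------------------------------------------------------------------

def _synthetic_envelope_family(kind: str, rng: np.random.Generator,
                               n: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Random spectral envelopes emulating coarse corpus statistics.

    ``speech_like``: steep lowpass tilt with 2-3 formant-like resonances and
    large across-example variance.  ``music_like``: shallower tilt, weaker
    resonances, smaller variance.  ``noise_like``: gently sloped broadband
    spectra for background noise.  These are synthetic stand-ins; they carry
    none of the fine structure of real corpora.
    """
    freqs = np.logspace(np.log10(50.0), np.log10(16000.0), 256)
    logf = np.log2(freqs / 500.0)
    if kind == "speech_like":
        tilt_mu, tilt_sd, n_peaks, peak_db, base = -6.0, 2.0, 3, 12.0, 0.0
    elif kind == "music_like":
        tilt_mu, tilt_sd, n_peaks, peak_db, base = -3.0, 1.0, 2, 6.0, 0.0
    elif kind == "noise_like":
        tilt_mu, tilt_sd, n_peaks, peak_db, base = -2.0, 1.5, 1, 4.0, 0.0
    else:
        raise AudioError(f"unknown profile kind {kind!r}")
    out = np.empty((n, len(freqs)))
    for i in range(n):
        tilt = rng.normal(tilt_mu, tilt_sd)
        db = base + tilt * np.clip(logf, 0.0, None)
        for _ in range(n_peaks):
            fc = np.exp(rng.uniform(np.log(300.0), np.log(4000.0)))
            bw = rng.uniform(0.3, 0.8)  # octaves
            db += rng.uniform(0.0, peak_db) * np.exp(
                -0.5 * (np.log2(freqs / fc) / bw) ** 2)
        out[i] = 10.0 ** (db / 20.0)
    return out, freqs


def profile_gaussian(kind: str, seed: int = 0) -> EnvelopeGaussian:
    """Cepstral Gaussian for a named synthetic profile, fitted once from its
    deterministic envelope family."""
    import zlib

    rng = np.random.default_rng(seed + zlib.crc32(kind.encode()) % 2**16)
    env, freqs = _synthetic_envelope_family(kind, rng)
    return fit_envelope_gaussian(env, freqs, power=(kind == "noise_like"))


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

@dataclass
class LabeledExample:
    input: object  # Waveform or Nervegram
    f0: float
    bin_index: int
    snr: float | None
    level: float
    provenance: dict = field(default_factory=dict)


@dataclass
class DatasetConfig:
    """Study conditions for one synthetic corpus.

    Defaults are the desk-scale conditions (50 bins x 20 exemplars); the
    full-scale grid is 700 bins (1/16 semitone) x 3000 exemplars with SNR
    uniform -10..+10 dB and level uniform 30..90 dB SPL.
    """

    f_min: float = 80.0
    f_max: float = 1000.0
    n_bins: int = 50
    exemplars_per_bin: int = 20
    snr_range: tuple[float, float] | None = (-10.0, 10.0)
    level_range: tuple[float, float] = (30.0, 90.0)
    profile: str = "speech_like"  # or music_like / matched / antimatched
    filter_mode: str | None = None
    duration: float = 0.150
    sample_rate: float = 32000.0

    def grid(self) -> F0BinGrid:
        bin_width = np.log2(self.f_max / self.f_min) * 12.0 / self.n_bins
        return F0BinGrid(self.f_min, self.f_max, bin_width)

    @classmethod
    def full_scale(cls, **kw) -> "DatasetConfig":
        kw.setdefault("n_bins", 700)
        kw.setdefault("exemplars_per_bin", 3000)
        return cls(**kw)


def total_examples(config: DatasetConfig) -> int:
    """Total dataset size implied by a config (computed, not materialized)."""
    return config.n_bins * config.exemplars_per_bin


@dataclass
class Dataset:
    examples: list
    grid: F0BinGrid
    config: DatasetConfig

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"f0": e.f0, "bin": e.bin_index, "snr": e.snr, "level": e.level,
              **e.provenance} for e in self.examples]
        )


def _resolve_profile(config: DatasetConfig) -> EnvelopeGaussian:
    if config.profile in ("speech_like", "music_like"):
        return profile_gaussian(config.profile)
    if config.profile == "matched":
        return profile_gaussian("speech_like")
    if config.profile == "antimatched":
        return antimatch(profile_gaussian("speech_like"))
    raise AudioError(f"unknown profile {config.profile!r}")


def build_dataset(
    config: DatasetConfig,
    rng: np.random.Generator,
    periphery=None,
) -> Dataset:
    """Materialize a labeled dataset.

    Exemplar counts per bin are met exactly.  F0s are drawn log-uniformly
    within each bin.  If ``periphery`` (an object with ``render``) is given,
    examples carry nervegrams; otherwise waveforms.
    """
    if config.snr_range is not None and config.snr_range[0] > config.snr_range[1]:
        raise AudioError("invalid SNR range")
    if config.level_range[0] > config.level_range[1]:
        raise AudioError("invalid level range")
    grid = config.grid()
    gauss = _resolve_profile(config)
    noise_gauss = profile_gaussian("noise_like")
    nfreqs = np.logspace(np.log10(50.0), np.log10(16000.0), 128)
    examples = []
    for b in range(grid.n_bins):
        lo, hi = grid.edges[b], grid.edges[b + 1]
        for _ in range(config.exemplars_per_bin):
            f0 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            w = sample_matched_tone(gauss, f0, rng, config.duration,
                                    config.sample_rate)
            if config.filter_mode is not None:
                w = random_filter_variant(w, config.filter_mode, rng)
            snr = None
            if config.snr_range is not None:
                snr = float(rng.uniform(*config.snr_range))
                env_db = 10.0 * np.log10(
                    np.maximum(noise_gauss.sample_envelope(rng, nfreqs), 1e-12) ** 2)
                noise = masking_noise("spectrally_matched", config.duration,
                                      config.sample_rate, rng,
                                      envelope_db=(nfreqs, env_db))
                w = mix_at_snr(w, noise, snr)
            level = float(rng.uniform(*config.level_range))
            w = set_level(w, level)
            x = periphery.render(w) if periphery is not None else w
            examples.append(LabeledExample(
                input=x, f0=f0, bin_index=b, snr=snr, level=level,
                provenance={"profile": config.profile}))
    return Dataset(examples, grid, config)
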