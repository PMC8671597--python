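"""Synthesis of the psychoacoustic stimuli.

Every stimulus class used for training and for the simulated psychophysical
experiments is synthesized here, deterministically given a seeded generator:

* harmonic complex tones with controllable phase relations (sine, cosine,
  random, alternating), per-component levels, and per-component frequency
  shifts;
* frequency-shifted complexes under the three fixed-shape spectral envelopes
  of the pitch-shift matching experiment (flat passband plus
  ``(10**x - 1)/9`` slopes, ``x = 1 - |(F - F_e) / (1.5 * F0)|``);
* complexes with a single mistuned harmonic;
* transposed tones (half-wave-rectified low-frequency envelope, lowpassed at
  20% of the carrier frequency, multiplied onto a high-frequency carrier);
* masking noises: modified uniform masking noise (flat 15 dB/Hz SPL below
  600 Hz, -2 dB/octave above), threshold-equalizing noise (equal power per
  ERB), and spectrally matched noise (envelope drawn from a cepstral
  Gaussian);
* the translatable bandpass filter used to set the lowest audible harmonic.

No onset/offset ramps are applied; users who need them can window the
returned samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .audio import (
    AudioError,
    P_REF,
    Waveform,
    component_amplitude,
    db_spl_to_rms,
    set_level,
    time_vector,
)

__all__ = [
    "HarmonicSpec",
    "SpectralEnvelopeMoore",
    "MOORE_ENVELOPES",
    "make_harmonic_complex",
    "harmonic_complex",
    "moore_envelope_value",
    "frequency_shift_complex",
    "mistuned_complex",
    "transposed_tone",
    "masking_noise",
    "bandpass_translate",
    "translated_filter_magnitude",
    "erb_hz",
    "erb_number",
]


# ---------------------------------------------------------------------------
# ERB helpers (Glasberg & Moore human auditory filter scale)
# ---------------------------------------------------------------------------

def erb_hz(f: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth of the human auditory filter at f (Hz)."""
    return 24.7 * (4.37 * np.asarray(f, dtype=float) / 1000.0 + 1.0)


def erb_number(f: np.ndarray | float) -> np.ndarray | float:
    """Cumulative ERB-number (Cam) scale."""
    return 21.4 * np.log10(0.00437 * np.asarray(f, dtype=float) + 1.0)


def erb_number_to_hz(n: np.ndarray | float) -> np.ndarray | float:
    return (10 ** (np.asarray(n, dtype=float) / 21.4) - 1.0) / 0.00437


# ---------------------------------------------------------------------------
# Harmonic complex tones
# ---------------------------------------------------------------------------

PHASE_MODES = ("sine", "cosine", "random", "alternating")


@dataclass
class HarmonicSpec:
    """Recipe for a harmonic (or slightly inharmonic) complex tone.

    ``component_shifts`` are per-component frequency offsets expressed in
    percent of F0, so component ``n`` sits at ``f0 * (n + shift_n / 100)``
    when ``shift_is_common`` (a common Hz offset, as in the frequency-shift
    experiment) or ``f0 * n * (1 + shift_n / 100)`` otherwise (proportional
    mistuning, as in the mistuned-harmonic experiment).
    """

    f0: float
    harmonic_numbers: Sequence[int]
    component_levels: Sequence[float] | float = 60.0
    phase_mode: str = "sine"
    component_shifts: Sequence[float] | float = 0.0
    shift_is_common: bool = False

    def __post_init__(self):
        h = np.asarray(self.harmonic_numbers, dtype=int)
        if h.size == 0:
            raise AudioError("empty harmonic list")
        if np.any(np.diff(h) <= 0) or np.any(h < 1):
            raise AudioError("harmonic_numbers must be strictly increasing positive integers")
        if self.phase_mode not in PHASE_MODES:
            raise AudioError(f"unknown phase_mode {self.phase_mode!r}")
        self.harmonic_numbers = h
        self.component_levels = np.broadcast_to(
            np.asarray(self.component_levels, dtype=float), h.shape
        ).copy()
        self.component_shifts = np.broadcast_to(
            np.asarray(self.component_shifts, dtype=float), h.shape
        ).copy()

    def component_frequencies(self) -> np.ndarray:
        n = self.harmonic_numbers.astype(float)
        s = self.component_shifts / 100.0
        if self.shift_is_common:
            return self.f0 * (n + s)
        return self.f0 * n * (1.0 + s)


def _phases(spec: HarmonicSpec, rng: np.random.Generator | None) -> np.ndarray:
    n = spec.harmonic_numbers
    if spec.phase_mode == "sine":
        return np.zeros(n.shape)
    if spec.phase_mode == "cosine":
        return np.full(n.shape, np.pi / 2.0)
    if spec.phase_mode == "alternating":
        # odd harmonics in sine phase, even harmonics in cosine phase
        return np.where(n % 2 == 0, np.pi / 2.0, 0.0)
    if rng is None:
        raise AudioError("random phase mode requires an rng")
    return rng.uniform(0.0, 2.0 * np.pi, size=n.shape)


def make_harmonic_complex(
    spec: HarmonicSpec,
    duration: float,
    sample_rate: float = 32000,
    rng: np.random.Generator | None = None,
) -> Waveform:
    """Sum of sinusoids at the spec's component frequencies and levels."""
    if duration <= 0:
        raise AudioError("duration must be positive")
    freqs = spec.component_frequencies()
    if np.any(freqs <= 0):
        raise AudioError("shifted component frequency not positive")
    if np.any(freqs >= sample_rate / 2):
        raise AudioError(
            f"component at {freqs.max():.1f} Hz exceeds the Nyquist frequency"
        )
    t = time_vector(duration, sample_rate)
    phases = _phases(spec, rng)
    amps = component_amplitude(spec.component_levels)
    x = np.zeros_like(t)
    for f, a, p in zip(freqs, amps, phases):
        x += a * np.sin(2.0 * np.pi * f * t + p)
    w = Waveform(x, sample_rate)
    w.meta.update(f0=spec.f0, phase_mode=spec.phase_mode)
    return w


def harmonic_complex(
    f0: float,
    duration: float,
    sample_rate: float = 32000,
    phase_mode: str = "sine",
    component_level: float = 50.0,
    max_freq: float | None = None,
    rng: np.random.Generator | None = None,
) -> Waveform:
    """Equal-amplitude complex with all harmonics up to ``max_freq``.

    ``max_freq`` defaults to just below the Nyquist frequency.
    """
    if max_freq is None:
        max_freq = sample_rate / 2 * 0.999
    n_max = int(np.floor(max_freq / f0))
    if n_max < 1:
        raise AudioError("f0 above the requested maximum frequency")
    spec = HarmonicSpec(
        f0=f0,
        harmonic_numbers=np.arange(1, n_max + 1),
        component_levels=component_level,
        phase_mode=phase_mode,
    )
    return make_harmonic_complex(spec, duration, sample_rate, rng)


# ---------------------------------------------------------------------------
# Fixed-shape spectral envelopes (pitch-shift matching experiment)
# ---------------------------------------------------------------------------

@dataclass
class SpectralEnvelopeMoore:
    """F0-dependent spectral envelope: flat harmonic passband plus slopes.

    The envelope is 1 inside a flat passband ``width`` harmonics wide centered
    at harmonic number ``center``.  On the flanks the amplitude at frequency F
    is ``(10**x - 1)/9`` with ``x = 1 - |(F - F_e)/(1.5 * F0)|`` where ``F_e``
    is the nearer passband edge, and 0 wherever ``x <= 0``.
    """

    kind: str
    center: float
    width: float

    @property
    def slope_scale(self) -> float:
        return 1.5  # slope extent in units of F0


MOORE_ENVELOPES = {
    "low_harmonics": SpectralEnvelopeMoore("low_harmonics", center=5, width=3),
    "mid_harmonics": SpectralEnvelopeMoore("mid_harmonics", center=11, width=5),
    "high_harmonics": SpectralEnvelopeMoore("high_harmonics", center=16, width=5),
}


def moore_envelope_value(
    freq: np.ndarray | float, envelope: SpectralEnvelopeMoore, f0: float
) -> np.ndarray | float:
    """Envelope amplitude in [0, 1] at ``freq`` for a given F0."""
    f = np.asarray(freq, dtype=float)
    lo = (envelope.center - envelope.width / 2.0) * f0
    hi = (envelope.center + envelope.width / 2.0) * f0
    edge = np.where(f < lo, lo, hi)
    x = 1.0 - np.abs((f - edge) / (1.5 * f0))
    slope = np.where(x > 0, (10.0**np.clip(x, 0, None) - 1.0) / 9.0, 0.0)
    out = np.where((f >= lo) & (f <= hi), 1.0, slope)
    return out if out.ndim else float(out)


def frequency_shift_complex(
    f0: float,
    envelope: SpectralEnvelopeMoore | str,
    shift: float,
    level: float = 70.0,
    duration: float = 0.150,
    sample_rate: float = 32000,
) -> Waveform:
    """Cosine-phase complex with all components offset by ``shift`` %F0.

    Component n sits at ``(n + shift/100) * f0``; amplitudes are weighted by
    the envelope evaluated at the shifted frequencies; the overall level is
    then set to ``level`` dB SPL.
    """
    if isinstance(envelope, str):
        try:
            envelope = MOORE_ENVELOPES[envelope]
        except KeyError:
            raise AudioError(f"unknown envelope kind {envelope!r}") from None
    n_max = int(np.floor(sample_rate / 2 / f0)) - 1
    n = np.arange(1, max(n_max, 2))
    freqs = (n + shift / 100.0) * f0
    weights = moore_envelope_value(freqs, envelope, f0)
    keep = (weights > 0) & (freqs < sample_rate / 2)
    if not np.any(keep):
        raise AudioError("no audible components under the envelope")
    # equal-amplitude cosine-phase components, envelope imposed multiplicatively
    base_level = 60.0
    amps_db = base_level + 20.0 * np.log10(weights[keep])
    spec = HarmonicSpec(
        f0=f0,
        harmonic_numbers=n[keep],
        component_levels=amps_db,
        phase_mode="cosine",
        component_shifts=np.full(keep.sum(), shift),
        shift_is_common=True,
    )
    w = make_harmonic_complex(spec, duration, sample_rate)
    w = set_level(w, level)
    w.meta.update(envelope=envelope.kind, shift_pct_f0=shift, target_f0=f0)
    return w


def mistuned_complex(
    f0: float,
    mistuned_harmonic: int,
    shift: float,
    component_level: float = 60.0,
    duration: float = 0.150,
    sample_rate: float = 32000,
) -> Waveform:
    """12 equal-amplitude sine-phase harmonics with one harmonic mistuned by ``shift`` %."""
    if not 1 <= mistuned_harmonic <= 12:
        raise AudioError("mistuned harmonic must be in 1..12")
    shifts = np.zeros(12)
    shifts[mistuned_harmonic - 1] = shift
    spec = HarmonicSpec(
        f0=f0,
        harmonic_numbers=np.arange(1, 13),
        component_levels=component_level,
        phase_mode="sine",
        component_shifts=shifts,
        shift_is_common=False,
    )
    w = make_harmonic_complex(spec, duration, sample_rate)
    w.meta.update(mistuned_harmonic=mistuned_harmonic, mistuning_pct=shift, target_f0=f0)
    return w


# ---------------------------------------------------------------------------
# Transposed tones
# ---------------------------------------------------------------------------

def transposed_tone(
    carrier: float,
    envelope_freq: float,
    level: float = 70.0,
    duration: float = 0.150,
    sample_rate: float = 32000,
) -> Waveform:
    """High-frequency carrier amplitude-modulated by a rectified low-frequency sinusoid.

    The half-wave-rectified envelope sinusoid is lowpass filtered by a
    4th-order Butterworth at 20% of the carrier frequency before
    multiplication; the overall level is set afterwards.
    """
    cutoff = 0.2 * carrier
    if envelope_freq >= cutoff:
        raise AudioError("envelope frequency must lie below the 20%-of-carrier cutoff")
    if carrier * 1.2 >= sample_rate / 2:
        raise AudioError("carrier too close to Nyquist for the modulation sidebands")
    t = time_vector(duration, sample_rate)
    env = np.maximum(np.sin(2.0 * np.pi * envelope_freq * t), 0.0)
    sos = sps.butter(4, cutoff, btype="low", fs=sample_rate, output="sos")
    env = sps.sosfiltfilt(sos, env)
    x = env * np.sin(2.0 * np.pi * carrier * t)
    w = set_level(Waveform(x, sample_rate), level)
    w.meta.update(carrier=carrier, envelope_freq=envelope_freq, target_f0=envelope_freq)
    return w


# ---------------------------------------------------------------------------
# Masking noises
# ---------------------------------------------------------------------------

def _uniform_masking_spectrum_level(f: np.ndarray) -> np.ndarray:
    """Modified uniform masking noise: 15 dB/Hz SPL below 600 Hz, -2 dB/oct above."""
    f = np.asarray(f, dtype=float)
    with np.errstate(divide="ignore"):
        rolloff = 15.0 - 2.0 * np.log2(np.maximum(f, 600.0) / 600.0)
    return np.where(f <= 600.0, 15.0, rolloff)


def masking_noise(
    kind: str,
    duration: float,
    sample_rate: float = 32000,
    rng: np.random.Generator | None = None,
    ten_level_per_erb: float = 10.0,
    envelope_db: tuple[np.ndarray, np.ndarray] | None = None,
) -> Waveform:
    """Gaussian noise shaped in the frequency domain to a target spectrum level.

    kinds
    -----
    ``modified_uniform``
        flat 15 dB/Hz SPL below 600 Hz, rolling off at 2 dB/octave above.
    ``threshold_equalizing``
        equal power per ERB (``ten_level_per_erb`` dB SPL per ERB) on the
        human ERB scale.
    ``spectrally_matched``
        spectrum level profile supplied via ``envelope_db`` as
        ``(freqs_hz, level_db_per_hz)``; used by the synthetic-dataset module.
    """
    if duration <= 0:
        raise AudioError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng()
    n = int(round(duration * sample_rate))
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    if kind == "modified_uniform":
        spec_level = _uniform_masking_spectrum_level(freqs)
    elif kind == "threshold_equalizing":
        spec_level = ten_level_per_erb - 10.0 * np.log10(erb_hz(np.maximum(freqs, 1.0)))
    elif kind == "spectrally_matched":
        if envelope_db is None:
            raise AudioError("spectrally_matched noise needs an envelope_db profile")
        ef, el = envelope_db
        spec_level = np.interp(freqs, ef, el, left=el[0], right=el[-1])
    else:
        raise AudioError(f"unknown masking noise kind {kind!r}")
    psd = P_REF**2 * 10.0 ** (spec_level / 10.0)  # Pa^2 / Hz, one-sided
    # white unit-variance noise has one-sided PSD 2/sample_rate... more simply:
    # shape a unit-variance white sequence, whose one-sided PSD is 1/(fs/2).
    white = rng.standard_normal(n)
    gain = np.sqrt(psd * sample_rate / 2.0)
    gain[freqs <= 0] = 0.0  # no DC
    x = np.fft.irfft(np.fft.rfft(white) * gain, n=n)
    w = Waveform(x, sample_rate)
    w.meta.update(noise_kind=kind)
    return w


# ---------------------------------------------------------------------------
# Translatable bandpass filter (lowest-audible-harmonic experiment)
# ---------------------------------------------------------------------------

_REF_BAND = (2500.0, 3500.0)  # -3 dB passband of the reference 4th-order Butterworth


def _reference_filter_magnitude(sample_rate: float, n_points: int = 8192):
    """|H(f)| of the reference bandpass on a fine grid, plus its -15 dB low edge."""
    sos = sps.butter(4, _REF_BAND, btype="bandpass", fs=sample_rate, output="sos")
    f = np.linspace(0.0, sample_rate / 2.0, n_points)
    _, h = sps.sosfreqz(sos, worN=f, fs=sample_rate)
    mag = np.abs(h)
    db = 20.0 * np.log10(np.maximum(mag, 1e-12))
    below = np.flatnonzero((f < _REF_BAND[0]) & (db < -15.0))
    edge_idx = below[-1]
    # linear interpolation of the -15 dB crossing
    f0_, f1_ = f[edge_idx], f[edge_idx + 1]
    d0, d1 = db[edge_idx], db[edge_idx + 1]
    edge = f0_ + (f1_ - f0_) * (-15.0 - d0) / (d1 - d0)
    return f, mag, edge


def translated_filter_magnitude(
    freqs: np.ndarray, lowest_audible_freq: float, sample_rate: float = 32000
) -> np.ndarray:
    """Magnitude response of the reference filter translated along frequency.

    The translation places the low-frequency edge of the -15 dB passband at
    ``lowest_audible_freq``.  Outside the original design grid the response
    is taken as zero.
    """
    grid, mag, edge = _reference_filter_magnitude(sample_rate)
    delta = lowest_audible_freq - edge
    hi_edge = _upper_edge_15db(grid, mag)
    if lowest_audible_freq <= 0 or hi_edge + delta >= sample_rate / 2:
        raise AudioError("translated passband falls outside (0, Nyquist)")
    return np.interp(np.asarray(freqs, dtype=float) - delta, grid, mag, left=0.0, right=0.0)


def _upper_edge_15db(grid: np.ndarray, mag: np.ndarray) -> float:
    db = 20.0 * np.log10(np.maximum(mag, 1e-12))
    above = np.flatnonzero((grid > _REF_BAND[1]) & (db < -15.0))
    return grid[above[0]]


def bandpass_translate(w: Waveform, lowest_audible_freq: float) -> Waveform:
    """Apply the translated bandpass as zero-phase magnitude multiplication."""
    if lowest_audible_freq <= 0:
        raise AudioError("lowest_audible_freq must be positive")
    n = w.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / w.sample_rate)
    mag = translated_filter_magnitude(freqs, lowest_audible_freq, w.sample_rate)
    x = np.fft.irfft(np.fft.rfft(w.samples) * mag, n=n)
    out = Waveform(x, w.sample_rate, dict(w.meta))
    out.meta["filter_low_edge_hz"] = lowest_audible_freq
    return out
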