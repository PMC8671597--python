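"""Waveform container and level/SNR conventions.

All sounds in the package are carried as :class:`Waveform` objects: sampled
sound-pressure signals in pascals.  Sound levels follow the standard acoustic
convention, dB SPL = 20*log10(rms / 20 uPa).  "Level per component" always
means the rms level of that partial alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

P_REF = 20e-6  # 20 micropascals, the SPL reference pressure
DEFAULT_SR = 32000


class AudioError(ValueError):
    """Raised for invalid synthesis or level requests."""


@dataclass
class Waveform:
    """A sound-pressure signal.

    Parameters
    ----------
    samples : ndarray
        Pressure samples in pascals.
    sample_rate : float
        Sampling rate in Hz (> 0).
    """

    samples: np.ndarray
    sample_rate: float = DEFAULT_SR
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise AudioError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def level_db_spl(self) -> float:
        r = self.rms()
        if r == 0:
            return -np.inf
        return 20.0 * np.log10(r / P_REF)

    def copy(self) -> "Waveform":
        return Waveform(self.samples.copy(), self.sample_rate, dict(self.meta))


def n_samples_for(duration: float, sample_rate: float) -> int:
    return int(round(duration * sample_rate))


def time_vector(duration: float, sample_rate: float) -> np.ndarray:
    n = n_samples_for(duration, sample_rate)
    return np.arange(n) / sample_rate


def db_spl_to_rms(level: float) -> float:
    """Pressure rms (Pa) for a given dB SPL level."""
    return P_REF * 10 ** (level / 20.0)


def component_amplitude(level: float) -> float:
    """Peak amplitude of a sinusoid whose own rms level is `level` dB SPL."""
    return np.sqrt(2.0) * db_spl_to_rms(level)


def set_level(w: Waveform, level: float) -> Waveform:
    """Scale a waveform to an overall level in dB SPL.

    Set-then-measure round-trips to well within 0.01 dB.
    """
    r = w.rms()
    if r == 0:
        raise AudioError("cannot set the level of a silent waveform")
    scale = db_spl_to_rms(level) / r
    out = Waveform(w.samples * scale, w.sample_rate, dict(w.meta))
    out.meta["level_db_spl"] = level
    return out


def mix_at_snr(signal: Waveform, noise: Waveform, snr: float) -> Waveform:
    """Add noise to a signal at a requested SNR (rms ratio, in dB).

    The signal is left untouched; the noise is rescaled.  Sample rates and
    lengths must match.
    """
    if signal.sample_rate != noise.sample_rate:
        raise AudioError("sample rates differ")
    if signal.n_samples != noise.n_samples:
        raise AudioError("lengths differ")
    s_rms, n_rms = signal.rms(), noise.rms()
    if n_rms == 0:
        raise AudioError("zero-power noise with finite SNR requested")
    if s_rms == 0:
        raise AudioError("zero-power signal with finite SNR requested")
    target_noise_rms = s_rms / 10 ** (snr / 20.0)
    out = Waveform(
        signal.samples + noise.samples * (target_noise_rms / n_rms),
        signal.sample_rate,
        dict(signal.meta),
    )
    out.meta["snr_db"] = snr
    return out


def write_wav(path, w: Waveform, sidecar: bool = True) -> None:
    """Persist as 32-bit float RIFF WAV plus a JSON sidecar of metadata."""
    path = Path(path)
    wavfile.write(path, int(w.sample_rate), w.samples.astype(np.float32))
    if sidecar:
        meta = {k: v for k, v in w.meta.items() if _jsonable(v)}
        meta["sample_rate"] = w.sample_rate
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_wav(path) -> Waveform:
    sr, x = wavfile.read(path)
    w = Waveform(np.asarray(x, dtype=np.float64), float(sr))
    side = Path(path).with_suffix(Path(path).suffix + ".json")
    if side.exists():
        w.meta.update(json.loads(side.read_text()))
    return w


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
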