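"""Unit-level tuning analyses of trained networks.

Treats network units as model neurons: time-averaged activations to harmonic
complex tones (45 dB SPL per component, in threshold-equalizing noise at
10 dB SPL per ERB) define per-unit F0 tuning curves on a 1/16-semitone grid
over 80-640 Hz, for five harmonic compositions (pure tones and successive
harmonics 1-9, 2-10, 4-12, 6-14).  F0 tuning strength of a unit is the mean
Pearson correlation between its pure-tone curve and each complex-tone
curve; inharmonic controls use a fixed random jitter pattern (offsets
uniform on +-50% of F0 with rejection sampling so adjacent components stay
at least 30 Hz apart at the enforcement F0), averaged across seeds; the
population response is activation versus lowest harmonic number (1-15) at
each unit's best F0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import AudioError, Waveform
from .dataset import F0BinGrid
from .stimuli import HarmonicSpec, make_harmonic_complex, masking_noise

__all__ = [
    "TuningStimuli",
    "JitterPattern",
    "jitter_pattern",
    "apply_jitter",
    "tuning_stimuli",
    "unit_tuning_curves",
    "f0_tuning_strength",
    "layer_tuning_summary",
    "population_response_lowest_harmonic",
]

COMPOSITIONS = {
    "pure_tone": None,
    "harmonics_1_9": (1, 9),
    "harmonics_2_10": (2, 10),
    "harmonics_4_12": (4, 12),
    "harmonics_6_14": (6, 14),
}

COMPONENT_LEVEL = 45.0
TEN_LEVEL_PER_ERB = 10.0
STIM_DURATION = 0.150
SAMPLE_RATE = 32000.0


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass
class TuningStimuli:
    """The tuning stimulus battery: compositions x log-spaced F0s."""

    f0s: np.ndarray
    compositions: tuple
    bin_grid: F0BinGrid

    @property
    def n_stimuli(self) -> int:
        return len(self.compositions) * len(self.f0s)


def tuning_stimuli(n_f0s: int = 2304, f0_range=(80.0, 640.0),
                   compositions=tuple(COMPOSITIONS)) -> TuningStimuli:
    """Full battery: 5 compositions x 2304 F0s (11,520 stimuli)."""
    f0s = np.geomspace(*f0_range, n_f0s)
    grid = F0BinGrid(f0_range[0], f0_range[1], 1.0 / 16.0)
    return TuningStimuli(f0s, tuple(compositions), grid)


@dataclass
class JitterPattern:
    """Fixed per-harmonic-number frequency offsets in fractions of F0."""

    offsets: dict  # harmonic number -> offset in [-0.5, 0.5]
    enforcement_f0: float
    seed: int | None = None


def jitter_pattern(rng: np.random.Generator, max_harmonic: int = 30,
                   enforcement_f0: float = 80.0, min_spacing_hz: float = 30.0,
                   max_attempts: int = 100000) -> JitterPattern:
    """Draw a jitter pattern by rejection sampling.

    Offsets for harmonics 2..max are uniform on [-0.5, 0.5] (the fundamental
    component is unjittered); the pattern is accepted only if every pair of
    adjacent shifted components is at least ``min_spacing_hz`` apart at the
    enforcement F0 (the minimum tested F0, so the constraint holds for all
    stimuli).
    """
    for _ in range(max_attempts):
        j = np.zeros(max_harmonic + 1)
        j[2:] = rng.uniform(-0.5, 0.5, size=max_harmonic - 1)
        comps = (np.arange(1, max_harmonic + 1) + j[1:]) * enforcement_f0
        if np.all(np.diff(comps) >= min_spacing_hz):
            return JitterPattern(
                {n: float(j[n]) for n in range(1, max_harmonic + 1)},
                enforcement_f0)
    raise AudioError("jitter rejection sampling failed")


def apply_jitter(f0: float, harmonics: np.ndarray,
                 pattern: JitterPattern | None) -> np.ndarray:
    """Component frequencies for a (possibly jittered) complex."""
    harmonics = np.asarray(harmonics, dtype=int)
    if pattern is None:
        return harmonics * f0
    off = np.array([pattern.offsets.get(int(n), 0.0) for n in harmonics])
    return (harmonics + off) * f0


def _render_tuning_stimulus(f0: float, composition, pattern,
                            rng: np.random.Generator) -> Waveform:
    if composition is None:  # pure tone at 45 dB SPL
        harmonics = np.array([1])
    else:
        harmonics = np.arange(composition[0], composition[1] + 1)
    freqs = apply_jitter(f0, harmonics, pattern)
    nyq = SAMPLE_RATE / 2
    keep = (freqs > 0) & (freqs < nyq)
    t = np.arange(int(round(STIM_DURATION * SAMPLE_RATE))) / SAMPLE_RATE
    from .audio import component_amplitude

    a = component_amplitude(COMPONENT_LEVEL)
    x = np.zeros_like(t)
    for f in freqs[keep]:
        x += a * np.sin(2 * np.pi * f * t)
    nz = masking_noise("threshold_equalizing", STIM_DURATION, SAMPLE_RATE,
                       rng, ten_level_per_erb=TEN_LEVEL_PER_ERB)
    return Waveform(x + nz.samples, SAMPLE_RATE, {"f0": f0})


# ---------------------------------------------------------------------------
# Tuning curves and metrics
# ---------------------------------------------------------------------------

def _normalize_rates(results, rates: np.ndarray) -> np.ndarray:
    model = getattr(results, "model", None)
    if model is not None and hasattr(model, "normalize_input"):
        return model.normalize_input(rates)
    return rates


def _time_average_units(act: np.ndarray) -> np.ndarray:
    """Collapse a batch of layer activations to (batch, units).

    Convolutional activations (B, F, T, C) average over the time axis,
    units being (frequency position, channel); fully connected activations
    (B, N) pass through.
    """
    if act.ndim == 4:
        return act.mean(axis=2).reshape(act.shape[0], -1)
    return act


def unit_tuning_curves(results, stimuli: TuningStimuli, layer: str,
                       rng: np.random.Generator,
                       periphery=None, pattern: JitterPattern | None = None,
                       batch: int = 64):
    """Bin-averaged, unit-max-normalized tuning curves for one layer.

    Returns ``(curves, excluded)`` where curves is a dict
    composition -> (n_units, n_bins) array and ``excluded`` the count of
    all-zero units (excluded from analysis, NaN rows).
    """
    from .periphery import PeripheryModel

    periphery = periphery or PeripheryModel()
    names = results.network.layer_names()
    if layer not in names:
        raise AudioError(f"unknown layer {layer!r}; have {names}")
    grid = stimuli.bin_grid
    bins = np.clip(np.searchsorted(grid.edges, stimuli.f0s, side="right") - 1,
                   0, grid.n_bins - 1)
    responses = {}
    for comp_name in stimuli.compositions:
        comp = COMPOSITIONS[comp_name]
        resp_rows = []
        for k in range(0, len(stimuli.f0s), batch):
            ngs = []
            for f0 in stimuli.f0s[k:k + batch]:
                w = _render_tuning_stimulus(f0, comp, pattern, rng)
                ngs.append(_normalize_rates(results, periphery.render(w).rates))
            acts = results.layer_activations(np.stack(ngs), rng)
            resp_rows.append(_time_average_units(np.asarray(acts[layer])))
        resp = np.concatenate(resp_rows)  # (n_stim, n_units)
        curve = np.full((grid.n_bins, resp.shape[1]), np.nan)
        for b in np.unique(bins):
            curve[b] = resp[bins == b].mean(axis=0)
        responses[comp_name] = curve.T  # (units, bins)
    # unit-max normalization over the full stimulus set
    stack = np.concatenate([np.nan_to_num(c) for c in responses.values()],
                           axis=1)
    unit_max = stack.max(axis=1)
    excluded = int(np.sum(unit_max <= 0))
    safe = np.where(unit_max > 0, unit_max, np.nan)
    curves = {k: v / safe[:, None] for k, v in responses.items()}
    return curves, excluded


def _final_layer_response(results, X, rng):
    return results.network.forward(np.asarray(X, dtype=np.float32),
                                   train=False, rng=rng)


def f0_tuning_strength(unit_curves: dict) -> float:
    """Mean Pearson r between the pure-tone curve and each complex curve.

    ``unit_curves`` maps composition name to a 1-D curve for one unit.
    Zero-variance pairs are skipped (and make the result NaN if all are)."""
    pure = np.asarray(unit_curves["pure_tone"], dtype=float)
    rs = []
    for name, c in unit_curves.items():
        if name == "pure_tone":
            continue
        c = np.asarray(c, dtype=float)
        ok = np.isfinite(pure) & np.isfinite(c)
        if ok.sum() < 3 or pure[ok].std() == 0 or c[ok].std() == 0:
            continue
        rs.append(np.corrcoef(pure[ok], c[ok])[0, 1])
    return float(np.mean(rs)) if rs else float("nan")


def layer_tuning_strengths(curves: dict) -> np.ndarray:
    """Per-unit tuning strength for a layer's curve dict."""
    n_units = next(iter(curves.values())).shape[0]
    return np.array([
        f0_tuning_strength({k: v[u] for k, v in curves.items()})
        for u in range(n_units)])


def layer_tuning_summary(results, stimuli: TuningStimuli,
                         rng: np.random.Generator, periphery=None,
                         jitter_seeds: tuple = (), layers=None) -> pd.DataFrame:
    """Mean F0 tuning strength per layer, harmonic and (optionally)
    inharmonic regimes (inharmonic averaged across jitter seeds)."""
    layers = layers or results.network.layer_names()
    rows = []
    for layer in layers:
        curves, excl = unit_tuning_curves(results, stimuli, layer, rng,
                                          periphery)
        strengths = layer_tuning_strengths(curves)
        row = {"layer": layer,
               "harmonic_tuning": float(np.nanmean(strengths)),
               "n_units": len(strengths), "excluded": excl}
        if jitter_seeds:
            vals = []
            for seed in jitter_seeds:
                pat = jitter_pattern(np.random.default_rng(seed))
                jc, _ = unit_tuning_curves(results, stimuli, layer, rng,
                                           periphery, pattern=pat)
                vals.append(np.nanmean(layer_tuning_strengths(jc)))
            row["inharmonic_tuning"] = float(np.mean(vals))
        rows.append(row)
    return pd.DataFrame(rows)


def population_response_lowest_harmonic(
        results, rng: np.random.Generator, periphery=None,
        n_f0s: int = 64, f0_range=(80.0, 640.0),
        lowest_harmonics=tuple(range(1, 16)), batch: int = 64) -> np.ndarray:
    """Population mean response vs lowest harmonic number (9-harmonic
    complexes), at each final-layer unit's best F0."""
    from .periphery import PeripheryModel

    periphery = periphery or PeripheryModel()
    f0s = np.geomspace(*f0_range, n_f0s)
    n_low = len(lowest_harmonics)
    resp = np.empty((n_low, n_f0s, results.model.grid.n_bins))
    for a, low in enumerate(lowest_harmonics):
        for k in range(0, n_f0s, batch):
            ngs = []
            for f0 in f0s[k:k + batch]:
                w = _render_tuning_stimulus(f0, (low, low + 8), None, rng)
                ngs.append(_normalize_rates(results, periphery.render(w).rates))
            resp[a, k:k + len(ngs)] = _final_layer_response(
                results, np.stack(ngs), rng)
    unit_max = np.abs(resp).max(axis=(0, 1))
    unit_max = np.where(unit_max > 0, unit_max, np.nan)
    norm = resp / unit_max  # normalized per unit
    best_f0 = np.nanargmax(norm.mean(axis=0), axis=0)  # per unit
    units = np.arange(resp.shape[2])
    tuning = norm[:, best_f0, units]  # (n_low, units)
    return np.nanmean(tuning, axis=1)
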