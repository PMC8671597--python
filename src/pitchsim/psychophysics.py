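"""Simulated psychophysical experiments and threshold/shift statistics.

Five classic experiments plus a level experiment, all operating on any
estimator obeying the F0-estimator contract:

``estimator(stimuli, centers, octaves, rng) -> ndarray of Hz``

where ``stimuli`` is a sequence of :class:`StimulusSpec` (lazy waveform
recipes carrying the true F0), ``centers`` the per-stimulus (or shared)
prediction-window centers in Hz, and ``octaves`` the window width.  Network
estimators render audio through a periphery model; oracle estimators read the
true F0 and add seeded Gaussian noise in log-F0, which gives closed-form
expected thresholds (sqrt(2) * sigma * Phi^-1(0.707)) for validating the
harness.

Experiments (full-scale protocol sizes; every experiment accepts reduced
grids for desk-scale runs):

* A - F0 discrimination vs lowest harmonic number and phase: 600 conditions
  (2 phases x 30 lowest harmonics x 10 reference F0s, 121 stimuli within
  +-6% of each reference; 7260 pairs per reference, 72,600 trials per
  phase x harmonic condition after pooling across references).
* B - pitch of alternating-phase complexes: 3 filters x 2 nominal F0 ranges
  x 354 stimuli (2124 total); histograms of predicted/true F0 ratios in 2%
  bins, window 3 octaves.
* C - frequency-shifted complexes: 3 spectral envelopes x 7 component
  shifts x F0 grid (3917 full scale); median pitch shift per cell.
* D - individually mistuned harmonics: 3 nominal F0s x 7 shifts x 7
  harmonic numbers x 178 F0s (26,166 stimuli); mean shift per cell.
* E - pure vs transposed tones: 6144 stimuli per class, 5 reference
  frequencies 80-320 Hz; each threshold from all pairs of in-window stimuli
  (the printed protocol: 233,586 pairs from 684 stimuli).
* Level experiment: 6144 pure tones 200-800 Hz at 10 levels (10-100 dB
  SPL), SNR +20 dB, pairs within 2.7 semitones, thresholds pooled across
  frequency per level.

Thresholds are the %-difference yielding 70.7% correct on a least-squares
cumulative-normal fit, capped at 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import curve_fit
from scipy.stats import norm, pearsonr

from .audio import AudioError, Waveform, mix_at_snr, set_level
from .stimuli import (
    HarmonicSpec,
    bandpass_translate,
    frequency_shift_complex,
    harmonic_complex,
    make_harmonic_complex,
    masking_noise,
    mistuned_complex,
    transposed_tone,
)

__all__ = [
    "StimulusSpec",
    "GaussianLogF0Oracle",
    "NetworkEstimator",
    "pairwise_2afc",
    "PsychometricFunction",
    "psychometric_function",
    "ThresholdResult",
    "fit_threshold",
    "ExperimentA",
    "ExperimentB",
    "ExperimentC",
    "ExperimentD",
    "ExperimentE",
    "LevelExperiment",
    "best_threshold",
    "transition_point",
    "SimilarityScore",
    "human_similarity",
    "cohens_d",
    "bounded_metric_transform",
    "oracle_threshold_prediction",
]

CRITERION = 0.707
THRESHOLD_CAP = 100.0


# ---------------------------------------------------------------------------
# Stimulus specs and estimators
# ---------------------------------------------------------------------------

@dataclass
class StimulusSpec:
    """Lazy stimulus recipe: the true (correct-answer) F0 plus a renderer."""

    true_f0: float
    render: Callable[[np.random.Generator], Waveform]
    meta: dict = field(default_factory=dict)


class GaussianLogF0Oracle:
    """Periphery-blind oracle: the true F0 perturbed by Gaussian noise of
    ``sigma_pct`` percent in log-F0, clipped into the prediction window."""

    def __init__(self, sigma_pct: float):
        self.sigma = sigma_pct / 100.0

    def __call__(self, stimuli, centers, octaves, rng):
        f0 = np.array([s.true_f0 for s in stimuli])
        pred = f0 * np.exp(rng.normal(0.0, self.sigma, size=f0.shape))
        c = np.broadcast_to(np.asarray(centers, dtype=float), f0.shape)
        return np.clip(pred, c * 2.0 ** (-octaves / 2), c * 2.0 ** (octaves / 2))


def oracle_threshold_prediction(sigma_pct: float) -> float:
    """Closed-form 70.7% 2AFC threshold for the Gaussian log-F0 oracle (%)."""
    return math.sqrt(2.0) * sigma_pct * norm.ppf(CRITERION)


class ConstantEstimator:
    """Always reports a constant (for tie-rule checks)."""

    def __init__(self, value: float = 200.0):
        self.value = value

    def __call__(self, stimuli, centers, octaves, rng):
        return np.full(len(stimuli), self.value)


class NetworkEstimator:
    """Adapts trained F0ClassifierResults + a periphery model to the contract.

    Optionally flattens the excitation pattern of every nervegram (the
    place-cue removal control).
    """

    def __init__(self, results, periphery, flatten: bool = False,
                 passes: int | None = None):
        self.results = results
        self.periphery = periphery
        self.flatten = flatten
        self.passes = passes

    def __call__(self, stimuli, centers, octaves, rng):
        from .classifier import window_mask
        from .periphery import flatten_excitation

        X = []
        for s in stimuli:
            ng = self.periphery.render(s.render(rng))
            if self.flatten:
                ng = flatten_excitation(ng)
            X.append(self.results.model.normalize_input(ng.rates))
        scores = self.results.class_scores(np.stack(X), rng, passes=self.passes)
        grid = self.results.model.grid
        c = np.broadcast_to(np.asarray(centers, dtype=float), (len(stimuli),))
        preds = np.empty(len(stimuli))
        for i in range(len(stimuli)):
            mask = window_mask(grid, c[i], octaves)
            masked = np.where(mask, scores[i], -np.inf)
            preds[i] = grid.centers[int(np.argmax(masked))]
        return preds


# ---------------------------------------------------------------------------
# 2AFC trials and psychometric functions
# ---------------------------------------------------------------------------

def pairwise_2afc(predictions: np.ndarray, true_f0s: np.ndarray,
                  rng: np.random.Generator,
                  pair_index: tuple[np.ndarray, np.ndarray] | None = None,
                  tie_noise: float = 1e-6) -> pd.DataFrame:
    """All pairwise trials: was the higher-F0 stimulus judged higher?

    Ties in the predictions are broken by seeded additive noise of magnitude
    ``tie_noise`` times the prediction range.  Returns one row per unordered
    pair with the %F0 difference and correctness.
    """
    p = np.asarray(predictions, dtype=float)
    f = np.asarray(true_f0s, dtype=float)
    if len(p) < 2:
        raise AudioError("need at least 2 stimuli for pairwise trials")
    if pair_index is None:
        i, j = np.triu_indices(len(p), k=1)
    else:
        i, j = pair_index
    scale = p.max() - p.min()
    if scale == 0:  # all-equal predictions: ties broken on the value scale
        scale = max(np.abs(p).max(), 1.0)
    noise = rng.normal(0.0, tie_noise * scale, size=p.shape)
    pn = p + noise
    hi_is_j = f[j] > f[i]
    hi, lo = np.where(hi_is_j, j, i), np.where(hi_is_j, i, j)
    correct = pn[hi] > pn[lo]
    delta = 100.0 * (f[hi] - f[lo]) / f[lo]
    return pd.DataFrame({"delta_pct": delta, "correct": correct})


@dataclass
class PsychometricFunction:
    """Proportion correct vs % difference, with trial counts."""

    delta_pct: np.ndarray
    proportion_correct: np.ndarray
    n_trials: np.ndarray

    def pooled_with(self, other: "PsychometricFunction") -> "PsychometricFunction":
        df = pd.concat([self.to_frame(), other.to_frame()])
        g = df.groupby("delta_pct", sort=True)
        n = g["n"].sum()
        k = g["k"].sum()
        return PsychometricFunction(n.index.to_numpy(), (k / n).to_numpy(),
                                    n.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta_pct": self.delta_pct,
            "k": self.proportion_correct * self.n_trials,
            "n": self.n_trials,
        })


def psychometric_function(trials: pd.DataFrame,
                          decimals: int = 9) -> PsychometricFunction:
    """Group trials by their exact %-difference values (the grids are
    discrete by construction, so no re-binning is applied)."""
    d = trials.copy()
    d["delta_pct"] = d["delta_pct"].round(decimals)
    g = d.groupby("delta_pct", sort=True)["correct"]
    return PsychometricFunction(
        g.mean().index.to_numpy(), g.mean().to_numpy(), g.count().to_numpy())


@dataclass
class ThresholdResult:
    threshold: float  # % difference at 70.7% correct, capped at 100
    condition: dict
    flag: str = "ok"  # ok | floor | cap
    fit_params: tuple | None = None


def fit_threshold(pf: PsychometricFunction, criterion: float = CRITERION,
                  cap: float = THRESHOLD_CAP,
                  condition: dict | None = None) -> ThresholdResult:
    """Least-squares cumulative-normal fit; threshold at the criterion.

    Degenerate functions (at ceiling or at chance everywhere) return the
    smallest tested difference (floored) or the cap, with a diagnostic flag.
    """
    condition = condition or {}
    d = np.asarray(pf.delta_pct, dtype=float)
    p = np.asarray(pf.proportion_correct, dtype=float)
    pos = d > 0
    d, p, w = d[pos], p[pos], np.asarray(pf.n_trials, dtype=float)[pos]
    if len(np.unique(d)) < 2:
        raise AudioError("psychometric function needs >= 2 distinct deltas")
    floor = float(d.min())
    order = np.argsort(d)
    # at ceiling even for the smallest tested differences: no information
    # below the floor, report the floor
    if np.average(p[order[:3]], weights=w[order[:3]]) > 0.98:
        return ThresholdResult(floor, condition, "floor")
    if np.average(p, weights=w) < 0.55:
        return ThresholdResult(cap, condition, "cap")

    def model(x, mu, s):
        return norm.cdf((x - mu) / s)

    s0 = max(np.interp(criterion, p[np.argsort(d)], np.sort(d)), floor)
    try:
        popt, _ = curve_fit(model, d, p, p0=[0.0, s0], sigma=1.0 / np.sqrt(w),
                            bounds=([-cap, 1e-6], [cap, 10 * cap]),
                            maxfev=10000)
    except RuntimeError:
        return ThresholdResult(cap, condition, "cap")
    mu, s = popt
    th = mu + s * norm.ppf(criterion)
    flag = "ok"
    if th > cap:
        th, flag = cap, "cap"
    elif th <= 0:
        th, flag = floor, "floor"
    return ThresholdResult(float(th), condition, flag, (float(mu), float(s)))


# ---------------------------------------------------------------------------
# Shared stimulus builders
# ---------------------------------------------------------------------------

STIM_DURATION = 0.150  # 50 ms target flanked by 50 ms continuation each side
SAMPLE_RATE = 32000.0


def _masked_filtered_complex(f0, phase, low_edge, component_level=48.3,
                             noise=True):
    def render(rng):
        w = harmonic_complex(f0, STIM_DURATION, SAMPLE_RATE, phase_mode=phase,
                             component_level=component_level, rng=rng)
        w = bandpass_translate(w, low_edge)
        if noise:
            nz = masking_noise("modified_uniform", STIM_DURATION, SAMPLE_RATE,
                               rng)
            w = Waveform(w.samples + nz.samples, w.sample_rate, dict(w.meta))
        return w

    return render


def _fixed_band_alternating(f0, band, component_level=50.0, noise=True):
    sos = sps.butter(4, band, btype="bandpass", fs=SAMPLE_RATE, output="sos")

    def render(rng):
        w = harmonic_complex(f0, STIM_DURATION, SAMPLE_RATE,
                             phase_mode="alternating",
                             component_level=component_level)
        x = sps.sosfiltfilt(sos, w.samples)
        if noise:
            nz = masking_noise("modified_uniform", STIM_DURATION, SAMPLE_RATE,
                               rng)
            x = x + nz.samples
        return Waveform(x, SAMPLE_RATE, dict(w.meta))

    return render


def _noisy_tone(freq, level, snr=None, noise=True):
    def render(rng):
        w = harmonic_complex(freq, STIM_DURATION, SAMPLE_RATE,
                             phase_mode="sine", max_freq=freq * 1.5)
        w = set_level(w, level)
        if noise:
            nz = masking_noise("modified_uniform", STIM_DURATION, SAMPLE_RATE,
                               rng)
            if snr is not None:
                return set_level(mix_at_snr(w, nz, snr), level)
            return Waveform(w.samples + nz.samples, w.sample_rate, dict(w.meta))
        return w

    return render


def _transposed(carrier, env_freq, level, noise=True):
    def render(rng):
        w = transposed_tone(carrier, env_freq, level, STIM_DURATION,
                            SAMPLE_RATE)
        if noise:
            nz = masking_noise("modified_uniform", STIM_DURATION, SAMPLE_RATE,
                               rng)
            w = Waveform(w.samples + nz.samples, w.sample_rate, dict(w.meta))
        return w

    return render


# ---------------------------------------------------------------------------
# Experiment A
# ---------------------------------------------------------------------------

class ExperimentA:
    """F0 discrimination vs lowest harmonic number and harmonic phase."""

    def __init__(self, phases=("sine", "random"), n_low=tuple(range(1, 31)),
                 n_refs: int = 10, n_stimuli: int = 121,
                 f0_ref_range=(100.0, 300.0), rove_pct: float = 6.0,
                 component_level: float = 48.3, noise: bool = True):
        self.phases = tuple(phases)
        self.n_low = tuple(n_low)
        self.n_refs = n_refs
        self.n_stimuli = n_stimuli
        self.refs = np.geomspace(*f0_ref_range, n_refs)
        self.rove = rove_pct / 100.0
        self.component_level = component_level
        self.noise = noise

    @property
    def n_conditions(self) -> int:
        return len(self.phases) * len(self.n_low) * self.n_refs

    @property
    def pairs_per_reference(self) -> int:
        return self.n_stimuli * (self.n_stimuli - 1) // 2

    @property
    def trials_per_condition(self) -> int:
        return self.n_refs * self.pairs_per_reference

    def stimuli_for(self, phase, n_low, ref):
        f0s = np.geomspace(ref * (1 - self.rove), ref * (1 + self.rove),
                           self.n_stimuli)
        low_edge = n_low * ref
        return [StimulusSpec(f0, _masked_filtered_complex(
                    f0, phase, low_edge, self.component_level, self.noise),
                    {"phase": phase, "n_low": n_low, "ref": ref})
                for f0 in f0s]

    def run(self, estimator, rng: np.random.Generator) -> pd.DataFrame:
        """One 70.7% threshold per (phase, lowest harmonic number)."""
        rows = []
        for phase in self.phases:
            for n_low in self.n_low:
                pf = None
                for ref in self.refs:
                    stims = self.stimuli_for(phase, n_low, ref)
                    preds = estimator(stims, ref, 1.0, rng)
                    trials = pairwise_2afc(
                        preds, [s.true_f0 for s in stims], rng)
                    # the +-rove log grid makes %-differences identical
                    # across references, so proportions pool exactly
                    this = psychometric_function(trials)
                    pf = this if pf is None else pf.pooled_with(this)
                res = fit_threshold(pf, condition={"phase": phase,
                                                   "n_low": n_low})
                rows.append({"phase": phase, "n_low": n_low,
                             "threshold": res.threshold, "flag": res.flag})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment B
# ---------------------------------------------------------------------------

FILTER_BANDS_B = {"low_harmonics": (125.0, 625.0),
                  "mid_harmonics": (1375.0, 1875.0),
                  "high_harmonics": (3900.0, 5400.0)}
F0_RANGES_B = {125.0: (120.0, 130.0), 250.0: (240.0, 260.0)}


class ExperimentB:
    """Pitch matching of alternating-phase complexes (ratio histograms)."""

    def __init__(self, n_per_cell: int = 354, noise: bool = True,
                 histogram_bin_pct: float = 2.0, ratio_span_octaves: float = 1.5):
        self.n_per_cell = n_per_cell
        self.noise = noise
        self.bin_ratio = 1.0 + histogram_bin_pct / 100.0
        self.span = ratio_span_octaves

    @property
    def n_stimuli(self) -> int:
        return len(FILTER_BANDS_B) * len(F0_RANGES_B) * self.n_per_cell

    def histogram_edges(self) -> np.ndarray:
        n = int(np.ceil(self.span * np.log(2) / np.log(self.bin_ratio)))
        return self.bin_ratio ** np.arange(-n, n + 1)

    def run(self, estimator, rng: np.random.Generator) -> pd.DataFrame:
        edges = self.histogram_edges()
        rows = []
        for fname, band in FILTER_BANDS_B.items():
            for nominal, (lo, hi) in F0_RANGES_B.items():
                f0s = np.geomspace(lo, hi, self.n_per_cell)
                stims = [StimulusSpec(
                    f0, _fixed_band_alternating(f0, band, noise=self.noise),
                    {"filter": fname, "nominal_f0": nominal}) for f0 in f0s]
                preds = estimator(stims, f0s, 3.0, rng)
                ratios = preds / f0s
                hist, _ = np.histogram(ratios, bins=edges)
                mass = hist / hist.sum() if hist.sum() else hist.astype(float)
                centers = np.sqrt(edges[:-1] * edges[1:])
                for c, m in zip(centers, mass):
                    rows.append({"filter": fname, "nominal_f0": nominal,
                                 "ratio": c, "mass": m})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiments C and D (pitch shifts)
# ---------------------------------------------------------------------------

class ExperimentC:
    """Frequency-shifted complexes: median pitch shift per (envelope, shift)."""

    SHIFTS = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    ENVELOPES = ("low_harmonics", "mid_harmonics", "high_harmonics")

    def __init__(self, n_f0s: int = 3917, f0_range=(80.0, 480.0),
                 level: float = 70.0):
        self.n_f0s = n_f0s
        self.f0s = np.geomspace(*f0_range, n_f0s)
        self.level = level

    @property
    def n_stimuli(self) -> int:
        return len(self.ENVELOPES) * len(self.SHIFTS) * self.n_f0s

    @property
    def n_cells(self) -> int:
        return len(self.ENVELOPES) * len(self.SHIFTS)

    def run(self, estimator, rng: np.random.Generator) -> pd.DataFrame:
        rows = []
        for env in self.ENVELOPES:
            for shift in self.SHIFTS:
                stims = [StimulusSpec(
                    f0,
                    (lambda f0=f0, env=env, shift=shift: lambda rng_:
                     frequency_shift_complex(f0, env, shift, self.level,
                                             STIM_DURATION, SAMPLE_RATE))(),
                    {"envelope": env, "shift": shift}) for f0 in self.f0s]
                preds = estimator(stims, self.f0s, 1.0, rng)
                shifts = 100.0 * (preds - self.f0s) / self.f0s
                rows.append({"envelope": env, "component_shift": shift,
                             "median_shift_pct": float(np.median(shifts))})
        return pd.DataFrame(rows)


class ExperimentD:
    """Mistuned single harmonics: mean pitch shift per condition cell."""

    SHIFTS = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    HARMONICS = (1, 2, 3, 4, 5, 6, 12)
    NOMINALS = (100.0, 200.0, 400.0)

    def __init__(self, n_f0s_per_nominal: int = 178, rove_pct: float = 4.0,
                 component_level: float = 60.0):
        self.n_f0s = n_f0s_per_nominal
        self.rove = rove_pct / 100.0
        self.component_level = component_level

    @property
    def n_stimuli(self) -> int:
        return (len(self.NOMINALS) * len(self.SHIFTS) * len(self.HARMONICS)
                * self.n_f0s)

    @property
    def n_cells(self) -> int:
        return len(self.NOMINALS) * len(self.SHIFTS) * len(self.HARMONICS)

    def run(self, estimator, rng: np.random.Generator) -> pd.DataFrame:
        rows = []
        for nominal in self.NOMINALS:
            f0s = np.geomspace(nominal * (1 - self.rove),
                               nominal * (1 + self.rove), self.n_f0s)
            for harm in self.HARMONICS:
                for shift in self.SHIFTS:
                    stims = [StimulusSpec(
                        f0,
                        (lambda f0=f0, harm=harm, shift=shift: lambda rng_:
                         mistuned_complex(f0, harm, shift,
                                          self.component_level,
                                          STIM_DURATION, SAMPLE_RATE))(),
                        {"nominal": nominal, "harmonic": harm,
                         "shift": shift}) for f0 in f0s]
                    preds = estimator(stims, f0s, 1.0, rng)
                    shifts = 100.0 * (preds - f0s) / f0s
                    rows.append({"nominal_f0": nominal, "harmonic": harm,
                                 "component_shift": shift,
                                 "mean_shift_pct": float(np.mean(shifts))})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment E and the level experiment
# ---------------------------------------------------------------------------

def pair_count(n: int) -> int:
    """Number of unordered pairs among n stimuli."""
    return n * (n - 1) // 2


class ExperimentE:
    """Pure vs transposed tone discrimination at low frequencies."""

    CARRIERS = (4000.0, 6350.0, 10080.0)

    def __init__(self, n_stimuli: int = 6144, freq_range=(80.0, 320.0),
                 n_refs: int = 5, half_window_semitones: float = 1.35,
                 level: float = 70.0, noise: bool = True):
        self.n_stimuli = n_stimuli
        self.freqs = np.geomspace(*freq_range, n_stimuli)
        self.refs = np.geomspace(*freq_range, n_refs + 2)[1:-1]
        self.half_window = half_window_semitones
        self.level = level
        self.noise = noise

    def in_window(self, ref: float) -> np.ndarray:
        semis = 12.0 * np.abs(np.log2(self.freqs / ref))
        return np.flatnonzero(semis <= self.half_window)

    def _run_class(self, estimator, rng, make_spec, label) -> list[dict]:
        rows = []
        for ref in self.refs:
            idx = self.in_window(ref)
            stims = [make_spec(self.freqs[i]) for i in idx]
            preds = estimator(stims, self.freqs[idx], 1.0, rng)
            trials = pairwise_2afc(preds, self.freqs[idx], rng)
            res = fit_threshold(psychometric_function(trials),
                                condition={"class": label, "ref": ref})
            rows.append({"stimulus_class": label, "ref_freq": ref,
                         "threshold": res.threshold, "flag": res.flag,
                         "n_stimuli": len(idx),
                         "n_trials": pair_count(len(idx))})
        return rows

    def run(self, estimator, rng: np.random.Generator) -> pd.DataFrame:
        rows = self._run_class(
            estimator, rng,
            lambda f: StimulusSpec(f, _noisy_tone(f, self.level,
                                                  noise=self.noise),
                                   {"class": "pure"}),
            "pure")
        for carrier in self.CARRIERS:
            rows += self._run_class(
                estimator, rng,
                lambda f, c=carrier: StimulusSpec(
                    f, _transposed(c, f, self.level, self.noise),
                    {"class": f"transposed_{c:.0f}"}),
                f"transposed_{carrier:.0f}")
        return pd.DataFrame(rows)


class LevelExperiment:
    """Pure-tone frequency discrimination vs overall stimulus level."""

    def __init__(self, n_stimuli: int = 6144, freq_range=(200.0, 800.0),
                 levels=tuple(range(10, 101, 10)), snr: float = 20.0,
                 half_window_semitones: float = 1.35,
                 max_pairs: int | None = None):
        self.freqs = np.geomspace(*freq_range, n_stimuli)
        self.levels = tuple(levels)
        self.snr = snr
        self.half_window = half_window_semitones
        self.max_pairs = max_pairs

    def run(self, estimator, rng: np.random.Generator) -> pd.DataFrame:
        # pairs of similar frequencies, pooled across the whole range
        logs = 12.0 * np.log2(self.freqs / self.freqs[0])
        i, j = np.triu_indices(len(self.freqs), k=1)
        keep = (logs[j] - logs[i]) <= 2.0 * self.half_window
        i, j = i[keep], j[keep]
        if self.max_pairs is not None and len(i) > self.max_pairs:
            sel = rng.choice(len(i), self.max_pairs, replace=False)
            i, j = i[sel], j[sel]
        rows = []
        for level in self.levels:
            stims = [StimulusSpec(f, _noisy_tone(f, level, snr=self.snr),
                                  {"level": level}) for f in self.freqs]
            preds = estimator(stims, self.freqs, 1.0, rng)
            trials = pairwise_2afc(preds, self.freqs, rng, pair_index=(i, j))
            res = fit_threshold(psychometric_function(trials),
                                condition={"level": level})
            rows.append({"level_db_spl": level, "threshold": res.threshold,
                         "flag": res.flag})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Threshold-curve summaries and human-model similarity
# ---------------------------------------------------------------------------

def best_threshold(curve: Sequence[float]) -> float:
    """Threshold at the lowest harmonic number (n_low = 1)."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise AudioError("empty threshold curve")
    return float(curve[0])


def transition_point(curve: Sequence[float], criterion: float = 1.0):
    """First lowest-harmonic-number whose threshold exceeds the criterion
    (harmonic numbers start at 1); None if never exceeded."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise AudioError("empty threshold curve")
    above = np.flatnonzero(curve > criterion)
    return int(above[0] + 1) if above.size else None


@dataclass
class SimilarityScore:
    r: float
    n: int
    transform: str

    def __post_init__(self):
        if self.n < 3:
            raise AudioError("similarity needs >= 3 paired points")


def _interp_human(human: pd.DataFrame, x_col: str, y_col: str,
                  x_new: np.ndarray, hold_low: float | None = None) -> np.ndarray:
    h = human.sort_values(x_col)
    x, y = h[x_col].to_numpy(dtype=float), h[y_col].to_numpy(dtype=float)
    out = np.interp(x_new, x, y)
    if hold_low is not None:
        out[np.asarray(x_new) <= hold_low] = np.interp(hold_low, x, y)
    return out


def human_similarity(model_results: pd.DataFrame, human_reference: pd.DataFrame,
                     experiment_id: str) -> SimilarityScore:
    """Pearson similarity between model and human result vectors.

    Vector construction follows each experiment's convention: thresholds are
    log-transformed (A, E); shift vectors are used raw with human-side
    interpolation across the stimulus axis (C) and imputed zeros at the 12th
    harmonic (D); histogram experiments (B) correlate per-condition
    histograms and average the coefficients.
    """
    eid = experiment_id.upper()
    if eid == "A":
        vec_m, vec_h = [], []
        for phase in model_results["phase"].unique():
            m = model_results[model_results["phase"] == phase]
            h = human_reference[human_reference["condition"] == phase]
            vec_m.append(np.log(m.sort_values("n_low")["threshold"].to_numpy()))
            vec_h.append(np.log(_interp_human(
                h, "n_low", "value", m.sort_values("n_low")["n_low"].to_numpy(),
                hold_low=5.0)))
        r = pearsonr(np.concatenate(vec_m), np.concatenate(vec_h))[0]
        return SimilarityScore(float(r), sum(len(v) for v in vec_m), "log")
    if eid == "B":
        rs = []
        for (f, nom), m in model_results.groupby(["filter", "nominal_f0"]):
            h = human_reference[(human_reference["condition"] == f)
                                & (human_reference["nominal_f0"] == nom)]
            hv = np.interp(m["ratio"], h["ratio"], h["value"])
            rs.append(pearsonr(m["mass"], hv)[0])
        return SimilarityScore(float(np.mean(rs)), len(model_results), "none")
    if eid == "C":
        vec_m, vec_h = [], []
        for env in model_results["envelope"].unique():
            m = model_results[model_results["envelope"] == env].sort_values(
                "component_shift")
            h = human_reference[human_reference["condition"] == env]
            vec_m.append(m["median_shift_pct"].to_numpy())
            vec_h.append(_interp_human(h, "component_shift", "value",
                                       m["component_shift"].to_numpy()))
        r = pearsonr(np.concatenate(vec_m), np.concatenate(vec_h))[0]
        return SimilarityScore(float(r), sum(map(len, vec_m)), "none")
    if eid == "D":
        m = model_results.sort_values(["nominal_f0", "harmonic",
                                       "component_shift"])
        vals_h = []
        for _, row in m.iterrows():
            if row["harmonic"] == 12:
                vals_h.append(0.0)  # inferred: no shift for high harmonics
                continue
            h = human_reference[
                (human_reference["nominal_f0"] == row["nominal_f0"])
                & (human_reference["harmonic"] == row["harmonic"])]
            vals_h.append(float(np.interp(row["component_shift"],
                                          h["component_shift"], h["value"])))
        r = pearsonr(m["mean_shift_pct"].to_numpy(), np.array(vals_h))[0]
        return SimilarityScore(float(r), len(m), "none")
    if eid == "E":
        m = model_results.sort_values(["stimulus_class", "ref_freq"])
        vals_h = []
        for _, row in m.iterrows():
            h = human_reference[
                human_reference["condition"] == row["stimulus_class"]]
            vals_h.append(float(np.interp(row["ref_freq"], h["ref_freq"],
                                          h["value"])))
        r = pearsonr(np.log(m["threshold"].to_numpy()),
                     np.log(np.array(vals_h)))[0]
        return SimilarityScore(float(r), len(m), "log")
    raise AudioError(f"unknown experiment id {experiment_id!r}")


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                 / (na + nb - 2))
    return float((a.mean() - b.mean()) / sp)


def bounded_metric_transform(r: np.ndarray | float,
                             method: str = "probit") -> np.ndarray | float:
    """Map a bounded similarity score in [-1, 1] to the real line before
    t-tests: probit of (r+1)/2 by default, or Fisher z."""
    r = np.asarray(r, dtype=float)
    if method == "probit":
        out = norm.ppf(np.clip((r + 1.0) / 2.0, 1e-9, 1 - 1e-9))
    elif method == "fisher":
        out = np.arctanh(np.clip(r, -1 + 1e-9, 1 - 1e-9))
    else:
        raise AudioError(f"unknown transform {method!r}")
    return out if out.ndim else float(out)
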