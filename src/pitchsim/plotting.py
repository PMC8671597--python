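"""Small plotting helpers for experiment results and tuning curves."""

from __future__ import annotations

import numpy as np


def plot_threshold_curves(df, ax=None, log_y=True):
    """Thresholds vs lowest harmonic number, one line per phase condition.

    Takes the tidy frame returned by ``ExperimentA.run`` (columns phase,
    n_low, threshold).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for phase, g in df.groupby("phase"):
        g = g.sort_values("n_low")
        ax.plot(g["n_low"], g["threshold"], "o-", label=str(phase), ms=3)
    ax.set_xlabel("lowest harmonic number")
    ax.set_ylabel("F0 discrimination threshold (%)")
    if log_y:
        ax.set_yscale("log")
    ax.legend(frameon=False)
    return ax


def plot_psychometric(pf, ax=None):
    """Proportion correct vs %-difference for one psychometric function."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.semilogx(pf.delta_pct, pf.proportion_correct, "ko", ms=3)
    ax.axhline(0.707, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("F0 difference (%)")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0.45, 1.02)
    return ax


def plot_tuning_curves(curves: dict, unit: int, f0_grid: np.ndarray,
                       ax=None):
    """One unit's F0 tuning curves, one line per harmonic composition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for name, c in curves.items():
        ax.semilogx(f0_grid, c[unit], label=name, lw=1)
    ax.set_xlabel("F0 (Hz)")
    ax.set_ylabel("normalized response")
    ax.legend(frameon=False, fontsize=7)
    return ax
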