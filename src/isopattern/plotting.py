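"""Autocorrelation profile plots in the style of the classical periodicity
figures: normalized counts vs distance, level 1.00 baseline, vertical bars
at multiples of 10.4 bases."""

from __future__ import annotations

from .autocorr import DinucProfile

HELICAL_REPEAT = 10.4


def plot_profile(profile: DinucProfile, ax=None, label: str | None = None):
    """Plot one smoothed profile; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    d = profile.distances
    ax.plot(d, profile.smoothed, lw=1.5, label=label or profile.dinucleotide)
    ax.axhline(1.0, color="0.6", lw=0.8)
    m = 1
    while m * HELICAL_REPEAT <= profile.d_max:
        x = m * HELICAL_REPEAT
        if x >= profile.d_min:
            ax.axvline(x, color="0.85", lw=0.8, zorder=0)
        m += 1
    ax.set_xlabel("distance (bases)")
    ax.set_ylabel("normalized counts")
    ax.set_xlim(profile.d_min, profile.d_max)
    return ax


def plot_profiles_by_class(profiles: dict[str, DinucProfile], ax=None):
    """Overlay per-isochore-class profiles (one line per class)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for label in sorted(profiles):
        plot_profile(profiles[label], ax=ax, label=label)
    ax.legend(fontsize=8)
    return ax
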