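"""Plot helpers for fitted mixture and rate models."""

from __future__ import annotations

import numpy as np
from scipy import stats


def plot_mixture(results, durations_ms, ax=None, n_bins: int = 40):
    """Histogram of durations with the fitted weighted component densities."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    d = np.asarray(durations_ms, dtype=float)
    x = d if results.domain == "linear_ms" else np.log10(d)
    ax.hist(x, bins=n_bins, density=True, alpha=0.4, label="pauses")
    grid = np.linspace(x.min(), x.max(), 400)
    total = np.zeros_like(grid)
    for tag, c in zip(("short", "long", "extra"), results.components):
        dens = c.weight * stats.norm.pdf(grid, c.mean, c.sd)
        if results.truncate_at_ms is not None:
            floor = (
                results.truncate_at_ms
                if results.domain == "linear_ms"
                else np.log10(results.truncate_at_ms)
            )
            dens = np.where(grid >= floor, dens / stats.norm.sf(floor, c.mean, c.sd), 0.0)
        total += dens
        ax.plot(grid, dens, label=f"{tag} (lambda={c.weight:.2f})")
    ax.plot(grid, total, "k--", lw=1, label="mixture")
    unit = "ms" if results.domain == "linear_ms" else "log10(ms)"
    ax.set_xlabel(f"pause duration ({unit})")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_ppc(ppc_results, ax=None):
    """Observed vs posterior-predicted count densities per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g, r in ppc_results.items():
        line, = ax.plot(r.bins, r.observed_density, marker="o", ls="-", label=f"{g} observed")
        ax.plot(r.bins, r.predicted_density, ls="--", color=line.get_color(),
                label=f"{g} predicted (TV={r.tv_distance:.2f})")
    ax.set_xlabel("pauses per fragment")
    ax.set_ylabel("probability")
    ax.legend()
    return ax


def plot_mu_differences(differences, ax=None):
    """Histograms of posterior mu differences with their HDIs shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, diff in differences.items():
        ax.hist(diff.samples, bins=60, density=True, alpha=0.4, label=name)
        ax.axvspan(diff.hdi.lower, diff.hdi.upper, alpha=0.1)
    ax.axvline(0.0, color="k", lw=1)
    ax.set_xlabel("difference in mu (pauses per fragment)")
    ax.set_ylabel("density")
    ax.legend()
    return ax
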