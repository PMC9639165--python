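"""Plotting helpers (matplotlib): psychometric curves, rate series,
selectivity heat maps.  Figure styling is deliberately minimal."""

from __future__ import annotations

import numpy as np

from .behavior import LogisticFit
from .classify import SelectivityMap
from .containers import TrialTable
from .rates import RateSeries


def plot_psychometric(trials: TrialTable, fit: LogisticFit | None = None, ax=None):
    """Proportion of T+ choices vs signed coherence, with the logistic fit."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    c = trials.df["c1"].to_numpy(float)
    y = (trials.df["choice"].to_numpy() == "T_plus").astype(float)
    for cv in np.unique(c):
        sel = c == cv
        p = y[sel].mean()
        se = np.sqrt(p * (1 - p) / sel.sum())
        ax.errorbar(cv, p, yerr=se, fmt="o", color="k")
    if fit is not None and fit.spec == "C":
        xs = np.linspace(c.min(), c.max(), 200)
        ax.plot(xs, 1 / (1 + np.exp(-(fit.beta0 + fit.beta1 * xs))), "-")
    ax.set_xlabel("signed coherence")
    ax.set_ylabel("proportion T+ choices")
    ax.set_ylim(0, 1)
    return ax


def plot_rate_series(series: RateSeries, ax=None, cmap="coolwarm"):
    """Mean rate per condition group vs time."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    groups = sorted(series.rates, key=lambda g: (isinstance(g, str), g))
    colors = plt.get_cmap(cmap)(np.linspace(0, 1, max(len(groups), 2)))
    for g, col in zip(groups, colors):
        ax.plot(series.time, series.rates[g], label=str(g), color=col)
    ax.set_xlabel(f"time from {series.alignment_event} (s)")
    ax.set_ylabel("firing rate (sp/s)")
    ax.legend(fontsize="small", title="group")
    return ax


def plot_selectivity_heatmap(smap: SelectivityMap, order=None, ax=None):
    """Per-neuron selectivity (rows) over window centers (columns)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    stat = smap.stat
    if order is not None:
        idx = [int(np.flatnonzero(smap.neuron_ids == n)[0]) for n in order]
        stat = stat[idx]
    vmax = np.nanmax(np.abs(stat)) or 1.0
    im = ax.imshow(stat, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   extent=[smap.window_centers[0], smap.window_centers[-1],
                           stat.shape[0], 0])
    ax.set_xlabel(f"time from {smap.alignment_event} (s)")
    ax.set_ylabel("neuron (sorted)")
    plt.colorbar(im, ax=ax, label=smap.statistic)
    return ax
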