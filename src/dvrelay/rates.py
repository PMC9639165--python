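"""Firing-rate estimation, buildup-rate analysis, and the P2-epoch analyses.

Rates are estimated by convolving the pooled point process with a
non-causal 100-ms boxcar, so the value at time tau is the average rate over
tau +- 50 ms.  Motion-aligned analyses of variable-duration trials exclude
spikes later than 250 ms after motion offset; each trial contributes to the
denominator only for the exposure it retains after its own cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import (BOXCAR_WIDTH, BUILDUP_SPAN, PSTH_BIN,
                     TRUNCATION_AFTER_OFFSET, WINDOW_WIDTH)
from .containers import SpikeData, TrialTable
from .windows import single_window_counts

__all__ = ["RateSeries", "BuildupResult", "P2Regression", "smooth_rate",
           "buildup_rate", "isolate_p2_component", "p2_regressions"]


@dataclass
class RateSeries:
    """Time-resolved mean rate per condition group (sp/s)."""

    time: np.ndarray                        # seconds relative to event
    rates: dict                             # group -> rate array
    n_trials: dict                          # group -> trial count
    alignment_event: str
    smoothing: str = f"boxcar {BOXCAR_WIDTH * 1e3:.0f} ms"


def _collect_spikes(spikes: SpikeData, trials: TrialTable, event: str,
                    neuron_ids, truncate: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool spike times relative to the event over trials x neurons.

    Returns (relative spike times, trial row index per spike, per-trial
    cutoff relative to the event — +inf when no truncation applies).
    """
    event_t = trials.event_times(event)
    tids = trials.trial_ids
    if truncate:
        cutoff = (trials.event_times("motion_off") + TRUNCATION_AFTER_OFFSET
                  - event_t)
    else:
        cutoff = np.full(len(tids), np.inf)
    rel_all, row_all = [], []
    for n in neuron_ids:
        for i, (tid, t0) in enumerate(zip(tids, event_t)):
            ts = spikes.spikes(n, tid)
            if len(ts) == 0:
                continue
            rel = ts - t0
            rel = rel[rel <= cutoff[i]]
            rel_all.append(rel)
            row_all.append(np.full(len(rel), i))
    if rel_all:
        return np.concatenate(rel_all), np.concatenate(row_all), cutoff
    return np.empty(0), np.empty(0, int), cutoff


def smooth_rate(spikes: SpikeData, trials: TrialTable, event: str,
                group_by: str | np.ndarray | None = None,
                span: tuple[float, float] = (-0.1, 0.6),
                neuron_ids=None, grid_step: float = 0.005,
                truncate: bool | None = None) -> RateSeries:
    """Boxcar-smoothed average firing rate, pooled over neurons and trials.

    ``group_by`` names a trial column (e.g. ``"c1"`` or ``"choice"``), or is
    an array of per-trial labels, or None (single group "all").  Truncation
    (drop spikes later than 250 ms after motion offset and shorten each
    trial's exposure accordingly) defaults to on for motion-aligned
    variable-duration data.

    rate(tau) = pooled spikes in tau +- 50 ms / pooled exposure time.
    """
    if neuron_ids is None:
        neuron_ids = spikes.neuron_ids
    if truncate is None:
        truncate = (event == "motion_on" and trials.variant == "variable_duration")
    if group_by is None:
        labels = np.array(["all"] * len(trials))
    elif isinstance(group_by, str):
        labels = trials.df[group_by].to_numpy()
    else:
        labels = np.asarray(group_by)
    groups = pd.unique(labels)

    lo, hi = span
    half = BOXCAR_WIDTH / 2
    t = np.arange(lo, hi + grid_step / 2, grid_step)
    rel, row, cutoff = _collect_spikes(spikes, trials, event, neuron_ids, truncate)

    rates: dict = {}
    n_trials: dict = {}
    n_neurons = len(neuron_ids)
    for g in groups:
        gmask = labels == g
        if not gmask.any():
            raise ValueError(f"group {g!r} has zero trials")
        gidx = np.flatnonzero(gmask)
        in_g = np.isin(row, gidx)
        s = np.sort(rel[in_g])
        # pooled spikes in tau +- half
        counts = (np.searchsorted(s, t + half, side="left")
                  - np.searchsorted(s, t - half, side="left"))
        # pooled exposure: overlap of [tau - half, tau + half] with each
        # trial's valid span (-inf, cutoff]
        cut = cutoff[gidx]
        expo = np.clip(np.minimum(cut[None, :], (t + half)[:, None])
                       - (t - half)[:, None], 0.0, BOXCAR_WIDTH).sum(axis=1)
        expo *= n_neurons
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(expo > 0, counts / expo, np.nan)
        rates[g] = r
        n_trials[g] = int(gmask.sum())
    return RateSeries(time=t, rates=rates, n_trials=n_trials,
                      alignment_event=event)


# ---------------------------------------------------------------------------
# buildup rate
# ---------------------------------------------------------------------------

@dataclass
class BuildupResult:
    onset: float | None                     # s from motion onset; None if undefined
    per_coherence: pd.DataFrame             # c, slope, slope_se
    slope_vs_coherence: float | None
    slope_se: float | None
    pvalue: float | None
    flagged: bool = False

    def summary(self) -> str:
        if self.flagged:
            return "Buildup rate: onset criterion never met (no decision-related activity)"
        return (f"Buildup onset {self.onset * 1e3:.0f} ms; "
                f"buildup-rate slope vs coherence "
                f"{self.slope_vs_coherence:.1f} +- {self.slope_se:.1f} "
                f"(sp/s/s per unit coherence, p = {self.pvalue:.2g})")


def _psth(spikes: SpikeData, trials: TrialTable, neuron_ids,
          span: tuple[float, float], bin_width: float = PSTH_BIN
          ) -> tuple[np.ndarray, dict]:
    """Truncation-aware PSTH (sp/s) per signed coherence; exposure-weighted."""
    rel, row, cutoff = _collect_spikes(spikes, trials, "motion_on", neuron_ids,
                                       truncate=trials.variant == "variable_duration")
    lo, hi = span
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    c1 = trials.df["c1"].to_numpy(float)
    n_neurons = len(neuron_ids)
    out = {}
    for c in np.unique(c1):
        gidx = np.flatnonzero(c1 == c)
        in_g = np.isin(row, gidx)
        counts, _ = np.histogram(rel[in_g], edges)
        cut = cutoff[gidx]
        expo = np.clip(np.minimum(cut[None, :], edges[1:, None])
                       - edges[:-1, None], 0.0, bin_width).sum(axis=1) * n_neurons
        with np.errstate(invalid="ignore", divide="ignore"):
            out[c] = np.where(expo > 0, counts / expo, np.nan)
    return centers, out


def buildup_rate(spikes: SpikeData, trials: TrialTable, neuron_ids=None,
                 onset_alpha: float = 0.01,
                 search_span: tuple[float, float] = (0.0, 0.6)) -> BuildupResult:
    """Buildup-rate analysis for the variable-duration motion epoch.

    Steps: (i) find the onset of decision-related activity — the first
    sliding 300-ms window (50-ms steps, motion aligned) whose counts
    discriminate the two strongest motion directions by rank-sum at
    ``onset_alpha``; the onset is the window's leading edge.  (ii) Compute
    20-ms PSTHs per signed coherence, detrend by subtracting the mean PSTH
    across coherences, and fit a line to the independent bins in
    [onset, onset + 200 ms] — the per-coherence buildup rate.  (iii) Regress
    buildup rate on signed coherence.
    """
    if neuron_ids is None:
        neuron_ids = spikes.neuron_ids
    c1 = trials.df["c1"].to_numpy(float)
    cmax = np.abs(c1).max()
    if cmax == 0 or not ((c1 == cmax).any() and (c1 == -cmax).any()):
        raise ValueError("need trials in both directions at the strongest coherence")

    # (i) onset
    strongest = np.abs(c1) == cmax
    tt = trials.subset(strongest)
    sgn = np.sign(tt.df["c1"].to_numpy(float))
    from .windows import align_counts  # local import to avoid cycle at module load
    counts = align_counts(spikes, tt, "motion_on", search_span,
                          neuron_ids=neuron_ids)
    pooled = counts.counts.sum(axis=0)      # trials x windows, pooled over neurons
    onset = None
    for w, center in enumerate(counts.window_centers):
        a = pooled[sgn > 0, w]
        b = pooled[sgn < 0, w]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        if stats.mannwhitneyu(a, b, alternative="two-sided").pvalue < onset_alpha:
            onset = float(center - WINDOW_WIDTH / 2)
            break
    if onset is None:
        return BuildupResult(onset=None, per_coherence=pd.DataFrame(),
                             slope_vs_coherence=None, slope_se=None,
                             pvalue=None, flagged=True)

    # (ii) detrended PSTH slopes over the first 200 ms of putative integration
    centers, psth = _psth(spikes, trials, neuron_ids,
                          (0.0, min(search_span[1], onset + BUILDUP_SPAN + PSTH_BIN)))
    grand = np.mean(np.vstack([psth[c] for c in sorted(psth)]), axis=0)
    sel = (centers >= onset) & (centers < onset + BUILDUP_SPAN)
    rows = []
    for c in sorted(psth):
        y = (psth[c] - grand)[sel]
        x = centers[sel]
        ok = np.isfinite(y)
        if ok.sum() < 3:
            continue
        res = stats.linregress(x[ok], y[ok])
        rows.append({"c": c, "slope": res.slope, "slope_se": res.stderr})
    per_c = pd.DataFrame(rows)

    # (iii) buildup rate vs signed coherence
    res = stats.linregress(per_c["c"], per_c["slope"])
    return BuildupResult(onset=onset, per_coherence=per_c,
                         slope_vs_coherence=float(res.slope),
                         slope_se=float(res.stderr), pvalue=float(res.pvalue))


# ---------------------------------------------------------------------------
# P2 analyses (two-pulse tasks)
# ---------------------------------------------------------------------------

def isolate_p2_component(spikes: SpikeData, trials: TrialTable,
                         neuron_ids=None,
                         span: tuple[float, float] = (-0.3, 0.6),
                         grid_step: float = 0.005) -> RateSeries:
    """Isolate the effect of the second pulse on the firing rate.

    Activity aligned to P2 onset is grouped by the strength of P2; each
    neuron's activity is detrended (subtracting its average across all
    trials) and baseline-adjusted (subtracting its mean in the 300-ms window
    around P2 onset), removing the carried P1 component.  Group series are
    averaged across neurons.
    """
    c2 = trials.df["c2"].to_numpy(float)
    if not np.isfinite(c2).any():
        raise ValueError("no trials with a second pulse (variant lacks P2?)")
    tt = trials.subset(np.isfinite(c2))
    c2 = tt.df["c2"].to_numpy(float)
    if neuron_ids is None:
        neuron_ids = spikes.neuron_ids

    groups = np.unique(c2)
    acc = None
    base_mask = None
    for n in neuron_ids:
        series = smooth_rate(spikes, tt, "p2_on", group_by=c2, span=span,
                             neuron_ids=[n], grid_step=grid_step, truncate=False)
        t = series.time
        if base_mask is None:
            base_mask = np.abs(t) <= WINDOW_WIDTH / 2 + 1e-9
            acc = {g: np.zeros(len(t)) for g in groups}
        all_mean = np.nanmean(np.vstack([series.rates[g] for g in groups]), axis=0)
        for g in groups:
            detr = series.rates[g] - all_mean
            detr = detr - np.nanmean(detr[base_mask])
            acc[g] += detr
    rates = {g: acc[g] / len(neuron_ids) for g in groups}
    n_trials = {g: int((c2 == g).sum()) for g in groups}
    return RateSeries(time=t, rates=rates, n_trials=n_trials,
                      alignment_event="p2_on",
                      smoothing=f"boxcar {BOXCAR_WIDTH * 1e3:.0f} ms, detrended, baseline-adjusted")


@dataclass
class P2Regression:
    """Regressions of the P2-epoch responses on the pulse strengths.

    R_start (300-ms window centered at P2 onset) tests whether the carried
    P1 evidence sets the starting level: R_start = alpha0 + alpha1 * C1st.
    R_end (300-ms window centered 300 ms after P2 onset) tests whether P2
    updates it: R_end = alpha0 + alpha1 * C1st + beta1 * C2nd with the
    alphas inherited (fixed) from the first fit.  Both are computed on
    correct trials, per-neuron standardized responses, separately for T+ and
    T- choices; the reported p-value is the larger of the two.
    """

    alpha0: float
    alpha1: float
    beta1: float
    p_alpha1: float                 # larger of the two choice groups
    p_beta1: float
    per_choice: pd.DataFrame
    skipped_groups: list = field(default_factory=list)


def p2_regressions(spikes: SpikeData, trials: TrialTable, neuron_ids,
                   min_group: int = 10) -> P2Regression:
    """Fit the P2-epoch regressions on correct, non-catch trials.

    ``neuron_ids`` selects the pool that holds the decision variable in the
    P2 epoch (leaders in variant 1, supporters in variant 2).  Responses are
    z-scored within neuron across included trials, then pooled.
    """
    df = trials.df
    keep = np.isfinite(df["c2"].to_numpy(float)) & df["correct"].to_numpy(bool)
    tt = trials.subset(keep)
    if len(tt) == 0:
        raise ValueError("no correct two-pulse trials")
    r_start = single_window_counts(spikes, tt, "p2_on", 0.0,
                                   WINDOW_WIDTH, neuron_ids).astype(float)
    r_end = single_window_counts(spikes, tt, "p2_on", 0.300,
                                 WINDOW_WIDTH, neuron_ids).astype(float)
    # per-neuron standardization
    for arr in (r_start, r_end):
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        arr -= mu
        arr /= sd

    c1 = tt.df["c1"].to_numpy(float)
    c2 = tt.df["c2"].to_numpy(float)
    choice = tt.choice_sign()
    n_neurons = len(neuron_ids)
    rows, skipped = [], []
    for side, name in ((1, "T_plus"), (-1, "T_minus")):
        sel = choice == side
        if sel.sum() < min_group:
            warnings.warn(f"choice group {name} has {sel.sum()} trials (< {min_group}); skipped")
            skipped.append(name)
            continue
        ys = r_start[:, sel].ravel()
        ye = r_end[:, sel].ravel()
        x1 = np.tile(c1[sel], n_neurons)
        x2 = np.tile(c2[sel], n_neurons)
        f8 = sm.OLS(ys, sm.add_constant(x1)).fit()
        a0, a1 = f8.params
        resid = ye - (a0 + a1 * x1)
        f9 = sm.OLS(resid, x2[:, None]).fit()
        rows.append({"choice": name, "alpha0": a0, "alpha1": a1,
                     "alpha1_se": f8.bse[1], "p_alpha1": f8.pvalues[1],
                     "beta1": f9.params[0], "beta1_se": f9.bse[0],
                     "p_beta1": f9.pvalues[0], "n_trials": int(sel.sum())})
    if not rows:
        raise ValueError("all choice groups too small")
    per = pd.DataFrame(rows)
    return P2Regression(
        alpha0=float(per["alpha0"].mean()),
        alpha1=float(per["alpha1"].mean()),
        beta1=float(per["beta1"].mean()),
        p_alpha1=float(per["p_alpha1"].max()),
        p_beta1=float(per["p_beta1"].max()),
        per_choice=per, skipped_groups=skipped)
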