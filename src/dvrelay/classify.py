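"""Leader/supporter/other categorization and sliding-window selectivity.

A neuron is a *leader* when its response field contains a choice target
while the evidence is viewed, and a *supporter* when it contains a choice
target from the gaze direction taken up during/after the intervening eye
movement (IEM).  Roles are assigned post hoc from the epochs in which a
neuron exhibits *sustained* decision-related activity: three consecutive,
consistent (same selectivity sign), individually significant tests in
overlapping 300-ms windows shifted by 50 ms (spanning >= 400 ms).

Choice selectivity (variable-duration task) uses the rank-sum test between
T+ and T- choice trials, with d' as the displayed magnitude.  The two-pulse
tasks preserve a graded quantity, so selectivity there is the Kendall tau
rank correlation of window counts with the signed strength of P1 (or, after
P2, with the sum of the pulse strengths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (IEM_END_BEFORE_REACQ, IEM_START_AFTER_SACCADE,
                     MOTION_EPOCH, P2_EPOCH, SUSTAINED_ALPHA,
                     SUSTAINED_MIN_WINDOWS, WINDOW_STEP, WINDOW_WIDTH)
from .containers import SpikeData, TrialTable, WindowedCounts
from .windows import align_counts

__all__ = [
    "SelectivityMap", "ClassificationResult", "selectivity_map",
    "sustained_selectivity", "classify_neurons", "selectivity_heatmap_order",
    "population_continuity",
]


@dataclass
class SelectivityMap:
    """Per-neuron, per-window selectivity statistics.

    ``stat`` is d' (choice selectivity) or Kendall tau (graded correlation),
    shape (n_neurons, n_windows); ``pvalue`` holds the per-window test
    p-values (rank-sum for d', tau test for Kendall).
    """

    statistic: str                 # "dprime" | "kendall"
    alignment_event: str
    window_centers: np.ndarray
    neuron_ids: np.ndarray
    stat: np.ndarray
    pvalue: np.ndarray

    @property
    def sign(self) -> np.ndarray:
        return np.sign(self.stat)


def dprime(x_plus: np.ndarray, x_minus: np.ndarray) -> float:
    """Standardized separation (mean difference / pooled SD); 0 if SD = 0."""
    n1, n2 = len(x_plus), len(x_minus)
    if n1 < 2 or n2 < 2:
        return 0.0
    v1, v2 = x_plus.var(ddof=1), x_minus.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if pooled == 0:
        return 0.0
    return float((x_plus.mean() - x_minus.mean()) / pooled)


def selectivity_map(counts: WindowedCounts, trials: TrialTable,
                    statistic: str = "dprime",
                    target: np.ndarray | None = None) -> SelectivityMap:
    """Compute a selectivity map from windowed counts.

    ``statistic="dprime"`` tests T+ vs T- choice trials per window with the
    rank-sum test and reports d'.  ``statistic="kendall"`` correlates counts
    with ``target`` (signed coherence or pulse sum) using Kendall tau; scipy
    enumerates the exact null for small tie-free samples and uses the
    tie-corrected normal approximation otherwise.
    """
    n_neurons, n_trials, n_windows = counts.counts.shape
    stat = np.zeros((n_neurons, n_windows))
    pval = np.ones((n_neurons, n_windows))
    if statistic == "dprime":
        plus = trials.choice_sign() > 0
        for ni in range(n_neurons):
            for w in range(n_windows):
                x = counts.counts[ni, :, w]
                a, b = x[plus], x[~plus]
                stat[ni, w] = dprime(a, b)
                if len(a) and len(b) and (np.ptp(x) > 0):
                    pval[ni, w] = stats.mannwhitneyu(
                        a, b, alternative="two-sided").pvalue
    elif statistic == "kendall":
        if target is None:
            raise ValueError("kendall statistic requires a target array")
        target = np.asarray(target, float)
        if len(target) != n_trials:
            raise ValueError("target length mismatch")
        for ni in range(n_neurons):
            for w in range(n_windows):
                x = counts.counts[ni, :, w]
                if np.ptp(x) == 0 or np.ptp(target) == 0:
                    continue
                tau, p = stats.kendalltau(x, target)
                stat[ni, w] = tau
                pval[ni, w] = p
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return SelectivityMap(statistic=statistic,
                          alignment_event=counts.alignment_event,
                          window_centers=counts.window_centers,
                          neuron_ids=counts.neuron_ids, stat=stat, pvalue=pval)


def sustained_selectivity(smap: SelectivityMap, neuron_id: int,
                          epoch: tuple[float, float],
                          alpha: float = SUSTAINED_ALPHA,
                          min_windows: int = SUSTAINED_MIN_WINDOWS) -> bool:
    """Sustained selectivity: >= ``min_windows`` consecutive windows inside
    ``epoch``, each significant at ``alpha`` with a consistent sign.

    ``epoch`` is (lo, hi) in the map's aligned time; a window belongs to the
    epoch when it lies entirely inside it.  Raises when the epoch is too
    short to hold the required consecutive windows (criterion undefined).
    """
    lo, hi = epoch
    need = WINDOW_WIDTH + (min_windows - 1) * WINDOW_STEP
    if hi - lo < need - 1e-9:
        raise ValueError(
            f"epoch {epoch} shorter than {need:.3f} s; sustained criterion undefined")
    c = smap.window_centers
    inside = (c - WINDOW_WIDTH / 2 >= lo - 1e-9) & (c + WINDOW_WIDTH / 2 <= hi + 1e-9)
    idx = np.flatnonzero(inside)
    if len(idx) < min_windows:
        raise ValueError(f"epoch {epoch} covered by fewer than {min_windows} windows")
    ni = int(np.flatnonzero(smap.neuron_ids == neuron_id)[0])
    sig = smap.pvalue[ni, idx] < alpha
    sgn = np.sign(smap.stat[ni, idx])
    for start in range(len(idx) - min_windows + 1):
        run_sig = sig[start: start + min_windows]
        run_sgn = sgn[start: start + min_windows]
        if run_sig.all() and run_sgn[0] != 0 and (run_sgn == run_sgn[0]).all():
            return True
    return False


@dataclass
class ClassificationResult:
    neuron_id: int
    config_id: int
    label: str                       # leader | supporter | other
    evidence: dict                   # epoch name -> bool (criterion met)


def _median_offset(trials: TrialTable, later: str, earlier: str) -> float:
    return float(np.median(trials.event_times(later) - trials.event_times(earlier)))


def _epoch_maps(spikes: SpikeData, trials: TrialTable, variant: str,
                neuron_ids=None) -> dict[str, tuple[SelectivityMap, tuple[float, float]]]:
    """Selectivity maps and epoch intervals used by the categorization rules."""
    maps: dict[str, tuple[SelectivityMap, tuple[float, float]]] = {}
    c1 = trials.df["c1"].to_numpy(float)

    def tp_map(event, span, use_pulse_sum, sub=None):
        tt = trials if sub is None else trials.subset(sub)
        counts = align_counts(spikes, tt, event, span, neuron_ids=neuron_ids)
        tgt = tt.df["c1"].to_numpy(float)
        if use_pulse_sum:
            tgt = tgt + tt.df["c2"].to_numpy(float)
        return selectivity_map(counts, tt, "kendall", target=tgt)

    if variant == "variable_duration":
        motion_span = (0.0, MOTION_EPOCH)
        counts = align_counts(spikes, trials, "motion_on", motion_span,
                              neuron_ids=neuron_ids)
        maps["motion"] = (selectivity_map(counts, trials, "dprime"), motion_span)
        iem_hi = _median_offset(trials, "fp_reacquired", "saccade_T0") - IEM_END_BEFORE_REACQ
        iem_span = (0.0, iem_hi)
        counts = align_counts(spikes, trials, "saccade_T0", iem_span,
                              neuron_ids=neuron_ids)
        maps["iem"] = (selectivity_map(counts, trials, "dprime"),
                       (IEM_START_AFTER_SACCADE, iem_hi))
    elif variant == "two_pulse_v1":
        maps["p1"] = (tp_map("motion_on", (0.0, MOTION_EPOCH), False),
                      (0.0, MOTION_EPOCH))
        iem_hi = _median_offset(trials, "fp_reacquired", "saccade_T0") - IEM_END_BEFORE_REACQ
        maps["iem"] = (tp_map("saccade_T0", (0.0, iem_hi), False),
                       (IEM_START_AFTER_SACCADE, iem_hi))
        noncatch = np.isfinite(trials.df["c2"].to_numpy(float))
        maps["p2_c1"] = (tp_map("p2_on", (0.0, P2_EPOCH), False, sub=noncatch),
                         (0.0, P2_EPOCH))
        maps["p2_sum"] = (tp_map("p2_on", (0.0, P2_EPOCH), True, sub=noncatch),
                          (0.0, P2_EPOCH))
    elif variant == "two_pulse_v2":
        maps["p1"] = (tp_map("motion_on", (0.0, MOTION_EPOCH), False),
                      (0.0, MOTION_EPOCH))
        maps["p2_c1"] = (tp_map("p2_on", (0.0, P2_EPOCH), False),
                         (0.0, P2_EPOCH))
        maps["p2_sum"] = (tp_map("p2_on", (0.0, P2_EPOCH), True),
                          (0.0, P2_EPOCH))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return maps


def classify_neurons(spikes: SpikeData, trials: TrialTable,
                     variant: str | None = None,
                     neuron_ids=None) -> list[ClassificationResult]:
    """Label each neuron leader / supporter / other, per target configuration.

    Sessions interleaving two target configurations are handled by
    classifying each ``config_id`` independently (the same neuron may hold
    different labels under different configurations).

    Rules (sustained = 3 consecutive consistent significant windows):

    * variable duration — leader: sustained choice selectivity in the 600-ms
      motion-viewing epoch and *not* in the IEM epoch (250 ms after the
      saccade to T0 until 200 ms before FP reacquisition); supporter:
      sustained choice selectivity in the IEM epoch.
    * two-pulse variant 1 — same epochs with Kendall tau against signed P1
      (or the P1+P2 sum after P2); a leader must additionally be sustained
      during the 600-ms epoch after P2 onset.
    * two-pulse variant 2 — leader and supporter must show sustained
      activity after P1 or after P2, but not both (leader: P1 only;
      supporter: P2 only).
    """
    if neuron_ids is None:
        neuron_ids = spikes.neuron_ids
    results: list[ClassificationResult] = []
    for cfg in sorted(trials.df["config_id"].unique()):
        sub = trials.subset(trials.df["config_id"].to_numpy() == cfg)
        var = variant or sub.variant
        maps = _epoch_maps(spikes, sub, var, neuron_ids=neuron_ids)

        def sus(name, nid):
            smap, epoch = maps[name]
            return sustained_selectivity(smap, nid, epoch)

        for nid in neuron_ids:
            if var == "variable_duration":
                ev = {"motion": sus("motion", nid), "iem": sus("iem", nid)}
                if ev["iem"]:
                    label = "supporter"
                elif ev["motion"]:
                    label = "leader"
                else:
                    label = "other"
            elif var == "two_pulse_v1":
                ev = {"p1": sus("p1", nid), "iem": sus("iem", nid),
                      "p2": sus("p2_c1", nid) or sus("p2_sum", nid)}
                if ev["iem"]:
                    label = "supporter"
                elif ev["p1"] and ev["p2"]:
                    label = "leader"
                else:
                    label = "other"
            else:  # two_pulse_v2
                ev = {"p1": sus("p1", nid),
                      "p2": sus("p2_c1", nid) or sus("p2_sum", nid)}
                if ev["p1"] and not ev["p2"]:
                    label = "leader"
                elif ev["p2"] and not ev["p1"]:
                    label = "supporter"
                else:
                    label = "other"
            results.append(ClassificationResult(neuron_id=int(nid),
                                                config_id=int(cfg),
                                                label=label, evidence=ev))
    return results


def classification_table(results: list[ClassificationResult]) -> pd.DataFrame:
    rows = [{"neuron_id": r.neuron_id, "config_id": r.config_id,
             "label": r.label, **{f"epoch_{k}": v for k, v in r.evidence.items()}}
            for r in results]
    return pd.DataFrame(rows)


def selectivity_heatmap_order(smap: SelectivityMap, role: str,
                              t_first_saccade: float | None = None) -> np.ndarray:
    """Neuron order for selectivity heat maps.

    Leaders are ordered by the time of maximum |stat| up to the first
    saccade; supporters by the time of maximum |stat| over the whole map.
    The sort is stable with ties broken by neuron_id.
    """
    c = smap.window_centers
    if role == "leader":
        if t_first_saccade is None:
            raise ValueError("leader ordering requires t_first_saccade")
        mask = c <= t_first_saccade
        if not mask.any():
            raise ValueError("no windows before the first saccade")
    elif role == "supporter":
        mask = np.ones(len(c), bool)
    else:
        raise ValueError(f"role must be leader or supporter, got {role!r}")
    sub = np.abs(smap.stat[:, mask])
    t_max = c[mask][sub.argmax(axis=1)]
    order = np.lexsort((smap.neuron_ids, t_max))
    return smap.neuron_ids[order]


def population_continuity(spikes: SpikeData, trials: TrialTable,
                          alpha: float = SUSTAINED_ALPHA,
                          neuron_ids=None) -> pd.DataFrame:
    """Population-level continuity of the decision representation.

    Tiles the trial from motion/P1 onset to the choice saccade with sliding
    windows aligned piecewise to motion onset, the saccade to T0 (where the
    variant has one), FP/T0 reacquisition and (two-pulse) P2 onset, and asks
    whether at least one neuron is significantly selective in every window.

    Returns one row per window with the segment name, window center and the
    number of significant neurons.
    """
    variant = trials.variant
    segments: list[tuple[str, str, float, float]] = []
    if variant in ("variable_duration", "two_pulse_v1"):
        segments.append(("motion", "motion_on", 0.0,
                         _median_offset(trials, "saccade_T0", "motion_on")))
        segments.append(("iem", "saccade_T0", 0.0,
                         _median_offset(trials, "fp_reacquired", "saccade_T0")))
        end_ev = "fp_reacquired"
    else:
        segments.append(("motion", "motion_on", 0.0,
                         _median_offset(trials, "fp_reacquired", "motion_on")))
        end_ev = "fp_reacquired"
    segments.append(("post", end_ev, 0.0,
                     _median_offset(trials, "choice_saccade", end_ev)))

    use_tau = variant != "variable_duration"
    noncatch = (np.isfinite(trials.df["c2"].to_numpy(float))
                if variant == "two_pulse_v1" else np.ones(len(trials), bool))
    rows = []
    for name, event, lo, hi in segments:
        if hi - lo < WINDOW_WIDTH:
            continue
        tt = trials
        counts = align_counts(spikes, tt, event, (lo, hi), neuron_ids=neuron_ids)
        if use_tau:
            smap = selectivity_map(counts, tt, "kendall",
                                   target=tt.df["c1"].to_numpy(float))
        else:
            smap = selectivity_map(counts, tt, "dprime")
        n_sig = (smap.pvalue < alpha).sum(axis=0)
        for w, center in enumerate(counts.window_centers):
            rows.append({"segment": name, "event": event, "center": center,
                         "n_significant": int(n_sig[w])})
    return pd.DataFrame(rows)
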