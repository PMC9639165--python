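"""Session-level pairwise analysis: epoch counts for classified
leader/supporter pairs and the CorCE table with permutation nulls.

The three 300-ms epochs bracket the intervening eye movement: *pre* begins
200 ms after motion/P1 onset; *IEM* begins 50 ms after the supporter neuron
starts to exhibit sustained decision-related activity (estimated from its
selectivity map); *post* is centered on P2 onset (two-pulse tasks) or
300 ms after reacquisition of the fixation point (variable duration, where
no second pulse exists).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import selectivity_map
from .config import (IEM_START_AFTER_SACCADE, PRE_EPOCH_AFTER_P1,
                     IEM_WINDOW_AFTER_START, SUSTAINED_ALPHA,
                     SUSTAINED_MIN_WINDOWS, WINDOW_WIDTH)
from .containers import SpikeData, TrialTable
from .corce import mediation_regressions, permutation_null
from .windows import align_counts, single_window_counts

__all__ = ["supporter_activity_start", "pair_epoch_counts",
           "pairwise_corce_table", "session_mediation"]


def _iem_alignment(variant: str) -> str:
    return "saccade_T0" if variant in ("variable_duration", "two_pulse_v1") \
        else "fp_reacquired"


def supporter_activity_start(spikes: SpikeData, trials: TrialTable,
                             neuron_id: int) -> float | None:
    """Leading edge of the first sustained-selectivity window triple.

    Time is relative to the IEM alignment event (saccade to T0, or pursuit
    completion in variant 2).  Returns None when the neuron never meets the
    sustained criterion in the IEM span.
    """
    variant = trials.variant
    event = _iem_alignment(variant)
    end = float(np.median(trials.event_times("choice_saccade")
                          - trials.event_times(event)))
    counts = align_counts(spikes, trials, event, (0.0, end),
                          neuron_ids=[neuron_id])
    if variant == "variable_duration":
        smap = selectivity_map(counts, trials, "dprime")
    else:
        smap = selectivity_map(counts, trials, "kendall",
                               target=trials.df["c1"].to_numpy(float))
    sig = smap.pvalue[0] < SUSTAINED_ALPHA
    sgn = np.sign(smap.stat[0])
    k = SUSTAINED_MIN_WINDOWS
    for start in range(len(sig) - k + 1):
        if sig[start: start + k].all() and sgn[start] != 0 \
                and (sgn[start: start + k] == sgn[start]).all():
            return float(smap.window_centers[start] - WINDOW_WIDTH / 2)
    return None


def pair_epoch_counts(spikes: SpikeData, trials: TrialTable, leader_id: int,
                      supporter_id: int,
                      iem_start: float | None = None) -> pd.DataFrame:
    """Per-trial epoch counts for one leader-supporter pair.

    Returns a DataFrame with columns ``c1, choice, l_pre, s_iem, l_post``
    plus the swapped-epoch controls ``s_pre, l_iem, s_post`` (counts of each
    neuron in the epochs where it does *not* represent the decision).
    Two-pulse catch trials are excluded (the post epoch needs P2 onset).
    """
    variant = trials.variant
    if variant != "variable_duration":
        trials = trials.subset(np.isfinite(trials.df["c2"].to_numpy(float)))
    if iem_start is None:
        iem_start = supporter_activity_start(spikes, trials, supporter_id)
        if iem_start is None:
            iem_start = IEM_START_AFTER_SACCADE
    iem_event = _iem_alignment(variant)
    nids = [leader_id, supporter_id]

    pre = single_window_counts(spikes, trials, "motion_on",
                               PRE_EPOCH_AFTER_P1 + WINDOW_WIDTH / 2,
                               neuron_ids=nids)
    iem = single_window_counts(spikes, trials, iem_event,
                               iem_start + IEM_WINDOW_AFTER_START + WINDOW_WIDTH / 2,
                               neuron_ids=nids)
    if variant == "variable_duration":
        post = single_window_counts(spikes, trials, "fp_reacquired", 0.300,
                                    neuron_ids=nids)
    else:
        post = single_window_counts(spikes, trials, "p2_on", 0.0,
                                    neuron_ids=nids)
    return pd.DataFrame({
        "c1": trials.df["c1"].to_numpy(float),
        "choice": trials.choice_sign(),
        "l_pre": pre[0], "s_iem": iem[1], "l_post": post[0],
        "s_pre": pre[1], "l_iem": iem[0], "s_post": post[1],
    })


#: epoch pairs reported in the CorCE table; informative pairs straddle a
#: handoff, uninformative controls pair the epochs where the neurons do not
#: carry the decision variable
EPOCH_PAIRS = (
    ("l_pre", "s_iem", True),
    ("s_iem", "l_post", True),
    ("l_pre", "l_post", True),
    ("l_iem", "s_pre", False),
)


def pairwise_corce_table(spikes: SpikeData, trials: TrialTable,
                         labels: pd.DataFrame, phi: float = 0.6,
                         n_perm: int = 1000,
                         seed: int | None = None) -> pd.DataFrame:
    """CorCE with permutation null for every classified leader x supporter
    pair in a session.

    ``labels`` is the classification table (columns ``neuron_id, config_id,
    label``).  Rows hold the pair, the epoch pair, CorCE, the permutation
    null mean/SD and the two-sided p-value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cfg in sorted(labels["config_id"].unique()):
        lab = labels[labels["config_id"] == cfg]
        tt = trials.subset(trials.df["config_id"].to_numpy() == cfg)
        leaders = lab.loc[lab["label"] == "leader", "neuron_id"].tolist()
        supporters = lab.loc[lab["label"] == "supporter", "neuron_id"].tolist()
        for lid in leaders:
            for sid in supporters:
                ep = pair_epoch_counts(spikes, tt, lid, sid)
                cond = ep["c1"].to_numpy()
                for a, b, informative in EPOCH_PAIRS:
                    perm = permutation_null(ep[a].to_numpy(), ep[b].to_numpy(),
                                            cond, phi, n_perm=n_perm, seed=rng)
                    rows.append({
                        "config_id": cfg, "leader": lid, "supporter": sid,
                        "epoch_pair": f"{a}:{b}", "informative": informative,
                        "corce": perm.observed, "null_mean": perm.null_mean,
                        "null_sd": perm.null_sd, "p": perm.pvalue,
                    })
    return pd.DataFrame(rows)


def session_mediation(spikes: SpikeData, trials: TrialTable, leader_id: int,
                      supporter_id: int) -> dict:
    """Mediation regressions for one pair, from session data."""
    ep = pair_epoch_counts(spikes, trials, leader_id, supporter_id)
    return mediation_regressions(ep["l_pre"], ep["s_iem"], ep["l_post"],
                                 ep["c1"], ep["choice"])
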