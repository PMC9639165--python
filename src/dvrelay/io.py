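"""Plain-text I/O for trial tables and spike data.

Formats
-------
``trials.tsv``
    Tab-separated; columns ``trial_id, task_variant, config_id, c1, c2,
    t_dur, choice, correct`` followed by one ``ev_<name>`` column per event.
    Empty fields denote undefined values (``c2`` on catch trials, events not
    part of a variant).

``spikes.tsv``
    Long format; columns ``neuron_id, trial_id, t_spike`` (seconds from
    trial start).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (ALL_EVENTS, REQUIRED_COLUMNS, SchemaError,
                         SpikeData, TrialTable)

_EV_PREFIX = "ev_"

# full precision round-trip for float64
_FLOAT_FMT = "%.17g"


def write_trials(trials: TrialTable, path: str) -> None:
    df = trials.df.copy()
    out = df[list(REQUIRED_COLUMNS)].copy()
    for ev in ALL_EVENTS:
        out[_EV_PREFIX + ev] = df[ev]
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_trials(path: str) -> TrialTable:
    """Read and validate a trials file.

    Raises :class:`~dvrelay.containers.SchemaError` when required columns are
    missing and :class:`~dvrelay.containers.ValidationError` (naming the
    offending rows) when invariants are violated.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    rename = {c: c[len(_EV_PREFIX):] for c in df.columns if c.startswith(_EV_PREFIX)}
    df = df.rename(columns=rename)
    df["correct"] = df["correct"].astype(bool)
    return TrialTable(df)


def write_spikes(spikes: SpikeData, path: str) -> None:
    neuron_col, trial_col, time_col = [], [], []
    for n in spikes.neuron_ids:
        for t, ts in sorted(spikes._spikes[n].items()):
            if len(ts) == 0:
                continue
            neuron_col.append(np.full(len(ts), n, int))
            trial_col.append(np.full(len(ts), t, int))
            time_col.append(ts)
    if neuron_col:
        df = pd.DataFrame({
            "neuron_id": np.concatenate(neuron_col),
            "trial_id": np.concatenate(trial_col),
            "t_spike": np.concatenate(time_col),
        })
    else:
        df = pd.DataFrame({"neuron_id": [], "trial_id": [], "t_spike": []})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_spikes(path: str, trials: TrialTable | None = None) -> SpikeData:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ("neuron_id", "trial_id", "t_spike")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    spikes: dict[int, dict[int, np.ndarray]] = {}
    for (n, t), grp in df.groupby(["neuron_id", "trial_id"], sort=True):
        spikes.setdefault(int(n), {})[int(t)] = np.sort(grp["t_spike"].to_numpy(float))
    return SpikeData(spikes, trial_ids=None if trials is None else trials.trial_ids)
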