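"""Shared fixtures: synthetic sessions and helpers for building tiny
trial tables and spike sets by hand."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dvrelay.containers import SpikeData, TrialTable
from dvrelay.simulate import GeneratorConfig, generate_session


def make_trials(rows: list[dict], validate: bool = True) -> TrialTable:
    """Build a TrialTable from partial row dicts (defaults filled in)."""
    defaults = {
        "task_variant": "variable_duration", "config_id": 0,
        "c1": 0.0, "c2": np.nan, "t_dur": 0.3,
        "choice": "T_plus", "correct": True,
    }
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults, trial_id=i)
        d.update(r)
        full.append(d)
    return TrialTable(pd.DataFrame(full), validate=validate)


def make_spikes(per_trial: dict[int, dict[int, list[float]]],
                trials: TrialTable | None = None) -> SpikeData:
    data = {n: {t: np.asarray(ts, float) for t, ts in by.items()}
            for n, by in per_trial.items()}
    return SpikeData(data, trial_ids=None if trials is None else trials.trial_ids)


def poisson_spike_trains(rate: float, duration: float, n_trials: int,
                         rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Homogeneous Poisson spike trains on [0, duration) per trial."""
    out = {}
    for t in range(n_trials):
        n = rng.poisson(rate * duration)
        out[t] = np.sort(rng.random(n) * duration)
    return out


@pytest.fixture(scope="session")
def vd_session():
    """Default variable-duration session (ground-truth pools, gain > 0)."""
    cfg = GeneratorConfig(task_variant="variable_duration",
                          n_trials_per_condition=150, seed=101)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def tp1_session():
    """Default two-pulse variant-1 session."""
    cfg = GeneratorConfig(task_variant="two_pulse_v1",
                          n_trials_per_condition=150, seed=102)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def tp2_session():
    """Default two-pulse variant-2 session."""
    cfg = GeneratorConfig(task_variant="two_pulse_v2",
                          n_trials_per_condition=150, seed=103)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def acceptance_session():
    """Larger default session used by the classification / continuity
    acceptance checks (10-neuron leader and supporter pools)."""
    cfg = GeneratorConfig(task_variant="variable_duration",
                          n_trials_per_condition=150,
                          n_leader=10, n_supporter=10, n_other=5,
                          pool_size_leader=10, pool_size_supporter=10,
                          seed=0)
    return generate_session(cfg)
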