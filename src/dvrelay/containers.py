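"""Core data containers: trial tables, spike data, windowed counts.

Conventions
-----------
* Time base: seconds, floating point, origin at trial start.
* A trial table is a pandas DataFrame (one row per trial) wrapped in
  :class:`TrialTable`, which validates the schema and the task invariants.
* Spike data are per-neuron, per-trial sorted arrays of spike times.
* Event columns are prefixed ``ev_`` in the on-disk schema; within the
  containers they are addressed by their bare names (``motion_on`` ...).

Variant 2 of the two-pulse task has no saccade to T0 (the only intervening
eye movement is pursuit); the time at which the gaze settles on T0 is stored
under ``fp_reacquired`` so every variant shares one "IEM complete" event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import TASK_VARIANTS

#: event order per task variant (used for monotonicity validation)
EVENT_ORDER: dict[str, tuple[str, ...]] = {
    "variable_duration": (
        "motion_on", "motion_off", "saccade_T0", "pursuit_start",
        "fp_reacquired", "go", "choice_saccade",
    ),
    "two_pulse_v1": (
        "motion_on", "motion_off", "saccade_T0", "pursuit_start",
        "fp_reacquired", "p2_on", "go", "choice_saccade",
    ),
    "two_pulse_v2": (
        "motion_on", "motion_off", "pursuit_start", "fp_reacquired",
        "p2_on", "go", "choice_saccade",
    ),
}

ALL_EVENTS: tuple[str, ...] = (
    "motion_on", "motion_off", "saccade_T0", "pursuit_start",
    "fp_reacquired", "p2_on", "go", "choice_saccade",
)

REQUIRED_COLUMNS: tuple[str, ...] = (
    "trial_id", "task_variant", "config_id", "c1", "c2", "t_dur",
    "choice", "correct",
)

CHOICES = ("T_plus", "T_minus")


class SchemaError(ValueError):
    """A file or frame does not match the documented column schema."""


class ValidationError(ValueError):
    """A row violates a trial-table invariant."""


def _sgn(x: float) -> int:
    return (x > 0) - (x < 0)


class TrialTable:
    """Validated table of behavioral trials.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain :data:`REQUIRED_COLUMNS` plus one column per event
        (bare event names).  ``c2`` is NaN when absent (catch trials and the
        variable-duration task); event times are NaN when undefined.
    validate : bool
        Run invariant checks (default True).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = df.copy().reset_index(drop=True)
        for ev in ALL_EVENTS:
            if ev not in df.columns:
                df[ev] = np.nan
        if validate:
            self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if df["trial_id"].duplicated().any():
            dups = df.loc[df["trial_id"].duplicated(), "trial_id"].tolist()
            raise ValidationError(f"duplicate trial_id values: {dups[:5]}")
        bad_rows: list[str] = []
        for idx, row in df.iterrows():
            variant = row["task_variant"]
            tid = row["trial_id"]
            if variant not in TASK_VARIANTS:
                bad_rows.append(f"row {idx} (trial {tid}): unknown task_variant {variant!r}")
                continue
            if row["choice"] not in CHOICES:
                bad_rows.append(f"row {idx} (trial {tid}): choice {row['choice']!r}")
            c1, c2 = row["c1"], row["c2"]
            if not -1 <= c1 <= 1:
                bad_rows.append(f"row {idx} (trial {tid}): c1={c1} outside [-1, 1]")
            if np.isfinite(c2):
                if not -1 <= c2 <= 1:
                    bad_rows.append(f"row {idx} (trial {tid}): c2={c2} outside [-1, 1]")
                elif c1 != 0 and c2 != 0 and _sgn(c1) != _sgn(c2):
                    bad_rows.append(
                        f"row {idx} (trial {tid}): sgn(c1) != sgn(c2) "
                        f"({c1} vs {c2}); pulses must share direction"
                    )
            if variant == "variable_duration":
                if not 0.100 - 1e-9 <= row["t_dur"] <= 0.550 + 1e-9:
                    bad_rows.append(
                        f"row {idx} (trial {tid}): t_dur={row['t_dur']} outside [0.100, 0.550]"
                    )
            times = [row[ev] for ev in EVENT_ORDER[variant] if np.isfinite(row[ev])]
            if any(b <= a for a, b in zip(times, times[1:])):
                bad_rows.append(
                    f"row {idx} (trial {tid}): event times not strictly increasing in task order"
                )
        if bad_rows:
            raise ValidationError(
                "invalid trial rows:\n" + "\n".join(bad_rows[:20])
                + ("" if len(bad_rows) <= 20 else f"\n... and {len(bad_rows) - 20} more")
            )

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        a = self.df[list(REQUIRED_COLUMNS) + list(ALL_EVENTS)]
        b = other.df[list(REQUIRED_COLUMNS) + list(ALL_EVENTS)]
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True

    @property
    def trial_ids(self) -> np.ndarray:
        return self.df["trial_id"].to_numpy()

    @property
    def variant(self) -> str:
        variants = self.df["task_variant"].unique()
        if len(variants) != 1:
            raise ValueError(f"table mixes task variants: {variants}")
        return variants[0]

    def event_times(self, event: str, trial_ids: Iterable[int] | None = None) -> np.ndarray:
        """Event time per trial; raises if the event is undefined for any trial."""
        if event not in ALL_EVENTS:
            raise KeyError(f"unknown event {event!r}")
        sub = self.df if trial_ids is None else self.df.set_index("trial_id").loc[list(trial_ids)].reset_index()
        t = sub[event].to_numpy(float)
        if np.isnan(t).any():
            bad = sub.loc[np.isnan(t), "trial_id"].tolist()
            raise ValueError(f"event {event!r} undefined for trials {bad[:10]}")
        return t

    def choice_sign(self) -> np.ndarray:
        """+1 for T+ choices, -1 for T- choices."""
        return np.where(self.df["choice"].to_numpy() == "T_plus", 1, -1)

    def subset(self, mask) -> "TrialTable":
        return TrialTable(self.df.loc[np.asarray(mask)], validate=False)


class SpikeData:
    """Per-neuron, per-trial spike timestamps (seconds from trial start).

    Internally a mapping ``neuron_id -> {trial_id -> sorted float array}``.
    Trials with no spikes may be absent from the inner mapping.
    """

    def __init__(self, spikes: Mapping[int, Mapping[int, np.ndarray]],
                 trial_ids: Iterable[int] | None = None, validate: bool = True):
        self._spikes: dict[int, dict[int, np.ndarray]] = {
            int(n): {int(t): np.asarray(ts, float) for t, ts in by_trial.items()}
            for n, by_trial in spikes.items()
        }
        self.trial_ids = (None if trial_ids is None
                          else np.asarray(list(trial_ids), int))
        if validate:
            self._validate()

    def _validate(self) -> None:
        known = set(self.trial_ids.tolist()) if self.trial_ids is not None else None
        for n, by_trial in self._spikes.items():
            for t, ts in by_trial.items():
                if known is not None and t not in known:
                    raise ValidationError(f"neuron {n}: spikes reference unknown trial {t}")
                if len(ts) and (ts < 0).any():
                    raise ValidationError(f"neuron {n}, trial {t}: negative spike time")
                if len(ts) > 1 and (np.diff(ts) < 0).any():
                    raise ValidationError(f"neuron {n}, trial {t}: spike times not sorted")

    @property
    def neuron_ids(self) -> list[int]:
        return sorted(self._spikes)

    def spikes(self, neuron_id: int, trial_id: int) -> np.ndarray:
        return self._spikes.get(int(neuron_id), {}).get(int(trial_id), np.empty(0))

    def n_spikes(self) -> int:
        return sum(len(ts) for by_trial in self._spikes.values() for ts in by_trial.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeData):
            return NotImplemented
        if self.neuron_ids != other.neuron_ids:
            return False
        for n in self.neuron_ids:
            a, b = self._spikes[n], other._spikes[n]
            keys_a = {k for k, v in a.items() if len(v)}
            keys_b = {k for k, v in b.items() if len(v)}
            if keys_a != keys_b:
                return False
            for t in keys_a:
                if not np.array_equal(a[t], b[t]):
                    return False
        return True


@dataclass
class WindowedCounts:
    """Spike counts in sliding windows aligned to a trial event.

    ``counts[n, i, w]`` is the number of spikes of neuron ``n`` (order
    ``neuron_ids``) on trial ``i`` (order ``trial_ids``) inside the half-open
    window ``[center_w - width/2, center_w + width/2)`` measured relative to
    the alignment event.
    """

    alignment_event: str
    window_width: float
    step: float
    window_centers: np.ndarray      # (n_windows,) seconds relative to event
    counts: np.ndarray              # (n_neurons, n_trials, n_windows) int
    neuron_ids: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative spike counts")
        self.window_centers = np.asarray(self.window_centers, float)
        self.neuron_ids = np.asarray(self.neuron_ids, int)
        self.trial_ids = np.asarray(self.trial_ids, int)

    def for_neuron(self, neuron_id: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.neuron_ids == neuron_id)[0])
        return self.counts[idx]
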