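"""Event-aligned sliding-window spike counting.

Windows are half-open on the right, ``[lo, hi)``, with the standard geometry
of 300 ms windows shifted by 50 ms (overridable).
"""

from __future__ import annotations

import numpy as np

from .config import WINDOW_STEP, WINDOW_WIDTH
from .containers import SpikeData, TrialTable, WindowedCounts


def window_centers(span: tuple[float, float], width: float = WINDOW_WIDTH,
                   step: float = WINDOW_STEP) -> np.ndarray:
    """Centers of all windows fully contained in ``span`` (relative times)."""
    lo, hi = span
    if hi - lo < width - 1e-12:
        raise ValueError(f"span {span} shorter than window width {width}")
    first = lo + width / 2
    n = int(np.floor((hi - lo - width) / step + 1e-9)) + 1
    return first + step * np.arange(n)


def align_counts(spikes: SpikeData, trials: TrialTable, event: str,
                 span: tuple[float, float], width: float = WINDOW_WIDTH,
                 step: float = WINDOW_STEP,
                 neuron_ids=None) -> WindowedCounts:
    """Count spikes in sliding windows aligned to a trial event.

    Parameters
    ----------
    span : (lo, hi)
        Interval, in seconds relative to the event, that must fully contain
        every window.
    width, step : float
        Window width and shift; both must be positive.

    Returns
    -------
    WindowedCounts
        ``counts[n, i, w]`` counts spikes in
        ``[center_w - width/2, center_w + width/2)`` relative to the event.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    centers = window_centers(span, width, step)
    event_t = trials.event_times(event)  # raises naming trials missing the event
    trial_ids = trials.trial_ids
    if neuron_ids is None:
        neuron_ids = spikes.neuron_ids
    neuron_ids = np.asarray(neuron_ids, int)

    edges_lo = centers - width / 2
    counts = np.zeros((len(neuron_ids), len(trial_ids), len(centers)), int)
    for ni, n in enumerate(neuron_ids):
        for ti, (tid, t0) in enumerate(zip(trial_ids, event_t)):
            ts = spikes.spikes(n, tid)
            if len(ts) == 0:
                continue
            rel = ts - t0
            # half-open [lo, lo+width): searchsorted side conventions
            lo_idx = np.searchsorted(rel, edges_lo, side="left")
            hi_idx = np.searchsorted(rel, edges_lo + width, side="left")
            counts[ni, ti] = hi_idx - lo_idx
    return WindowedCounts(
        alignment_event=event, window_width=width, step=step,
        window_centers=centers, counts=counts,
        neuron_ids=neuron_ids, trial_ids=trial_ids,
    )


def single_window_counts(spikes: SpikeData, trials: TrialTable, event: str,
                         center: float | np.ndarray,
                         width: float = WINDOW_WIDTH,
                         neuron_ids=None) -> np.ndarray:
    """Counts in one half-open window per trial, ``[c - w/2, c + w/2)``.

    ``center`` may be a scalar (same relative center on every trial) or an
    array with one relative center per trial.  Returns ``(n_neurons,
    n_trials)``.
    """
    event_t = trials.event_times(event)
    centers = np.broadcast_to(np.asarray(center, float), event_t.shape)
    trial_ids = trials.trial_ids
    if neuron_ids is None:
        neuron_ids = spikes.neuron_ids
    neuron_ids = np.asarray(neuron_ids, int)
    out = np.zeros((len(neuron_ids), len(trial_ids)), int)
    for ni, n in enumerate(neuron_ids):
        for ti, (tid, t0, c) in enumerate(zip(trial_ids, event_t, centers)):
            ts = spikes.spikes(n, tid)
            if len(ts) == 0:
                continue
            lo = t0 + c - width / 2
            out[ni, ti] = (np.searchsorted(ts, lo + width, side="left")
                           - np.searchsorted(ts, lo, side="left"))
    return out
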