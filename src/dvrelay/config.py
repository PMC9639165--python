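"""Shared constants and configuration loading.

All durations are seconds, times are measured from trial start, and the
decision variable (DV) is dimensionless (bound units).  The analysis-window
geometry and epoch offsets used throughout the pipeline live here so that no
module hard-codes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

#: Canonical signed motion coherences (fraction of coherently moving dots;
#: sign points toward the T+ choice target).
COHERENCES: tuple[float, ...] = (
    -0.64, -0.32, -0.16, -0.08, -0.04, 0.0, 0.04, 0.08, 0.16, 0.32, 0.64,
)

#: Magnitudes used when drawing independent pulse strengths.
COHERENCE_MAGNITUDES: tuple[float, ...] = (0.0, 0.04, 0.08, 0.16, 0.32, 0.64)

# ---- counting-window geometry -------------------------------------------------
WINDOW_WIDTH = 0.300   #: sliding spike-counting window width
WINDOW_STEP = 0.050    #: shift between consecutive windows

# ---- rate estimation ----------------------------------------------------------
BOXCAR_WIDTH = 0.100        #: non-causal boxcar for firing-rate smoothing
PSTH_BIN = 0.020            #: PSTH bin width for buildup-rate estimation
BUILDUP_SPAN = 0.200        #: span of putative integration used for the slope
TRUNCATION_AFTER_OFFSET = 0.250  #: spikes later than this after motion offset are dropped

# ---- epoch definitions --------------------------------------------------------
MOTION_EPOCH = 0.600        #: leader epoch: this long after motion/P1 onset
P2_EPOCH = 0.600            #: leader (variant 1) epoch after P2 onset
IEM_START_AFTER_SACCADE = 0.250   #: IEM epoch begins this long after the saccade to T0
IEM_END_BEFORE_REACQ = 0.200      #: ... and ends this long before FP reacquisition
SUSTAINED_MIN_WINDOWS = 3   #: consecutive significant windows required (>= 400 ms)
SUSTAINED_ALPHA = 0.05      #: per-window significance level

# ---- pairwise (CorCE) epochs --------------------------------------------------
PRE_EPOCH_AFTER_P1 = 0.200  #: pre-IEM 300 ms window begins this long after P1 onset
IEM_WINDOW_AFTER_START = 0.050  #: IEM window begins this long after sustained-activity start

#: pulse duration in the two-pulse tasks
PULSE_DURATION = 0.080

TASK_VARIANTS = ("variable_duration", "two_pulse_v1", "two_pulse_v2")


@dataclass
class EventTimingConfig:
    """Uniform ranges (seconds) for the per-trial event timeline."""

    targets_delay: tuple[float, float] = (0.050, 0.250)
    motion_delay: tuple[float, float] = (0.200, 0.500)
    fp_off_after_motion: float = 0.500
    saccade_latency: tuple[float, float] = (0.180, 0.220)
    t0_hold: tuple[float, float] = (0.500, 0.600)
    pursuit_duration: float = 0.733
    post_pursuit_delay: tuple[float, float] = (0.200, 0.600)
    p2_delay: tuple[float, float] = (0.500, 0.600)  # after FP/T0 reacquisition
    go_delay: float = 0.500                          # after P2 offset (two-pulse)
    choice_latency: float = 0.250

    def as_dict(self) -> dict:
        return {
            "targets_delay": self.targets_delay,
            "motion_delay": self.motion_delay,
            "fp_off_after_motion": self.fp_off_after_motion,
            "saccade_latency": self.saccade_latency,
            "t0_hold": self.t0_hold,
            "pursuit_duration": self.pursuit_duration,
            "post_pursuit_delay": self.post_pursuit_delay,
            "p2_delay": self.p2_delay,
            "go_delay": self.go_delay,
            "choice_latency": self.choice_latency,
        }


def load_config(path: str) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def validate_coherence(c: float, strict: bool = False) -> float:
    """Check a signed coherence value.

    Values must lie in [-1, 1]; with ``strict=True`` membership in the
    canonical set is enforced (the simulator's convention).
    """
    if not -1.0 <= c <= 1.0:
        raise ValueError(f"coherence {c} outside [-1, 1]")
    if strict and not any(abs(c - v) < 1e-9 for v in COHERENCES):
        raise ValueError(f"coherence {c} not in canonical set {COHERENCES}")
    return c
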