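"""Synthetic sessions: trials and spike trains with the generative structure
the analyses assume.

A single drift-diffusion decision variable (DV) drives both the behavioral
choice and the latent firing rates of two pools of neurons: *leaders*, whose
response field contains a choice target while the evidence is viewed, and
*supporters*, whose response field contains a choice target from the new
gaze direction during/after the intervening eye movement (IEM).  The DV is
relayed: supporters inherit the frozen DV (plus pool noise) at the saccade,
and in tasks where the gaze returns, the leader pool re-acquires the DV by
reading out the supporter pool's spike counts.  Spike counts are
doubly stochastic with sub-Poisson dispersion (Fano factor ``phi`` < 1).

Sub-Poisson counts
------------------
Counts are drawn per 20-ms bin from a mixture-binomial law: with integrated
intensity ``mu`` per bin, ``n`` is randomized between ``floor(mu/(1-phi))``
and that plus one, and the count is Binomial(n, mu/n); the mixture weight is
chosen so that E[count] = mu and Var[count] = phi * mu hold exactly.  Bins
with ``mu < 1 - phi`` fall back to Bernoulli(mu) — the smallest dispersion a
{0, 1}-valued count admits.  (No orderly point process can be sub-Poisson in
arbitrarily small independent bins; dispersion control at the counting-
window scale is what the analyses require.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import DDMParams
from .config import (COHERENCE_MAGNITUDES, COHERENCES, EventTimingConfig,
                     PULSE_DURATION)
from .containers import SpikeData, TrialTable

__all__ = [
    "GeneratorConfig", "Session", "simulate_dv", "simulate_dv_paths",
    "generate_session", "sample_subpoisson_counts", "simulate_pair_epochs",
    "simulate_diffusion_counts",
]

#: visual-response latency between stimulus/DV time and firing-rate time
RESPONSE_LAG = 0.050
#: overlap of pool activity around each handoff (epochs overlap at handoff)
HANDOFF_OVERLAP = 0.100
#: supporter-count readout window for the handoff back to leaders,
#: relative to the supporter pool's activation time
READOUT_WINDOW = (0.050, 0.350)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-session generator.

    Rates are in spikes/s; the DV is in bound units; ``phi`` is the Fano
    factor of the spike-count point process.  ``pool_size_*`` is the total
    number of neurons in a pool, of which ``n_leader``/``n_supporter`` are
    "recorded" (appear in the spike data); unrecorded members still shape
    the handoff readout.
    """

    task_variant: str = "variable_duration"
    n_trials_per_condition: int = 150
    ddm: DDMParams = field(default_factory=lambda: DDMParams(15.0, 1.0, 0.0))
    timing: EventTimingConfig = field(default_factory=EventTimingConfig)
    n_leader: int = 6
    n_supporter: int = 6
    n_other: int = 4
    pool_size_leader: int = 6
    pool_size_supporter: int = 6
    r0: float = 30.0           # baseline rate
    gain: float = 25.0         # sp/s per DV unit
    sigma_pool: float = 0.10   # DV noise added at each pool handoff
    sigma_member: float = 0.10 # per-neuron, per-trial DV trait noise
    phi: float = 0.6
    dt: float = 1e-3           # DV simulation step
    spike_bin: float = 0.020   # spike-count generation bin
    catch_fraction: float = 1 / 3  # variant 1 only
    t_dur_scale: float = 0.300     # truncated-exponential scale (variable duration)
    config_id: int = 0
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.phi <= 1):
            raise ValueError("phi must be in (0, 1]")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.pool_size_leader < self.n_leader or self.pool_size_supporter < self.n_supporter:
            raise ValueError("pool size smaller than number of recorded neurons")


@dataclass
class Session:
    """A generated session: trials, spikes, and ground truth for tests."""

    trials: TrialTable
    spikes: SpikeData
    truth: pd.DataFrame          # per-trial latent DV values
    labels: pd.DataFrame         # per-neuron ground-truth role and pool
    config: GeneratorConfig

    def write(self, trials_path: str, spikes_path: str,
              truth_path: str | None = None) -> None:
        from .io import write_spikes, write_trials
        write_trials(self.trials, trials_path)
        write_spikes(self.spikes, spikes_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# decision-variable simulation
# ---------------------------------------------------------------------------

def simulate_dv_paths(params: DDMParams, c: np.ndarray, n_steps: np.ndarray,
                      dt: float, rng: np.random.Generator,
                      v0: np.ndarray | float = 0.0
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Euler-Maruyama paths with absorbing bounds.

    Parameters
    ----------
    c : array (n,)
        Signed coherence per path.
    n_steps : int array (n,)
        Number of dt steps each path runs (paths are frozen at their own
        duration and, earlier, at a bound).

    Returns
    -------
    V : (n, max_steps + 1) array
        Paths, frozen at +-B once absorbed and at their terminal value after
        their own duration.
    choice : (n,) int (+1 / -1)
    absorbed : (n,) bool
    t_abs : (n,) float, absorption time (nan if not absorbed)
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    c = np.atleast_1d(np.asarray(c, float))
    n_steps = np.atleast_1d(np.asarray(n_steps, int))
    n = len(c)
    T = int(n_steps.max())
    drift = params.kappa * (c + params.C0) * dt
    incr = drift[:, None] + np.sqrt(dt) * rng.standard_normal((n, T))
    # freeze increments beyond each path's own duration
    step_idx = np.arange(1, T + 1)
    incr[step_idx[None, :] > n_steps[:, None]] = 0.0
    v0 = np.broadcast_to(np.asarray(v0, float), (n,))
    V = np.empty((n, T + 1))
    V[:, 0] = v0
    np.cumsum(incr, axis=1, out=V[:, 1:])
    V[:, 1:] += v0[:, None]

    B = params.B
    hit = np.abs(V[:, 1:]) >= B
    absorbed = hit.any(axis=1)
    first = np.where(absorbed, hit.argmax(axis=1) + 1, T + 1)
    # freeze at the bound from the first crossing on
    sign_at_hit = np.sign(V[np.arange(n), np.minimum(first, T)])
    frozen = step_idx[None, :] >= first[:, None]
    V[:, 1:] = np.where(frozen, (sign_at_hit * B)[:, None], V[:, 1:])

    terminal = V[np.arange(n), n_steps]
    choice = np.sign(terminal).astype(int)
    ties = choice == 0
    if ties.any():
        choice[ties] = np.where(rng.random(ties.sum()) < 0.5, 1, -1)
    t_abs = np.where(absorbed, first * dt, np.nan)
    return V, choice, absorbed, t_abs


def simulate_dv(params: DDMParams, c: float, t_dur: float, dt: float = 1e-3,
                seed: int | np.random.Generator | None = None):
    """One DV path: Euler-Maruyama with increments N(kappa (c + C0) dt, dt).

    Returns ``(t, V, choice, decision_time)``: the path is frozen at +-B
    once absorbed; ``choice`` is the bound sign if absorbed by ``t_dur``,
    else the sign of V(t_dur), with V = 0 ties broken by a fair coin;
    ``decision_time`` is the absorption time, or nan.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_steps = int(round(t_dur / dt))
    if n_steps < 1:
        raise ValueError("t_dur must be at least one dt step")
    V, choice, absorbed, t_abs = simulate_dv_paths(
        params, np.array([c]), np.array([n_steps]), dt, rng)
    t = dt * np.arange(n_steps + 1)
    return t, V[0, : n_steps + 1], int(choice[0]), float(t_abs[0])


def simulate_behavior_trials(params: DDMParams, n_trials: int,
                             t_dur_range: tuple[float, float] = (0.100, 0.550),
                             t_dur_scale: float = 0.300, dt: float = 1e-3,
                             coherences=COHERENCES,
                             seed: int | np.random.Generator | None = None
                             ) -> TrialTable:
    """Variable-duration behavioral trials only (no spikes).

    Coherences are drawn uniformly from the canonical set and durations from
    a truncated exponential; choices come from the bounded drift-diffusion
    decision rule.  Event columns are left undefined.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    c = rng.choice(np.asarray(coherences, float), n_trials)
    t_dur = _truncated_exp(rng, t_dur_scale, *t_dur_range, n_trials)
    n_steps = np.round(t_dur / dt).astype(int)
    _, choice, _, _ = simulate_dv_paths(params, c, n_steps, dt, rng)
    correct = np.where(c == 0, rng.random(n_trials) < 0.5, choice == np.sign(c))
    df = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "task_variant": "variable_duration",
        "config_id": 0,
        "c1": c, "c2": np.nan, "t_dur": n_steps * dt,
        "choice": np.where(choice > 0, "T_plus", "T_minus"),
        "correct": correct,
    })
    return TrialTable(df, validate=False)


# ---------------------------------------------------------------------------
# sub-Poisson count sampling
# ---------------------------------------------------------------------------

def sample_subpoisson_counts(mu: np.ndarray, phi: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Counts with mean ``mu`` and variance ``phi * mu`` (see module docs)."""
    if not (0 < phi <= 1):
        raise ValueError("phi must be in (0, 1]")
    mu = np.asarray(mu, float)
    if (mu < 0).any():
        raise ValueError("negative intensities")
    if phi == 1.0:
        return rng.poisson(mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    q = 1.0 - phi
    ratio = mu / q
    full = ratio >= 1.0
    # small-intensity floor: Bernoulli(mu), Fano = 1 - mu
    small = (~full) & (mu > 0)
    if small.any():
        out[small] = (rng.random(int(small.sum())) < mu[small]).astype(np.int64)
    if full.any():
        m = np.floor(ratio[full]).astype(np.int64)
        mu_f = mu[full]
        inv_target = q / mu_f                     # required E[1/n]
        theta = (1.0 / m - inv_target) * m * (m + 1)
        theta = np.clip(theta, 0.0, 1.0)
        n = m + (rng.random(m.shape) < theta)
        out[full] = rng.binomial(n, mu_f / n)
    return out


def _spike_times_from_bins(counts: np.ndarray, bin_width: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Uniform spike times within each bin; ``counts`` is (n_bins,)."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = np.repeat(np.arange(len(counts)) * bin_width, counts)
    return np.sort(starts + bin_width * rng.random(total))


# ---------------------------------------------------------------------------
# piecewise-constant rate assembly
# ---------------------------------------------------------------------------

def _bin_means_piecewise(breaks: np.ndarray, values: np.ndarray,
                         bin_edges: np.ndarray) -> np.ndarray:
    """Integrated mean of a piecewise-constant rate over bins.

    ``values[k]`` holds on ``[breaks[k], breaks[k+1])``; the rate is 0
    outside ``[breaks[0], breaks[-1]]``.  Returns per-bin integrals (counts
    expected per bin, i.e. rate * time).
    """
    cum = np.concatenate([[0.0], np.cumsum(values * np.diff(breaks))])
    F = np.interp(bin_edges, breaks, cum, left=0.0, right=cum[-1])
    return np.diff(F)


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _truncated_exp(rng, scale, lo, hi, size):
    """Truncated exponential via inverse CDF."""
    u = rng.random(size)
    a, b = np.exp(-lo / scale), np.exp(-hi / scale)
    return -scale * np.log(a - u * (a - b))


def generate_session(config: GeneratorConfig) -> Session:
    """Generate one session (trials + spikes + ground truth).

    The latent structure per trial:

    * The DV evolves by bounded drift-diffusion while evidence is on screen
      (the full motion epoch in the variable-duration task; each 80-ms pulse
      in the two-pulse tasks) and is frozen in between.
    * Leader neuron ``j`` fires at ``max(0, r0 + gain * (DV + eps_j))``
      during its epochs of response-field alignment and at ``r0`` elsewhere;
      ``eps_j`` is a per-neuron, per-trial trait draw (weakly correlated
      pool).
    * At the saccade, the supporter pool inherits the frozen DV plus pool
      noise; where the gaze returns (variable duration and variant 1), the
      leader pool re-acquires the DV by averaging the supporter pool's
      spike-count readout over a 300-ms window.
    * In variant 1 the second pulse updates the leader pool's DV (the pool
      holding the DV post-IEM); in variant 2 it updates the supporter pool.
    """
    variant = config.task_variant
    if variant not in ("variable_duration", "two_pulse_v1", "two_pulse_v2"):
        raise ValueError(f"unknown task variant {variant!r}")
    rng = np.random.default_rng(config.seed)
    tm = config.timing
    ddm = config.ddm
    dt = config.dt

    conditions = list(COHERENCES)
    n_per = config.n_trials_per_condition
    c1 = np.repeat(conditions, n_per)
    n_trials = len(c1)
    order = rng.permutation(n_trials)
    c1 = c1[order]

    two_pulse = variant != "variable_duration"
    if two_pulse:
        t_dur = np.full(n_trials, PULSE_DURATION)
        mag2 = rng.choice(COHERENCE_MAGNITUDES, n_trials)
        sign2 = np.where(c1 != 0, np.sign(c1),
                         np.where(rng.random(n_trials) < 0.5, 1, -1))
        c2 = mag2 * sign2
        if variant == "two_pulse_v1" and config.catch_fraction > 0:
            catch = rng.random(n_trials) < config.catch_fraction
        else:
            catch = np.zeros(n_trials, bool)
        c2 = np.where(catch, np.nan, c2)
    else:
        t_dur = _truncated_exp(rng, config.t_dur_scale, 0.100, 0.550, n_trials)
        c2 = np.full(n_trials, np.nan)
        catch = np.zeros(n_trials, bool)

    # --- P1 / motion DV paths ---------------------------------------------
    n_steps = np.round(t_dur / dt).astype(int)
    V1, choice1, absorbed, t_abs = simulate_dv_paths(ddm, c1, n_steps, dt, rng)
    v1 = V1[np.arange(n_trials), n_steps]      # frozen DV after P1 / motion

    # --- P2 increment (two-pulse) -----------------------------------------
    if two_pulse:
        p2_steps = int(round(PULSE_DURATION / dt))
        c2_eff = np.where(catch, 0.0, c2)
        V2, _, _, _ = simulate_dv_paths(
            ddm, np.where(catch, 0.0, c2_eff),
            np.full(n_trials, p2_steps), dt, rng, v0=v1)
        v_total = np.where(catch, v1, V2[:, p2_steps])
        delta2 = np.where(catch, 0.0, v_total - v1)
        choice_sign = np.sign(v_total).astype(int)
        ties = choice_sign == 0
        if ties.any():
            choice_sign[ties] = np.where(rng.random(ties.sum()) < 0.5, 1, -1)
    else:
        v_total = v1
        delta2 = np.zeros(n_trials)
        choice_sign = choice1

    # correctness: sign of the shared direction; 0%-only trials rewarded at random
    dir_sign = np.where(c1 != 0, np.sign(c1),
                        np.where(np.nan_to_num(c2) != 0, np.sign(np.nan_to_num(c2)), 0))
    correct = np.where(dir_sign == 0, rng.random(n_trials) < 0.5,
                       choice_sign == dir_sign)

    # --- event timeline ----------------------------------------------------
    ev = {k: np.full(n_trials, np.nan) for k in
          ("motion_on", "motion_off", "saccade_T0", "pursuit_start",
           "fp_reacquired", "p2_on", "go", "choice_saccade")}
    motion_on = (rng.uniform(*tm.targets_delay, n_trials)
                 + rng.uniform(*tm.motion_delay, n_trials))
    ev["motion_on"] = motion_on
    ev["motion_off"] = motion_on + t_dur
    if variant in ("variable_duration", "two_pulse_v1"):
        fp_off = ev["motion_off"] + tm.fp_off_after_motion
        ev["saccade_T0"] = fp_off + rng.uniform(*tm.saccade_latency, n_trials)
        ev["pursuit_start"] = ev["saccade_T0"] + rng.uniform(*tm.t0_hold, n_trials)
        ev["fp_reacquired"] = ev["pursuit_start"] + tm.pursuit_duration
        if variant == "variable_duration":
            ev["go"] = ev["fp_reacquired"] + rng.uniform(*tm.post_pursuit_delay, n_trials)
        else:
            p2_on = ev["fp_reacquired"] + rng.uniform(*tm.p2_delay, n_trials)
            ev["p2_on"] = np.where(catch, np.nan, p2_on)
            ev["go"] = p2_on + PULSE_DURATION + tm.go_delay
    else:  # two_pulse_v2: pursuit is the only IEM
        ev["pursuit_start"] = ev["motion_off"] + rng.uniform(*tm.t0_hold, n_trials)
        ev["fp_reacquired"] = ev["pursuit_start"] + tm.pursuit_duration
        p2_on = ev["fp_reacquired"] + rng.uniform(*tm.p2_delay, n_trials)
        ev["p2_on"] = p2_on
        ev["go"] = p2_on + PULSE_DURATION + tm.go_delay
    ev["choice_saccade"] = ev["go"] + tm.choice_latency
    trial_end = ev["choice_saccade"] + 0.100

    # --- pool latent DVs ---------------------------------------------------
    # supporter pool common DV: frozen DV + pool noise at the first handoff
    d_s_common = v1 + config.sigma_pool * rng.standard_normal(n_trials)
    # handoff-back (filled after supporter spikes are drawn)
    d_lpost_common = np.zeros(n_trials)

    nl, ns, no = config.n_leader, config.n_supporter, config.n_other
    leader_ids = list(range(nl))
    supporter_ids = list(range(nl, nl + ns))
    other_ids = list(range(nl + ns, nl + ns + no))
    labels = pd.DataFrame({
        "neuron_id": leader_ids + supporter_ids + other_ids,
        "true_role": ["leader"] * nl + ["supporter"] * ns + ["other"] * no,
        "config_id": config.config_id,
    })

    bw = config.spike_bin
    trial_ids = np.arange(n_trials)
    lag = RESPONSE_LAG

    if variant == "two_pulse_v2":
        handoff_t = ev["fp_reacquired"]        # gaze arrives at T0 (pursuit end)
        leader_end = ev["fp_reacquired"] + HANDOFF_OVERLAP
        supp_start = ev["fp_reacquired"] - HANDOFF_OVERLAP
        supp_end = ev["choice_saccade"]
    else:
        handoff_t = ev["saccade_T0"]
        leader_end = ev["saccade_T0"] + HANDOFF_OVERLAP
        supp_start = ev["saccade_T0"]
        supp_end = ev["fp_reacquired"] + HANDOFF_OVERLAP

    gain, r0, phi = config.gain, config.r0, config.phi

    def leader_breaks(i: int, eps: float, eps_post: float) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant rate for one leader on trial i."""
        t_on = ev["motion_on"][i] + lag
        t_off = ev["motion_off"][i] + lag
        k = n_steps[i]
        dv_path = V1[i, : k + 1]
        # motion epoch at dt resolution, then frozen DV until leader_end
        seg_t = [0.0, t_on]
        seg_v = [r0]
        seg_t.extend(t_on + dt * np.arange(1, k + 1))
        seg_v.extend(np.maximum(0.0, r0 + gain * (dv_path[:k] + eps)))
        seg_t.append(leader_end[i])
        seg_v.append(max(0.0, r0 + gain * (v1[i] + eps)))
        if variant in ("variable_duration", "two_pulse_v1"):
            # baseline gap, then post-IEM re-acquisition
            t_back = ev["fp_reacquired"][i] - HANDOFF_OVERLAP
            seg_t.append(t_back)
            seg_v.append(r0)
            if variant == "two_pulse_v1" and not catch[i] and np.isfinite(ev["p2_on"][i]):
                t_p2 = ev["p2_on"][i] + lag
                seg_t.append(t_p2)
                seg_v.append(max(0.0, r0 + gain * (d_lpost_common[i] + eps_post)))
                seg_t.append(ev["choice_saccade"][i])
                seg_v.append(max(0.0, r0 + gain * (d_lpost_common[i] + delta2[i] + eps_post)))
            else:
                seg_t.append(ev["choice_saccade"][i])
                seg_v.append(max(0.0, r0 + gain * (d_lpost_common[i] + eps_post)))
            seg_t.append(trial_end[i])
            seg_v.append(r0)
        else:
            seg_t.append(trial_end[i])
            seg_v.append(r0)
        return np.asarray(seg_t), np.asarray(seg_v)

    def supporter_breaks(i: int, dv_i: float, dv_post_p2: float) -> tuple[np.ndarray, np.ndarray]:
        seg_t = [0.0, supp_start[i]]
        seg_v = [r0]
        if variant == "two_pulse_v2" and np.isfinite(ev["p2_on"][i]):
            t_p2 = ev["p2_on"][i] + lag
            seg_t.append(t_p2)
            seg_v.append(max(0.0, r0 + gain * dv_i))
            seg_t.append(supp_end[i])
            seg_v.append(max(0.0, r0 + gain * dv_post_p2))
        else:
            seg_t.append(supp_end[i])
            seg_v.append(max(0.0, r0 + gain * dv_i))
        seg_t.append(trial_end[i])
        seg_v.append(r0)
        return np.asarray(seg_t), np.asarray(seg_v)

    # --- supporter pool spikes (all members; readout needs them) -----------
    spikes: dict[int, dict[int, np.ndarray]] = {nid: {} for nid in
                                                leader_ids + supporter_ids + other_ids}
    readout_counts = np.zeros((config.pool_size_supporter, n_trials))
    exposure = READOUT_WINDOW[1] - READOUT_WINDOW[0]
    member_dv = np.empty((config.pool_size_supporter, n_trials))
    for m in range(config.pool_size_supporter):
        nu = config.sigma_member * rng.standard_normal(n_trials)
        member_dv[m] = d_s_common + nu
        recorded = m < ns
        nid = supporter_ids[m] if recorded else None
        for i in trial_ids:
            dv_i = member_dv[m, i]
            dv_post = dv_i + delta2[i] if variant == "two_pulse_v2" else dv_i
            bt, bv = supporter_breaks(i, dv_i, dv_post)
            n_bins = int(np.ceil(trial_end[i] / bw))
            edges = bw * np.arange(n_bins + 1)
            mu = _bin_means_piecewise(bt, bv, edges)
            counts = sample_subpoisson_counts(mu, phi, rng)
            ts = _spike_times_from_bins(counts, bw, rng)
            w0 = handoff_t[i] + READOUT_WINDOW[0]
            readout_counts[m, i] = ((ts >= w0) & (ts < w0 + exposure)).sum()
            if recorded and len(ts):
                spikes[nid][int(i)] = ts

    # handoff back: pool-average spike-count readout + pool noise
    if gain > 0:
        d_lpost_common[:] = ((readout_counts.mean(axis=0) - r0 * exposure)
                             / (gain * exposure)
                             + config.sigma_pool * rng.standard_normal(n_trials))
    # (gain == 0: no decision signal anywhere; leave at 0)

    # --- leader and "other" spikes -----------------------------------------
    for j, nid in enumerate(leader_ids):
        eps = config.sigma_member * rng.standard_normal(n_trials)
        eps_post = config.sigma_member * rng.standard_normal(n_trials)
        for i in trial_ids:
            bt, bv = leader_breaks(i, eps[i], eps_post[i])
            n_bins = int(np.ceil(trial_end[i] / bw))
            edges = bw * np.arange(n_bins + 1)
            mu = _bin_means_piecewise(bt, bv, edges)
            counts = sample_subpoisson_counts(mu, phi, rng)
            ts = _spike_times_from_bins(counts, bw, rng)
            if len(ts):
                spikes[nid][int(i)] = ts
    for nid in other_ids:
        for i in trial_ids:
            n_bins = int(np.ceil(trial_end[i] / bw))
            mu = np.full(n_bins, r0 * bw)
            mu[-1] = r0 * (trial_end[i] - (n_bins - 1) * bw)
            counts = sample_subpoisson_counts(mu, phi, rng)
            ts = _spike_times_from_bins(counts, bw, rng)
            if len(ts):
                spikes[nid][int(i)] = ts

    df = pd.DataFrame({
        "trial_id": trial_ids,
        "task_variant": variant,
        "config_id": config.config_id,
        "c1": c1, "c2": c2, "t_dur": t_dur,
        "choice": np.where(choice_sign > 0, "T_plus", "T_minus"),
        "correct": correct,
        **ev,
    })
    trials = TrialTable(df)
    truth = pd.DataFrame({
        "trial_id": trial_ids,
        "v1": v1, "v_total": v_total, "delta2": delta2,
        "d_s_common": d_s_common, "d_lpost_common": d_lpost_common,
        "absorbed": absorbed, "catch": catch,
    })
    return Session(trials=trials,
                   spikes=SpikeData(spikes, trial_ids=trial_ids, validate=False),
                   truth=truth, labels=labels, config=config)


# ---------------------------------------------------------------------------
# focused generators for pairwise analyses
# ---------------------------------------------------------------------------

def simulate_pair_epochs(n_trials: int, pool_size: int = 50,
                         sigma_pool: float = 0.10, sigma_member: float = 0.10,
                         phi: float = 0.6, r0: float = 30.0, gain: float = 25.0,
                         window: float = 0.300, kappa: float = 15.0,
                         C0: float = 0.0, B: float = 1.0,
                         t_acc: float = 0.080,
                         independent: bool = False,
                         seed: int | np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Simulate per-trial epoch counts for one leader-supporter pair.

    Implements the relay chain at the counting-window level: the leader's
    pre-IEM latent rate tracks the frozen DV; the supporter pool inherits
    the DV plus pool noise; the post-IEM leader reads out the supporter
    pool's actual spike counts (pool average) plus pool noise.  With
    ``pool_size=1`` and ``sigma_pool=0`` the recorded supporter's count is
    the entire conduit of the handoff back (full mediation); with a large
    pool of weakly correlated members, conditioning on the one recorded
    member cannot absorb the pool signal.

    ``independent=True`` severs the supporter from the DV (independent pools
    null for calibration).

    Returns a DataFrame with columns ``c1, choice, l_pre, s_iem, l_post``
    (counts) and the latent rates ``lam_l_pre, lam_s, lam_l_post``.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    params = DDMParams(kappa, B, C0)
    c1 = rng.choice(COHERENCES, n_trials)
    z = rng.standard_normal(n_trials)
    v1 = np.clip(params.kappa * (c1 + params.C0) * t_acc + np.sqrt(t_acc) * z,
                 -B, B)
    choice = np.sign(v1).astype(int)
    ties = choice == 0
    if ties.any():
        choice[ties] = np.where(rng.random(ties.sum()) < 0.5, 1, -1)

    lam_l_pre = np.maximum(0.0, r0 + gain * (v1 + sigma_member * rng.standard_normal(n_trials)))
    l_pre = sample_subpoisson_counts(lam_l_pre * window, phi, rng)

    if independent:
        # conditionally independent null: same condition dependence, fresh DV
        v1_indep = np.clip(params.kappa * (c1 + params.C0) * t_acc
                           + np.sqrt(t_acc) * rng.standard_normal(n_trials), -B, B)
        d_s_common = v1_indep + sigma_pool * rng.standard_normal(n_trials)
    else:
        d_s_common = v1 + sigma_pool * rng.standard_normal(n_trials)
    member_dv = d_s_common[None, :] + sigma_member * rng.standard_normal((pool_size, n_trials))
    lam_s_members = np.maximum(0.0, r0 + gain * member_dv)
    s_counts = sample_subpoisson_counts(lam_s_members * window, phi, rng)

    d_back = ((s_counts.mean(axis=0) - r0 * window) / (gain * window)
              + sigma_pool * rng.standard_normal(n_trials))
    lam_l_post = np.maximum(0.0, r0 + gain * (d_back + sigma_member * rng.standard_normal(n_trials)))
    l_post = sample_subpoisson_counts(lam_l_post * window, phi, rng)

    return pd.DataFrame({
        "c1": c1, "choice": choice,
        "l_pre": l_pre, "s_iem": s_counts[0], "l_post": l_post,
        "lam_l_pre": lam_l_pre, "lam_s": lam_s_members[0], "lam_l_post": lam_l_post,
    })


def simulate_diffusion_counts(n_trials: int, n_bins: int = 5,
                              bin_width: float = 0.100, r0: float = 50.0,
                              gain: float = 20.0, sigma_step: float = 0.5,
                              phi: float = 0.6,
                              seed: int | np.random.Generator | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Counts whose latent rates follow unbounded discrete diffusion.

    The latent rate is constant within each counting bin and performs a
    random-walk step between bins: rate_b = r0 + gain * X_b with
    X_b = sum_{k<=b} zeta_k, zeta iid N(0, sigma_step^2).  Then
    corr(rate_i, rate_j) = sqrt(i/j) for i <= j exactly — the unbounded-
    diffusion prediction used to calibrate the Fano factor.

    Returns ``(counts, rates)`` each of shape (n_trials, n_bins).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    steps = sigma_step * rng.standard_normal((n_trials, n_bins))
    X = np.cumsum(steps, axis=1)
    rates = np.maximum(0.0, r0 + gain * X)
    counts = sample_subpoisson_counts(rates * bin_width, phi, rng)
    return counts, rates
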