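"""Behavioral analyses: psychometric logistic fits, bounded drift-diffusion
choice model, and the one-pulse vs two-pulse simulation comparison.

Model
-----
The decision variable V accumulates momentary motion evidence,

    dV = kappa * (C + C0) dt + dW,

with C the signed coherence, C0 a bias in coherence units, kappa the drift
sensitivity, and W a standard Wiener process.  A choice is made when V
reaches an absorbing bound at +B (T+ choice) or -B (T-); if neither bound is
reached by the stimulus duration t_dur the choice is the sign of V(t_dur)
(ties broken by a fair coin).  Choice probabilities are computed by
discrete-time propagation of the DV density with absorbing boundaries, and
the three free parameters (kappa, B, C0) are fitted to choices by maximum
likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .containers import TrialTable

__all__ = [
    "DDMParams", "LogisticFit", "DDMResults", "PulseModelComparison",
    "fit_choice_logistic", "ddm_choice_prob", "ddm_choice_prob_curve",
    "DriftDiffusionModel", "fit_ddm", "compare_pulse_models",
    "simulate_bernoulli_choices",
]


@dataclass
class DDMParams:
    """Bounded drift-diffusion parameters.

    kappa : drift sensitivity (DV units per second per unit coherence)
    B     : bound height (DV units), must be positive
    C0    : bias, in coherence units (drift offset)
    """

    kappa: float
    B: float
    C0: float = 0.0

    def __post_init__(self):
        if not np.isfinite([self.kappa, self.B, self.C0]).all():
            raise ValueError("non-finite DDM parameters")
        if self.B <= 0:
            raise ValueError("bound height B must be positive")


# ---------------------------------------------------------------------------
# logistic psychometric fits
# ---------------------------------------------------------------------------

#: predictor specifications for the logistic factorizations
LOGISTIC_SPECS = ("C", "Cavg", "C1st+C2nd", "Cweaker+Cstronger")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression of T+ choices."""

    spec: str
    params: np.ndarray            # beta0, beta1[, beta2]
    bse: np.ndarray               # standard errors
    llf: float
    separation: bool              # complete/quasi-separation diagnostic
    result: object = field(repr=False, default=None)  # statsmodels results

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def beta1(self) -> float:
        return float(self.params[1])

    @property
    def beta2(self) -> float:
        if len(self.params) < 3:
            raise AttributeError(f"spec {self.spec!r} has no beta2")
        return float(self.params[2])

    def summary(self):
        return self.result.summary()


def _weaker_stronger(c1: np.ndarray, c2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split pulses by relative strength; |c1| == |c2| ties label c1 weaker."""
    first_weaker = np.abs(c1) <= np.abs(c2)
    weaker = np.where(first_weaker, c1, c2)
    stronger = np.where(first_weaker, c2, c1)
    return weaker, stronger


def _design(trials: TrialTable, spec: str) -> np.ndarray:
    df = trials.df
    c1 = df["c1"].to_numpy(float)
    if spec == "C":
        X = c1[:, None]
    else:
        c2 = df["c2"].to_numpy(float)
        if np.isnan(c2).any():
            raise ValueError("spec requires both pulses; exclude catch trials first")
        if spec == "Cavg":
            X = ((c1 + c2) / 2)[:, None]
        elif spec == "C1st+C2nd":
            X = np.column_stack([c1, c2])
        elif spec == "Cweaker+Cstronger":
            X = np.column_stack(_weaker_stronger(c1, c2))
        else:
            raise ValueError(f"unknown predictor spec {spec!r}; one of {LOGISTIC_SPECS}")
    return X


def fit_choice_logistic(trials: TrialTable, spec: str = "C") -> LogisticFit:
    """Fit logit Pr+ = beta0 + beta' X with X given by ``spec``.

    ``spec`` selects the factorization: ``"C"`` (signed coherence),
    ``"Cavg"`` (pulse average), ``"C1st+C2nd"`` (pulse order) or
    ``"Cweaker+Cstronger"`` (pulse strength; |c1| = |c2| ties assign the
    first pulse to the weaker regressor).

    Complete separation is detected (fitted probabilities collapsing onto
    {0, 1}) and reported in the ``separation`` flag rather than raised.
    """
    X = _design(trials, spec)
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct predictor values")
    y = (trials.df["choice"].to_numpy() == "T_plus").astype(float)
    exog = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        except Exception:  # perfect separation can abort Newton; fall back
            res = sm.Logit(y, exog).fit(method="bfgs", disp=0, maxiter=500)
            separation = True
    fitted = res.predict(exog)
    eps = 1e-8
    if np.all((fitted < eps) | (fitted > 1 - eps)) or np.abs(res.params).max() > 1e3:
        separation = True
    return LogisticFit(spec=spec, params=np.asarray(res.params),
                       bse=np.asarray(res.bse), llf=float(res.llf),
                       separation=separation, result=res)


# ---------------------------------------------------------------------------
# bounded drift-diffusion: density propagation
# ---------------------------------------------------------------------------

def _propagate(params: DDMParams, c: float, t_max: float, dt: float,
               grid_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Propagate the DV density; return times and P(T+ | t_dur = t).

    Returns ``(t, p_plus)`` where ``t`` runs over multiples of ``dt`` from 0
    to ``t_max`` and ``p_plus[k]`` is the probability of a T+ choice if the
    stimulus ends at ``t[k]``: mass absorbed at +B plus surviving mass above
    zero (mass exactly at zero split evenly).

    The grid spans ``[-R, R]`` with ``R = min(B, drift * t + 6 sqrt(t))``;
    when B exceeds the dynamic range the edges still absorb, and edge mass is
    attributed to the corresponding sign (it lies > 6 SD from the mean path,
    so re-crossing is negligible).  The increment kernel is the Gaussian
    N(mu dt, dt) integrated over grid cells and normalized, so total mass
    (absorbed + surviving) is conserved to floating-point precision.
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    mu = params.kappa * (c + params.C0)
    sd_step = np.sqrt(dt)
    # dynamic range: bounded by B, but never wider than the diffusion needs
    reach = abs(mu) * t_max + 6.0 * np.sqrt(t_max) + 4.0 * sd_step
    R = min(params.B, reach)
    half = grid_points // 2
    h = R / half
    if h > sd_step / 3:
        # refine so the kernel is well resolved on the grid
        half = int(np.ceil(R / (sd_step / 3)))
        h = R / half
    if half > 60000:
        raise ValueError("propagation grid too large; check parameters/grid config")
    x = h * np.arange(-half, half + 1)          # symmetric, includes 0 and +-R
    bounded = params.B <= reach                 # grid edge is the true bound

    # kernel over integer offsets, from CDF differences, normalized
    kh = int(np.ceil((abs(mu) * dt + 6 * sd_step) / h))
    offs = h * np.arange(-kh, kh + 1)
    edges = np.concatenate([[-np.inf], offs[:-1] + h / 2, [np.inf]])
    # discretizing onto cells of width h adds ~h^2/12 variance per step;
    # compensate so the discrete kernel variance matches dt
    sd_eff = np.sqrt(max(dt - h * h / 12.0, 0.25 * dt))
    kernel = np.diff(stats.norm.cdf(edges, loc=mu * dt, scale=sd_eff))
    kernel /= kernel.sum()

    n_steps = int(round(t_max / dt))
    p = np.zeros(len(x))
    p[half] = 1.0                               # start at V = 0
    zero_idx = half
    pos = slice(half + 1, None)

    p_plus = np.empty(n_steps + 1)
    absorbed_up = 0.0
    absorbed_dn = 0.0
    p_plus[0] = 0.5                             # all mass at 0, split evenly
    interior = slice(1, len(x) - 1)
    for k in range(1, n_steps + 1):
        full = np.convolve(p[interior], kernel)
        # full covers grid indices 1-kh .. len(x)-2+kh; absorb beyond bounds
        lo_tail = full[: kh].sum()              # indices <= 0  (x <= -R)
        hi_tail = full[-kh:].sum() if kh else 0.0  # indices >= len(x)-1 (x >= R)
        absorbed_dn += lo_tail
        absorbed_up += hi_tail
        p = np.zeros(len(x))
        p[interior] = full[kh: kh + len(x) - 2]
        p_plus[k] = absorbed_up + p[pos].sum() + 0.5 * p[zero_idx]
    t = dt * np.arange(n_steps + 1)
    total = absorbed_up + absorbed_dn + p.sum()
    if abs(total - 1.0) > 1e-6:
        raise RuntimeError(f"probability not conserved: total={total!r}")
    return t, p_plus


def ddm_choice_prob_curve(params: DDMParams, c: float, t_max: float,
                          dt: float = 5e-4, grid_points: int = 400
                          ) -> tuple[np.ndarray, np.ndarray]:
    """P(T+ choice) as a function of stimulus duration, on a dt grid."""
    return _propagate(params, c, t_max, dt, grid_points)


def ddm_choice_prob(params: DDMParams, c: float, t_dur: float,
                    dt: float = 5e-4, grid_points: int = 400) -> float:
    """Probability of a T+ choice for one coherence and duration.

    Computed by density propagation with absorbing boundaries; the choice is
    +B absorption, or sign of the surviving DV at ``t_dur`` (mass exactly at
    zero split evenly).
    """
    if t_dur <= 0:
        raise ValueError("t_dur must be positive")
    t, p_plus = _propagate(params, c, t_dur, dt, grid_points)
    return float(p_plus[-1])


# ---------------------------------------------------------------------------
# maximum-likelihood DDM fit
# ---------------------------------------------------------------------------

@dataclass
class DDMResults:
    """Results of a bounded drift-diffusion fit to choices."""

    params: DDMParams
    llf: float
    converged: bool
    n_trials: int
    at_bounds: bool                      # search box reached (degenerate data)
    optimizer: object = field(repr=False, default=None)
    _fit_dt: float = 5e-4

    def predicted_p_plus(self, c: float, t_dur: float) -> float:
        return ddm_choice_prob(self.params, c, t_dur, dt=self._fit_dt)

    def predicted_accuracy(self, c_mag: float, t_dur: np.ndarray) -> np.ndarray:
        """P(correct) vs duration for one motion strength |c| > 0.

        Averages the two directions, as plotted accuracy-vs-duration curves
        do.
        """
        t_dur = np.atleast_1d(np.asarray(t_dur, float))
        t_max = float(t_dur.max())
        tp, pp = ddm_choice_prob_curve(self.params, +abs(c_mag), t_max, dt=self._fit_dt)
        tm, pm = ddm_choice_prob_curve(self.params, -abs(c_mag), t_max, dt=self._fit_dt)
        acc_p = np.interp(t_dur, tp, pp)
        acc_m = 1.0 - np.interp(t_dur, tm, pm)
        return (acc_p + acc_m) / 2

    def summary(self) -> str:
        p = self.params
        lines = [
            "Bounded drift-diffusion fit (maximum likelihood)",
            f"  n_trials      {self.n_trials}",
            f"  kappa         {p.kappa:10.4f}",
            f"  B             {p.B:10.4f}",
            f"  C0            {p.C0:10.4f}",
            f"  log-likelihood {self.llf:10.2f}",
            f"  converged     {self.converged}",
        ]
        if self.at_bounds:
            lines.append("  WARNING: estimate at search-box boundary (degenerate data?)")
        return "\n".join(lines)


class DriftDiffusionModel:
    """Bounded drift-diffusion model of choices in the variable-duration task.

    Parameters
    ----------
    trials : TrialTable
        Must span at least two coherences and two durations.
    dt : float
        Time step of the density propagation used in the likelihood.

    ``fit()`` maximizes the Bernoulli log-likelihood of the observed choices
    over (kappa, B, C0) by Nelder-Mead on (log kappa, log B, C0).
    """

    #: search box (log kappa, log B, C0)
    BOUNDS = ((np.log(0.5), np.log(100.0)), (np.log(0.05), np.log(10.0)), (-0.3, 0.3))

    def __init__(self, trials: TrialTable, dt: float = 5e-4, grid_points: int = 400):
        df = trials.df
        self.c = df["c1"].to_numpy(float)
        self.t_dur = df["t_dur"].to_numpy(float)
        if len(np.unique(self.c)) < 2 or len(np.unique(np.round(self.t_dur, 6))) < 2:
            raise ValueError("need >= 2 coherences and >= 2 durations")
        self.y = (df["choice"].to_numpy() == "T_plus")
        self.dt = dt
        self.grid_points = grid_points
        self.t_max = float(self.t_dur.max())
        # group trials by signed coherence: one propagation per coherence
        self._c_values, self._c_index = np.unique(self.c, return_inverse=True)

    def loglike(self, params: DDMParams) -> float:
        ll = 0.0
        for j, cv in enumerate(self._c_values):
            sel = self._c_index == j
            t, p_plus = _propagate(params, cv, self.t_max, self.dt, self.grid_points)
            p = np.interp(self.t_dur[sel], t, p_plus)
            p = np.clip(p, 1e-10, 1 - 1e-10)
            yj = self.y[sel]
            ll += float(np.log(p[yj]).sum() + np.log1p(-p[~yj]).sum())
        return ll

    def fit(self, start: DDMParams | None = None, maxiter: int = 300) -> DDMResults:
        if start is None:
            start = DDMParams(10.0, 0.8, 0.0)
        x0 = np.array([np.log(start.kappa), np.log(start.B), start.C0])
        lo = np.array([b[0] for b in self.BOUNDS])
        hi = np.array([b[1] for b in self.BOUNDS])

        def nll(x):
            xc = np.clip(x, lo, hi)
            penalty = 1e4 * float(np.sum((x - xc) ** 2))
            p = DDMParams(float(np.exp(xc[0])), float(np.exp(xc[1])), float(xc[2]))
            return -self.loglike(p) + penalty

        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options=dict(maxiter=maxiter, xatol=1e-3, fatol=1e-3))
        if not res.success and res.status != 1:  # status 1: maxiter reached
            raise RuntimeError(f"DDM fit did not converge: {res.message}\n{res}")
        xf = np.clip(res.x, lo, hi)
        at_bounds = bool(np.any(np.abs(res.x - xf) > 1e-9)
                         or np.any(np.abs(xf - lo) < 1e-6)
                         or np.any(np.abs(xf - hi) < 1e-6))
        params = DDMParams(float(np.exp(xf[0])), float(np.exp(xf[1])), float(xf[2]))
        return DDMResults(params=params, llf=-float(res.fun), converged=bool(res.success),
                          n_trials=len(self.y), at_bounds=at_bounds, optimizer=res,
                          _fit_dt=self.dt)


def fit_ddm(trials: TrialTable, dt: float = 5e-4, **kwargs) -> DDMResults:
    """Convenience wrapper: ``DriftDiffusionModel(trials, dt).fit(**kwargs)``."""
    return DriftDiffusionModel(trials, dt=dt).fit(**kwargs)


# ---------------------------------------------------------------------------
# Model-1 vs Model-2 pulse comparison
# ---------------------------------------------------------------------------

@dataclass
class PulseModelComparison:
    """Simulation-based comparison of one-pulse vs two-pulse choice models.

    Model-1: the choice is based on one pulse picked at random on each trial,
    logit Pr+ = alpha0 + alpha1 * C_rand.  Model-2: both pulses contribute,
    logit Pr+ = alpha0 + alpha1 * (C1 + C2).  The alphas are mapped from the
    data's pulse-average fit (alpha0 = beta0; alpha1 = beta1 for Model-1 and
    beta1 / 2 for Model-2), choices are simulated from the Bernoulli
    distribution, and each replicate is refit with the weaker/stronger
    factorization whose weight pattern discriminates the models.
    """

    data_fit_avg: LogisticFit           # pulse-average fit giving the alphas
    data_fit_ws: LogisticFit            # weaker/stronger fit to the data
    alpha0: float
    alpha1_m1: float
    alpha1_m2: float
    n_choices: int
    n_reps: int
    model1_betas: np.ndarray            # (n_reps, 2): beta_weaker, beta_stronger
    model2_betas: np.ndarray
    model1_betas_order: np.ndarray      # (n_reps, 2): beta_1st, beta_2nd
    model2_betas_order: np.ndarray

    def ensemble_stats(self, model: int, order: bool = False):
        arr = {1: (self.model1_betas, self.model1_betas_order),
               2: (self.model2_betas, self.model2_betas_order)}[model][int(order)]
        return arr.mean(axis=0), arr.std(axis=0, ddof=1)

    def summary(self) -> str:
        m1_mu, m1_sd = self.ensemble_stats(1)
        m2_mu, m2_sd = self.ensemble_stats(2)
        d = self.data_fit_ws.params[1:]
        return "\n".join([
            "Pulse-model comparison (weaker/stronger factorization)",
            f"  data:    beta_weaker={d[0]:.3f}  beta_stronger={d[1]:.3f}",
            f"  Model-1: beta_weaker={m1_mu[0]:.3f}+-{m1_sd[0]:.3f}  "
            f"beta_stronger={m1_mu[1]:.3f}+-{m1_sd[1]:.3f}",
            f"  Model-2: beta_weaker={m2_mu[0]:.3f}+-{m2_sd[0]:.3f}  "
            f"beta_stronger={m2_mu[1]:.3f}+-{m2_sd[1]:.3f}",
            f"  ({self.n_reps} replicates of {self.n_choices} simulated choices)",
        ])


def simulate_bernoulli_choices(model: int, alpha0: float, alpha1: float,
                               c1: np.ndarray, c2: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
    """Simulate choices (bool, True = T+) from Model-1 or Model-2."""
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    if model == 1:
        pick_first = rng.random(len(c1)) < 0.5
        c_eff = np.where(pick_first, c1, c2)
    elif model == 2:
        c_eff = c1 + c2
    else:
        raise ValueError("model must be 1 or 2")
    p = 1.0 / (1.0 + np.exp(-(alpha0 + alpha1 * c_eff)))
    return rng.random(len(c1)) < p


def compare_pulse_models(trials: TrialTable, n_choices: int = 10_000,
                         n_reps: int = 200, seed: int | None = None
                         ) -> PulseModelComparison:
    """Run the pulse-model comparison on two-pulse trials (catch excluded).

    Pulse strengths for the simulated choices are resampled (with
    replacement) from the data's pulse pairs, so the simulated ensembles see
    the same stimulus distribution as the fits to the data.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    df = trials.df
    has_p2 = np.isfinite(df["c2"].to_numpy(float))
    if not has_p2.all():
        trials = trials.subset(has_p2)
        df = trials.df
    if len(df) == 0:
        raise ValueError("no two-pulse trials")
    c1 = df["c1"].to_numpy(float)
    c2 = df["c2"].to_numpy(float)

    fit_avg = fit_choice_logistic(trials, "Cavg")
    fit_ws = fit_choice_logistic(trials, "Cweaker+Cstronger")
    alpha0 = fit_avg.beta0
    alpha1_m1 = fit_avg.beta1
    alpha1_m2 = fit_avg.beta1 / 2.0

    rng = np.random.default_rng(seed)
    out = {1: ([], []), 2: ([], [])}
    for model, alpha1 in ((1, alpha1_m1), (2, alpha1_m2)):
        for _ in range(n_reps):
            idx = rng.integers(0, len(c1), n_choices)
            s1, s2 = c1[idx], c2[idx]
            y = simulate_bernoulli_choices(model, alpha0, alpha1, s1, s2, rng)
            sim = _pulse_table(s1, s2, y)
            out[model][0].append(fit_choice_logistic(sim, "Cweaker+Cstronger").params[1:])
            out[model][1].append(fit_choice_logistic(sim, "C1st+C2nd").params[1:])
    return PulseModelComparison(
        data_fit_avg=fit_avg, data_fit_ws=fit_ws, alpha0=alpha0,
        alpha1_m1=alpha1_m1, alpha1_m2=alpha1_m2,
        n_choices=n_choices, n_reps=n_reps,
        model1_betas=np.array(out[1][0]), model2_betas=np.array(out[2][0]),
        model1_betas_order=np.array(out[1][1]), model2_betas_order=np.array(out[2][1]),
    )


def _pulse_table(c1: np.ndarray, c2: np.ndarray, y_plus: np.ndarray) -> TrialTable:
    """Minimal two-pulse trial table for refitting simulated choices."""
    n = len(c1)
    shared = np.where(c1 != 0, np.sign(c1), np.sign(c2))
    correct = np.where(shared == 0, True, (np.where(y_plus, 1, -1) == shared))
    df = pd.DataFrame({
        "trial_id": np.arange(n),
        "task_variant": "two_pulse_v1",
        "config_id": 0,
        "c1": c1, "c2": c2, "t_dur": 0.080,
        "choice": np.where(y_plus, "T_plus", "T_minus"),
        "correct": correct,
    })
    return TrialTable(df, validate=False)
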