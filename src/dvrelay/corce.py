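"""Variance and correlation of conditional expectations (VarCE / CorCE),
Fano-factor calibration against unbounded diffusion, permutation nulls, and
the mediation regressions for simultaneously recorded pairs.

The latent firing rate, not the realized spike count, is taken to carry the
decision variable.  Spike counts are modelled as doubly stochastic: given
the rate, the count has variance ``phi * mean`` (point-process noise, Fano
factor phi).  Subtracting that component from the residual count variance
leaves the variance of the conditional expectation,

    VarCE[x] = Var[x_res] - phi * <x>,

and replacing the variances in a correlation by VarCEs yields the
correlation of the latent rates,

    CorCE[l, s] = Cov[l_res, s_res] / sqrt(VarCE[l] * VarCE[s]),

where residuals are taken about the mean of trials sharing the same signed
motion strength.  The covariance numerator is left uncorrected: counts in
different epochs (or different neurons) are conditionally independent given
the two rates, so point-process noise does not contribute to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "EpochSpec", "VarCEResult", "PhiEstimate", "PermutationResult",
    "residual_counts", "varce", "corce_pair", "corce_matrix",
    "diffusion_corr_prediction", "estimate_phi", "permutation_null",
    "mediation_regressions",
]


@dataclass
class EpochSpec:
    """The three 300-ms counting epochs bracketing the IEM.

    pre-IEM begins 200 ms after P1 onset; the IEM window begins 50 ms after
    the supporter's sustained-activity start (from classification); post-IEM
    is centered on P2 onset.  Offsets are relative to the named events.
    """

    pre_event: str = "motion_on"
    pre_start: float = 0.200
    iem_event: str = "saccade_T0"
    iem_start: float = 0.050            # added to the supporter activity start
    post_event: str = "p2_on"
    post_center: float = 0.0
    width: float = 0.300


# ---------------------------------------------------------------------------
# residuals, VarCE, CorCE
# ---------------------------------------------------------------------------

def _group_indices(conditions: np.ndarray) -> dict:
    conditions = np.asarray(conditions)
    return {k: np.flatnonzero(conditions == k) for k in np.unique(conditions)}


def residual_counts(counts: np.ndarray, conditions: np.ndarray) -> np.ndarray:
    """Counts minus their condition-group mean (groups: signed coherence).

    Every group must have >= 2 trials; group means of the residuals are 0
    exactly.
    """
    counts = np.asarray(counts, float)
    res = np.empty_like(counts)
    for k, idx in _group_indices(conditions).items():
        if len(idx) < 2:
            raise ValueError(f"condition group {k!r} has a single trial; "
                             "residuals undefined")
        res[idx] = counts[idx] - counts[idx].mean()
    return res


@dataclass
class VarCEResult:
    value: float
    raw_variance: float
    point_process: float        # phi * mean count
    clipped: bool               # negative estimate clipped to 0


def varce(residuals: np.ndarray, mean_count: float, phi: float) -> VarCEResult:
    """Variance of the conditional expectation of the count.

    ``Var[residuals] - phi * mean_count``; a negative estimate (sampling
    noise) is clipped to 0 and flagged.
    """
    residuals = np.asarray(residuals, float)
    if len(residuals) < 2:
        raise ValueError("need at least 2 residuals")
    if mean_count < 0:
        raise ValueError("mean count must be non-negative")
    if not 0 <= phi <= 1:
        raise ValueError("phi must be in [0, 1]")
    raw = float(residuals.var(ddof=1))
    pp = phi * float(mean_count)
    v = raw - pp
    clipped = v < 0
    return VarCEResult(value=max(v, 0.0), raw_variance=raw,
                       point_process=pp, clipped=clipped)


def corce_pair(l_counts: np.ndarray, s_counts: np.ndarray,
               conditions: np.ndarray, phi: float,
               shared_point_noise: bool = False) -> float:
    """CorCE between two epoch counts.

    ``shared_point_noise=True`` subtracts the point-process component from
    the covariance numerator as well — required only when the two inputs
    share their spiking noise (e.g. a count correlated with itself), where
    conditional independence given the rates does not hold.

    Returns nan (with a warning) when either VarCE is non-positive.
    """
    l_res = residual_counts(l_counts, conditions)
    s_res = residual_counts(s_counts, conditions)
    vl = varce(l_res, np.mean(l_counts), phi)
    vs = varce(s_res, np.mean(s_counts), phi)
    if vl.value <= 0 or vs.value <= 0:
        warnings.warn("non-positive VarCE; CorCE undefined")
        return np.nan
    cov = float(np.dot(l_res, s_res) / (len(l_res) - 1))
    if shared_point_noise:
        cov -= phi * np.sqrt(np.mean(l_counts) * np.mean(s_counts))
    return cov / np.sqrt(vl.value * vs.value)


def corce_matrix(counts: np.ndarray, conditions: np.ndarray | None,
                 phi: float) -> np.ndarray:
    """CorCE between all column pairs of a (n_trials, n_bins) count array.

    The diagonal subtracts the point-process component from the numerator
    (a count shares its own spiking noise), so it equals 1 whenever the
    VarCE is positive.
    """
    counts = np.asarray(counts, float)
    n_trials, n_bins = counts.shape
    if conditions is None:
        conditions = np.zeros(n_trials)
    res = np.column_stack([residual_counts(counts[:, b], conditions)
                           for b in range(n_bins)])
    means = counts.mean(axis=0)
    varces = np.array([varce(res[:, b], means[b], phi).value
                       for b in range(n_bins)])
    cov = res.T @ res / (n_trials - 1)
    out = np.full((n_bins, n_bins), np.nan)
    ok = varces > 0
    denom = np.sqrt(np.outer(varces, varces))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = cov / denom
        np.fill_diagonal(out, np.where(ok, (np.diag(cov) - phi * means) / varces, np.nan))
    out[~ok, :] = np.nan
    out[:, ~ok] = np.nan
    return out


# ---------------------------------------------------------------------------
# Fano-factor estimation against the unbounded-diffusion prediction
# ---------------------------------------------------------------------------

def diffusion_corr_prediction(n_bins: int, kind: str = "sqrt") -> np.ndarray:
    """Predicted latent-rate correlations for unbounded diffusion.

    For a rate performing a random walk sampled in bins i <= j the
    correlation is sqrt(i/j) (``kind="sqrt"``, default); ``kind="linear"``
    gives i/j, the alternative normalization sometimes quoted.
    """
    i = np.arange(1, n_bins + 1, dtype=float)
    ratio = np.minimum.outer(i, i) / np.maximum.outer(i, i)
    if kind == "sqrt":
        return np.sqrt(ratio)
    if kind == "linear":
        return ratio
    raise ValueError("kind must be 'sqrt' or 'linear'")


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999, 0.999))


@dataclass
class PhiEstimate:
    phi: float
    objective: np.ndarray          # objective value per grid point
    grid: np.ndarray
    corce: np.ndarray              # CorCE matrix at phi
    prediction: np.ndarray

    def rmse_z(self) -> float:
        iu = np.triu_indices_from(self.corce, k=1)
        d = _fisher_z(self.corce[iu]) - _fisher_z(self.prediction[iu])
        return float(np.sqrt(np.nanmean(d ** 2)))


def estimate_phi(counts: np.ndarray, conditions: np.ndarray | None = None,
                 prediction: str = "sqrt",
                 grid: np.ndarray | None = None) -> PhiEstimate:
    """Estimate the point-process Fano factor phi from decision-formation
    counts.

    ``counts`` is (n_trials, n_bins) with bins tiling putative integration
    (>= 5 bins recommended: 5 bins give the 10 unique off-diagonal CorCE
    values).  phi is chosen on a grid in (0, 1] to minimize the squared
    Fisher-z error between the off-diagonal CorCE values and the
    unbounded-diffusion prediction.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("counts must be (n_trials, n_bins) with >= 2 bins")
    if np.ptp(counts) == 0:
        raise ValueError("degenerate (all-equal) counts")
    n_bins = counts.shape[1]
    pred = diffusion_corr_prediction(n_bins, prediction)
    if grid is None:
        grid = np.round(np.arange(0.05, 1.0001, 0.01), 4)
    iu = np.triu_indices(n_bins, k=1)
    zp = _fisher_z(pred[iu])
    obj = np.full(len(grid), np.inf)
    for g, phi in enumerate(grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            C = corce_matrix(counts, conditions, phi)
        vals = C[iu]
        if np.isnan(vals).any():
            continue
        obj[g] = float(np.sum((_fisher_z(vals) - zp) ** 2))
    if not np.isfinite(obj).any():
        raise ValueError("objective undefined on the whole grid (VarCE <= 0)")
    best = int(np.argmin(obj))
    phi_hat = float(grid[best])
    C = corce_matrix(counts, conditions, phi_hat)
    return PhiEstimate(phi=phi_hat, objective=obj, grid=np.asarray(grid),
                       corce=C, prediction=pred)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    pvalue: float                  # two-sided, add-one convention
    null: np.ndarray = field(repr=False, default=None)


def permutation_null(l_counts: np.ndarray, s_counts: np.ndarray,
                     conditions: np.ndarray, phi: float,
                     n_perm: int = 1000,
                     seed: int | np.random.Generator | None = None
                     ) -> PermutationResult:
    """Permutation distribution of CorCE under H0 of no within-trial
    coupling.

    One neuron's counts are re-paired by permuting trials *within* each
    signed-coherence group, preserving both marginal count distributions and
    the condition structure.  Groups with < 2 trials are skipped with a
    warning (they carry no pairing information).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    l_counts = np.asarray(l_counts, float)
    s_counts = np.asarray(s_counts, float)
    conditions = np.asarray(conditions)
    keep = np.ones(len(l_counts), bool)
    for k, idx in _group_indices(conditions).items():
        if len(idx) < 2:
            warnings.warn(f"condition group {k!r} too small to permute; skipped")
            keep[idx] = False
    l_counts, s_counts, conditions = l_counts[keep], s_counts[keep], conditions[keep]

    observed = corce_pair(l_counts, s_counts, conditions, phi)
    l_res = residual_counts(l_counts, conditions)
    s_res = residual_counts(s_counts, conditions)
    n = len(l_res)
    # permuting within groups leaves both marginals (hence both VarCEs)
    # unchanged: only the covariance numerator varies across surrogates
    vl = varce(l_res, l_counts.mean(), phi).value
    vs = varce(s_res, s_counts.mean(), phi).value
    if not (vl > 0 and vs > 0) or not np.isfinite(observed):
        warnings.warn("CorCE undefined (non-positive VarCE); permutation "
                      "p-value not available")
        return PermutationResult(observed=np.nan, null_mean=np.nan,
                                 null_sd=np.nan, pvalue=np.nan,
                                 null=np.full(n_perm, np.nan))
    denom = np.sqrt(vl * vs)

    perm_idx = np.tile(np.arange(n), (n_perm, 1))
    for k, idx in _group_indices(conditions).items():
        block = perm_idx[:, idx]
        perm_idx[:, idx] = rng.permuted(block, axis=1)
    null = (s_res[perm_idx] @ l_res) / (n - 1) / denom
    p = (1 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1)
    return PermutationResult(observed=observed,
                             null_mean=float(np.mean(null)),
                             null_sd=float(np.std(null, ddof=1)),
                             pvalue=float(p), null=null)


# ---------------------------------------------------------------------------
# mediation regressions
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def mediation_regressions(l_pre: np.ndarray, s_iem: np.ndarray,
                          l_post: np.ndarray, c1: np.ndarray,
                          choice: np.ndarray) -> dict:
    """OLS regressions probing transfer and mediation of the DV.

    With per-neuron z-scored epoch counts and covariates C1st (signed P1
    strength) and I_choice (+1 / -1):

    * ``s_on_lpre``:    s_IEM  ~ C1st + I_choice + l_pre      (transfer in)
    * ``lpost_on_s``:   l_post ~ C1st + I_choice + s_IEM      (transfer out)
    * ``autocorr``:     l_post ~ C1st + I_choice + l_pre      (autocorrelation)
    * ``mediation``:    l_post ~ C1st + I_choice + l_pre + s_IEM

    The hypothesis of interest is beta3 = 0 (the coefficient on the last
    epoch regressor; in ``mediation`` beta3 is the coefficient on l_pre and
    beta4 the one on s_IEM).  Returns a dict with the statsmodels results
    under those keys plus a tidy coefficient ``table``.
    """
    l_pre, s_iem, l_post = map(_zscore, (l_pre, s_iem, l_post))
    c1 = np.asarray(c1, float)
    choice = np.asarray(choice, float)
    base = np.column_stack([np.ones_like(c1), c1, choice])
    names_base = ["const", "C1st", "I_choice"]

    def fit(y, extra_cols, extra_names):
        X = np.column_stack([base] + [np.asarray(e, float)[:, None] for e in extra_cols])
        names = names_base + extra_names
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify collinear columns by rank growth
            collinear = []
            r = 0
            for j in range(X.shape[1]):
                rj = np.linalg.matrix_rank(X[:, : j + 1])
                if rj == r:
                    collinear.append(names[j])
                r = rj
            raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
        res = sm.OLS(y, X).fit()
        return res, names

    out: dict = {}
    rows = []
    for key, y, extras, enames in (
        ("s_on_lpre", s_iem, [l_pre], ["l_pre"]),
        ("lpost_on_s", l_post, [s_iem], ["s_iem"]),
        ("autocorr", l_post, [l_pre], ["l_pre"]),
        ("mediation", l_post, [l_pre, s_iem], ["l_pre", "s_iem"]),
    ):
        res, names = fit(y, extras, enames)
        out[key] = res
        for name, b, se, p in zip(names, res.params, res.bse, res.pvalues):
            rows.append({"model": key, "term": name, "coef": b, "se": se, "p": p})
    out["table"] = pd.DataFrame(rows)
    return out
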