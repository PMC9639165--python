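# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of the `dvrelay` pipeline.

## Task structure

Three task variants are represented. In the **variable-duration** task a
random-dot motion stimulus of signed coherence
C ∈ ±{0, 0.04, 0.08, 0.16, 0.32, 0.64} is viewed for 100–550 ms (truncated
exponential, scale 0.30 s); the animal then makes an instructed saccade to
a neutral target T0, holds 500–600 ms, smooth-pursues back to the original
fixation point (733 ms), and reports the choice after a go cue. The
**two-pulse** variants replace the motion epoch with two 80-ms pulses of
independent strength and common direction, shown before (P1) and after (P2)
the intervening eye movement(s); variant 1 returns the gaze to the original
fixation before P2 (a random third of trials omit P2 — catch trials),
variant 2 shows P2 from the new gaze position at T0 after a single pursuit.
Event-timing ranges are configuration constants
(`dvrelay.config.EventTimingConfig`); per-trial delays are drawn uniformly
from them. In variant 2 there is no saccade to T0; the pursuit endpoint is
stored in the `fp_reacquired` event column so all variants share one
"IEM complete" marker.

## Decision model

The decision variable follows dV = κ(C + C₀)dt + dW with absorbing bounds
±B. Defaults κ = 15, B = 1, C₀ = 0 (in bound units per second and
coherence units); these produce psychometric slopes and accuracy-by-duration
curves in the range typical of macaque motion discrimination. The bias is a
drift offset, not a starting-point offset.

Choice probabilities are computed by explicit discrete-time convolution of
the DV density with the per-step Gaussian increment kernel on a uniform
grid (default dt = 0.5 ms; grid step the smaller of B/200 and one third of
the per-step SD). Mass transported beyond ±B accumulates in absorbing
bins; surviving mass above/below zero (the mass exactly at zero split
evenly) decides unabsorbed trials. Two numerical details matter:

* the increment kernel is built from CDF differences and renormalized, so
  total probability is conserved to floating point (the propagator raises
  if conservation drifts past 1e-6);
* discretizing onto cells of width h inflates the kernel variance by
  ≈ h²/12 per step; the kernel SD is deflated to compensate. Without this
  the unbounded-limit error vs Φ(κ|c|√t) is ≈1e-3; with it, ≈1e-5.

When B exceeds the dynamic range of the diffusion the grid is sized to the
diffusion (|μ|T + 6√T) and edge absorption is attributed to the
corresponding sign; the edges are >6 SD from the mean path, so re-crossing
is negligible. The likelihood of a trial set propagates once per distinct
coherence, recording P(T₊ | t) at every step, and reads each trial off
that curve; fitting maximizes the Bernoulli log-likelihood by Nelder–Mead
on (log κ, log B, C₀) inside a search box (estimates on the box are
flagged — the degenerate all-correct-choices case lands there).

**Identifiability.** At κ = 15, B = 1 with durations ≤ 0.55 s, choices are
nearly uninformative about B: accuracy saturates at strong coherences and
the bound rarely binds at weak ones. The per-trial Fisher information for B
is ≈ 8×10⁻⁵ (vs ≈ 8×10⁻⁴ for κ), so at n = 10,000 the sampling SD of B̂ is
of order 0.5–1. κ and C₀ recover to a few percent; B̂ scatters widely.
Recovery checks on B should be read with this in mind; it is a property of
the task regime, not of the estimator (the propagation was verified against
200,000-path Monte Carlo at matched step size).

## Pulse-model comparison

The data's pulse-average logistic fit (logit Pr₊ = β₀ + β₁C_avg) supplies
α₀ = β₀ and α₁ = β₁ (Model 1, one pulse picked uniformly per trial) or
β₁/2 (Model 2, both pulses summed). Choices are simulated from the
Bernoulli distribution (default 10,000 per replicate, 200 replicates),
pulse pairs resampled from the data, and each replicate refit with the
weaker/stronger factorization. Under Model 2 the two weights are equal;
under Model 1 the weaker pulse needs the larger weight. The order
factorization (C_1st/C_2nd) does not separate the models because sampling
is unbiased in pulse order. Ties |c₁| = |c₂| assign the first pulse to the
"weaker" regressor.

## Synthetic sessions

One latent DV per trial drives choice and rates. Leaders fire at
max(0, r₀ + g·(DV + ε)) while their response field is aligned (evidence
viewing until just after the saccade; again from just before fixation
reacquisition in the variants where the gaze returns) and at baseline
r₀ = 30 sp/s elsewhere; g = 25 sp/s per DV unit; ε is a per-neuron,
per-trial trait draw (SD 0.1) that keeps pool members weakly, not
perfectly, correlated. At the first handoff the supporter pool inherits the
frozen DV plus pool noise (SD 0.1). At the handoff back, the leader pool's
DV is the **spike-count readout of the supporter pool**: the pool average
of (count − r₀Δ)/(gΔ) over a 300-ms mid-IEM window, plus pool noise. This
choice makes the relay physically concrete — the quantity transmitted is
carried by spikes — and it fixes the semantics of the mediation analysis:
if the pool is a single fully recorded neuron with no pool noise, its
observed count is the entire conduit, and conditioning on it removes the
leader's pre/post autocorrelation; with a 50-member pool, one member's
count cannot absorb the pool signal. P2 updates the pool that holds the DV
when it arrives (leaders in variant 1, supporters in variant 2) by a
bounded diffusion increment over the 80-ms pulse.

**Sub-Poisson spiking.** Counts are generated in 20-ms bins. Given the
integrated intensity μ per bin, n is randomized between m = ⌊μ/(1−φ)⌋ and
m+1 with the mixture weight solving E[1/n] = (1−φ)/μ, and the count is
Binomial(n, μ/n); this yields E = μ and Var = φμ *exactly*. A per-bin
Binomial recipe cannot work at 1-ms resolution: a bin with μ ≈ 0.03 is
effectively Bernoulli, whose Fano factor is 1−μ ≈ 1 — no independent-bin
construction is sub-Poisson at that scale. Bins with μ < 1−φ therefore fall
back to Bernoulli(μ); with the default rates this affects only deeply
suppressed bins. Spike times are uniform within the bin. Window counts at
the 300-ms analysis scale inherit Fano ≈ φ (verified to ±0.05 at 20,000
trials). φ defaults to 0.6.

**What the generator does not emulate.** No perisaccadic transients, no
response-field geometry (T⁺ is global), no rate adaptation or oscillatory
structure, no slow nonstationarity across a session, no 40-ms uninformative
pulse onset (beyond the fixed 50-ms response latency), and choices are
driven by the behavioral DV rather than by a readout of the recorded
neurons. Passing tests therefore show the *analyses* behave as designed
under the generative assumptions, not that real LIP data satisfy those
assumptions.

## Rate analyses

Rates convolve the pooled point process with a non-causal 100-ms boxcar and
divide by pooled exposure; motion-aligned variable-duration analyses drop
spikes later than 250 ms after motion offset, with each trial leaving the
denominator at its own cutoff. Buildup rates use 20-ms PSTH bins, detrended
by the across-coherence mean; the onset of decision-related activity is the
leading edge of the first 300-ms window discriminating the two strongest
motions (rank-sum, p < 0.01), and slopes are fit to the independent bins in
[onset, onset + 200 ms], then regressed on signed coherence. The
P2-isolation procedure groups by P2 strength, subtracts each neuron's
all-trial average, and re-zeros each series in the 300-ms window around P2
onset; the regressions of the P2-epoch start/end responses inherit the α
coefficients of the start fit when testing the P2 weight β₁, use per-neuron
z-scored counts, correct trials only, run separately per choice and report
the larger p-value. "Inherited" is read as *fixed*, not refit, because the
hypothesis concerns the added P2 term only.

## Classification

Sustained decision-related activity = three consecutive, individually
significant (p < 0.05), same-sign statistics in 300-ms windows stepped by
50 ms (≥ 400 ms span). The variable-duration task uses rank-sum on choice
(displayed as d′ = mean difference / pooled SD); the two-pulse tasks use
Kendall τ against signed P1 strength, and against the P1+P2 sum in
post-P2 epochs (a neuron qualifies on either). Leaders must be sustained in
the 600-ms evidence epoch and *not* in the IEM epoch (250 ms after the
saccade to 200 ms before reacquisition); supporters must be sustained in
the IEM epoch; variant-2 roles are defined by exclusivity (after P1 or P2,
not both). Epoch boundaries use the median event offsets of the session;
windows align to events per trial.

**Null calibration.** Because adjacent windows share five sixths of their
spikes, per-window test statistics correlate at ρ ≈ 0.86 and the triple
rule attenuates the nominal 5% much less than independence would suggest:
direct null simulation gives ≈ 4% false positives per neuron in a 600-ms
epoch and ≈ 6% in the longer IEM epoch. The reported false-positive
calibration uses the 600-ms evidence epoch that defines the criterion.
This is an inherent property of the overlapping-window rule, worth knowing
before interpreting small populations.

## VarCE / CorCE

Residuals are taken about signed-coherence condition means (groups need
≥ 2 trials). VarCE subtracts φ × mean count; negative values are clipped to
zero and flagged, and CorCE is reported as undefined (NaN) when a
denominator is non-positive — typical for epochs in which a neuron carries
no decision signal. The covariance numerator is *not* corrected: counts in
different epochs/neurons are conditionally independent given the rates.
(A count correlated with itself violates that assumption; the self-pair
convenience flag subtracts the point-process term from the numerator too,
which restores CorCE = 1 exactly.) With φ = 0 the statistic reduces to the
ordinary correlation of residuals and is exactly invariant to
condition-dependent offsets.

φ is estimated by grid search (0.05–1.00, step 0.01) minimizing the summed
squared Fisher-z difference between the 10 unique off-diagonal CorCE values
of five decision-formation bins and the unbounded-diffusion prediction.
The prediction is √(i/j) for bins i ≤ j, which is exact when the latent
rate is constant within each bin and takes an independent random-walk step
between bins — the geometry the calibration simulator implements; i/j is
selectable for comparison (`prediction="linear"`).

The permutation null re-pairs one neuron's counts by permuting trials
within each signed-coherence group (1,000 surrogates by default; both
marginals and the condition structure are preserved, so only the covariance
numerator varies). p-values use the add-one convention and are uniform
under independence (KS-checked in the acceptance suite). Mediation uses
OLS on per-pair z-scored epoch counts with C_1st and the choice indicator
as covariates; rank-deficient designs are rejected naming the collinear
columns.

## Problem sizes in the acceptance computations

Drift-diffusion recovery: 10,000 trials. Pulse comparison: 200 replicates
of 10,000 choices. Classification: 150 trials/condition with 10-neuron
leader and supporter pools; null calibration: 50 trials/condition, 120
neurons at zero gain. VarCE/CorCE calibrations: 10,000–20,000 trials.
Permutation validity: 200 repetitions at 200 surrogates. Mediation:
5,000 trials, pool sizes 50 vs 1. These sizes put Monte-Carlo error well
inside the stated tolerances for every quantity except B̂ (see
Identifiability above).

## Known limitations

* B is weakly identified from fixed-duration choices at the default
  parameters; only κ and C₀ recovery is sharp.
* The sustained-selectivity rule's false-positive rate is epoch-length
  dependent (≈4–6%, not 0.05³) because of window overlap.
* Kendall τ p-values use scipy's exact enumeration only for small tie-free
  samples; spike counts tie heavily, so in practice the tie-corrected
  normal approximation is used.
* Sub-Poisson dispersion is exact at the generation-bin scale; windows
  straddling bin edges are split binomially, nudging edge contributions
  toward Poisson (negligible at 300-ms windows).
* CorCE estimates can exceed 1 when VarCE denominators are underestimated;
  values are not clipped (only Fisher-z inputs are, at |r| ≤ 0.999).
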