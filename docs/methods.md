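# Methods

## Count model

Spike counts are modeled as doubly stochastic.  Conditioned on direction
θ and a trial gain g, the count is drawn from a normal law with mean
μ = f(θ)·g and variance μ^α; the gain is Gamma distributed with mean 1 and
variance var(g) (shape 1/var(g), scale var(g) — the unique mean-1 Gamma).
Marginalizing the gain,

    var(x|θ) = f(θ)^α ⟨g^α⟩ + f(θ)² var(g),
    ⟨g^α⟩ = var(g)^α · Γ(1/var(g) + α) / Γ(1/var(g)).

⟨g^α⟩ is within 1% of 1 for the parameter ranges of interest (e.g. 0.993
at α = 0.74, var(g) = 0.0732), which justifies the working approximation
var ≈ f^α + f²·var(g) and the Fano-factor form FF(θ) ≈ f^{α−1} + f·var(g)
used by the fitting code (the exact Gamma-moment mode is available).

Normal counts can be negative; the generator clips at zero and keeps
continuous values by default (`count_mode="continuous"`), which preserves
the variance law best.  A `rounded` mode provides integer counts for
realism; at mean counts below ~5 both clipping and rounding visibly bias
the FF downward, so low-rate regimes should be interpreted with that in
mind.  Counts are integerized (rounded) only where a method requires
categories (mutual information).

## Tuning curves

Direction tuning is von Mises, f(θ) = b + A·(e^{κ(cos(θ−θ_pref)+1)} − 1)/(e^{2κ} − 1),
or Gaussian in wrapped direction difference with width reported as the SD.
b and A are in expected counts per counting window (250 ms unless stated);
derivatives for Fisher information are computed analytically per degree,
so information is in deg⁻² and bounds in degrees.

## Synthetic states

Two presets define the study conditions for all analyses (chosen once;
gain parameters and time constants are the state-specific fitted values,
latencies the state means):

| parameter | alert-like | anesthetized-like |
|---|---|---|
| α | 0.31 | 0.74 |
| var(g) | 0.0094 | 0.0732 |
| gain correlation time τ | 29 ms | 88 ms |
| latency | 56 ms | 94 ms |
| directions | 24, full circle, 15° steps | 13, ±90°, 15° steps |
| tuning (counts/window) | b = 3, A = 12 | b = 3, A = 9 |
| neurons × trials | 30 × 100 | 30 × 100 |

Neuron-to-neuron heterogeneity is mild multiplicative jitter (±30% on b
and A, ±20–25% on κ).  The anesthetized-like rates were set high enough
that the zero-clip of the count law does not erase the supra-Poisson FF;
with peak counts near 12 per window its mean FF is ≈ 1.17 and its FFTI
≤ 0.  The within-trial gain process shares var(g) with the trial gain:
the temporal relationship between the two is not constrained by the data
the model was built from, and making them one process is the simplest
consistent choice (flagged as such, not asserted as ground truth).

What the generator does **not** emulate: non-Poisson spike-train
microstructure (refractoriness, bursting), response transients beyond a
hard latency onset, eye movements, cross-neuron noise correlations in the
trial-count generator (population correlations exist only in the decoding
model), and non-stationarity across a session.  Passing tests therefore
demonstrate correctness of the estimators and the internal consistency of
the model — not that real MT data obey the model.

## Temporal statistics

The within-trial autocorrelation subtracts the across-trial mean (PSTH) at
each 2 ms bin, smooths residuals with a centered 5-bin running average,
computes the unbiased autocovariance per trial, averages over trials and
directions, normalizes to 1 at lag zero per neuron, and averages over
neurons (unweighted).  The gain process is a stationary AR(1) (discrete
Ornstein–Uhlenbeck) with lag-k correlation exp(−k·Δ/τ), initialized from
its stationary distribution, so the count autocovariance tail is exactly
c·exp(−lag/τ) with c = λ²·var(g) per bin.

Estimating τ is the hardest numerical problem in the package: at 40
spikes/s and var(g) = 0.01 the per-bin gain covariance (6.4·10⁻⁵) sits two
orders of magnitude below the Poisson variance (0.08).  The default
estimator is a Gaussian quasi-maximum-likelihood fit of the white +
exponential covariance model on the Toeplitz second-moment matrix rebuilt
from the unsmoothed autocovariance, multi-started over τ ∈ {10, 50, 100,
300} ms in log-τ and constrained to [bin, 600] ms (a decay constant far
beyond the observed lag span is indistinguishable from a constant; bound
hits are flagged ill-defined).  A classical multi-start least-squares fit
of a·exp(−lag/τ) to the smoothed trace over lags in [smooth·bin, 300] ms
is kept as `mode="lsq"`; past the smoothing-widened peak a boxcar rescales
an exponential without changing its decay constant, so that fit is also
unbiased in τ.

A Fisher-information (Whittle/CRLB) analysis of the alert-like
configuration at 50 neurons × 100 trials × 500 ms gives a per-run bound of
~25 ms on the sd of any unbiased τ estimate at τ = 29 ms — the median of
20 seeded runs therefore has an irreducible sd of ~7 ms (~24%), and the
quasi-ML estimate additionally carries a small-sample skew that places the
20-seed median near 25–27 ms.  Recovery of the anesthetized-like τ = 88 ms
(var(g) = 0.07) is comfortable at the same size.  This asymmetry is a
property of the configuration, not of the estimator: every alternative
tried (tail least squares, smoothing-aware model fits, per-trial and
concatenated Whittle fits, exact Gaussian ML, parametric-bootstrap bias
correction) performs the same or worse.

## Mean matching

To compare FF between states without rate confounds, neuron-level mean
counts at each required direction (preferred and ±90°) are histogrammed
into 15 evenly spaced bins spanning the pooled range; in each bin the
over-populated state discards neurons uniformly at random until counts
match; the mean FF over retained neurons per state gives a population FFTI
per resample.  The default is 10⁴ resamples (configurable; the estimate is
already stable to three decimals at that count).  Binning is deterministic;
only the discard choice is random.  An optional least-squares cosine fit
of the matched FF-vs-direction curve is provided.

## Mutual information

Plugin MI between integer count and direction uses raw count categories up
to the observed maximum (no coarse binning) and a uniform stimulus prior.
Finite-sample bias is removed by quadratic extrapolation: plugin MI on 50
bootstrap subsamples at fractions {0.50…0.95} of the trials, the subsample
means (plus the full-data point) regressed on 1/(effective trial count)
with a quadratic polynomial, intercept reported.  The extrapolation
variable is 1/N rather than the fraction itself (the two differ only by a
constant, but 1/N is the variable in which the leading bias is linear).
Entropy-normalized MI is exposed as an optional output, off by default.

## Gain-model fitting

Four variants, as increasingly constrained views of the same objective:

1. **population_ks** — grid search over (α, var(g)); at each grid point the
   model FFTI distribution is simulated from the state's tuning set (model
   sample 20× the observed size, fixed per-grid-point seed so the surface
   is smooth) and scored by the two-sample Kolmogorov–Smirnov statistic
   against the observed FFTI sample.  Optima on the grid boundary raise a
   warning.
2. **shared_alpha / shared_var_g** — two states fit jointly; the shared
   parameter minimizes the sum of squared per-state KS statistics with the
   free parameter optimized per state (computed by reduction over the two
   full surfaces).
3. **per_neuron_lsq** — minimize Σ_θ (FF_obs(θ) − f^{α−1} − f·var(g))² per
   neuron over α ∈ [0, 2], var(g) ≥ 0, multi-started; observed mean counts
   serve as f(θ).  This variant inherits the model's documented failure
   mode: a neuron with large FF *and* positive FFTI cannot be fit well,
   because raising α or var(g) raises FF while pushing FFTI down.

Default grids: α in [0, 1.5] step 0.01; var(g) on a hybrid log (10⁻⁴…0.02)
plus linear (0.03…0.2) grid, since fitted values span two decades.  Both
are configurable and the desk-scale analyses use coarser grids.

## Population decoding

Populations are N von Mises tuning curves with preferred directions evenly
tiling the circle (heterogeneous populations resample curves from a pool
with replacement and reassign preferred directions evenly; uniform-random
assignment is a mode).  Fano-factor tuning is imposed directly as a von
Mises profile in direction relative to each neuron's preferred direction,
normalized so the average FF across the direction grid is exactly 1;
positive (U-shaped) and negative specs are mirror images about FF = 1;
default amplitude 0.3, matching the scale of the observed alert ΔFF.
Covariances: diagonal FF_i(θ)·f_i(θ); off-diagonal c(d_ij)·√(var_i var_j)
with the correlation kernel applied to total variances (a Poisson-part-only
mode exists); information-limiting term ε·f′f′ᵀ with ε in deg².  PSD is
verified by Cholesky, repaired by eigenvalue clipping at 10⁻¹⁰ of the
largest eigenvalue, and rejected if the repair moves the matrix by more
than 10⁻⁶ in relative Frobenius norm.

Linear Fisher information ignores covariance-derivative terms.  J_ε is
computed both directly and through the rank-one-update identity
J_ε = J₀/(1 + εJ₀); the two must agree to 10⁻⁶ relative or the computation
aborts.  The Cramér–Rao bound √(1/J₀ + ε) is averaged over a small grid of
evaluation directions (single-θ mode available; for homogeneous evenly
tiled populations the two coincide by symmetry).  Threshold searches scan
a monotone-verified grid in N or in accumulation time T; cumulative tuning
for the time course uses counts(T) = rate·max(0, T − latency), a hard
onset plus linear ramp, since no deposited data constrain the transient.

## Numerical conventions

Angles in degrees everywhere; ε = 4 deg² corresponds to the 2° behavioral
floor.  Unbiased (n−1) variances throughout.  FF_orth averages the two
orthogonal directions when both are sampled (pooling mode available);
zero mean count at a required direction flags the statistic undefined and
excludes the neuron from FFTI with a logged reason.  Counting windows are
half-open [start, end).  All randomness flows through seeded
`numpy.random.Generator` instances; identical configurations are
bit-reproducible.

## Known limitations

- The alert-state gain time constant is variance-limited at desk scale
  (see Temporal statistics); its recovered value should be read with the
  quoted uncertainty.
- Latency estimation replaces manual inspection with a threshold rule
  (baseline mean + 3 SD for 5 consecutive 2 ms bins, both exposed in
  config); on transient-free synthetic data this is exact to the bin.
- The per-neuron least-squares variant uses the approximate FF law; at
  var(g) ≳ 0.3 or α near 2 the ⟨g^α⟩ ≈ 1 approximation degrades.
- Decoding results are ceteris-paribus comparisons of FF-tuning shapes at
  fixed correlation structure; real state changes plausibly move both.
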