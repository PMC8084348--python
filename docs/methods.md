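# Methods

## Model and estimand

For stationary point processes the transfer entropy (TE) rate from a
source *Y* to a target *X* given conditioning processes **Z** is the
expected log-ratio of the target's instantaneous event rate conditioned
on (target, source, conditioning) histories versus (target,
conditioning) histories, averaged over target events and scaled by the
target's mean rate λ̄_X. It is reported in nats per unit time; time
units are never rescaled internally, so the output units follow the
input event times.

Direct rate estimation is avoided by a Bayesian inversion: the TE rate
equals λ̄_X times the difference of two Kullback–Leibler divergences
between history densities *at* target events (p_X) and at arbitrary
times (p_U), one over joint histories (target + source + conditioning)
and one over conditioning-only histories. Histories are represented as
fixed-length vectors of backward inter-event intervals: the first
component is the interval from the observation time to the most recent
event (strict predecessor — an observation at a target event embeds the
ISI ending at that event), subsequent components are the preceding
inter-event intervals. Four sample sets are built: `J_X`, `C_X` at
every target event with sufficient history, and `J_U`, `C_U` at `N_U`
target-independent points placed within the span of the target process,
at fixed intervals (interior grid, default) or uniformly at random.
λ̄_X is estimated as (N_X − 1)/τ over the *retained* target events
(points dropped for insufficient history do not count); all
normalisations use retained counts.

## kNN estimators

Each KL divergence is estimated with Kozachenko–Leonenko terms: an
entropy term (k-th neighbour within the anchor's own set, self
excluded) and a cross-entropy term (k-th neighbour in the other set).
Two combinations are exposed:

* **4kl** — all four searches use the same fixed `k_global`; the
  ln(N−1), ln N_U, digamma and unit-ball-volume constants cancel in
  pairs.
* **ct** (default) — per KL term, the search radius is shared: the
  radius is the larger of the two k_global-th neighbour distances, the
  per-sample neighbour counts within that radius replace k in digamma
  corrections, and the ε terms are the distances to those count-th
  neighbours. This cancels a large part of the individual-term biases.
  When every count equals `k_global` the ct and 4kl estimates coincide
  exactly (a unit test pins this).

Distances use the Manhattan (ℓ1) norm by default; Euclidean and
Chebyshev are available. Distances are stored as raw distances rather
than ball diameters: any constant factor applied to all ε terms cancels
between the paired terms, and a test asserts the estimate is invariant
to a 2× convention change (`eps_scale`). In-radius counting is
non-strict (≤); ties are measure-zero for continuous data and the
sorted-distance representation makes tie order immaterial. Coincident
points (ε = 0) are clamped to the smallest positive float with a
warning; fully degenerate inputs raise an error.

Searches run on KD-trees with exclusion-window post-filtering. Queries
over-fetch a padded neighbour count and fall back to exhaustive scans
for the rare rows where padding is insufficient, so every result is
exactly what an all-pairs scan gives (the test suite verifies equality
to 1e-10 against an independent brute-force implementation, with
Theiler exclusion on and off, for both variants and all three norms).
All distance values are computed by one shared formula so that
radius-membership decisions are bit-consistent between the tree path
and the fallback path.

## Dynamic-correlation (Theiler) exclusion

Every sample records an exclusion window from the earliest event that
contributed an interval to any of its components, up to its observation
time. Neighbour searches skip candidates whose window intersects the
anchor's (closed intervals). Exclusion is on by default in all four
searches; a flag disables it (used by the oracle tests). Joint and
conditioning-only embeddings track their own windows (the
conditioning-only window ignores source events). Samples left with
fewer than `k_global` admissible neighbours in any search are dropped
from the average with a warning and the retained count is decremented.

## Surrogates and significance

The null hypothesis of zero conditional TE is the factorisation
p_X(x, y, z) = p_X(x, z) · p_U(y | x, z). Local-permutation surrogates
conform to it by replacing each target-event sample's source block with
that of one of its `k_perm` (x, z)-nearest neighbours in a pool of
embeddings built at `N_U_surrogate` target-independent points; already
used pool indices are removed from candidate sets to reduce duplicates
(falling back to the full candidate set when exhausted). The
permutation search uses the estimator's norm and honours Theiler
exclusion. Surrogate samples carry *both* exclusion windows — their own
and the pool donor's — and searches anchored at (or passing through)
surrogate samples exclude on either. Surrogate TE estimates reuse the
original `J_U`/`C_U` sets; the conditioning-term contributions are
unchanged by construction and are computed once. A fixed-interval pool
is identical across surrogates and is built and searched once; a random
pool is rebuilt per surrogate unless sharing is requested.

The p-value is the fraction of surrogate estimates at least as large as
the original (a conservative (c+1)/(n+1) variant is available);
`effective_te` is the original minus the surrogate mean. Time-shift
surrogates (whole-source translation by one uniform draw; no wrapping,
boundary samples drop by the usual history rule) implement the
conventional — and for conditional tests incorrect — null in which the
source is independent of everything.

## Benchmark simulators

* **Homogeneous Poisson** — i.i.d. exponential intervals.
* **Coupled pair** — Poisson source; target rate a truncated Gaussian
  bump in the time since the last source event (baseline 0.5, bump
  height 5, support 1, variance 0.01 time²; bump branch applies for
  t_y1 < t_cut, baseline from t_cut on). Simulated by thinning a
  Poisson stream at the analytic supremum rate; candidates before the
  first source event use the baseline; a burn-in prefix is discarded
  before selecting the contiguous block of target events. With the
  default source rate of 1.0 the ground-truth TE rate is
  0.5076 ± 0.001 nats/time. The test suite recomputes this truth with
  an exact filtering oracle: a grid filter over the hidden
  time-since-last-source-event state with closed-form (matrix
  exponential) no-event updates — no nearest-neighbour machinery. The
  same oracle shows the truth falls to ≈ 0.38 when the source rate is
  halved to 0.5, which is the variant used when reproducing the binned
  estimator's convergence to roughly half the reference value.
* **Noisy copy** — quasi-periodic mother (period 1, truncated-normal
  jitter, sd 0.05) and two daughters shifted by 0.25 and 0.5 with
  normal jitter (sd 0.05); daughter 1 optionally translated by ω.
  Conditioning on the mother makes daughter-1 → daughter-2 flow zero
  despite strong pairwise correlation.
* **Stimulus** — piecewise-constant-rate inhomogeneous Poisson
  (0.5 s windows, rates uniform on [0, 40] Hz), thinned from a bound
  rate, with a sequential refractory scan (keep iff ≥ refractory after
  the last *kept* event).
* **LIF target** — event-driven leaky integrate-and-fire neuron:
  exact exponential decay between delayed synaptic arrivals (no Euler
  step-size parameter), instantaneous ±strength jumps, threshold spikes
  with reset and a hard refractory period during which dynamics are
  frozen and arrivals are lost.

Every simulator takes an explicit seed and is bit-reproducible;
source/target/thinning draws use independent substreams. The simulators
emulate the benchmark systems' statistics only — no biophysical realism
beyond the stated models, and passing tests on them does not establish
performance on real recordings, whose non-stationarity, bursting and
measurement jitter the generators do not model.

## Discrete-time baseline

Events are binned (presence/absence by default) and the plugin
histogram estimate of the conditional mutual information between the
target's present bin and the lagged source history, given target (and
conditioning) histories, is divided by the bin width. Bins start at the
first target event. Unobserved history patterns contribute no samples
(0·log 0 = 0); no smoothing. The lag search first optimises the
conditioning lag on pairwise TE, then the source lag on conditional TE,
ties toward smaller lags; lags shift the whole history window. The
categorical conditional-permutation surrogate permutes source-history
codes within strata of identical (target, conditioning) history codes
at the chosen lags. This estimator is deliberately the paper-trail
baseline: on the coupled benchmark it converges, depending on bin
width, to values well away from the continuous-time ground truth.

## Problem sizes and numerical choices

Default problem sizes in the test suite are chosen to keep the full
suite in the tens of minutes on one CPU: the coupled-pair ground-truth
check uses 10 runs of 10^5 target events (the estimate's run-to-run
s.d. there is ≈ 0.004 nats/time); the zero-TE bias check uses 100
pairs of 10^4 events; surrogate calibration and power checks use 10^4
target events with reduced surrogate counts per test (p-value
resolution stated in each test). Long sums of near-cancelling logs are
accumulated in float64 via numpy pairwise summation, which is
sufficient at these sizes.

## Known limitations

* No whitening, marginal uniformisation, or local-nonuniformity bias
  corrections; the raw-interval representation is used as is.
* Embedding lengths are user-set; no automatic selection.
* The local-permutation surrogate ensemble is generated from a single
  realisation: at moderate sample sizes (≈10^4 events) its spread can
  under-represent the across-realisation variability of the estimator
  on strongly periodic processes, so p-values on such systems
  concentrate near 0 or 1 rather than spreading uniformly; calibration
  improves with the sample size (the reference behaviour was
  established at 5×10^4 events). See the calibration tests for the
  empirically measured false-positive rates.
* Continuous-valued (non-event) time series are out of scope.
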