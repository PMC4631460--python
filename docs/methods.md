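# Methods

## Sensor model

A nanotube sensor is a set of `N_T` equivalent, independent binding sites.
With ambient concentration `C` [M], an empty site fills at rate `kA·C`
[s⁻¹] and an occupied site empties at rate `kD` [s⁻¹]. The occupancy count
is a birth–death chain on `{0..N_T}` with adsorption propensity
`kA·C·(N_T − y)` and desorption propensity `kD·y`; its chemical master
equation (CME) is the `(N_T+1)`-dimensional linear ODE system with the
tridiagonal generator built by `sensor_model.cme_generator`.

Because the sites are independent and the per-site process is a two-state
Markov chain, the CME solves in closed form. Over one interval `Δt` with
`C` frozen, each initially occupied site remains occupied with probability
`λF` and each initially empty site is occupied with probability `λE`:

    a = kA·C + kD,   ρ = kA·C / a   (stationary occupied fraction)
    λE = ρ·(1 − e^(−aΔt)),   λF = λE + e^(−aΔt)

so the count conditioned on the previous count is
`Bin(y_prev, λF) * Bin(N_T − y_prev, λE)` (convolution). This form of
λF/λE is algebraically identical to the textbook expression containing
`kD/(kA·C)` but has no singularity at `C → 0`: `ρ → 0` gives the
pure-desorption limit (`λE = 0`, `λF = e^(−kD·Δt)`) without a branch. The
only special case is `a = 0` (both `C = 0` and `kD = 0`), where the kernel
is the identity. The derivatives `∂λF/∂C`, `∂λE/∂C` used by the Kalman
linearization are analytic (`occupancy_fraction_derivatives`), with the
`kD = 0` limit handled explicitly.

The continuum (mean-field) update `N⁺ = N·λF + (N_T − N)·λE` coincides
with the exact kernel's conditional mean; the moment-matched Gaussian
observation model uses the kernel's exact mean and variance (moment
matching is exact for binomials). The CME matrix exponential is retained
purely as an independent oracle: tests require kernel-vs-CME agreement to
≤ 1e−8 total variation and mean agreement to 1e−10.

## Simulators

Ground truth follows either a Gaussian random walk
(`x_k = x_{k−1} + N(0, q)`) or a regime-switching walk whose step variance
`q_{r_k}` is selected by a hidden two-state Markov chain (`r = 0`
quiescent, `r = 1` drifting) sampled from the transition matrix `Π`
starting in the quiescent state. A `forced_switch_time` mode pins the
regime path (quiescent before, drifting after) for paired detection
experiments and figure-style demonstrations. Truth trajectories are
clipped at zero — concentration is physical; with the quiescent-cell
noise (`q = 1e−16` over 2000 steps from `1e−5` M) the clip never
activates, while in the two-regime condition it occasionally binds, which
is the intended physical behaviour.

Counts are drawn either by an exact Gillespie simulation of the jump
process within each interval (kinetic Monte Carlo — the default for
benchmark data) or directly from the analytic kernel
(`simulate_counts_exact`). The two samplers are distributionally identical
at the sampling instants; the suite asserts this with a chi-square test at
1e5 one-step replicates. Sensors are conditionally independent given the
shared truth.

Defaults are the study conditions: `kA = 100` M⁻¹s⁻¹, `kD = 1e−3` s⁻¹,
`N_T = 10`, `Δt = 1` s; quiescent-cell runs are 2000 steps from
`x0 = 1e−5` M with sensors starting empty; two-regime runs are 4000 steps
with `q = (1e−16, 5e−14)` M², `Π = [[0.99, 0.01], [0.01, 0.99]]`, and
initial counts uniform on {0..9}. `x0 = 1e−5` M is the documented choice
for "a low (~10 µM) concentration"; it is configurable.

## Filters

The state is scalar, the state Jacobian exactly 1, so the Kalman predict
step is `cov += q`. The update stacks the `N_s` sensors: with diagonal
observation noise `R` and observation gradient vector `c`, the innovation
covariance `S = R + P·ccᵀ` is diagonal-plus-rank-one and the gain,
posterior and Gaussian innovation log-likelihood are computed in closed
form in O(N_s) (Sherman–Morrison / matrix-determinant lemma). The
linearization point is the predicted mean, clipped to zero if negative
(logged); posterior means are floored at zero for reporting only, the
internal recursion is unclipped.

Numerical safeguard: each sensor's observation variance is floored at
`1e−4` counts². At a clipped linearization point (`C = 0`, empty sensor)
the Gaussian model's variance is exactly zero while its gradient is ~1e3
counts/M; without the floor a run of zero counts drives the state
covariance to ~1e−18 M² and the next nonzero count throws the mean to
~1e−3 M with no recovery (observed in two-regime runs). The floor is ~1%
of the typical operating variance (~1e−2), so regular updates are
unaffected; it bounds the information of a single count observation at
the degenerate boundary, which is where the Gaussian approximation of a
discrete count is least trustworthy.

GPB2 branches over the four recent regime pairs, running predict (with the
arriving regime's `q`) and update per branch, weights branches by
`p(r_{k−1}|Y_{k−1})·Π[r_{k−1},r_k]·(innovation likelihood)` in log space,
and merges per arrival regime (mixture mean plus spread-of-means
covariance inflation). With `Π = I` and a degenerate initial regime it
reduces exactly to the plain KF (asserted to 1e−10).

The bootstrap particle filter proposes from the random-walk prior and
weights by the exact convolved-binomial likelihood, computed for all
particles at once from cached binomial-coefficient tables and cumulative
power arrays. Weights are combined in log space with max subtraction;
systematic resampling triggers at ESS < M/2, after which the point
estimate is the plain particle mean (otherwise the weighted mean).
Particles pushed negative by the proposal are reflected at zero — at the
study noise scales the reflection is a sub-1e−7 M perturbation affecting
a negligible fraction of proposals. `M = 200` by default.

The jump-Markov particle filter keeps one population per current regime
plus `p(r_k|Y_k)`. Each step expands to the four `(r_{k−1}, r_k)` branches,
propagates with the arriving regime's variance, and assigns each branch the
mass `p(r_{k−1}|Y_{k−1})·Π[r_{k−1},r_k]·L̄` where `L̄` is the branch's
marginal likelihood (`Σᵢ w_{k−1,i}·likᵢ`); the point estimate is the
mass-weighted sum of branch posterior means. Branches sharing an arrival
regime are collapsed: a single contributor is kept as-is (resampling only
at ESS < M/2, matching the plain filter's schedule — with `Π = I` the jump
filter consumes the random stream identically to the plain PF and their
particle paths coincide); multiple contributors are merged by systematic
resampling from the weighted mixture. No Metropolis rejuvenation step is
added: the branching/weighting recursion is complete as specified, and
the regime-path probability construction (prior mass × transition ×
marginal likelihood) is the standard choice.

The initial filter belief is `N(2e−5, 1e−10)` M — a deliberately wrong
mean (2× the truth) with a standard deviation of one state scale
(1e−5 M). An alternative initial covariance of `1e−5` is selectable
(`literal_init_cov`); taken as a variance in M² it corresponds to a
~3e−3 M standard deviation, 300× the state scale, and degrades the
particle filters badly, so the state-scale default is used.

## Benchmark metric

Per run, the scaled RMSE is `sqrt(mean((C_true − Ĉ)²·1e10))` — i.e.
concentrations in units of 1e−5 M, so 1.0 ≡ 10 µM error. Across runs the
aggregate is the square root of the grand mean of squared scaled errors
over all runs and samples (a `use_sqrt=False` variant reporting the plain
mean square is available). The Monte Carlo standard error is the delta-
method propagation of the standard error of the per-run mean squares.
Replicate seeds are spawned deterministically from one base seed and the
same datasets are reused across estimators within a sensor count, making
every comparison paired and every benchmark bit-reproducible.

Benchmark sizes: 100 replicate runs per cell; the quiescent-cell
experiment is run at 1, 5, 10 and 20 sensors, the two-regime experiment at
1 and 5 sensors (the sensor counts a single-cell neighbourhood supports,
and where the filters' ranking is already established).

## What the synthetic data does and does not show

The generator reproduces exactly the statistical structure the estimators
assume: piecewise-constant concentration over sampling intervals,
conditionally independent sensors, Markovian site kinetics with known
`kA`, `kD`, and Gaussian (or regime-switched Gaussian) concentration
increments. Passing benchmarks therefore demonstrate correctness of the
inference under the model, not robustness to model error: real SWNT data
adds photophysics, site heterogeneity, analyte cross-reactivity, spatial
concentration gradients, and unknown kinetic constants, none of which are
simulated. Within the model, the single-sensor configuration is strongly
information-limited (sensor response time `1/a ≈ 500` s at 10 µM): regime
awareness yields little at one sensor, and the drift-detection advantage
of GPB2/PF-MCMC over their single-regime counterparts is asserted in the
five-sensor configuration, where the posterior actually resolves the
drift. The hidden-regime posterior itself stays near the chain's 50/50
stationary law — single count transitions barely separate the two step
variances — so the jump filters' benefit comes from branch-adaptive
process noise rather than confident regime identification.

## Known limitations

- Single spatial location, single analyte; no transport model couples
  sensors.
- Kinetic constants are assumed known; no joint parameter/state
  estimation.
- The Gaussian filters use a first-order linearization; at saturating
  concentrations (`kA·C ≫ kD`) the observation gradient collapses and all
  filters lose information — an intrinsic sensor property, not a numerical
  artifact.
- No smoothing (fixed-interval or lag) is provided; all estimates are
  filtered.
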