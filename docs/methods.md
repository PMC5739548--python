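# Methods

## The model

`sartwell` simulates the within-host growth of an invading population —
pathogenic bacteria, mutant or cancerous cells — competing against healthy
resident cells on a contact network, and studies the distribution of the
time until the invaders dominate.  That time is the model's *incubation
period*: the delay between exposure and the onset of symptoms.  The point
of the model is that strongly right-skewed, approximately lognormal
incubation-period distributions (Sartwell's law) arise from the stochastic
dynamics alone, with no heterogeneity between hosts required.

The dynamics are a two-type Moran process on an undirected connected graph
of `N` nodes.  Residents have fitness 1, invaders relative fitness `r > 0`
(possibly infinite).  One elementary event occurs per time step:

* **Birth-death (Bd)** — a node is picked with probability proportional to
  its fitness; a uniformly random neighbour adopts its type.
* **Death-birth (Db)** — a node is picked with probability proportional to
  the *inverse* of its fitness (it dies); it adopts the type of a
  uniformly random neighbour.

Only these two of the six classical update-rule variants are implemented;
they are the most common and suffice to expose the rule-dependence of the
results.  Time is counted in elementary events, *including* events that
change nothing (invader replacing invader, resident replacing resident):
the analytic treatment of waiting times as geometric random variables
depends on counting every event.  A trial starts from `dose` invaders
(default 1) placed uniformly at random and ends when the invader count
reaches a threshold — the full network for fixation, or `ceil(f*N)` for a
partial-takeover fraction `f` — or hits zero (extinction).  Ensembles
conditioned on takeover use plain rejection: extinct trials are discarded
and counted.  Rejected trials consume the random stream, so ensembles are
reproducible given a seed but depend on the rejection history.

The model treats time as division events, not wall-clock time; mapping
steps to physical time would multiply by a per-disease proliferation rate
and is out of scope.  One-to-many (viral burst) reproduction is outside
the model's assumptions.

## Two skew mechanisms

**Infinitely fit invaders (coupon collection).**  At `r = inf` the invader
count never decreases; on the complete graph the chance that an event adds
an invader when `m` are present is `p_m = (N-m)/(N-1)`, so the fixation
time is the coupon-collector sum `T = sum_{k=1}^{N-1} Geo(k/(N-1))` with
mean `(N-1) H_{N-1} ~ N log N + N*gamma`.  Normalized as `(T - mu)/N`, it
converges to a Gumbel(−γ, 1) law — right-skewed, lognormal-looking.  The
star graph (spoke count `N`) converges to the same Gumbel with centering
`N² log N + (γ−1) N²` and scale `N²`.  The 1D ring grows as a contiguous
arc (`T = Geo(1) + sum_{m=2}^{N-1} Geo(1/m)`) and satisfies a
Lindeberg-Feller CLT: asymptotically normal with mean `(N²−N)/2` and
variance `(2N³−3N²+N)/6`.  Lattices of dimension `d ≥ 3` are right-skewed
with skewness `2 ζ(3η)/ζ(2η)^{3/2}`, `η = 1 − 1/d`, which increases with
`d` toward the Gumbel skewness `12√6 ζ(3)/π³ ≈ 1.1395`; `d = 2` is the
critical dimension.

**Neutral invaders (conditioned random walk).**  At `r = 1` the invader
count performs an unbiased random walk; on the complete graph the chance
the next *change* is a growth step is `r/(r+1)` for any `m`.  Conditioning
on fixation (reaching `N` before 0, probability `1/N` from a single
neutral invader) biases trajectories toward early growth but leaves a long
right tail of meandering excursions — right skew again, for any topology.

## Execution strategies and exactness

`run_trial` defaults to *jump-chain* kernels: because the per-event change
probability is constant between changes, the waiting time to the next
change is exactly geometric, so simulating only the embedded change chain
with geometric waits reproduces the per-step law *exactly* (no
approximation).  Three kernels exist:

* complete graph — the invader count is a sufficient statistic;
* 1D ring, Bd, dose 1 — the invader set stays a contiguous arc with
  per-event probabilities `p+ = r/(mr+N−m)`, `p− = 1/(mr+N−m)`;
* general graphs — an event-driven chain that maintains, per node, the
  count of opposite-type neighbours and the selection weight, picks the
  changing node proportionally to `weight × opposite-fraction`, and
  updates only the flipped node's neighbourhood.

`method="per_step"` forces the literal one-event-per-iteration loop
(`bd_step`/`db_step`), and `per_step_fixation_ensemble` is a bookkeeping-
optimized literal simulator; both serve as the reference implementations
against which the jump chains and the closed-form samplers
(`sample_coupon_collector`, `sample_ring_growth`,
`sample_complete_takeover`) are validated by two-sample KS tests.
Infinite fitness is a dedicated code path (uniform choice over invaders
under Bd, over residents under Db), never a large float.

## Statistics layer

The headline statistic is the **dispersion factor**: the geometric
standard deviation `σ_G = exp( sqrt( Σ log(x/μ_G)² / (n−1) ) )` with
`μ_G` the geometric mean.  It is dimensionless and scale-invariant, and
`log σ_G` estimates the scale of an unshifted lognormal; observed
infectious-disease incubation data give `σ_G ≈ 1.1–1.5`.  Conventions:
sample sd uses the `n−1` denominator; skewness is the moment estimator
`m₃/m₂^{3/2}` without bias correction.  Confidence intervals for `σ_G`
are percentile bootstrap (2000 resamples, 95%).

Moment fits: the Gumbel fit sets `β = sd·√6/π`, `α = mean − βγ`; the
three-parameter shifted lognormal matches mean, variance and skewness by
solving the depressed cubic `u³ + 3u − skew = 0` for `u = sqrt(w−1)`,
`w = exp(σ_log²)` (unique real root; non-positive skewness has no fit and
is reported as `converged=False`).

## Study conditions and generator defaults

The experiment runners fix the conditions the simulated-figure scenarios
use: heterogeneity and population-drift runs use a complete graph of
`N = 500`, `r = 10`, dose 1, full takeover.  Heterogeneity draws, per
replicate: fitness `r ~ Gamma(shape 10)` — the scale is set to 1 so the
mean equals the baseline fitness 10, which the source conditions leave
unstated; thresholds uniform on `{2,…,N}` or `ceil(f·N)` with
`f ~ Uniform(0,1)`; dose `1 + Poisson(10)`.  Draws with dose ≥ threshold
are rejected and redrawn.  Population drift adds a resident (adjacent to
all — hence the complete-graph restriction) or removes a uniform resident
with probability `1/N` per step (`N` the *initial* size, read from the
stated "constant … chance"), or ±1 each step with probability 1/2 in the
random-walk mode; the population event precedes the Moran event within a
step, an ordering the source leaves open.  The dispersion-factor table
runs nine families at the figure-caption sizes (e.g. complete `N=150`,
star 75 spokes, ring `N=75`, 2D `60×60`, 3D `11³` at `r=inf`; smaller
sizes at `r=1`).  Random families (Erdős–Rényi, small-world, k-regular,
scale-free) draw a *fresh connected graph per replicate*, so those
ensembles average over the graph distribution; for the scale-free family
this matters — per-realization dispersion ranges roughly 1.36–2.17 at
`N=100`, `m=3` — and the mixture value (~1.48–1.51) is what the package
reports.  The small-world base ring degree `k = 2` (shortcut probability
0.25) is a package default; only the shortcut probability is stated in
the source conditions.  Lattices are periodic (toroidal) in all
dimensions so every node has degree `2d`; boundary conditions above 1D
are a package choice and 2D/3D dispersion values are mildly sensitive to
it.

## Numerical choices, degenerate inputs, tie-breaks

* Standardizing finite-`N` complete-graph samples uses the exact harmonic
  centering `(N−1)H_{N−1}`, not the `N log N + Nγ` asymptote.
* `limit_law` exposes the star and ring constants exactly as the
  asymptotic formulas print them; see limitations for their finite-`N`
  accuracy.
* Absorbing states are legal inputs to the step functions and are
  returned unchanged (at `r = inf` with no invader to reproduce, or no
  resident to die, the event is a no-op but still a step).
* Disconnected random graphs are resampled with an incremented seed (cap
  100); k-regular parity violations and nonpositive truncation fractions
  raise.
* Rejection sampling caps total attempts at `1000 × n_samples` by default
  and raises if exceeded (a guard against implausibly low fixation
  probability, e.g. strongly deleterious invaders).
* Dose nodes are placed uniformly without replacement; the ring jump
  chain requires dose 1 (contiguity), other doses fall through to the
  general kernel.

## What desk-scale runs show — and what they do not

Test and table defaults use 10³–10⁴ replicates and the figure-caption
network sizes (the largest routine runs are `N=500` truncation sweeps and
`N=3600` lattice trials); the reference analyses used 10⁵–10⁶ replicates
and up to `N=5000`.  At 10⁴ replicates the dispersion factors are stable
to ±0.01–0.02, which is what the acceptance layer asserts.  Synthetic
ensembles are exactly the model's own law — they validate the
implementation and the limit theory, not the biology; nothing here
establishes that real incubation data follow these dynamics, only that
the model reproduces the observed dispersion range (≈1.1–1.4 for fit
invaders, ≈1.7 for neutral ones) and distribution shapes.

## Known limitations

* Asymptotic constants are leading-order: at 75 spokes the star centering
  `N² log N + (γ−1)N²` sits ~1.8% below the exact finite-`N` mean
  (21 908 vs 22 313), enough to fail a 10⁴-sample KS test against the
  Gumbel even though the *shape* matches (KS p ≈ 0.4 after zero-mean,
  unit-variance standardization).  Shape comparisons should standardize
  empirically.
* The ring is normal only asymptotically: its exact skewness is
  `≈ 2.6/√N` (0.302 at `N=75`), and the printed asymptotic variance
  exceeds the exact `N(N−1)(N−2)/3` by ~2% at that size, so
  10⁴-sample KS tests against a normal reject at `N=75`.
* Truncated Bd takeover converges to normality slowly: the exact
  cumulants of `T_f` give skewness 0.70 (`f=0.1`) and 0.19 (`f=0.9`) at
  `N=500`, and 0.21/0.06 at `N=5000`.  The qualitative Bd-vs-Db contrast
  (truncation removes the Bd slow phase, never the Db one) is robust at
  every size; near-zero Bd skew is not reached until `N ≫ 10⁴`.
* No continuous-time embedding, no directed/weighted graphs, no
  fitness heterogeneity across nodes within a run (only across runs), no
  importance sampling for deep-conditioning regimes.
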