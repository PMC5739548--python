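# sartwell

**Fixation-time distributions of Moran dynamics on networks — a stochastic
model of disease incubation periods.**

Incubation periods of diseases as different as typhoid, measles, polio and
several cancers share a striking statistical signature: right-skewed,
approximately lognormal distributions with a geometric standard deviation
("dispersion factor") of about 1.1–1.5 — Sartwell's law.  The classical
explanation appeals to heterogeneity between hosts, doses or strains.
This package implements an alternative: model the incubation process as an
invader (a pathogenic bacterium, a mutant cell) reproducing and competing
with healthy resident cells on a contact network under Moran dynamics.
The time until the invaders take over the network is the incubation
period, and its distribution comes out right-skewed for a wide range of
fitness levels, update rules and topologies — with no heterogeneity at
all.  The package is aimed at researchers in evolutionary dynamics,
mathematical epidemiology and cancer modelling who want reproducible
simulations of these dynamics together with the matching closed-form
limit laws and summary statistics.

## The model in brief

A network of `N` nodes holds residents (fitness 1) and invaders (fitness
`r`, possibly infinite).  Each time step is one elementary event:

- **Bd (Birth-death):** pick a node with probability ∝ fitness; a uniform
  neighbour adopts its type.
- **Db (Death-birth):** pick a node with probability ∝ 1/fitness (it
  dies); it adopts a uniform neighbour's type.

Starting from one random invader, the time `T` (in elementary events,
counting no-change events) until invaders occupy the whole network — or a
fraction `f` of it — is the incubation period; runs where the invaders go
extinct are discarded (no symptoms ever develop).

Two mechanisms generate the skew:

- `r = ∞` (aggressive invaders): on the complete graph
  `T = Σ_{k=1}^{N−1} Geo(k/(N−1))` — the coupon collector's waiting time —
  and `(T − μ)/N → Gumbel(−γ, 1)` with `μ = (N−1)H_{N−1} ≈ N log N + Nγ`.
  The star graph is Gumbel too; 1D/2D lattices are asymptotically normal;
  lattices with `d ≥ 3` have skewness `2ζ(3η)/ζ(2η)^{3/2}`, `η = 1 − 1/d`.
- `r = 1` (neutral invaders): the invader count is an unbiased random
  walk conditioned to hit `N` before 0 (probability `1/N`), which skews
  the surviving trajectories right on essentially any topology.

The headline statistic is the dispersion factor
`σ_G = exp( √( Σ log(x/μ_G)² / (n−1) ) )`, the geometric standard
deviation that Sartwell used to characterize incubation-period
variability.

## Worked example

Simulate 10⁴ fixation times for an infinitely fit invader on a complete
graph of 150 cells and fit a Gumbel by the method of moments:

```sh
$ sartwell simulate --graph complete --n 150 --rule Bd --r inf \
      --reps 10000 --seed 1 --out times.csv
10000 takeover times on complete -> times.csv (mean 828.4, sd 185.1,
skew 1.112, dispersion 1.2356, rejected 0)

$ sartwell fit --input times.csv --family gumbel
{"family": "gumbel",
 "params": {"alpha": 745.05, "beta": 144.33}, "converged": true}
```

The mean ≈ 828 matches the coupon-collector prediction
`149·H₁₄₉ ≈ 832`; the skew ≈ 1.11 is near the Gumbel skewness
`12√6 ζ(3)/π³ ≈ 1.14`; and the dispersion factor ≈ 1.236 sits in the
1.1–1.4 band the model predicts for highly fit invaders — squarely inside
the 1.1–1.5 range reported for real infectious diseases.  The same library
calls are available in Python (`sartwell.sample_coupon_collector`,
`sartwell.run_conditioned_ensemble`, `sartwell.stats.dispersion_factor`,
…).

Closed-form limit-law constants, e.g. for the 75-node ring (normal, mean
`(N²−N)/2`, sd `√((2N³−3N²+N)/6)`):

```sh
$ sartwell theory --graph ring_1d --n 75
{"family": "normal", "location": 2775.0, "scale": 371.25, ...}
```

The dispersion-factor table across all nine network families (here the
`r = ∞` regime at 500 replicates; ~1 min):

```sh
$ sartwell table1 --reps 500 --seed 1 --regimes inf
Network            r  dispersion                95% CI    reps
Complete         inf      1.2297      [1.2106, 1.2480]     500
Star             inf      1.3517      [1.3262, 1.3752]     500
1D Lattice       inf      1.1381      [1.1279, 1.1475]     500
2D Lattice       inf      1.0722      [1.0676, 1.0763]     500
3D Lattice       inf      1.1304      [1.1207, 1.1403]     500
Erdős-Rényi      inf      1.2561      [1.2368, 1.2765]     500
Small-World      inf      1.3200      [1.2993, 1.3406]     500
k-Regular        inf      1.2140      [1.1976, 1.2287]     500
Scale-Free       inf      1.4911      [1.4322, 1.5603]     500
```

`sartwell sweep --scenario truncation|heterogeneity|population` runs the
partial-takeover, host/pathogen-heterogeneity and drifting-population
scenarios and prints the skewness of each ensemble.

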