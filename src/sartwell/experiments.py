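"""Figure-level experiment runners: baseline ensembles, truncation sweeps,
host/pathogen heterogeneity, and time-varying population size.

Every runner takes an explicit RNG (or seed) and is bit-reproducible from
its configuration.  The heterogeneity and variable-population scenarios
follow the study conditions of the underlying model: a complete graph of
N=500 cells, invader fitness r=10, a single-invader dose, and complete
takeover, unless overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .engine import (
    Fitness,
    INFINITE_FITNESS,
    SampleSet,
    SimulationSpec,
    run_conditioned_ensemble,
    run_trial,
    sample_complete_takeover,
)
from .graphs import Network, make_network
from .stats import dispersion_factor, skewness, standardize

__all__ = [
    "HeterogeneitySpec",
    "PopulationChangeSpec",
    "run_heterogeneous_ensemble",
    "run_variable_population",
    "run_truncation_sweep",
    "run_network_ensemble",
    "classify_skew",
    "TABLE1_SCENARIOS",
    "dispersion_table",
]


# ---------------------------------------------------------------------------
# heterogeneity (host response, pathogen strain, dose)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Per-replicate random draws emulating between-host variability.

    fitness_gamma_shape
        If set, each replicate draws invader fitness r ~ Gamma(shape)
        (unit scale, so shape 10 has mean 10 — the baseline fitness).
    threshold_dist
        ``"uniform_integer"`` draws the symptom threshold uniformly from
        {2, ..., N}; ``"uniform_fraction"`` draws f ~ Uniform(0,1) and uses
        ceil(f*N).  ``None`` keeps the base threshold.
    dose_poisson_mean / dose_shift
        If the mean is set, each replicate draws the initial invader count
        from shift + Poisson(mean).
    Draws with dose >= threshold (or a zero fitness draw) are rejected and
    redrawn.
    """

    fitness_gamma_shape: float | None = None
    threshold_dist: Literal["uniform_integer", "uniform_fraction"] | None = None
    dose_poisson_mean: float | None = None
    dose_shift: int = 1

    @property
    def is_baseline(self) -> bool:
        return (
            self.fitness_gamma_shape is None
            and self.threshold_dist is None
            and self.dose_poisson_mean is None
        )


def _draw_replicate_spec(
    base: SimulationSpec, het: HeterogeneitySpec, rng: np.random.Generator
) -> SimulationSpec:
    n = base.network.node_count
    for _ in range(10_000):
        fit = base.fitness
        if het.fitness_gamma_shape is not None:
            r = float(rng.gamma(het.fitness_gamma_shape))
            if r <= 0:
                continue
            fit = Fitness(r)
        thr = base.resolved_threshold
        if het.threshold_dist == "uniform_integer":
            thr = int(rng.integers(2, n + 1))
        elif het.threshold_dist == "uniform_fraction":
            thr = int(math.ceil(float(rng.random()) * n))
        dose = base.dose
        if het.dose_poisson_mean is not None:
            dose = int(het.dose_shift + rng.poisson(het.dose_poisson_mean))
        if dose >= thr or dose < 1 or thr > n:
            continue
        return replace(base, fitness=fit, dose=dose, threshold=thr)
    raise RuntimeError("could not draw a valid (dose, threshold, fitness) triple")


def default_heterogeneity_base(seed: int | None = None) -> SimulationSpec:
    """Complete graph N=500, Bd, r=10, dose 1, complete takeover."""
    return SimulationSpec(
        network=make_network("complete", n=500),
        rule="Bd",
        fitness=Fitness(10.0),
        dose=1,
        threshold=None,
        seed=seed,
    )


def run_heterogeneous_ensemble(
    base: SimulationSpec,
    het: HeterogeneitySpec,
    n_samples: int,
    rng: np.random.Generator | None = None,
    max_attempts: int | None = None,
) -> SampleSet:
    """Takeover times with per-replicate heterogeneity, conditioned on
    takeover.  Each attempt draws fresh heterogeneity parameters; extinct
    trials are rejected."""
    if rng is None:
        rng = np.random.default_rng(base.seed)
    if het.is_baseline:
        return run_conditioned_ensemble(base, n_samples, rng, max_attempts)
    if max_attempts is None:
        max_attempts = 1000 * n_samples
    times = np.empty(n_samples, dtype=np.int64)
    got = rejected = attempts = 0
    while got < n_samples:
        if attempts >= max_attempts:
            raise RuntimeError("attempt cap exceeded in heterogeneous ensemble")
        spec = _draw_replicate_spec(base, het, rng)
        res = run_trial(spec, rng)
        attempts += 1
        if res.outcome == "reached_threshold":
            times[got] = res.steps
            got += 1
        else:
            rejected += 1
    return SampleSet(times=times, spec=base, n_rejected=rejected,
                     meta={"heterogeneity": het.__dict__.copy()})


# ---------------------------------------------------------------------------
# time-varying population size (complete graph)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationChangeSpec:
    """Resident-population drift on the complete graph.

    ``grow``/``shrink``: with probability ``per_step_probability`` (default
    1/N0) a resident node is added (adjacent to all preexisting nodes) or
    a uniformly random resident removed, each time step.  ``random_walk``:
    every time step a resident is added or removed, each direction with
    probability 1/2.  ``static``: no change.  Removal with no residents
    left is a no-op (takeover is then already complete).
    """

    mode: Literal["static", "grow", "shrink", "random_walk"] = "static"
    per_step_probability: float | None = None

    def probability(self, n0: int) -> float:
        if self.mode == "random_walk":
            return 1.0
        if self.per_step_probability is None:
            return 1.0 / n0
        return self.per_step_probability


def _variable_population_trial(
    n0: int, r: float, dose: int, pop: PopulationChangeSpec, rng: np.random.Generator
) -> tuple[bool, int]:
    """One Bd trial on a complete graph whose resident pool drifts.

    Each time step applies the population event first, then one Moran
    event; both together count as a single step.  Ends at takeover
    (no residents) or extinction (no invaders)."""
    m = dose
    res = n0 - dose
    p_event = pop.probability(n0)
    steps = 0
    mode = pop.mode
    while m > 0 and res > 0:
        if mode == "grow":
            if rng.random() < p_event:
                res += 1
        elif mode == "shrink":
            if rng.random() < p_event and res > 0:
                res -= 1
        elif mode == "random_walk":
            if rng.random() < 0.5:
                res += 1
            elif res > 0:
                res -= 1
        if res == 0:
            steps += 1
            break
        ntot = m + res
        w = m * r + res
        u = rng.random() * w * (ntot - 1)
        if u < m * r * res:
            m += 1
            res -= 1
        elif u < m * r * res + res * m:
            m -= 1
            res += 1
        steps += 1
    return m > 0, steps


def run_variable_population(
    base: SimulationSpec,
    pop: PopulationChangeSpec,
    n_samples: int,
    rng: np.random.Generator | None = None,
    max_attempts: int | None = None,
) -> SampleSet:
    """Conditioned takeover times under a drifting resident population.

    The base spec must be a complete graph (a newly added node is adjacent
    to all preexisting nodes, which presumes complete mixing)."""
    if base.network.family != "complete":
        raise ValueError("variable-population runs are defined on the complete graph")
    if base.fitness.infinite:
        raise ValueError("variable-population runner expects finite fitness")
    if rng is None:
        rng = np.random.default_rng(base.seed)
    if max_attempts is None:
        max_attempts = 1000 * n_samples
    n0 = base.network.node_count
    times = np.empty(n_samples, dtype=np.int64)
    got = rejected = attempts = 0
    while got < n_samples:
        if attempts >= max_attempts:
            raise RuntimeError("attempt cap exceeded in variable-population ensemble")
        ok, steps = _variable_population_trial(
            n0, base.fitness.value, base.dose, pop, rng
        )
        attempts += 1
        if ok:
            times[got] = steps
            got += 1
        else:
            rejected += 1
    return SampleSet(times=times, spec=base, n_rejected=rejected,
                     meta={"population": pop.__dict__.copy()})


# ---------------------------------------------------------------------------
# truncation sweep
# ---------------------------------------------------------------------------


def classify_skew(skew: float) -> str:
    """Crude shape label for a standardized takeover-time sample:
    |skew| < 0.15 -> 'normal-like'; skew > 0.3 -> 'gumbel-like'."""
    if abs(skew) < 0.15:
        return "normal-like"
    if skew > 0.3:
        return "gumbel-like"
    return "intermediate"


def run_truncation_sweep(
    network: Network,
    rule: str,
    f_values: Sequence[float],
    n_samples: int,
    rng: np.random.Generator | None = None,
    fitness: Fitness = INFINITE_FITNESS,
) -> dict[float, dict]:
    """Takeover times to a fraction f of the network, for each f.

    Returns ``{f: {"sample": SampleSet, "skewness": float, "shape": str}}``.
    On the complete graph at infinite fitness the exact geometric-sum
    sampler is used; otherwise the conditioned per-step ensemble.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = network.node_count
    out: dict[float, dict] = {}
    for f in f_values:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"truncation fraction must be in (0, 1], got {f}")
        thr = max(2, int(math.ceil(f * n)))
        if network.family == "complete" and fitness.infinite:
            ss = sample_complete_takeover(n, n_samples, rule=rule, threshold=thr, rng=rng)
        else:
            spec = SimulationSpec(
                network=network, rule=rule, fitness=fitness, threshold=thr
            )
            ss = run_conditioned_ensemble(spec, n_samples, rng)
        g = skewness(standardize(ss.times))
        out[f] = {"sample": ss, "skewness": g, "shape": classify_skew(g)}
    return out


# ---------------------------------------------------------------------------
# dispersion-factor table across network families
# ---------------------------------------------------------------------------

#: (label, family, params, fitness) for the two fitness regimes of the
#: dispersion-factor table; sizes follow the simulated-figure conditions.
TABLE1_SCENARIOS: dict[str, list[tuple[str, str, dict]]] = {
    "inf": [
        ("Complete", "complete", {"n": 150}),
        ("Star", "star", {"spokes": 75}),
        ("1D Lattice", "ring_1d", {"n": 75}),
        ("2D Lattice", "lattice_2d", {"shape": (60, 60)}),
        ("3D Lattice", "lattice_3d", {"shape": (11, 11, 11)}),
        ("Erdős-Rényi", "erdos_renyi", {"n": 115, "rho": 0.5}),
        ("Small-World", "small_world", {"n": 75, "rho": 0.25}),
        ("k-Regular", "k_regular", {"n": 100, "k": 3}),
        ("Scale-Free", "scale_free", {"n": 100, "m": 3}),
    ],
    "1": [
        ("Complete", "complete", {"n": 50}),
        ("Star", "star", {"spokes": 25}),
        ("1D Lattice", "ring_1d", {"n": 50}),
        ("2D Lattice", "lattice_2d", {"shape": (7, 7)}),
        ("3D Lattice", "lattice_3d", {"shape": (4, 4, 4)}),
        ("Erdős-Rényi", "erdos_renyi", {"n": 25, "rho": 0.5}),
        ("Small-World", "small_world", {"n": 25, "rho": 0.25}),
        ("k-Regular", "k_regular", {"n": 22, "k": 3}),
        ("Scale-Free", "scale_free", {"n": 22, "m": 3}),
    ],
}

_RANDOM_FAMILIES = {"erdos_renyi", "small_world", "k_regular", "scale_free"}


def run_network_ensemble(
    family: str,
    params: dict,
    rule: str,
    fitness: Fitness,
    n_samples: int,
    rng: np.random.Generator,
    fresh_graph: bool | None = None,
) -> SampleSet:
    """Conditioned takeover-time ensemble on a network family.

    Random families draw a fresh connected graph for every replicate by
    default, so the ensemble averages over the graph distribution as well
    as the dynamics.
    """
    if fresh_graph is None:
        fresh_graph = family in _RANDOM_FAMILIES
    if not fresh_graph:
        net = make_network(family, params, seed=int(rng.integers(2**31)))
        spec = SimulationSpec(network=net, rule=rule, fitness=fitness)
        return run_conditioned_ensemble(spec, n_samples, rng)
    times = np.empty(n_samples, dtype=np.int64)
    got = rejected = attempts = 0
    max_attempts = 1000 * n_samples
    while got < n_samples:
        if attempts >= max_attempts:
            raise RuntimeError("attempt cap exceeded in network ensemble")
        net = make_network(family, params, seed=int(rng.integers(2**31)))
        spec = SimulationSpec(network=net, rule=rule, fitness=fitness)
        res = run_trial(spec, rng)
        attempts += 1
        if res.outcome == "reached_threshold":
            times[got] = res.steps
            got += 1
        else:
            rejected += 1
    return SampleSet(times=times, n_rejected=rejected,
                     meta={"family": family, "params": dict(params), "rule": rule})


def dispersion_table(
    reps: int = 2000,
    seed: int = 0,
    regimes: Sequence[str] = ("inf", "1"),
    families: Sequence[str] | None = None,
    rule: str = "Bd",
    ci: bool = True,
    n_boot: int = 2000,
) -> list[dict]:
    """Dispersion factors (geometric standard deviations) of takeover
    times across network families, for infinitely fit and neutral
    invaders, with percentile-bootstrap 95% confidence intervals.

    Returns one record per (network, regime) with keys ``network``,
    ``fitness``, ``dispersion``, ``ci_low``/``ci_high`` and ``n``.
    """
    from .stats import bootstrap_dispersion_ci

    root = np.random.SeedSequence(seed)
    records = []
    for regime in regimes:
        fit = INFINITE_FITNESS if regime == "inf" else Fitness(float(regime))
        for (label, family, params), ss_seed in zip(
            TABLE1_SCENARIOS[regime], root.spawn(len(TABLE1_SCENARIOS[regime]))
        ):
            if families is not None and family not in families:
                continue
            rng = np.random.default_rng(ss_seed)
            sample = run_network_ensemble(family, params, rule, fit, reps, rng)
            summ = dispersion_factor(sample.times)
            rec = {
                "network": label,
                "family": family,
                "params": dict(params),
                "fitness": regime,
                "n": reps,
                "dispersion": summ.dispersion,
            }
            if ci:
                lo, hi = bootstrap_dispersion_ci(sample.times, n_boot=n_boot, rng=rng)
                rec["ci_low"], rec["ci_high"] = lo, hi
            records.append(rec)
    return records
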