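"""Moran Birth-death / Death-birth dynamics and fixation-time sampling.

The model: a network of ``N`` cells holds two types, residents (fitness 1)
and invaders (relative fitness ``r``, possibly infinite).  One elementary
update event happens per time step:

* **Bd** (Birth-death): a node is chosen from the whole population with
  probability proportional to its fitness; a uniformly random neighbour
  then adopts the chosen node's type.
* **Db** (Death-birth): a node is chosen to die with probability
  proportional to the *inverse* of its fitness; it adopts the type of a
  uniformly random neighbour.

Time is counted in elementary events, *including* events that change
nothing (an invader replacing an invader, a resident replacing a
resident).  The incubation period of a trial is the number of events from
the introduction of the invaders until their count first reaches a
threshold (the full population for fixation, or ``ceil(f*N)`` for partial
takeover).  Runs in which the invaders die out are discarded when an
ensemble conditioned on takeover is requested.

Two execution strategies are available and are identical in distribution:

* ``method="per_step"`` draws every elementary event explicitly via
  :func:`bd_step` / :func:`db_step` — the reference implementation;
* ``method="auto"`` (default) samples the waiting time between state
  *changes* as a geometric random variable and only simulates the embedded
  change chain.  Because the per-event change probability is constant
  between changes, the waiting time is exactly geometric, so this is a
  lossless acceleration, not an approximation.  Specialised chains exist
  for the complete graph (invader count is a sufficient statistic) and the
  1D ring under Bd (the invader set stays a contiguous arc); all other
  cases use a generic event-driven chain over the full label vector.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .graphs import Network

__all__ = [
    "Fitness",
    "INFINITE_FITNESS",
    "SimulationSpec",
    "TrialResult",
    "SampleSet",
    "bd_step",
    "db_step",
    "run_trial",
    "run_conditioned_ensemble",
    "per_step_fixation_ensemble",
    "sample_coupon_collector",
    "sample_ring_growth",
    "sample_complete_takeover",
]

Rule = Literal["Bd", "Db"]


@dataclass(frozen=True)
class Fitness:
    """Relative fitness ``r`` of an invader (residents have fitness 1).

    ``Fitness(math.inf)`` is the infinitely-fit limit, implemented as a
    dedicated code path (uniform choice over invaders under Bd, over
    residents under Db) rather than as a large float.
    """

    value: float

    def __post_init__(self):
        if not (self.value > 0):
            raise ValueError(f"fitness must be positive, got {self.value}")

    @property
    def infinite(self) -> bool:
        return math.isinf(self.value)


INFINITE_FITNESS = Fitness(math.inf)


@dataclass(frozen=True)
class SimulationSpec:
    """A single-trial configuration.

    ``threshold`` is the invader count at which symptoms are declared
    (``None`` means the whole network, i.e. fixation); ``dose`` invaders
    are placed uniformly at random without replacement at the start.
    """

    network: Network
    rule: Rule = "Bd"
    fitness: Fitness = INFINITE_FITNESS
    dose: int = 1
    threshold: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.rule not in ("Bd", "Db"):
            raise ValueError(f"rule must be 'Bd' or 'Db', got {self.rule!r}")
        n = self.network.node_count
        thr = self.resolved_threshold
        if not 1 <= self.dose < thr <= n:
            raise ValueError(
                f"need 1 <= dose ({self.dose}) < threshold ({thr}) <= N ({n})"
            )

    @property
    def resolved_threshold(self) -> int:
        return self.network.node_count if self.threshold is None else self.threshold

    def to_dict(self) -> dict:
        return {
            "family": self.network.family,
            "params": dict(self.network.params),
            "rule": self.rule,
            "fitness": "inf" if self.fitness.infinite else self.fitness.value,
            "dose": self.dose,
            "threshold": self.resolved_threshold,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TrialResult:
    outcome: Literal["reached_threshold", "extinct"]
    steps: int
    attempts_used: int = 1


@dataclass
class SampleSet:
    """An ensemble of takeover times with its provenance."""

    times: np.ndarray
    spec: SimulationSpec | None = None
    n_rejected: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def attempts(self) -> int:
        return len(self.times) + self.n_rejected

    def to_csv(self, path) -> None:
        """One integer time per row, plus a JSON sidecar with provenance."""
        np.savetxt(path, self.times, fmt="%d", header="time", comments="")
        sidecar = {
            "n_rejected": int(self.n_rejected),
            "spec": self.spec.to_dict() if self.spec is not None else None,
            **self.meta,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


# ---------------------------------------------------------------------------
# single elementary events (reference implementation)
# ---------------------------------------------------------------------------


def _weighted_pick(weights: np.ndarray, rng: np.random.Generator) -> int:
    total = weights.sum()
    cum = np.cumsum(weights)
    return int(np.searchsorted(cum, rng.random() * total, side="right"))


def bd_step(
    labels: np.ndarray, network: Network, fitness: Fitness, rng: np.random.Generator
) -> np.ndarray:
    """One Bd event, in place: fitness-weighted birth, uniform-neighbour death.

    ``labels`` is a boolean array, ``True`` marking invaders.  Under
    infinite fitness the reproducing node is uniform over invaders; if no
    invader exists the (absorbing) state is returned unchanged.
    """
    n = network.node_count
    if n == 0:
        raise ValueError("empty network")
    if fitness.infinite:
        inv = np.flatnonzero(labels)
        if len(inv) == 0:
            return labels
        i = int(rng.choice(inv))
    else:
        w = np.where(labels, fitness.value, 1.0)
        i = _weighted_pick(w, rng)
    nbrs = network.neighbors(i)
    j = int(nbrs[rng.integers(len(nbrs))])
    labels[j] = labels[i]
    return labels


def db_step(
    labels: np.ndarray, network: Network, fitness: Fitness, rng: np.random.Generator
) -> np.ndarray:
    """One Db event, in place: inverse-fitness death, uniform-neighbour birth.

    Under infinite fitness the dying node is uniform over residents
    (invaders never die); the all-invader state is returned unchanged.
    """
    n = network.node_count
    if n == 0:
        raise ValueError("empty network")
    if fitness.infinite:
        res = np.flatnonzero(~labels)
        if len(res) == 0:
            return labels
        i = int(rng.choice(res))
    else:
        w = np.where(labels, 1.0 / fitness.value, 1.0)
        i = _weighted_pick(w, rng)
    nbrs = network.neighbors(i)
    j = int(nbrs[rng.integers(len(nbrs))])
    labels[i] = labels[j]
    return labels


# ---------------------------------------------------------------------------
# exact jump-chain trial kernels
# ---------------------------------------------------------------------------


def _complete_growth_probs(n: int, m: int, r: float, rule: Rule) -> tuple[float, float]:
    """(p_up, p_down) for one elementary event on the complete graph.

    Bd: p_m+ = [mr/(mr+N-m)] * (N-m)/(N-1),  p_m- = [(N-m)/(mr+N-m)] * m/(N-1).
    Db mirrors the two stages with inverse-fitness death weights.  Infinite
    r gives p_m+ = (N-m)/(N-1) (Bd) or m/(N-1) (Db), p_m- = 0.
    """
    k = n - m
    if math.isinf(r):
        return ((k / (n - 1), 0.0) if rule == "Bd" else (m / (n - 1), 0.0))
    if rule == "Bd":
        w = m * r + k
        return (m * r / w) * (k / (n - 1)), (k / w) * (m / (n - 1))
    w = m + k * r
    return (k * r / w) * (m / (n - 1)), (m / w) * (k / (n - 1))


def _complete_trial(
    n: int, r: float, rule: Rule, dose: int, threshold: int, rng: np.random.Generator
) -> tuple[bool, int]:
    """Jump-chain trial on the complete graph (invader count is Markov)."""
    m = dose
    steps = 0
    while 0 < m < threshold:
        up, down = _complete_growth_probs(n, m, r, rule)
        pc = up + down
        steps += int(rng.geometric(pc))
        m += 1 if (down == 0.0 or rng.random() * pc < up) else -1
    return m >= threshold, steps


def _ring_trial(
    n: int, r: float, dose: int, threshold: int, rng: np.random.Generator
) -> tuple[bool, int]:
    """Jump-chain Bd trial on the periodic ring, single initial invader.

    The invader set stays a contiguous arc, and for every 1 <= m <= N-1 the
    per-event probabilities are p+ = r/(mr+N-m), p- = 1/(mr+N-m)
    (p+ = 1/m, p- = 0 at infinite r, except p+ = 1 at m = 1).
    """
    if dose != 1:
        raise ValueError("ring jump chain requires dose=1 (contiguity)")
    m = dose
    steps = 0
    inf = math.isinf(r)
    while 0 < m < threshold:
        if inf:
            up, down = (1.0 if m == 1 else 1.0 / m), 0.0
        else:
            w = m * r + (n - m)
            up, down = r / w, 1.0 / w
        pc = up + down
        steps += int(rng.geometric(pc))
        m += 1 if (down == 0.0 or rng.random() * pc < up) else -1
    return m >= threshold, steps


def _event_trial(
    network: Network,
    r: float,
    rule: Rule,
    labels: np.ndarray,
    threshold: int,
    rng: np.random.Generator,
) -> tuple[bool, int]:
    """Generic event-driven jump chain on an arbitrary network.

    The chosen node ``i`` (fitness-weighted for Bd, inverse-fitness for Db)
    causes a change with probability opp_i/deg_i, where opp_i counts
    neighbours of the opposite type: under Bd a uniform opposite neighbour
    flips, under Db node ``i`` itself flips.  We maintain
    ``w_i = s_i * opp_i / deg_i`` (s the selection weight), draw the wait
    to the next change as Geometric(sum(w)/sum(s)), and pick the changing
    node proportionally to ``w``.
    """
    indptr, indices = network.indptr, network.indices
    n = network.node_count
    deg = np.diff(indptr).astype(np.float64)
    lab = labels.astype(bool).copy()
    m = int(lab.sum())

    opp = np.zeros(n, dtype=np.float64)
    for i in range(n):
        nb = indices[indptr[i] : indptr[i + 1]]
        opp[i] = np.count_nonzero(lab[nb] != lab[i])

    inf = math.isinf(r)
    if inf:
        # Bd: only invaders reproduce; Db: only residents die
        def sel(l: np.ndarray) -> np.ndarray:
            return l.astype(np.float64) if rule == "Bd" else (~l).astype(np.float64)
    else:
        ri = r if rule == "Bd" else 1.0 / r

        def sel(l: np.ndarray) -> np.ndarray:
            return np.where(l, ri, 1.0)

    s = sel(lab)
    w = s * opp / deg
    W = s.sum()
    steps = 0

    while 0 < m < threshold:
        total = w.sum()
        steps += int(rng.geometric(total / W))
        cum = np.cumsum(w)
        i = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        if rule == "Bd":
            nb = indices[indptr[i] : indptr[i + 1]]
            opp_nb = nb[lab[nb] != lab[i]]
            x = int(opp_nb[rng.integers(len(opp_nb))])
        else:
            x = i
        # flip node x and refresh bookkeeping for x and its neighbours
        new = not lab[x]
        lab[x] = new
        m += 1 if new else -1
        nbx = indices[indptr[x] : indptr[x + 1]]
        opp[x] = deg[x] - opp[x]
        same = lab[nbx] == new
        opp[nbx] += np.where(same, -1.0, 1.0)
        sx_old = s[x]
        if inf:
            s[x] = 1.0 if (new == (rule == "Bd")) else 0.0
        else:
            s[x] = ri if new else 1.0
        W += s[x] - sx_old
        w[x] = s[x] * opp[x] / deg[x]
        w[nbx] = s[nbx] * opp[nbx] / deg[nbx]
    return m >= threshold, steps


# ---------------------------------------------------------------------------
# trials and ensembles
# ---------------------------------------------------------------------------


def _initial_labels(n: int, dose: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(n, dtype=bool)
    labels[rng.choice(n, size=dose, replace=False)] = True
    return labels


def run_trial(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    method: Literal["auto", "per_step"] = "auto",
) -> TrialResult:
    """Run one trial to takeover or extinction; count every elementary event.

    ``method="auto"`` uses the exact jump-chain kernels; ``"per_step"``
    forces the literal one-event-per-iteration reference loop.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    net = spec.network
    n = net.node_count
    thr = spec.resolved_threshold
    r = spec.fitness.value

    if method == "per_step":
        labels = _initial_labels(n, spec.dose, rng)
        step = bd_step if spec.rule == "Bd" else db_step
        steps = 0
        m = int(labels.sum())
        while 0 < m < thr:
            step(labels, net, spec.fitness, rng)
            steps += 1
            m = int(labels.sum())
        outcome = "reached_threshold" if m >= thr else "extinct"
        return TrialResult(outcome=outcome, steps=steps)

    if net.family == "complete":
        # the initial invader placement is exchangeable on the complete
        # graph, so only the dose matters
        ok, steps = _complete_trial(n, r, spec.rule, spec.dose, thr, rng)
    elif net.family == "ring_1d" and spec.rule == "Bd" and spec.dose == 1:
        ok, steps = _ring_trial(n, r, spec.dose, thr, rng)
    else:
        labels = _initial_labels(n, spec.dose, rng)
        ok, steps = _event_trial(net, r, spec.rule, labels, thr, rng)
    return TrialResult(
        outcome="reached_threshold" if ok else "extinct", steps=steps
    )


def run_conditioned_ensemble(
    spec: SimulationSpec,
    n_samples: int,
    rng: np.random.Generator | None = None,
    max_attempts: int | None = None,
    method: Literal["auto", "per_step"] = "auto",
) -> SampleSet:
    """Collect ``n_samples`` takeover times, rejecting extinct trials.

    Plain rejection sampling conditions the ensemble on the invaders
    reaching the threshold before extinction.  Rejected trials consume the
    random stream, so results are reproducible given the seed but depend
    on the rejection history.  ``max_attempts`` (default
    ``1000 * n_samples``) guards against implausibly low fixation
    probability.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if max_attempts is None:
        max_attempts = 1000 * n_samples
    times = np.empty(n_samples, dtype=np.int64)
    got = 0
    rejected = 0
    attempts = 0
    while got < n_samples:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"exceeded {max_attempts} attempts with only {got}/{n_samples} "
                "takeovers; fixation probability appears implausibly low"
            )
        res = run_trial(spec, rng, method=method)
        attempts += 1
        if res.outcome == "reached_threshold":
            times[got] = res.steps
            got += 1
        else:
            rejected += 1
    return SampleSet(times=times, spec=spec, n_rejected=rejected)


def per_step_fixation_ensemble(
    network: Network,
    n_samples: int,
    rng: np.random.Generator | None = None,
    dose: int = 1,
) -> SampleSet:
    """Literal event-by-event Bd fixation ensemble at infinite fitness.

    Every elementary event is drawn explicitly: a uniform invader gives
    birth onto a uniform neighbour.  No waiting times are collapsed, so
    this is the reference implementation the closed-form samplers
    (:func:`sample_coupon_collector`, :func:`sample_ring_growth`) and the
    jump-chain kernels are validated against.  Bookkeeping (an invader
    membership list and chunked pre-drawn uniforms) keeps it usable at
    10^4-replicate scale.
    """
    if rng is None:
        rng = np.random.default_rng()
    indptr, indices = network.indptr, network.indices
    n = network.node_count
    times = np.empty(n_samples, dtype=np.int64)
    chunk = 1 << 14
    for t in range(n_samples):
        is_inv = np.zeros(n, dtype=bool)
        start = rng.choice(n, size=dose, replace=False)
        is_inv[start] = True
        inv = list(start)
        m = dose
        steps = 0
        buf = rng.random(chunk)
        pos = 0
        while m < n:
            if pos + 2 > chunk:
                buf = rng.random(chunk)
                pos = 0
            i = inv[int(buf[pos] * m)]
            lo, hi = indptr[i], indptr[i + 1]
            j = indices[lo + int(buf[pos + 1] * (hi - lo))]
            pos += 2
            steps += 1
            if not is_inv[j]:
                is_inv[j] = True
                inv.append(j)
                m += 1
        times[t] = steps
    return SampleSet(times=times, meta={"sampler": "per_step", "n": n, "dose": dose})


# ---------------------------------------------------------------------------
# closed-form fast samplers for solvable graphs (infinite fitness, Bd)
# ---------------------------------------------------------------------------


def sample_coupon_collector(
    n: int, n_samples: int, rng: np.random.Generator | None = None
) -> SampleSet:
    """Fixation times on the complete graph at infinite fitness (Bd).

    With ``m`` invaders the chance an event adds one is
    ``p_m = (N-m)/(N-1)``, so the fixation time is the coupon-collector
    sum ``T = sum_{k=1}^{N-1} Geo(k/(N-1))`` with mean ``(N-1) H_{N-1}``.
    Identical in law to the per-step engine at r = inf, f = 1.
    """
    if n < 2:
        raise ValueError("need N >= 2")
    if rng is None:
        rng = np.random.default_rng()
    k = np.arange(1, n, dtype=np.float64)
    t = rng.geometric(k / (n - 1), size=(n_samples, n - 1)).sum(axis=1)
    return SampleSet(times=t, meta={"sampler": "coupon_collector", "n": n})


def sample_ring_growth(
    n: int, n_samples: int, rng: np.random.Generator | None = None
) -> SampleSet:
    """Fixation times on the periodic 1D ring at infinite fitness (Bd).

    The invader arc grows by one at rate 1/m per event (1 at m=1), so
    ``T = Geo(1) + sum_{m=2}^{N-1} Geo(1/m)`` with mean ``N(N-1)/2``.
    Identical in law to the per-step engine on the ring.
    """
    if n < 2:
        raise ValueError("need N >= 2")
    if rng is None:
        rng = np.random.default_rng()
    t = np.ones(n_samples, dtype=np.int64)
    if n > 2:
        m = np.arange(2, n, dtype=np.float64)
        t = t + rng.geometric(1.0 / m, size=(n_samples, n - 2)).sum(axis=1)
    return SampleSet(times=t, meta={"sampler": "ring_growth", "n": n})


def sample_complete_takeover(
    n: int,
    n_samples: int,
    rule: Rule = "Bd",
    threshold: int | None = None,
    rng: np.random.Generator | None = None,
) -> SampleSet:
    """Partial-takeover times on the complete graph at infinite fitness.

    ``T_f = sum_{m=1}^{M-1} Geo(p_m)`` with ``M`` the threshold and
    ``p_m = (N-m)/(N-1)`` (Bd) or ``m/(N-1)`` (Db).  Under Bd the slow
    geometric waits sit at the *end* of the invasion (residents scarce), so
    truncating at f < 1 removes them; under Db they sit at the beginning
    and survive truncation — the mechanism behind the rule-dependence of
    the takeover-time shape.
    """
    if n < 2:
        raise ValueError("need N >= 2")
    thr = n if threshold is None else threshold
    if not 1 < thr <= n:
        raise ValueError("threshold must be in (1, N]")
    if rng is None:
        rng = np.random.default_rng()
    m = np.arange(1, thr, dtype=np.float64)
    p = (n - m) / (n - 1) if rule == "Bd" else m / (n - 1)
    t = rng.geometric(p, size=(n_samples, thr - 1)).sum(axis=1)
    return SampleSet(
        times=t, meta={"sampler": "complete_takeover", "n": n, "rule": rule, "threshold": thr}
    )
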