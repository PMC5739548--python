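"""Unit and property tests for the Moran update rules and trial engines.

Independent oracles used here:

* exact one-step transition probabilities on the complete graph,
  p_m+ = [mr/(mr+N-m)] (N-m)/(N-1), p_m- = [(N-m)/(mr+N-m)] m/(N-1);
* exhaustive enumeration of a single update event on tiny graphs;
* an absorbing-Markov-chain linear solve for the neutral fixation
  probability;
* the closed-form geometric-sum samplers for the complete graph and ring.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from sartwell.engine import (
    Fitness,
    INFINITE_FITNESS,
    SimulationSpec,
    bd_step,
    db_step,
    per_step_fixation_ensemble,
    run_conditioned_ensemble,
    run_trial,
    sample_complete_takeover,
    sample_coupon_collector,
    sample_ring_growth,
)
from sartwell.graphs import make_network
from sartwell.theory import complete_fixation_mean


def enumerate_step(labels, net, r, rule):
    """Exact distribution over next states of one update event.

    Returns {labels_tuple: probability} by enumerating every (first node,
    neighbour) choice with its probability — the brute-force oracle for
    the step functions.
    """
    n = net.node_count
    w = np.array([r if labels[i] else 1.0 for i in range(n)])
    if rule == "Db":
        w = 1.0 / w
    w = w / w.sum()
    out = {}
    for i in range(n):
        nbrs = net.neighbors(i)
        for j in nbrs:
            nxt = list(labels)
            if rule == "Bd":
                nxt[j] = labels[i]
            else:
                nxt[i] = labels[j]
            key = tuple(nxt)
            out[key] = out.get(key, 0.0) + w[i] / len(nbrs)
    return out


def growth_prob(step_dist, labels):
    m0 = sum(labels)
    return sum(p for s, p in step_dist.items() if sum(s) == m0 + 1)


class TestSingleStep:
    def test_complete_growth_probability_matches_formula(self, rng):
        # N=3, m=1, r=1: p_1+ = (1/3)(2/2) = 1/3, from the exact enumeration
        net = make_network("complete", n=3)
        dist = enumerate_step((1, 0, 0), net, 1.0, "Bd")
        assert growth_prob(dist, (1, 0, 0)) == pytest.approx(1.0 / 3.0)

        # empirical frequencies of bd_step agree with p_m+/p_m- at N=20
        n, m, r = 20, 7, 2.0
        labels0 = np.zeros(n, dtype=bool)
        labels0[:m] = True
        netc = make_network("complete", n=n)
        reps = 20000
        ups = downs = 0
        for _ in range(reps):
            lab = labels0.copy()
            bd_step(lab, netc, Fitness(r), rng)
            dm = int(lab.sum()) - m
            ups += dm == 1
            downs += dm == -1
        w = m * r + (n - m)
        p_up = (m * r / w) * ((n - m) / (n - 1))
        p_dn = ((n - m) / w) * (m / (n - 1))
        for k, p in [(ups, p_up), (downs, p_dn)]:
            assert abs(k / reps - p) < 4 * math.sqrt(p * (1 - p) / reps)

    def test_infinite_fitness_complete_growth(self, rng):
        # r->inf Bd on complete graph: p_m = (N-m)/(N-1) exactly
        n, m = 10, 4
        net = make_network("complete", n=n)
        labels0 = np.zeros(n, dtype=bool)
        labels0[:m] = True
        reps = 20000
        ups = 0
        for _ in range(reps):
            lab = labels0.copy()
            bd_step(lab, net, INFINITE_FITNESS, rng)
            ups += int(lab.sum()) == m + 1
        p = (n - m) / (n - 1)
        assert abs(ups / reps - p) < 4 * math.sqrt(p * (1 - p) / reps)

    def test_absorbing_states_unchanged(self, rng):
        net = make_network("ring_1d", n=6)
        all_inv = np.ones(6, dtype=bool)
        all_res = np.zeros(6, dtype=bool)
        for fit in (Fitness(2.0), INFINITE_FITNESS):
            for step in (bd_step, db_step):
                assert step(all_inv.copy(), net, fit, rng).all()
                assert not step(all_res.copy(), net, fit, rng).any()

    def test_db_star_hub_invader_always_converts(self, rng):
        # r->inf Db with the hub as sole invader: a uniform spoke dies and
        # its only neighbour (the hub) is an invader, so every step converts
        net = make_network("star", spokes=5)
        hub = int(net.degrees.argmax())
        for _ in range(50):
            lab = np.zeros(6, dtype=bool)
            lab[hub] = True
            db_step(lab, net, INFINITE_FITNESS, rng)
            assert int(lab.sum()) == 2

    @pytest.mark.parametrize("n", [3, 4])
    def test_db_growth_equals_bd_growth_on_complete_graph(self, n):
        # exhaustive one-step enumeration: at r=1 on the complete graph the
        # two rules give identical growth probability from every mixed state
        net = make_network("complete", n=n)
        for m in range(1, n):
            labels = tuple(1 if i < m else 0 for i in range(n))
            g_bd = growth_prob(enumerate_step(labels, net, 1.0, "Bd"), labels)
            g_db = growth_prob(enumerate_step(labels, net, 1.0, "Db"), labels)
            assert g_bd == pytest.approx(g_db)

    def test_enumeration_probabilities_sum_to_one(self):
        net = make_network("ring_1d", n=4)
        for labels in itertools.product([0, 1], repeat=4):
            for rule in ("Bd", "Db"):
                dist = enumerate_step(labels, net, 3.0, rule)
                assert sum(dist.values()) == pytest.approx(1.0)


class TestTrials:
    def test_two_node_fixation_is_one_step(self, rng):
        spec = SimulationSpec(network=make_network("complete", n=2))
        for _ in range(20):
            res = run_trial(spec, rng)
            assert res.outcome == "reached_threshold"
            assert res.steps == 1

    def test_three_node_complete_mean_three(self, rng):
        # T = 1 + Geo(1/2) so E[T] = 3 at r->inf
        spec = SimulationSpec(network=make_network("complete", n=3))
        steps = [run_trial(spec, rng).steps for _ in range(8000)]
        assert np.mean(steps) == pytest.approx(3.0, abs=4 * np.std(steps) / np.sqrt(8000))
        assert min(steps) >= 2  # at least one step per added invader

    def test_infinite_fitness_never_goes_extinct(self, rng):
        for family, params in [("ring_1d", {"n": 12}), ("star", {"spokes": 8})]:
            net = make_network(family, params)
            for rule in ("Bd", "Db"):
                spec = SimulationSpec(network=net, rule=rule)
                for _ in range(30):
                    assert run_trial(spec, rng).outcome == "reached_threshold"

    def test_per_step_monotone_invader_count_at_infinite_fitness(self, rng):
        net = make_network("ring_1d", n=8)
        labels = np.zeros(8, dtype=bool)
        labels[3] = True
        prev = 1
        for _ in range(200):
            bd_step(labels, net, INFINITE_FITNESS, rng)
            m = int(labels.sum())
            assert m >= prev
            assert m + int((~labels).sum()) == 8  # conservation
            prev = m

    @pytest.mark.parametrize(
        "family, params, rule, r",
        [
            ("complete", {"n": 8}, "Bd", math.inf),
            ("complete", {"n": 8}, "Db", 2.0),
            ("ring_1d", {"n": 8}, "Bd", 1.5),
            ("star", {"spokes": 7}, "Bd", math.inf),
        ],
    )
    def test_jump_chain_matches_per_step_in_distribution(self, family, params, rule, r, rng):
        """The geometric jump-chain kernels and the literal per-step loop
        sample the same takeover-time law (two-sample KS)."""
        net = make_network(family, params)
        fit = INFINITE_FITNESS if math.isinf(r) else Fitness(r)
        spec = SimulationSpec(network=net, rule=rule, fitness=fit)
        a, b = [], []
        for _ in range(2500):
            ra = run_trial(spec, rng, method="per_step")
            if ra.outcome == "reached_threshold":
                a.append(ra.steps)
            rb = run_trial(spec, rng, method="auto")
            if rb.outcome == "reached_threshold":
                b.append(rb.steps)
        assert ks_2samp(a, b).pvalue > 0.01


class TestConditionedEnsembles:
    def test_neutral_acceptance_rate_matches_markov_chain_solve(self, rng):
        # absorbing-chain oracle: neutral fixation probability from one
        # invader is 1/N (solved linearly, not assumed)
        n = 4
        # embedded walk on m with reflecting waits: P(up|change)=1/2
        a = np.zeros((n - 1, n - 1))
        b = np.zeros(n - 1)
        for m in range(1, n):
            row = m - 1
            a[row, row] = 1.0
            if m + 1 < n:
                a[row, row + 1] = -0.5
            else:
                b[row] += 0.5
            if m - 1 >= 1:
                a[row, row - 1] = -0.5
        fix_prob = np.linalg.solve(a, b)[0]
        assert fix_prob == pytest.approx(1.0 / n)

        spec = SimulationSpec(
            network=make_network("complete", n=n), fitness=Fitness(1.0)
        )
        ss = run_conditioned_ensemble(spec, 2000, rng)
        rate = len(ss.times) / ss.attempts
        se = math.sqrt((1 / n) * (1 - 1 / n) / ss.attempts)
        assert abs(rate - 1.0 / n) < 4 * se

    def test_infinite_fitness_rejects_nothing(self, rng):
        spec = SimulationSpec(network=make_network("complete", n=30))
        ss = run_conditioned_ensemble(spec, 500, rng)
        assert ss.n_rejected == 0

    def test_neutral_complete_times_right_skewed(self, rng):
        from sartwell.stats import skewness

        spec = SimulationSpec(
            network=make_network("complete", n=50), fitness=Fitness(1.0)
        )
        ss = run_conditioned_ensemble(spec, 1500, rng, max_attempts=500_000)
        assert skewness(ss.times) > 0.5

    def test_times_bounded_below_by_conversions_needed(self, rng):
        spec = SimulationSpec(network=make_network("ring_1d", n=20), dose=1)
        ss = run_conditioned_ensemble(spec, 300, rng)
        assert (ss.times >= 19).all()

    def test_reproducible_given_seed(self):
        spec = SimulationSpec(
            network=make_network("complete", n=25), fitness=Fitness(2.0), seed=123
        )
        a = run_conditioned_ensemble(spec, 400)
        b = run_conditioned_ensemble(spec, 400)
        assert np.array_equal(a.times, b.times)
        assert a.n_rejected == b.n_rejected

    def test_attempt_cap_raises(self, rng):
        # fitness far below neutral: fixation from one invader in N=40 is
        # vanishingly rare, so a tiny cap must trip the safety error
        spec = SimulationSpec(
            network=make_network("complete", n=40), fitness=Fitness(0.05)
        )
        with pytest.raises(RuntimeError, match="attempts"):
            run_conditioned_ensemble(spec, 50, rng, max_attempts=60)


class TestFastSamplers:
    def test_coupon_collector_degenerate_and_mean(self, rng):
        assert (sample_coupon_collector(2, 50, rng).times == 1).all()
        n = 150
        ss = sample_coupon_collector(n, 20000, rng)
        exact = complete_fixation_mean(n)  # (N-1) H_{N-1} ~ N log N + N gamma
        se = ss.times.std(ddof=1) / math.sqrt(len(ss.times))
        assert abs(ss.times.mean() - exact) < 3 * se
        assert exact == pytest.approx(n * math.log(n) + n * np.euler_gamma, rel=0.01)

    def test_ring_growth_degenerate_and_mean(self, rng):
        assert (sample_ring_growth(2, 50, rng).times == 1).all()
        n = 75
        ss = sample_ring_growth(n, 20000, rng)
        se = ss.times.std(ddof=1) / math.sqrt(len(ss.times))
        assert abs(ss.times.mean() - n * (n - 1) / 2) < 3 * se

    def test_ring_equals_complete_at_n3(self, rng):
        # ring and complete graph coincide on three nodes
        a = sample_ring_growth(3, 6000, rng)
        b = sample_coupon_collector(3, 6000, rng)
        assert ks_2samp(a.times, b.times).pvalue > 0.01

    def test_per_step_reference_matches_samplers(self, rng):
        net = make_network("complete", n=40)
        ps = per_step_fixation_ensemble(net, 4000, rng)
        cc = sample_coupon_collector(40, 4000, rng)
        assert ks_2samp(ps.times, cc.times).pvalue > 0.01

    def test_bd_and_db_fixation_agree_on_complete_graph(self, rng):
        # at r->inf, f=1 the Bd and Db geometric sums share the same
        # success-probability multiset, so the laws coincide
        a = sample_complete_takeover(60, 6000, rule="Bd", rng=rng)
        b = sample_complete_takeover(60, 6000, rule="Db", rng=rng)
        assert ks_2samp(a.times, b.times).pvalue > 0.01


class TestSpecValidation:
    def test_spec_rejects_bad_dose_threshold(self):
        net = make_network("complete", n=10)
        with pytest.raises(ValueError):
            SimulationSpec(network=net, dose=0)
        with pytest.raises(ValueError):
            SimulationSpec(network=net, dose=5, threshold=5)
        with pytest.raises(ValueError):
            SimulationSpec(network=net, threshold=11)
        with pytest.raises(ValueError):
            SimulationSpec(network=net, rule="bD")
        with pytest.raises(ValueError):
            Fitness(0.0)

    def test_sampleset_csv_roundtrip(self, tmp_path, rng):
        spec = SimulationSpec(network=make_network("complete", n=12), seed=5)
        ss = run_conditioned_ensemble(spec, 100, rng)
        out = tmp_path / "times.csv"
        ss.to_csv(out)
        back = np.loadtxt(out, skiprows=1, dtype=np.int64)
        assert np.array_equal(back, ss.times)
        import json

        sidecar = json.loads((tmp_path / "times.csv.json").read_text())
        assert sidecar["spec"]["family"] == "complete"
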