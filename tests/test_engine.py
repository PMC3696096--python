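"""Update rules, schedules, the run loop and the plugin registry."""

import itertools
import math

import numpy as np
import pytest

import netgame as ng
from netgame import Strategy, UpdateRuleSpec
from netgame.engine import (
    available_rules,
    register_rule,
    unregister_rule,
    update_best_takes_over,
    update_fermi,
    update_proportional,
)

from conftest import random_networks
from reference_sim import naive_run


class StubRng:
    """Scripted draws; raises if a rule draws more than scripted."""

    def __init__(self, ints=(), floats=()):
        self._i = iter(ints)
        self._f = iter(floats)

    def integers(self, n):
        try:
            return next(self._i)
        except StopIteration:
            raise AssertionError("unexpected integer draw")

    def random(self, size=None):
        try:
            return next(self._f)
        except StopIteration:
            raise AssertionError("unexpected uniform draw")


def path(labels="abcd"):
    labs = list(labels)
    return ng.Network(labs, list(zip(labs, labs[1:])))


class TestBestTakesOver:
    def test_unique_maximum_is_adopted(self):
        net = path("fxy")  # f-x-y; focal f sees only x
        s = np.array([0, 1, 0], dtype=np.int8)
        pay = np.array([3.0, 6.0, 2.0])
        assert update_best_takes_over(0, pay, s, net, StubRng()) == Strategy.D

    def test_tie_breaks_uniformly(self):
        net = path("fx")
        s = np.array([0, 1], dtype=np.int8)
        pay = np.array([6.0, 6.0])
        # candidates ordered (focal, neighbor); scripted index picks each
        assert update_best_takes_over(0, pay, s, net, StubRng(ints=[0])) == Strategy.C
        assert update_best_takes_over(0, pay, s, net, StubRng(ints=[1])) == Strategy.D
        # empirical coin-flip over many seeds
        picks = [
            update_best_takes_over(0, pay, s, net, np.random.default_rng(k))
            for k in range(400)
        ]
        assert 0.4 < np.mean(picks) < 0.6

    def test_self_strictly_best_keeps_strategy(self):
        net = path("fxy")
        s = np.array([1, 0, 0], dtype=np.int8)
        pay = np.array([9.0, 8.0, 1.0])
        assert update_best_takes_over(0, pay, s, net, StubRng()) == Strategy.D

    def test_isolated_node_keeps_strategy(self):
        net = ng.Network(["a", "b", "c"], [("b", "c")])
        s = np.array([1, 0, 0], dtype=np.int8)
        assert update_best_takes_over(0, np.zeros(3), s, net, StubRng()) == Strategy.D


class TestFermi:
    def test_equal_payoffs_give_half(self):
        net = path("fx")
        s = np.array([0, 1], dtype=np.int8)
        pay = np.array([2.0, 2.0])
        adopt = update_fermi(0, pay, s, net, 0.1, StubRng(ints=[0], floats=[0.499]))
        keep = update_fermi(0, pay, s, net, 0.1, StubRng(ints=[0], floats=[0.501]))
        assert adopt == Strategy.D and keep == Strategy.C

    def test_closed_form_probability(self):
        # K = 0.1, focal payoff 1, neighbor 2: p = 1/(1+e^-10) ~ 0.9999546
        net = path("fx")
        s = np.array([0, 1], dtype=np.int8)
        pay = np.array([1.0, 2.0])
        p = 1.0 / (1.0 + math.exp(-10.0))
        below = StubRng(ints=[0], floats=[p - 1e-7])
        above = StubRng(ints=[0], floats=[p + 1e-7])
        assert update_fermi(0, pay, s, net, 0.1, below) == Strategy.D
        assert update_fermi(0, pay, s, net, 0.1, above) == Strategy.C

    def test_huge_payoff_gap_saturates(self):
        net = path("fx")
        s = np.array([0, 1], dtype=np.int8)
        pay = np.array([0.0, 1e6])
        # adoption probability -> 1: even u = 1 - 1e-12 adopts
        rng = StubRng(ints=[0], floats=[1.0 - 1e-12])
        assert update_fermi(0, pay, s, net, 0.1, rng) == Strategy.D

    def test_no_overflow_at_extreme_gaps(self):
        net = path("fx")
        s = np.array([1, 0], dtype=np.int8)
        pay = np.array([1e9, -1e9])
        rng = StubRng(ints=[0], floats=[0.5])
        assert update_fermi(0, pay, s, net, 0.1, rng) == Strategy.D  # keeps


class TestProportional:
    def test_no_uphill_no_draw(self, pd_game):
        net = path("fx")
        s = np.array([0, 1], dtype=np.int8)
        pay = np.array([5.0, 5.0])
        # neighbor not strictly better: keeps with certainty, no uniform drawn
        rng = StubRng(ints=[0], floats=[])
        assert update_proportional(0, pay, s, net, pd_game, rng) == Strategy.C

    def test_full_gap_adopts_with_probability_one(self, pd_game):
        # k_focal = k_j = 1, gap 6, denom 1 * (max(T,R) - min(S,P)) = 6 -> p = 1
        net = path("fx")
        s = np.array([0, 1], dtype=np.int8)
        pay = np.array([0.0, 6.0])
        rng = StubRng(ints=[0], floats=[1.0 - 1e-12])
        assert update_proportional(0, pay, s, net, pd_game, rng) == Strategy.D

    def test_identical_strategies_absorbing(self, pd_game):
        net = path("fx")
        s = np.array([1, 1], dtype=np.int8)
        pay = np.array([0.0, 9.0])
        rng = StubRng(ints=[0], floats=[0.0])
        assert update_proportional(0, pay, s, net, pd_game, rng) == Strategy.D

    def test_degenerate_payoff_matrix_rejected(self):
        m = ng.PayoffMatrix2x2(R=1, S=1, T=1, P=1)
        net = path("fx")
        s = np.array([0, 1], dtype=np.int8)
        with pytest.raises(ValueError, match="degenerate"):
            update_proportional(0, np.array([0.0, 1.0]), s, net, m,
                                StubRng(ints=[0]))


class TestStep:
    @pytest.mark.parametrize("rule", ["best_takes_over", "fermi", "proportional"])
    @pytest.mark.parametrize("schedule", ["synchronous", "semi_synchronous"])
    def test_uniform_states_are_absorbing(self, pd_game, rule, schedule):
        net = ng.make_graph("erdos_renyi", n=9, p=0.4, seed=2)
        rng = np.random.default_rng(0)
        for s0 in (ng.strategy_vector(net), ng.strategy_vector(net, net.labels)):
            s1 = ng.step(net, s0, pd_game, UpdateRuleSpec(name=rule),
                         schedule=schedule, rng=rng)
            assert np.array_equal(s0, s1)

    def test_k5_single_defector_fixates_in_one_step(self, pd_game, k5):
        # defector earns 4T = 24 > every cooperator's 3R = 9: all imitate it
        s = ng.strategy_vector(k5, ["n1"])
        s1 = ng.step(k5, s, pd_game, UpdateRuleSpec(), rng=np.random.default_rng(0))
        assert np.all(s1 == Strategy.D)

    def test_star_defecting_leaf_reverts_in_one_step(self, pd_game, star5):
        # hub earns 4R + S = 12 > leaf's T = 6: the leaf imitates the hub
        s = ng.strategy_vector(star5, ["n2"])
        s1 = ng.step(star5, s, pd_game, UpdateRuleSpec(),
                     rng=np.random.default_rng(0))
        assert np.all(s1 == Strategy.C)

    def test_semi_synchronous_q1_equals_synchronous_modulo_draws(self, pd_game, k5):
        s = ng.strategy_vector(k5, ["n1"])
        sync = ng.step(k5, s, pd_game, UpdateRuleSpec(),
                       schedule="synchronous", rng=np.random.default_rng(0))
        semi = ng.step(k5, s, pd_game, UpdateRuleSpec(q=1.0),
                       schedule="semi_synchronous", rng=np.random.default_rng(0))
        assert np.array_equal(sync, semi)  # here tie-free, so draws don't matter


class TestRun:
    def test_all_defect_stays_at_one(self, pd_game, k5):
        trace = ng.run(k5, ng.strategy_vector(k5, k5.labels), pd_game,
                       UpdateRuleSpec(), rounds=10, seed=1)
        assert np.all(trace.defector_fraction == 1.0)
        assert len(trace.defector_fraction) == 11

    def test_k5_trace_matches_enumerated_dynamics(self, pd_game, k5):
        trace = ng.run(k5, ng.strategy_vector(k5, ["n3"]), pd_game,
                       UpdateRuleSpec(), rounds=5, seed=0)
        assert trace.defector_fraction.tolist() == [0.2, 1, 1, 1, 1, 1]

    @pytest.mark.parametrize("rule", ["best_takes_over", "fermi", "proportional"])
    def test_same_seed_same_trace(self, pd_game, rule):
        net = ng.make_graph("erdos_renyi", n=10, p=0.4, seed=8)
        s = ng.strategy_vector(net, ["n1", "n5"])
        kw = dict(rounds=20, seed=123)
        a = ng.run(net, s, pd_game, UpdateRuleSpec(name=rule), **kw)
        b = ng.run(net, s, pd_game, UpdateRuleSpec(name=rule), **kw)
        assert np.array_equal(a.defector_fraction, b.defector_fraction)
        assert np.array_equal(a.final_strategies, b.final_strategies)

    def test_rounds_and_convergence_mutually_exclusive(self, pd_game, k5):
        s = ng.strategy_vector(k5)
        with pytest.raises(ValueError, match="exactly one"):
            ng.run(k5, s, pd_game, UpdateRuleSpec())
        with pytest.raises(ValueError, match="exactly one"):
            ng.run(k5, s, pd_game, UpdateRuleSpec(), rounds=5,
                   convergence=ng.ConvergenceSpec())

    def test_nonconvergence_is_flagged_not_raised(self, pd_game):
        # noisy Fermi dynamics with a cap below two full windows can never
        # certify drift convergence
        net = ng.make_graph("ring_lattice", n=12, k=2)
        spec = ng.ConvergenceSpec(window=50, max_rounds=60)
        trace = ng.run(net, ng.strategy_vector(net, ["n1", "n7"]), pd_game,
                       UpdateRuleSpec(name="fermi", K=10.0),
                       convergence=spec, seed=3)
        assert trace.converged is False
        assert trace.rounds == 60

    def test_fraction_always_in_unit_interval(self, pd_game):
        for seed, net in enumerate(random_networks(5, 10, seed=42)):
            trace = ng.run(net, ng.strategy_vector(net, ["n1"]), pd_game,
                           UpdateRuleSpec(name="fermi"), rounds=30, seed=seed)
            assert trace.defector_fraction.min() >= 0
            assert trace.defector_fraction.max() <= 1


class TestPluginRegistry:
    def test_registered_rule_drives_dynamics(self, pd_game, k5):
        register_rule("always_defect", lambda i, pay, s, net, params, rng: 1)
        try:
            s1 = ng.step(k5, ng.strategy_vector(k5), pd_game,
                         UpdateRuleSpec(name="plugin:always_defect"),
                         rng=np.random.default_rng(0))
            assert np.all(s1 == Strategy.D)
        finally:
            unregister_rule("always_defect")

    def test_builtin_name_collision_rejected(self):
        with pytest.raises(ValueError, match="already registered"):
            register_rule("fermi", lambda *a: 0)

    def test_duplicate_plugin_name_rejected(self):
        register_rule("tmp_rule", lambda *a: 0)
        try:
            with pytest.raises(ValueError, match="already registered"):
                register_rule("tmp_rule", lambda *a: 1)
        finally:
            unregister_rule("tmp_rule")

    def test_plugin_rng_flows_from_run_seed(self, pd_game, k5):
        register_rule("coin", lambda i, pay, s, net, params, rng:
                      int(rng.random() < 0.5))
        try:
            spec = UpdateRuleSpec(name="coin")
            s0 = ng.strategy_vector(k5)
            a = ng.run(k5, s0, pd_game, spec, rounds=10, seed=5)
            b = ng.run(k5, s0, pd_game, spec, rounds=10, seed=5)
            assert np.array_equal(a.defector_fraction, b.defector_fraction)
        finally:
            unregister_rule("coin")

    def test_unknown_rule_name(self, pd_game, k5):
        with pytest.raises(KeyError, match="unknown update rule"):
            ng.step(k5, ng.strategy_vector(k5), pd_game,
                    UpdateRuleSpec(name="nope"), rng=np.random.default_rng(0))


class TestOracleEquivalence:
    """The engine must match a naive recompute-everything simulator exactly."""

    @pytest.mark.parametrize("rule", ["best_takes_over", "fermi", "proportional"])
    @pytest.mark.parametrize("schedule", ["synchronous", "semi_synchronous"])
    def test_traces_identical_on_random_graphs(self, pd_game, rule, schedule):
        for k, net in enumerate(random_networks(25, 12, seed=hash(rule) % 1000)):
            seed = 1000 + k
            rng = np.random.default_rng(seed)
            defectors = [lab for lab in net.labels if rng.random() < 0.3]
            s0 = ng.strategy_vector(net, defectors)
            trace = ng.run(net, s0, pd_game, UpdateRuleSpec(name=rule),
                           schedule=schedule, rounds=15, seed=seed)
            ref_frac, ref_final = naive_run(
                net, s0, pd_game.R, pd_game.S, pd_game.T, pd_game.P,
                rule=rule, schedule=schedule, rounds=15, seed=seed,
            )
            assert trace.defector_fraction.tolist() == ref_frac
            assert trace.final_strategies.tolist() == ref_final

    def test_weighted_edges_as_probabilities_match_oracle(self):
        m = ng.get_game("pd_canonical")
        rng = np.random.default_rng(9)
        nets = random_networks(10, 10, seed=77)
        for k, base in enumerate(nets):
            # reweight edges into (0, 1) so weight_mode has bite
            edges = [(u, v, float(rng.uniform(0.1, 1.0)))
                     for u, v, _ in base.edge_list()]
            net = ng.Network(base.labels, edges)
            s0 = ng.strategy_vector(net, net.labels[::2])
            trace = ng.run(net, s0, m, UpdateRuleSpec(), weight_mode=True,
                           rounds=12, seed=50 + k)
            ref_frac, ref_final = naive_run(
                net, s0, m.R, m.S, m.T, m.P, weight_mode=True,
                rounds=12, seed=50 + k,
            )
            assert trace.defector_fraction.tolist() == ref_frac
            assert trace.final_strategies.tolist() == ref_final


def brute_force_orbits(net):
    """Automorphism orbits by exhaustive permutation search (n <= 8)."""
    n = net.n_nodes
    adj = {frozenset((int(a), int(b))) for a, b in zip(net.edge_u, net.edge_v)}
    orbits = {i: {i} for i in range(n)}
    for perm in itertools.permutations(range(n)):
        if all(frozenset((perm[a], perm[b])) in adj for e in adj for a, b in [tuple(e)]):
            for i in range(n):
                orbits[i].add(perm[i])
    return orbits


class TestAutomorphismSymmetry:
    def test_tie_free_deterministic_orbits_have_identical_traces(self, pd_game):
        # star and complete graphs: single-defector dynamics meet no payoff
        # ties, so best-takes-over runs are fully deterministic
        for net in (ng.make_graph("star", leaves=5), ng.make_graph("complete", n=6)):
            orbits = brute_force_orbits(net)
            traces = {}
            for i, lab in enumerate(net.labels):
                t = ng.run(net, ng.strategy_vector(net, [lab]), pd_game,
                           UpdateRuleSpec(), rounds=6, seed=0)
                traces[i] = t.defector_fraction.tolist()
            for i, orb in orbits.items():
                for j in orb:
                    assert traces[i] == traces[j]
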