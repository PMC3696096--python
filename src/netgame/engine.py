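"""Simulation engine: repeated rounds of play plus imitation dynamics.

One simulation round is (1) every node collects its accumulated payoff from
pairwise games with its neighbors, then (2) nodes revise their strategy by an
imitation rule, either all at once (synchronous) or each with probability q
(semi-synchronous).  Three replicator-type rules are built in and arbitrary
user rules can be registered as plugins.

Reproducibility contract
------------------------
A run is driven by a single ``numpy.random.Generator``; an identical seed
yields an identical trace.  Per round the draws occur in this fixed order:

1. with ``weight_mode`` on, one uniform per edge (edge order) for edge firing;
2. with the semi-synchronous schedule, one uniform vector of length n for
   per-node participation;
3. for each updating node in ascending node-index order, the rule's own
   draws:

   * ``best_takes_over`` — draws one integer only when several members of the
     closed neighborhood tie for the maximal payoff (candidates ordered focal
     first, then neighbors ascending);
   * ``fermi`` — one integer (neighbor choice) then one uniform (adoption);
     an isolated node draws nothing;
   * ``proportional`` — one integer (neighbor choice), then one uniform only
     if the chosen neighbor's payoff strictly exceeds the focal one.

This protocol is part of the public behavior: an independent implementation
that follows it reproduces traces exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .gamecore import PayoffMatrix2x2, Strategy, round_payoffs
from .netio import Network

__all__ = [
    "UpdateRuleSpec",
    "Trace",
    "update_best_takes_over",
    "update_fermi",
    "update_proportional",
    "register_rule",
    "unregister_rule",
    "available_rules",
    "step",
    "run",
]

#: plugin contract: (focal, payoffs, strategies, net, params, rng) -> Strategy
RuleFn = Callable[..., int]

BUILTIN_RULES = ("best_takes_over", "fermi", "proportional")


@dataclass
class UpdateRuleSpec:
    """Which imitation rule to apply and its knobs.

    K is the Fermi selection noise (smaller = closer to deterministic payoff
    comparison); q the per-node participation probability of the
    semi-synchronous schedule.  ``params`` is passed through to plugins.
    """

    name: str = "best_takes_over"
    K: float = 0.1
    q: float = 0.5
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("Fermi noise K must be > 0")
        if not 0 < self.q <= 1:
            raise ValueError("semi-synchronous q must be in (0, 1]")

    @property
    def resolved_name(self) -> str:
        return self.name.removeprefix("plugin:")


@dataclass
class Trace:
    """Per-round defector fraction and final state of one replicate."""

    defector_fraction: np.ndarray  # length rounds + 1, entry 0 = initial state
    final_strategies: np.ndarray
    rounds: int
    seed: int
    converged: Optional[bool] = None  # None = fixed-round run, no criterion

    def __post_init__(self):
        f = np.asarray(self.defector_fraction, dtype=float)
        if f.min() < 0 or f.max() > 1:
            raise ValueError("defector fraction outside [0, 1]")
        if len(f) != self.rounds + 1:
            raise ValueError("trace length must be rounds + 1")
        self.defector_fraction = f


# ---------------------------------------------------------------------------
# Built-in rules
# ---------------------------------------------------------------------------


def update_best_takes_over(focal, payoffs, s, net: Network, rng) -> int:
    """Adopt the strategy of the highest-payoff member of the closed
    neighborhood; ties among maximal members break uniformly at random."""
    nbrs = net.adjacency[focal]
    if len(nbrs) == 0:
        return int(s[focal])
    best = max(payoffs[focal], payoffs[nbrs].max())
    winners = []
    if payoffs[focal] == best:
        winners.append(focal)
    winners.extend(int(j) for j in nbrs if payoffs[j] == best)
    if len(winners) == 1:
        return int(s[winners[0]])
    return int(s[winners[int(rng.integers(len(winners)))]])


def update_fermi(focal, payoffs, s, net: Network, K: float, rng) -> int:
    """Pairwise-comparison (Fermi) rule: copy a random neighbor j with
    probability 1 / (1 + exp((pi_focal - pi_j) / K))."""
    nbrs = net.adjacency[focal]
    if len(nbrs) == 0:
        return int(s[focal])
    j = int(nbrs[int(rng.integers(len(nbrs)))])
    x = (payoffs[focal] - payoffs[j]) / K
    p = 1.0 / (1.0 + math.exp(min(max(x, -700.0), 700.0)))
    return int(s[j]) if rng.random() < p else int(s[focal])


def update_proportional(
    focal, payoffs, s, net: Network, m: PayoffMatrix2x2, rng
) -> int:
    """Replicator-style proportional imitation: copy a random neighbor j only
    if it did strictly better, with probability
    (pi_j - pi_focal) / (max(k_focal, k_j) * (max(T, R) - min(S, P)))."""
    nbrs = net.adjacency[focal]
    if len(nbrs) == 0:
        return int(s[focal])
    denom_payoff = max(m.T, m.R) - min(m.S, m.P)
    if denom_payoff <= 0:
        raise ValueError("degenerate payoff matrix: max(T, R) == min(S, P)")
    j = int(nbrs[int(rng.integers(len(nbrs)))])
    if payoffs[j] <= payoffs[focal]:
        return int(s[focal])
    k = max(len(net.adjacency[focal]), len(net.adjacency[j]))
    p = (payoffs[j] - payoffs[focal]) / (k * denom_payoff)
    return int(s[j]) if rng.random() < p else int(s[focal])


# ---------------------------------------------------------------------------
# Rule registry (plugins)
# ---------------------------------------------------------------------------


def _bto_adapter(focal, payoffs, s, net, params, rng):
    return update_best_takes_over(focal, payoffs, s, net, rng)


def _fermi_adapter(focal, payoffs, s, net, params, rng):
    return update_fermi(focal, payoffs, s, net, params["K"], rng)


def _proportional_adapter(focal, payoffs, s, net, params, rng):
    return update_proportional(focal, payoffs, s, net, params["m"], rng)


_RULES: dict[str, RuleFn] = {
    "best_takes_over": _bto_adapter,
    "fermi": _fermi_adapter,
    "proportional": _proportional_adapter,
}


def register_rule(name: str, rule: RuleFn) -> None:
    """Register a plugin rule callable mapping
    (focal, payoffs, strategies, network, params, rng) -> Strategy.
    Name collisions (including with built-ins) are rejected."""
    key = name.removeprefix("plugin:")
    if key in _RULES:
        raise ValueError(f"rule name {key!r} already registered")
    _RULES[key] = rule


def unregister_rule(name: str) -> None:
    """Remove a previously registered plugin rule (built-ins are protected)."""
    key = name.removeprefix("plugin:")
    if key in BUILTIN_RULES:
        raise ValueError(f"cannot unregister built-in rule {key!r}")
    _RULES.pop(key, None)


def available_rules() -> list[str]:
    return sorted(_RULES)


def _resolve_rule(rule: UpdateRuleSpec) -> RuleFn:
    try:
        return _RULES[rule.resolved_name]
    except KeyError:
        raise KeyError(
            f"unknown update rule {rule.name!r}; known: {available_rules()}"
        )


# ---------------------------------------------------------------------------
# Stepping and running
# ---------------------------------------------------------------------------


def step(
    net: Network,
    s: np.ndarray,
    m: PayoffMatrix2x2,
    rule: UpdateRuleSpec,
    schedule: str = "synchronous",
    weight_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Advance the population one round; returns the new strategy vector.

    Payoffs are computed once from the current strategies; every update in
    the round sees those pre-step payoffs and strategies.  Under the
    semi-synchronous schedule each node participates with probability q.
    """
    if rng is None:
        rng = np.random.default_rng()
    if schedule not in ("synchronous", "semi_synchronous"):
        raise ValueError(f"unknown schedule {schedule!r}")
    fn = _resolve_rule(rule)
    params = dict(rule.params)
    params.setdefault("K", rule.K)
    params.setdefault("q", rule.q)
    params["m"] = m
    payoffs = round_payoffs(net, s, m, weight_mode=weight_mode, rng=rng)
    if schedule == "semi_synchronous":
        participate = rng.random(net.n_nodes) < rule.q
    else:
        participate = None
    new = s.copy()
    for i in range(net.n_nodes):
        if participate is not None and not participate[i]:
            continue
        new[i] = fn(i, payoffs, s, net, params, rng)
    return new


def run(
    net: Network,
    initial: np.ndarray,
    m: PayoffMatrix2x2,
    rule: UpdateRuleSpec,
    schedule: str = "synchronous",
    weight_mode: bool = False,
    rounds: int | None = None,
    convergence=None,
    seed: int = 0,
) -> Trace:
    """Run one replicate and record the defector fraction per round.

    Exactly one of ``rounds`` (fixed length) or ``convergence`` (a
    :class:`~netgame.centrality.ConvergenceSpec`; run until the windowed mean
    defector fraction drifts less than the threshold, capped at
    ``max_rounds``) must be given.  Hitting the cap is reported through
    ``Trace.converged``, never raised.

    Once the population is uniform (all-C or all-D) under a built-in
    imitation rule the state is absorbing, so the remaining rounds are
    recorded without further simulation.
    """
    from .centrality import drift_converged  # local import avoids a cycle

    if (rounds is None) == (convergence is None):
        raise ValueError("give exactly one of rounds= or convergence=")
    s = np.asarray(initial, dtype=np.int8).copy()
    if s.shape != (net.n_nodes,):
        raise ValueError("initial strategy vector does not match network size")
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    fractions = [float(np.mean(s == Strategy.D))]
    # uniform states are absorbing only under pure imitation dynamics
    can_shortcut = rule.resolved_name in BUILTIN_RULES
    converged: Optional[bool] = None

    def uniform() -> bool:
        return can_shortcut and (s == s[0]).all()

    if rounds is not None:
        t = 0
        while t < rounds:
            if uniform():
                fractions.extend([fractions[-1]] * (rounds - t))
                t = rounds
                break
            s = step(net, s, m, rule, schedule, weight_mode, rng)
            fractions.append(float(np.mean(s == Strategy.D)))
            t += 1
    else:
        spec = convergence
        t = 0
        while True:
            if uniform():
                # frozen state: drift is zero once two full windows exist,
                # but the round cap still binds
                target = min(2 * spec.window, spec.max_rounds)
                fractions.extend([fractions[-1]] * max(target - t, 0))
                t = max(t, target)
                converged = 2 * spec.window <= spec.max_rounds
                break
            if t >= 2 * spec.window and drift_converged(fractions, spec):
                converged = True
                break
            if t >= spec.max_rounds:
                converged = False
                break
            s = step(net, s, m, rule, schedule, weight_mode, rng)
            fractions.append(float(np.mean(s == Strategy.D)))
            t += 1
    return Trace(
        defector_fraction=np.asarray(fractions),
        final_strategies=s,
        rounds=t,
        seed=seed,
        converged=converged,
    )
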