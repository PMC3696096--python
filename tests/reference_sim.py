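"""Independent naive reference simulator used as an oracle.

Recomputes everything from scratch each round with plain Python dicts and
loops — no caching, no vectorization, no absorbing-state shortcuts — and
follows the engine's documented per-round draw protocol so that, given the
same seed, it must produce the identical trace.  Kept deliberately separate
from the package: it shares no simulation code with it.
"""

from __future__ import annotations

import math

import numpy as np


def naive_run(
    net,
    initial,
    R, S, T, P,
    rule="best_takes_over",
    schedule="synchronous",
    K=0.1,
    q=0.5,
    weight_mode=False,
    rounds=10,
    seed=0,
):
    """Run `rounds` rounds; returns (defector fractions incl. round 0, final strategies)."""
    rng = np.random.default_rng(seed)
    labels = list(net.labels)
    n = len(labels)
    edges = [(labels.index(u), labels.index(v), w) for u, v, w in net.edge_list()]
    nbrs = {i: [] for i in range(n)}
    for a, b, _ in edges:
        nbrs[a].append(b)
        nbrs[b].append(a)
    nbrs = {i: sorted(v) for i, v in nbrs.items()}
    payoff = {  # (own, other) -> payoff to own; 0 = cooperate, 1 = defect
        (0, 0): R, (0, 1): S, (1, 0): T, (1, 1): P,
    }
    s = [int(x) for x in initial]
    fractions = [sum(s) / n]
    for _ in range(rounds):
        # 1. edge firing draws (edge order), if weights act as probabilities
        if weight_mode:
            u = rng.random(len(edges))
            live = [
                (a, b) for (a, b, w), x in zip(edges, u) if x < min(1.0, w)
            ]
        else:
            live = [(a, b) for a, b, _ in edges]
        pay = {i: 0.0 for i in range(n)}
        for a, b in live:
            pay[a] += payoff[(s[a], s[b])]
            pay[b] += payoff[(s[b], s[a])]
        # 2. participation draws
        if schedule == "semi_synchronous":
            part = rng.random(n) < q
        else:
            part = [True] * n
        # 3. per-node rule draws, ascending node order
        new = list(s)
        for i in range(n):
            if not part[i]:
                continue
            if not nbrs[i]:
                continue
            if rule == "best_takes_over":
                best = max([pay[i]] + [pay[j] for j in nbrs[i]])
                winners = ([i] if pay[i] == best else []) + [
                    j for j in nbrs[i] if pay[j] == best
                ]
                if len(winners) == 1:
                    new[i] = s[winners[0]]
                else:
                    new[i] = s[winners[int(rng.integers(len(winners)))]]
            elif rule == "fermi":
                j = nbrs[i][int(rng.integers(len(nbrs[i])))]
                x = (pay[i] - pay[j]) / K
                x = min(max(x, -700.0), 700.0)
                if rng.random() < 1.0 / (1.0 + math.exp(x)):
                    new[i] = s[j]
            elif rule == "proportional":
                j = nbrs[i][int(rng.integers(len(nbrs[i])))]
                if pay[j] > pay[i]:
                    denom = max(len(nbrs[i]), len(nbrs[j])) * (
                        max(T, R) - min(S, P)
                    )
                    if rng.random() < (pay[j] - pay[i]) / denom:
                        new[i] = s[j]
            else:
                raise ValueError(rule)
        s = new
        fractions.append(sum(s) / n)
    return fractions, s
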