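"""Symmetric 2-strategy normal-form games and per-round payoff accumulation.

A game is the 2x2 payoff matrix (R, S, T, P): R is the reward for mutual
cooperation, S the sucker's payoff of a cooperator exploited by a defector,
T the temptation to defect against a cooperator and P the punishment for
mutual defection.  The canonical prisoner's dilemma orders them T > R > P > S,
which makes defection individually rational while mutual cooperation pays
more — the tension the spatial simulations probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .netio import Network

__all__ = [
    "Strategy",
    "PayoffMatrix2x2",
    "GAME_PRESETS",
    "get_game",
    "pair_payoff",
    "round_payoffs",
    "strategy_vector",
]


class Strategy(IntEnum):
    """The two strategies of a social dilemma game."""

    C = 0  # cooperate
    D = 1  # defect


@dataclass(frozen=True)
class PayoffMatrix2x2:
    """Payoffs of a symmetric 2-strategy game from the row player's side.

    Attributes
    ----------
    R : reward, both cooperate
    S : sucker, cooperator meets defector
    T : temptation, defector meets cooperator
    P : punishment, both defect
    """

    R: float
    S: float
    T: float
    P: float

    def __post_init__(self):
        for name in ("R", "S", "T", "P"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"payoff {name} must be finite, got {v}")

    @property
    def is_prisoners_dilemma(self) -> bool:
        """Canonical PD ordering T > R > P > S (advisory, not enforced)."""
        return self.T > self.R > self.P > self.S

    def as_array(self) -> np.ndarray:
        """Matrix M with M[own, other]; strategies indexed C=0, D=1."""
        return np.array([[self.R, self.S], [self.T, self.P]], dtype=float)


#: Named game presets selectable from configuration.
GAME_PRESETS: dict[str, PayoffMatrix2x2] = {
    # canonical prisoner's dilemma at maximal temptation
    "pd_canonical": PayoffMatrix2x2(R=3.0, S=0.0, T=6.0, P=1.0),
    # low-temptation PD used for the strike-network case study
    "pd_strike": PayoffMatrix2x2(R=3.0, S=0.0, T=3.1, P=1.0),
    # weak PD: punishment degenerate at the sucker payoff
    "weak_pd": PayoffMatrix2x2(R=3.0, S=0.0, T=6.0, P=0.0),
    # hawk-dove with resource V=2, fight cost C=3 (defect = hawk)
    "hawk_dove": PayoffMatrix2x2(R=1.0, S=0.0, T=2.0, P=-0.5),
}


def get_game(name_or_matrix) -> PayoffMatrix2x2:
    """Resolve a preset name, an (R, S, T, P) tuple or a matrix instance."""
    if isinstance(name_or_matrix, PayoffMatrix2x2):
        return name_or_matrix
    if isinstance(name_or_matrix, str):
        try:
            return GAME_PRESETS[name_or_matrix]
        except KeyError:
            raise KeyError(
                f"unknown game preset {name_or_matrix!r}; "
                f"choose from {sorted(GAME_PRESETS)}"
            )
    R, S, T, P = name_or_matrix
    return PayoffMatrix2x2(R=float(R), S=float(S), T=float(T), P=float(P))


def pair_payoff(m: PayoffMatrix2x2, own: Strategy, other: Strategy) -> float:
    """Payoff to `own` when meeting `other`: (C,C)->R (C,D)->S (D,C)->T (D,D)->P."""
    return m.as_array()[int(own), int(other)]


def strategy_vector(net: Network, defectors=()) -> np.ndarray:
    """All-cooperate vector with the given nodes (labels or indices) defecting."""
    s = np.zeros(net.n_nodes, dtype=np.int8)
    for d in defectors:
        idx = d if isinstance(d, (int, np.integer)) else net.index(d)
        s[idx] = Strategy.D
    return s


def round_payoffs(
    net: Network,
    s: np.ndarray,
    m: PayoffMatrix2x2,
    weight_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Accumulated payoff of every node for one round of pairwise games.

    Each node plays every incident edge that *fires* this round and sums the
    resulting pair payoffs (no degree normalization, no carry-over between
    rounds).  With ``weight_mode`` off every edge fires.  With it on, edge
    (u, v) fires with probability min(1, w_uv) — edge weights read as the
    probability the game is played — with a single Bernoulli draw per edge
    shared by both endpoints; weights above 1 are clamped with a warning.
    """
    s = np.asarray(s, dtype=np.int8)
    if s.shape != (net.n_nodes,):
        raise ValueError(
            f"strategy vector has length {s.shape}, network has {net.n_nodes} nodes"
        )
    M = m.as_array()
    u, v = net.edge_u, net.edge_v
    if weight_mode:
        if rng is None:
            raise ValueError("weight_mode requires an rng")
        if np.any(net.weights > 1):
            warnings.warn(
                "edge weights > 1 clamped to firing probability 1",
                stacklevel=2,
            )
        fire = rng.random(net.n_edges) < np.minimum(net.weights, 1.0)
        u, v = u[fire], v[fire]
    payoffs = np.zeros(net.n_nodes, dtype=float)
    if len(u):
        np.add.at(payoffs, u, M[s[u], s[v]])
        np.add.at(payoffs, v, M[s[v], s[u]])
    return payoffs
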