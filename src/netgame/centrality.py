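"""Game centrality (GC) for nodes, linked pairs and node sets.

GC of a node i is the defector fraction, averaged over the last 50 recorded
rounds, that the population reaches when node i starts as the sole defector
in an otherwise fully cooperating network — a dynamic measure of i's power
to break cooperation.  The same protocol applies with a linked pair or an
arbitrary node set seeded as defectors.

Two stopping thresholds govern the estimate:

* **drift threshold** — a replicate's repeated rounds stop once the mean
  defector fraction changed by less than 0.01 between the last two 50-round
  windows (the trajectory has settled);
* **fluctuation threshold** — replicates are added (in batches) until the
  standard error of the per-replicate windowed mean falls below 0.01.

GC is a *relative* measure: it compares nodes of the same network under the
same game, rule and schedule; its numeric value shifts with any of those.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import Trace, UpdateRuleSpec, run
from .gamecore import PayoffMatrix2x2, Strategy, strategy_vector
from .netio import Network
from .stats import mean_sem

__all__ = [
    "ConvergenceSpec",
    "GCEstimate",
    "drift_converged",
    "game_centrality_node",
    "game_centrality_edge",
    "game_centrality_set",
    "sampled_set_gc",
    "gc_table",
]


@dataclass
class ConvergenceSpec:
    """Stopping rules for one GC estimate.

    window        rounds in the GC averaging window (and the drift windows)
    drift_threshold   per-replicate halting: |mean(last window) -
                      mean(previous window)| must fall below this
    sem_threshold     across-replicate halting: SEM of per-replicate GC
    min_replicates / max_replicates / max_rounds   batching bounds
    batch_size        replicates added between SEM checks
    """

    window: int = 50
    drift_threshold: float = 0.01
    sem_threshold: float = 0.01
    min_replicates: int = 10
    max_replicates: int = 10_000
    max_rounds: int = 10_000
    batch_size: int = 10

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.drift_threshold <= 0 or self.sem_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if not 1 <= self.min_replicates <= self.max_replicates:
            raise ValueError("need 1 <= min_replicates <= max_replicates")


@dataclass
class GCEstimate:
    """A GC value with its uncertainty and provenance."""

    target: object  # node label, (u, v) pair, or frozenset of labels
    gc: float
    sem: float
    replicates: int
    rounds: list[int] = field(default_factory=list)  # per-replicate round counts
    converged: bool = True
    values: np.ndarray | None = None  # per-replicate windowed means


def drift_converged(fractions: Sequence[float], spec: ConvergenceSpec) -> bool:
    """Has the windowed mean defector fraction stopped drifting?

    True iff at least two full windows of rounds are available and the means
    of the last two adjacent non-overlapping windows differ by less than the
    drift threshold.
    """
    f = np.asarray(fractions, dtype=float)
    w = spec.window
    if len(f) - 1 < 2 * w:  # entry 0 is the initial state, not a played round
        return False
    return abs(f[-w:].mean() - f[-2 * w:-w].mean()) < spec.drift_threshold


def _replicate_gc(trace: Trace, window: int) -> float:
    """Per-replicate GC: mean defector fraction over the final window."""
    return float(trace.defector_fraction[-window:].mean())


def _estimate(
    net: Network,
    defectors: Sequence[str],
    m: PayoffMatrix2x2,
    rule: UpdateRuleSpec,
    schedule: str,
    spec: ConvergenceSpec,
    seed: int,
    weight_mode: bool = False,
    target: object = None,
) -> GCEstimate:
    """Shared replicate-batching protocol behind all GC entry points.

    Replicate r runs with seed ``seed + r``; batches of replicates are added
    until the SEM of the per-replicate windowed means drops below the
    fluctuation threshold (with at least ``min_replicates``), or the
    replicate cap is hit.
    """
    initial = strategy_vector(net, defectors)
    values: list[float] = []
    rounds: list[int] = []
    all_drift_ok = True
    while True:
        batch = min(spec.batch_size, spec.max_replicates - len(values))
        for r in range(len(values), len(values) + batch):
            trace = run(
                net,
                initial,
                m,
                rule,
                schedule=schedule,
                weight_mode=weight_mode,
                convergence=spec,
                seed=seed + r,
            )
            values.append(_replicate_gc(trace, spec.window))
            rounds.append(trace.rounds)
            if trace.converged is False:
                all_drift_ok = False
        mean, sem = mean_sem(values)
        enough = len(values) >= spec.min_replicates and len(values) >= 2
        if (enough and sem < spec.sem_threshold) or len(values) >= spec.max_replicates:
            break
    converged = bool(all_drift_ok and sem < spec.sem_threshold)
    return GCEstimate(
        target=target,
        gc=float(mean),
        sem=float(sem),
        replicates=len(values),
        rounds=rounds,
        converged=converged,
        values=np.asarray(values),
    )


def game_centrality_node(
    net: Network,
    i: str,
    m: PayoffMatrix2x2,
    rule: UpdateRuleSpec | None = None,
    schedule: str = "synchronous",
    spec: ConvergenceSpec | None = None,
    seed: int = 0,
    weight_mode: bool = False,
) -> GCEstimate:
    """GC of node i: sole initial defector in an all-cooperator network."""
    rule = rule or UpdateRuleSpec()
    spec = spec or ConvergenceSpec()
    net.index(i)  # raises KeyError for unknown nodes
    return _estimate(
        net, [i], m, rule, schedule, spec, seed, weight_mode, target=str(i)
    )


def game_centrality_edge(
    net: Network,
    u: str,
    v: str,
    m: PayoffMatrix2x2,
    rule: UpdateRuleSpec | None = None,
    schedule: str = "synchronous",
    spec: ConvergenceSpec | None = None,
    seed: int = 0,
    weight_mode: bool = False,
) -> GCEstimate:
    """GC of a linked pair: both endpoints of an existing edge defect first.

    Defined only for adjacent nodes; non-edges raise ``ValueError``.
    """
    rule = rule or UpdateRuleSpec()
    spec = spec or ConvergenceSpec()
    if not net.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge; edge GC needs a linked pair")
    return _estimate(
        net, [u, v], m, rule, schedule, spec, seed, weight_mode,
        target=(str(u), str(v)),
    )


def game_centrality_set(
    net: Network,
    nodes: Iterable[str],
    m: PayoffMatrix2x2,
    rule: UpdateRuleSpec | None = None,
    schedule: str = "synchronous",
    spec: ConvergenceSpec | None = None,
    seed: int = 0,
    weight_mode: bool = False,
) -> GCEstimate:
    """GC of an arbitrary nonempty node set seeded as the initial defectors."""
    rule = rule or UpdateRuleSpec()
    spec = spec or ConvergenceSpec()
    nodes = [str(x) for x in nodes]
    if not nodes:
        raise ValueError("defector set must be nonempty")
    for x in nodes:
        net.index(x)
    return _estimate(
        net, nodes, m, rule, schedule, spec, seed, weight_mode,
        target=frozenset(nodes),
    )


@dataclass
class SampledSetGC:
    """Distribution of set-GC values over random subsets of a node pool."""

    mean: float
    sem: float
    values: np.ndarray  # one GC per sampled subset
    samples: list[GCEstimate]


def sampled_set_gc(
    net: Network,
    pool: Sequence[str],
    size: int,
    samples: int,
    m: PayoffMatrix2x2,
    rule: UpdateRuleSpec | None = None,
    schedule: str = "synchronous",
    spec: ConvergenceSpec | None = None,
    seed: int = 0,
    weight_mode: bool = False,
) -> SampledSetGC:
    """Mean set GC over random ``size``-node subsets of ``pool``.

    Each sample draws a subset uniformly without replacement, computes its
    set GC, and the summary is the mean with standard error across samples.
    The raw per-sample values are kept for distribution comparisons.
    """
    pool = [str(x) for x in pool]
    if size > len(pool):
        raise ValueError(f"subset size {size} exceeds pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    estimates: list[GCEstimate] = []
    for _ in range(samples):
        subset = list(rng.choice(pool, size=size, replace=False))
        sub_seed = int(rng.integers(2**31 - 1))
        estimates.append(
            game_centrality_set(
                net, subset, m, rule, schedule=schedule, spec=spec,
                seed=sub_seed, weight_mode=weight_mode,
            )
        )
    values = np.array([e.gc for e in estimates])
    mean, sem = mean_sem(values)
    return SampledSetGC(mean=float(mean), sem=float(sem), values=values,
                        samples=estimates)


def gc_table(
    net: Network,
    targets,
    m: PayoffMatrix2x2,
    rule: UpdateRuleSpec | None = None,
    schedule: str = "synchronous",
    spec: ConvergenceSpec | None = None,
    seed: int = 0,
    weight_mode: bool = False,
) -> pd.DataFrame:
    """Ranked GC table for many targets, sorted by GC descending.

    ``targets`` may be the string ``"all"`` (node sweep), a list of node
    labels, or a list of (u, v) edge pairs.  Equal GC values share a rank.
    Columns: target, gc, sem, replicates, mean_rounds, converged, rank.
    """
    rule = rule or UpdateRuleSpec()
    spec = spec or ConvergenceSpec()
    if isinstance(targets, str) and targets == "all":
        targets = list(net.labels)
    rows = []
    for k, t in enumerate(targets):
        t_seed = seed + k * max(spec.max_replicates, 1)
        if isinstance(t, (tuple, list)):
            est = game_centrality_edge(
                net, t[0], t[1], m, rule, schedule, spec, t_seed, weight_mode
            )
            name = f"{t[0]}--{t[1]}"
        else:
            est = game_centrality_node(
                net, t, m, rule, schedule, spec, t_seed, weight_mode
            )
            name = str(t)
        rows.append(
            {
                "target": name,
                "gc": est.gc,
                "sem": est.sem,
                "replicates": est.replicates,
                "mean_rounds": float(np.mean(est.rounds)) if est.rounds else 0.0,
                "converged": est.converged,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["target", "gc", "sem", "replicates", "mean_rounds", "converged"],
    )
    if len(df):
        df = df.sort_values("gc", ascending=False, kind="stable").reset_index(drop=True)
        df["rank"] = df["gc"].rank(method="min", ascending=False).astype(int)
    else:
        df["rank"] = pd.Series(dtype=int)
    return df
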