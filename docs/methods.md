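# Methods

## The model

Agents occupy the nodes of an undirected network and carry one of two
strategies, cooperate (C) or defect (D). Each round every node plays a
symmetric 2×2 game with each neighbor and accumulates the pair payoffs:
R for C–C, S and T for the C–D encounter (cooperator and defector side
respectively), P for D–D. Payoffs are recomputed fresh each round — there
is no memory — and are *not* degree-normalized; accumulated payoffs are the
standard convention for spatial games with best-response-style imitation,
and nothing in the protocol calls for normalizing them. After the play
phase, nodes revise strategies by imitation (below). The canonical
prisoner's dilemma preset uses R=3, S=0, T=6, P=1: the maximal temptation
makes an almost-fully-cooperating population as sensitive as possible to a
single defector, which is exactly what game centrality probes. A
low-temptation preset (T=3.1) and weak-PD / hawk–dove presets are included;
arbitrary (R, S, T, P) are accepted, with the PD ordering check advisory
only.

Edge weights are optionally read as the probability that the game is played
across that edge in a round (`weight_mode`): one Bernoulli draw per edge per
round, shared by both endpoints, since the game on an edge is a single
event. Weights above 1 (which arise naturally in structure networks, where
weights are inverse distances) are clamped to probability 1 with a warning.
The default leaves weights unused, matching the simulation conditions of the
reported case studies.

## Update rules and schedules

* **best_takes_over** — adopt the strategy of the maximal-payoff member of
  the closed neighborhood (focal node included). Ties among maximal members
  break uniformly at random; this is the rule's only stochasticity, and it is
  what makes outcomes like "defection fixates in 8% of replicates" possible
  at all under an otherwise deterministic dynamic.
* **fermi** — pick one neighbor j uniformly; adopt its strategy with
  probability 1/(1 + exp((Π_focal − Π_j)/K)). The pairwise-comparison form is
  the standard one; the noise K (default 0.1, configurable) is not dictated
  by the protocol, so it is surfaced in every config manifest rather than
  buried.
* **proportional** — pick one neighbor j uniformly; if it did strictly
  better, adopt with probability (Π_j − Π_focal)/(max(k_focal, k_j)·(max(T,R)
  − min(S,P))), the replicator-rule normalization that bounds the ratio in
  [0, 1] for accumulated payoffs.

Schedules: **synchronous** (every node updates against the pre-step payoffs)
and **semi-synchronous** (each node updates with independent probability q
per round, default 0.5 — the minimal interpolation between synchronous and
fully asynchronous updating). Isolated nodes keep their strategy. User rules
plug in by name via `register_rule` and receive the run's RNG, so plugins
inherit reproducibility.

Every replicate is driven by one `numpy.random.Generator`; the per-round
draw order (edge firing → participation → per-node rule draws in ascending
node order) is documented in `engine.py` and is part of the public contract.
An independent naive simulator that follows it (kept in
`tests/reference_sim.py`, sharing no code with the engine) reproduces traces
bit-for-bit; this dual-route check runs in both the test suite and the
acceptance script. Replicate r of an estimate uses seed `root_seed + r`.
Uniform populations are absorbing under all built-in rules (imitation can
only copy existing strategies), so once a replicate reaches all-C or all-D
the remaining rounds are recorded without simulation; this shortcut is
disabled for plugin rules, which need not preserve uniformity.

## Game centrality

GC of a target (node, linked pair, or node set) is estimated as:

1. start from all-cooperate with the target defecting;
2. per replicate, iterate rounds until the **drift criterion** holds — the
   mean defector fraction over the last 50-round window differs from the
   previous, non-overlapping 50-round window by less than 0.01 — or a
   10,000-round cap is hit (reported, never raised: lattice-like topologies
   may genuinely never settle);
3. the replicate's GC is its defector fraction averaged over the final
   50-round window;
4. replicates are added in batches of 10 until the **fluctuation
   criterion** holds — SEM of the per-replicate GC below 0.01 — with at
   least 10 and at most 10,000 replicates.

The drift test is operationalized as the difference of two adjacent
non-overlapping window means, the most direct reading of "the mean changed
less than the threshold over the last window". An estimate is flagged
converged only if both criteria were met in every replicate; a
non-converged replicate still contributes its final-window mean, so the
estimate degrades gracefully rather than disappearing. For deterministic
dynamics (best-takes-over with no ties encountered) all replicates are
identical and the estimate terminates at the minimum 10 replicates with
SEM 0. All thresholds, the window, and the caps live in `ConvergenceSpec`
and are recorded in the run manifest.

Edge GC requires the pair to be linked (the measure is defined for
neighboring pairs); set GC accepts any nonempty subset. `sampled_set_gc`
draws subsets uniformly without replacement within each sample and keeps the
raw per-sample GC values so that distributions, not just means, can be
compared (the chi-square below). GC is a *relative* measure: it ranks nodes
of one network under one game setting; its absolute value moves with the
payoffs, rule, schedule and topology.

## Protein structure networks

`build_psn` converts a heavy-atom structure into a residue interaction
network: residues are nodes; a pair is linked if at least one heavy-atom
pair lies within the cutoff (default 4.0 Å = 0.4 nm), excluding the
covalent backbone C(i)–N(i+1) peptide-bond pair; the edge weight is the
inverse of the arithmetic mean over the *qualifying* (≤ cutoff) atom-pair
distances, so weights are bounded below by 1/cutoff; contact-free residues
are dropped. Three construction choices were genuinely open and are made
explicit here: (1) "non-covalent" is applied at the atom-pair level, so
sequence-adjacent residues still connect through side-chain contacts —
excluding sequence neighbors wholesale is a different convention; (2) only
qualifying pairs enter the average, keeping the weight a property of the
contact interface rather than of residue size; (3) hydrogens are excluded,
so structures with and without explicit protons give the same network.
All three are visible in the code and the cutoff is a CLI flag. Alternate
locations resolve to the highest-occupancy conformer; insertion codes stay
part of the residue identity; only the first model of a multi-model file is
read.

## Statistics

Goodman–Kruskal gamma is computed from exact concordant/discordant pair
counts (ties ignored), with the classical asymptotic standard error and a
normal-approximation p-value against gamma = 0; it is checked against
exhaustive brute-force enumeration. The two-sample chi-square for GC
distributions bins both samples on a common 10-bin equal-width grid over
[0, 1] and pools adjacent sparse bins (expected count < 5) before the
homogeneity test — the binning is a package choice, stated here because no
canonical one exists. `steiger_test` compares two dependent correlations
sharing a variable (Fisher-z based), for questions like "does GC predict a
covariate better than degree does". `mean_sem` returns NaN SEM for a single
value rather than pretending to an uncertainty.

## Synthetic data and what the tests show

The graph generator produces complete graphs, stars, ring lattices, grids,
Erdős–Rényi and Barabási–Albert graphs with deterministic seeding. Complete
graphs and stars admit closed-form GC (every K_n node has GC 1 because the
lone defector's T(n−1) beats every cooperator's R(n−2)+S; a star leaf has
GC 0 and the hub GC 1), which anchors the analytic test suite; random
graphs exercise the engine-versus-oracle equivalence. These fixtures
emulate topology only: they have no community structure, no degree–function
correlation, and no weights with physical meaning, so passing them
validates the *mechanics* (payoff accounting, update rules, schedules,
stopping rules, reproducibility) — not any biological claim about real
interactomes, which require the external networks referenced in the
acceptance tests.

Problem sizes were chosen to keep the default suite fast while still
exercising every code path: GC oracles on K_3–K_20 and stars up to 10
leaves, oracle equivalence on 200 random graphs of up to 12 nodes over 20
rounds for all six rule×schedule combinations, 500 random gamma inputs of
length 20, and a full 34-node karate-club sweep.

## Known limitations

Directed games, >2 strategies, group (public-goods) interactions, mutation
noise and coevolving topology are out of scope. The Fermi K, proportional
normalization and semi-synchronous q are conventions, not measured
quantities; results quoted under them should state them (the manifest does).
GC values on fluctuating dynamics (e.g. PD on square lattices) may never
meet the drift criterion; the package reports this instead of forcing
convergence. The inverse measure (a lone cooperator in an all-defect
background) and GC of richer node aggregates (cliques, communities) are
natural extensions not implemented here.
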