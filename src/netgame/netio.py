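"""Network container, Pajek .net reader/writer and synthetic graph generators.

The simulator operates on undirected, optionally weighted graphs with stable
text labels as node identifiers.  Self-loops are never stored (a node does not
play against itself) and edge weights are strictly positive.  Real networks
come in as Pajek ``.net`` documents; test fixtures and demo arenas are built
by :func:`make_graph`.
"""

from __future__ import annotations

import io
import logging
import re
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "PajekError",
    "read_pajek",
    "write_pajek",
    "make_graph",
    "read_node_list",
]


class PajekError(ValueError):
    """Raised for malformed Pajek documents; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class Network:
    """Undirected weighted graph with ordered, text-labelled nodes.

    Parameters
    ----------
    labels
        Node identifiers in a fixed order; must be unique.
    edges
        Iterable of ``(u, v, weight)`` or ``(u, v)`` tuples referring to
        labels.  Missing weights default to 1.0.  Self-loops and duplicate
        (including reciprocal) edges are rejected here: readers are expected
        to have cleaned them up already.
    """

    def __init__(
        self,
        labels: Sequence[str],
        edges: Iterable[tuple] = (),
    ):
        self.labels: list[str] = [str(x) for x in labels]
        self._index: dict[str, int] = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != len(self.labels):
            raise ValueError("duplicate node labels")
        eu, ev, ew = [], [], []
        seen: set[tuple[int, int]] = set()
        for e in edges:
            if len(e) == 2:
                u, v = e
                w = 1.0
            else:
                u, v, w = e
            try:
                iu, iv = self._index[str(u)], self._index[str(v)]
            except KeyError as exc:
                raise ValueError(f"edge endpoint {exc.args[0]!r} is not a declared node")
            if iu == iv:
                raise ValueError(f"self-loop on node {u!r}")
            w = float(w)
            if not np.isfinite(w) or w <= 0:
                raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {w}")
            key = (min(iu, iv), max(iu, iv))
            if key in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)
            eu.append(key[0])
            ev.append(key[1])
            ew.append(w)
        self.edge_u = np.asarray(eu, dtype=np.intp)
        self.edge_v = np.asarray(ev, dtype=np.intp)
        self.weights = np.asarray(ew, dtype=float)
        self._adjacency: list[np.ndarray] | None = None

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return len(self.edge_u)

    def index(self, label: str) -> int:
        try:
            return self._index[str(label)]
        except KeyError:
            raise KeyError(f"node {label!r} not in network")

    def __contains__(self, label: object) -> bool:
        return str(label) in self._index

    def has_edge(self, u: str, v: str) -> bool:
        iu, iv = self.index(u), self.index(v)
        key = (min(iu, iv), max(iu, iv))
        return any(
            (a, b) == key for a, b in zip(self.edge_u, self.edge_v)
        )

    @property
    def adjacency(self) -> list[np.ndarray]:
        """Neighbor index arrays, one per node, in ascending index order."""
        if self._adjacency is None:
            nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for a, b in zip(self.edge_u, self.edge_v):
                nbrs[a].append(b)
                nbrs[b].append(a)
            self._adjacency = [np.array(sorted(x), dtype=np.intp) for x in nbrs]
        return self._adjacency

    def degree(self, label: str) -> int:
        return len(self.adjacency[self.index(label)])

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [
            (self.labels[a], self.labels[b], w)
            for a, b, w in zip(self.edge_u, self.edge_v, self.weights)
        ]

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for u, v, w in self.edge_list():
            g.add_edge(u, v, weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        labels = [str(n) for n in g.nodes()]
        edges = [
            (str(u), str(v), float(d.get("weight", 1.0)))
            for u, v, d in g.edges(data=True)
            if str(u) != str(v)
        ]
        return cls(labels, edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        if self.labels != other.labels:
            return False
        mine = {(a, b): w for a, b, w in zip(self.edge_u, self.edge_v, self.weights)}
        theirs = {(a, b): w for a, b, w in zip(other.edge_u, other.edge_v, other.weights)}
        return mine.keys() == theirs.keys() and all(
            mine[k] == theirs[k] for k in mine
        )

    def __repr__(self) -> str:
        return f"<Network: {self.n_nodes} nodes, {self.n_edges} edges>"


# ---------------------------------------------------------------------------
# Pajek I/O
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^\*(\w+)(?:\s+(\S+))?", re.IGNORECASE)


def _tokenize(line: str) -> list[str]:
    """Split a Pajek line into tokens, honoring double-quoted labels."""
    return re.findall(r'"[^"]*"|\S+', line)


def read_pajek(text: str) -> Network:
    """Parse a Pajek ``.net`` document into a :class:`Network`.

    Both ``*Edges`` and ``*Arcs`` sections are accepted; arcs are symmetrized
    into undirected edges (all networks simulated here are undirected).
    Duplicate and reciprocal entries collapse to a single edge keeping the
    first weight; self-loops are dropped with a warning; a missing weight
    defaults to 1.0.

    Raises
    ------
    PajekError
        On a malformed header, a vertex index out of range or a non-positive
        weight; the message names the offending line number.
    """
    n_vertices: int | None = None
    labels: list[str] = []
    section: str | None = None
    edges: list[tuple[int, int, float]] = []
    seen: dict[tuple[int, int], float] = {}
    order: list[tuple[int, int]] = []

    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        if line.startswith("*"):
            m = _HEADER_RE.match(line)
            if m is None:
                raise PajekError(f"malformed section header {line!r}", lineno)
            name = m.group(1).lower()
            if name == "vertices":
                if m.group(2) is None:
                    raise PajekError("*Vertices header missing a count", lineno)
                try:
                    n_vertices = int(m.group(2))
                except ValueError:
                    raise PajekError(
                        f"*Vertices count {m.group(2)!r} is not an integer", lineno
                    )
                if n_vertices < 0:
                    raise PajekError("negative vertex count", lineno)
                labels = [str(i) for i in range(1, n_vertices + 1)]
                section = "vertices"
            elif name in ("edges", "arcs"):
                if n_vertices is None:
                    raise PajekError(
                        f"*{name.capitalize()} section before *Vertices", lineno
                    )
                section = "edges"
            else:
                # *Matrix etc. — unsupported sections are skipped wholesale
                section = "skip"
            continue
        if section == "vertices":
            toks = _tokenize(line)
            try:
                idx = int(toks[0])
            except ValueError:
                raise PajekError(f"vertex index {toks[0]!r} is not an integer", lineno)
            if not 1 <= idx <= (n_vertices or 0):
                raise PajekError(
                    f"vertex index {idx} out of range 1..{n_vertices}", lineno
                )
            if len(toks) > 1:
                labels[idx - 1] = toks[1].strip('"')
        elif section == "edges":
            toks = _tokenize(line)
            if len(toks) < 2:
                raise PajekError(f"edge line needs two endpoints: {line!r}", lineno)
            try:
                iu, iv = int(toks[0]), int(toks[1])
            except ValueError:
                raise PajekError(f"non-integer endpoint in {line!r}", lineno)
            for idx in (iu, iv):
                if not 1 <= idx <= (n_vertices or 0):
                    raise PajekError(
                        f"vertex index {idx} out of range 1..{n_vertices}", lineno
                    )
            w = 1.0
            if len(toks) >= 3:
                try:
                    w = float(toks[2])
                except ValueError:
                    raise PajekError(f"weight {toks[2]!r} is not a number", lineno)
            if w <= 0:
                raise PajekError(f"non-positive weight {w}", lineno)
            if iu == iv:
                logger.warning("line %d: dropping self-loop on vertex %d", lineno, iu)
                continue
            key = (min(iu, iv), max(iu, iv))
            if key not in seen:  # first weight wins
                seen[key] = w
                order.append(key)
        elif section is None:
            raise PajekError(f"content before any section header: {line!r}", lineno)

    if n_vertices is None:
        raise PajekError("document has no *Vertices section")
    edges = [(labels[a - 1], labels[b - 1], seen[(a, b)]) for a, b in order]
    return Network(labels, edges)


def write_pajek(net: Network) -> str:
    """Serialize a :class:`Network` as a Pajek document.

    ``read_pajek(write_pajek(net))`` reproduces ``net`` exactly (labels,
    edges, weights).
    """
    lines = [f"*Vertices {net.n_nodes}"]
    for i, lab in enumerate(net.labels, start=1):
        lines.append(f'{i} "{lab}"')
    lines.append("*Edges")
    for a, b, w in zip(net.edge_u, net.edge_v, net.weights):
        lines.append(f"{a + 1} {b + 1} {float(w)!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Synthetic graph generators
# ---------------------------------------------------------------------------


def make_graph(kind: str, seed: int | None = None, **params) -> Network:
    """Build a named synthetic graph with node labels ``n1…nN``.

    Supported kinds and their parameters:

    ``complete``        ``n``
    ``star``            ``leaves`` (hub is ``n1``)
    ``ring_lattice``    ``n``, ``k`` (each node linked to k nearest, k even)
    ``grid``            ``rows``, ``cols``
    ``erdos_renyi``     ``n``, ``p`` (+ ``seed``)
    ``barabasi_albert`` ``n``, ``m`` (+ ``seed``)

    Deterministic for a fixed seed.
    """
    if kind == "complete":
        g = nx.complete_graph(int(params["n"]))
    elif kind == "star":
        g = nx.star_graph(int(params["leaves"]))
    elif kind == "ring_lattice":
        n, k = int(params["n"]), int(params.get("k", 2))
        if k % 2 or k <= 0:
            raise ValueError("ring_lattice needs even k > 0")
        g = nx.circulant_graph(n, list(range(1, k // 2 + 1)))
    elif kind == "grid":
        g = nx.grid_2d_graph(int(params["rows"]), int(params["cols"]))
    elif kind == "erdos_renyi":
        g = nx.gnp_random_graph(int(params["n"]), float(params["p"]), seed=seed)
    elif kind == "barabasi_albert":
        g = nx.barabasi_albert_graph(int(params["n"]), int(params["m"]), seed=seed)
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    if g.number_of_nodes() == 0 and kind != "complete":
        raise ValueError("generated graph has no nodes")
    mapping = {node: f"n{i + 1}" for i, node in enumerate(g.nodes())}
    labels = [mapping[node] for node in g.nodes()]
    edges = [(mapping[u], mapping[v]) for u, v in g.edges() if u != v]
    return Network(labels, edges)


def read_node_list(text: str) -> list[str]:
    """Parse a node-list file: one label per line, ``#`` comments allowed."""
    out = []
    for raw in io.StringIO(text):
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out
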