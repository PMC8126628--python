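"""Coupling-graph generators and the gap-junction current.

Seven coupling structures are used in the experiments: the complete graph
(z = n-1), the periodic 2-D grid (z = 4), the grid overlaid with a random
k-regular set of long-range connections per neuron (z = 4 + k for k = 5, 20,
50), and Watts-Strogatz small-world rings (z = 4, 24, 54 at rewiring
probability p).  All graphs are undirected and simple.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Topology",
    "make_full",
    "make_grid",
    "add_long_range",
    "make_ws",
    "gap_currents",
    "build_network",
]


@dataclass(frozen=True)
class Topology:
    """Undirected simple coupling graph on neurons 0..n-1."""

    n: int
    edges: frozenset  # of 2-tuples (i, j) with i < j
    kind: str = "custom"
    seed: int | None = None
    _csr: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loop in topology")
            if not (0 <= i < j < self.n):
                raise ValueError(f"bad edge ({i}, {j}) for n={self.n}")

    @property
    def z(self) -> float:
        """Mean connectivity (mean degree)."""
        return 2.0 * len(self.edges) / self.n

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, i: int) -> list:
        indptr, indices = self.csr()
        return list(indices[indptr[i]:indptr[i + 1]])

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two int arrays (sorted lexicographically)."""
        e = np.array(sorted(self.edges), dtype=np.int64).reshape(-1, 2)
        return e[:, 0], e[:, 1]

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) adjacency in compressed sparse row form."""
        if self._csr is None:
            adj = [[] for _ in range(self.n)]
            for i, j in self.edges:
                adj[i].append(j)
                adj[j].append(i)
            indptr = np.zeros(self.n + 1, dtype=np.int64)
            for i, nbrs in enumerate(adj):
                indptr[i + 1] = indptr[i] + len(nbrs)
            indices = np.concatenate([np.sort(a) for a in adj if a] or
                                     [np.empty(0, dtype=np.int64)]).astype(np.int64)
            object.__setattr__(self, "_csr", (indptr, indices))
        return self._csr

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def save_edgelist(self, path: str | os.PathLike) -> None:
        """Two integer columns, 0-based, one edge per line."""
        a, b = self.edge_arrays()
        np.savetxt(path, np.column_stack([a, b]), fmt="%d",
                   header=f"n={self.n} kind={self.kind}")

    @classmethod
    def load_edgelist(cls, path: str | os.PathLike, n: int | None = None) -> "Topology":
        arr = np.loadtxt(path, dtype=int).reshape(-1, 2)
        if n is None:
            n = int(arr.max()) + 1
        edges = frozenset((min(i, j), max(i, j)) for i, j in arr)
        return cls(n=n, edges=edges, kind="loaded")


def _from_graph(g: nx.Graph, kind: str, seed: int | None = None) -> Topology:
    edges = frozenset((min(i, j), max(i, j)) for i, j in g.edges())
    return Topology(n=g.number_of_nodes(), edges=edges, kind=kind, seed=seed)


def make_full(n: int) -> Topology:
    """Complete graph: every neuron coupled to every other (z = n - 1)."""
    if n < 2:
        raise ValueError("full network needs n >= 2")
    return _from_graph(nx.complete_graph(n), "full")


def make_grid(rows: int, cols: int) -> Topology:
    """Periodic 2-D lattice: up/down/left/right coupling, every degree 4.

    Periodic boundaries make the mean connectivity exactly z = 4 (open
    boundaries would give 3.6 on a 10x10 grid).  Nodes are numbered
    row-major.
    """
    if rows < 3 or cols < 3:
        raise ValueError("grid needs rows, cols >= 3")
    g = nx.grid_2d_graph(rows, cols, periodic=True)
    g = nx.relabel_nodes(g, {(r, c): r * cols + c for r, c in g.nodes()})
    return _from_graph(g, "grid")


def add_long_range(base: Topology, k: int, seed: int = 0, max_tries: int = 200) -> Topology:
    """Overlay a uniformly random k-regular graph on the non-adjacent pairs.

    Every neuron gains exactly ``k`` long-range partners it was not already
    coupled to, so the mean connectivity rises by exactly k (grid z=4 ->
    z = 4 + k).  Requires n*k even and enough non-neighbors per node.
    """
    n = base.n
    if k == 0:
        return base
    if k < 0 or (n * k) % 2 != 0:
        raise ValueError("need k >= 0 with n*k even")
    deg = base.degrees()
    if np.any(n - 1 - deg < k):
        raise ValueError("some node lacks capacity for k extra links")
    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        g = nx.random_regular_graph(k, n, seed=int(rng.integers(2**31)))
        bad = [e for e in g.edges() if (min(e), max(e)) in base.edges]
        ok = True
        guard = 0
        while bad and guard < 50 * len(g.edges()):
            guard += 1
            u, v = bad.pop()
            if not g.has_edge(u, v):
                continue
            edges = list(g.edges())
            x, y = edges[int(rng.integers(len(edges)))]
            # double-edge swap (u,v),(x,y) -> (u,x),(v,y), keeping the graph
            # simple and avoiding the base edges
            new = [(u, x), (v, y)]
            if (len({u, v, x, y}) < 4
                    or any(g.has_edge(a, b) for a, b in new)
                    or any((min(a, b), max(a, b)) in base.edges for a, b in new)):
                bad.append((u, v))
                continue
            g.remove_edge(u, v)
            g.remove_edge(x, y)
            g.add_edge(u, x)
            g.add_edge(v, y)
            bad = [e for e in g.edges() if (min(e), max(e)) in base.edges]
        if bad:
            continue  # reshuffle from a fresh regular graph
        edges = base.edges | {(min(e), max(e)) for e in g.edges()}
        return Topology(n=n, edges=frozenset(edges),
                        kind=f"{base.kind}_plus_long_range", seed=seed)
    raise RuntimeError(f"could not place a conflict-free {k}-regular overlay")


def make_ws(n: int, z: int, p: float, seed: int = 0) -> Topology:
    """Watts-Strogatz small-world ring: z nearest neighbors, rewiring prob p.

    Each ring edge is rewired (one endpoint moved to a uniform random node)
    independently with probability p, avoiding self-loops and duplicates;
    the edge count, hence mean degree z, is preserved.
    """
    if z % 2 != 0:
        raise ValueError("z must be even for the ring construction")
    if z >= n:
        raise ValueError("need z < n")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    g = nx.watts_strogatz_graph(n, z, p, seed=seed)
    return _from_graph(g, "ws", seed)


def build_network(kind: str, n: int = 100, z: float | None = None,
                  p: float = 0.03, seed: int = 0,
                  rows: int | None = None, cols: int | None = None) -> Topology:
    """Build any of the named coupling structures from a config-style spec.

    kind: 'full' | 'grid' | 'grid_plus_long_range' | 'ws'.  For grids,
    rows/cols default to a square layout of n.  For the long-range overlay,
    z must be 4 + k.
    """
    if kind == "full":
        return make_full(n)
    if rows is None or cols is None:
        side = int(round(np.sqrt(n)))
        if side * side != n:
            raise ValueError("grid kinds need square n or explicit rows/cols")
        rows = cols = side
    if kind == "grid":
        return make_grid(rows, cols)
    if kind == "grid_plus_long_range":
        if z is None or z < 4:
            raise ValueError("grid_plus_long_range needs z >= 4")
        return add_long_range(make_grid(rows, cols), int(z) - 4, seed=seed)
    if kind == "ws":
        if z is None:
            raise ValueError("ws needs z")
        return make_ws(n, int(z), p, seed=seed)
    raise ValueError(f"unknown network kind: {kind}")


def gap_currents(V: np.ndarray, topo: Topology, g_gj: float) -> np.ndarray:
    """Gap-junction input to each neuron: I_gj[i] = sum_k g_gj (V_k - V_i).

    Positive when the neighbors sit above V_i.  Antisymmetric pairwise
    exchange makes the network total exactly zero for any undirected
    topology.
    """
    V = np.asarray(V, dtype=float)
    if V.shape[0] != topo.n:
        raise ValueError(f"V has {V.shape[0]} entries for n={topo.n}")
    a, b = topo.edge_arrays()
    I = np.zeros_like(V)
    flow = g_gj * (V[b] - V[a])  # current into a from b
    np.add.at(I, a, flow)
    np.add.at(I, b, -flow)
    return I
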