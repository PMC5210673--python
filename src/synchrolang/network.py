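"""Connected k-regular social networks and meeting sampling.

The group's social structure is a connected k-regular graph on ``n`` agents:
every agent maintains exactly ``k`` social ties, and the graph is connected so
that group-level coordination is possible at all.  Graphs are drawn with the
pairing (configuration-model) algorithm and rejection of disconnected
outcomes, which is approximately uniform over the set of connected k-regular
graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "SocialNetwork",
    "GraphGenerationError",
    "build_k_regular",
    "sample_meeting",
    "read_edge_list",
    "write_edge_list",
]

#: bounded number of rejection-sampling attempts before giving up
DEFAULT_MAX_TRIES = 1000


class GraphGenerationError(RuntimeError):
    """Raised when rejection sampling fails to produce a connected graph."""


def _check_feasible(n: int, k: int) -> None:
    if k < 1:
        raise ValueError(f"degree k must be >= 1, got k={k}")
    if n < k + 1:
        raise ValueError(f"need n >= k+1 for a simple k-regular graph, got n={n}, k={k}")
    if (n * k) % 2 != 0:
        raise ValueError(f"no k-regular graph exists with n*k odd (n={n}, k={k})")


@dataclass(frozen=True)
class SocialNetwork:
    """A connected k-regular graph on agents 0..n-1.

    ``edges`` is a sorted tuple of unordered pairs (i, j) with i < j;
    ``adjacency`` maps each agent to the frozen set of its neighbours.
    """

    n: int
    k: int
    edges: tuple[tuple[int, int], ...]
    adjacency: dict[int, frozenset[int]] = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def from_edges(cls, n: int, edges) -> "SocialNetwork":
        edges = tuple(sorted(tuple(sorted(map(int, e))) for e in edges))
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j in edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references an agent outside 0..{n - 1}")
            adj[i].add(j)
            adj[j].add(i)
        degrees = {len(s) for s in adj.values()}
        if len(degrees) != 1:
            raise ValueError(f"graph is not regular: degree set {sorted(degrees)}")
        k = degrees.pop()
        frozen = {i: frozenset(s) for i, s in adj.items()}
        return cls(n=n, k=k, edges=edges, adjacency=frozen)

    def validate(self) -> None:
        _check_feasible(self.n, self.k)
        seen = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at agent {i}")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i},{j})")
            seen.add((i, j))
        if len(self.edges) != self.n * self.k // 2:
            raise ValueError(
                f"edge count {len(self.edges)} != n*k/2 = {self.n * self.k // 2}"
            )
        for i in range(self.n):
            if len(self.adjacency.get(i, ())) != self.k:
                raise ValueError(f"agent {i} has degree {len(self.adjacency.get(i, ()))}, expected {self.k}")
        if not self.is_connected():
            raise ValueError("graph is not connected")

    def is_connected(self) -> bool:
        # breadth-first search from agent 0
        seen = {0}
        frontier = [0]
        while frontier:
            nxt = []
            for u in frontier:
                for v in self.adjacency[u]:
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        return len(seen) == self.n

    def edge_array(self) -> np.ndarray:
        """Edges as an (m, 2) int array, cached per instance."""
        arr = getattr(self, "_edge_array", None)
        if arr is None:
            arr = np.asarray(self.edges, dtype=np.int64)
            object.__setattr__(self, "_edge_array", arr)
        return arr

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g


def build_k_regular(
    n: int,
    k: int,
    seed: int | np.random.Generator,
    max_tries: int = DEFAULT_MAX_TRIES,
) -> SocialNetwork:
    """Draw a connected k-regular graph on n agents.

    Uses configuration-model pairing with rejection of disconnected outcomes;
    identical seed yields an identical graph.  Raises ``ValueError`` for
    infeasible (n, k) and ``GraphGenerationError`` if ``max_tries`` successive
    draws are all disconnected.
    """
    _check_feasible(n, k)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(max_tries):
        g = nx.random_regular_graph(k, n, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return SocialNetwork.from_edges(n, g.edges())
    raise GraphGenerationError(
        f"failed to draw a connected {k}-regular graph on {n} nodes in {max_tries} tries"
    )


def sample_meeting(network: SocialNetwork, rng: np.random.Generator) -> tuple[int, int]:
    """Draw one meeting: a uniformly random edge (each tie equally likely).

    The order of the returned pair carries no meaning — both endpoints update.
    """
    edges = network.edges
    return edges[int(rng.integers(len(edges)))]


def write_edge_list(network: SocialNetwork, path: str | Path) -> None:
    """Write the network as one ``i j`` pair per line (0-based ids)."""
    path = Path(path)
    lines = [f"{i} {j}" for i, j in network.edges]
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path, n: int | None = None) -> SocialNetwork:
    """Read an edge-list file and validate all network invariants.

    ``n`` defaults to max agent id + 1.
    """
    path = Path(path)
    edges = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'i j', got {line!r}")
        edges.append((int(parts[0]), int(parts[1])))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    if n is None:
        n = max(max(e) for e in edges) + 1
    return SocialNetwork.from_edges(n, edges)
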