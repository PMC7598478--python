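"""Contact networks: representation, configuration-model generation, edge-list I/O.

A contact network is a simple, connected, undirected graph whose nodes are
agents (dense 0-based integers).  Synthetic networks follow a truncated
power-law configuration model: degrees are drawn i.i.d. from the normalized
discrete law ``P(k) ~ k^-beta`` on ``k_min <= k <= n-1`` (a simple graph
cannot realize degree ``n``), realized by uniform stub matching with
erasure of self-loops and multi-edges, and regenerated until connected.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "ContactNetwork",
    "generate_configuration_network",
    "truncated_powerlaw_pmf",
    "read_edge_list",
    "write_edge_list",
    "EdgeListFormatError",
    "GenerationError",
]


class EdgeListFormatError(ValueError):
    """Malformed edge-list file (self-loop, duplicate, bad tokens)."""


class GenerationError(RuntimeError):
    """No connected simple graph obtained within the attempt budget."""


class ContactNetwork:
    """Simple undirected graph with adjacency-list lookup.

    Nodes are ``0..n-1``; edges are unordered pairs of distinct nodes.
    """

    __slots__ = ("n", "adjacency", "_edges")

    def __init__(self, n: int, edges: Iterable[Tuple[int, int]]):
        canon = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) outside node range 0..{n - 1}")
            canon.add((min(u, v), max(u, v)))
        self.n = int(n)
        self._edges = sorted(canon)
        self.adjacency: List[List[int]] = [[] for _ in range(self.n)]
        for u, v in self._edges:
            self.adjacency[u].append(v)
            self.adjacency[v].append(u)

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.n

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def edges(self) -> List[Tuple[int, int]]:
        """Canonical edge list (sorted, smaller endpoint first)."""
        return list(self._edges)

    def neighbors(self, v: int) -> List[int]:
        return self.adjacency[v]

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency], dtype=np.int64)

    def is_connected(self) -> bool:
        if self.n == 0:
            return False
        seen = np.zeros(self.n, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            u = stack.pop()
            for w in self.adjacency[u]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        return bool(seen.all())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self._edges)
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ContactNetwork(n={self.n}, edges={self.n_edges})"


def truncated_powerlaw_pmf(n: int, beta: float, k_min: int) -> Tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of ``P(k) ~ k^-beta`` on ``k_min..n-1``.

    The normalizing constant is computed by direct summation over the
    support; the upper cutoff is ``n-1`` because a simple graph caps the
    degree there.
    """
    if beta <= 1:
        raise ValueError("beta must exceed 1")
    if not 1 <= k_min < n:
        raise ValueError("need 1 <= k_min < n")
    ks = np.arange(k_min, n, dtype=np.int64)
    w = ks.astype(float) ** (-beta)
    return ks, w / w.sum()


def generate_configuration_network(n: int, beta: float, k_min: int = 3,
                                   seed: int | np.random.Generator | None = None,
                                   max_attempts: int = 100) -> ContactNetwork:
    """Truncated power-law configuration-model network.

    Degrees are sampled by inverse CDF on the exact normalized discrete law;
    an odd degree sum is repaired by incrementing one uniformly chosen node
    (bounded by ``n-1``); stubs are matched uniformly and self-loops /
    multi-edges erased; the whole construction is retried until the graph
    is connected.
    """
    if n <= k_min:
        raise ValueError(f"need n > k_min (got n={n}, k_min={k_min})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ks, probs = truncated_powerlaw_pmf(n, beta, k_min)
    cdf = np.cumsum(probs)

    for _ in range(max_attempts):
        degrees = ks[np.searchsorted(cdf, rng.random(n), side="right").clip(max=len(ks) - 1)]
        if degrees.sum() % 2 == 1:
            i = int(rng.integers(n))
            degrees = degrees.copy()
            degrees[i] = min(degrees[i] + 1, n - 1)
            if degrees.sum() % 2 == 1:  # bumped node already at n-1: move on
                j = (i + 1) % n
                degrees[j] = min(degrees[j] + 1, n - 1)
                if degrees.sum() % 2 == 1:
                    continue
        stubs = np.repeat(np.arange(n), degrees)
        rng.shuffle(stubs)
        half = len(stubs) // 2
        pairs = {(min(u, v), max(u, v))
                 for u, v in zip(stubs[:half], stubs[half:]) if u != v}
        net = ContactNetwork(n, pairs)
        if net.is_connected():
            return net
    raise GenerationError(
        f"no connected simple graph in {max_attempts} attempts "
        f"(n={n}, beta={beta}, k_min={k_min})")


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def write_edge_list(network: ContactNetwork, path) -> None:
    """Write the canonical edge list with a ``#nodes N`` header."""
    with open(path, "w") as fh:
        fh.write(f"#nodes {network.n}\n")
        for u, v in network.edges:
            fh.write(f"{u} {v}\n")


def read_edge_list(path, strict: bool = False) -> ContactNetwork:
    """Read a whitespace-separated edge list.

    Lines starting with ``#`` are comments; a ``#nodes N`` header declares
    the node count (needed for isolated nodes).  Self-loops and duplicate
    edges are format errors naming the offending line.  A disconnected
    graph warns, or raises when ``strict`` is set.
    """
    import warnings

    edges = []
    seen = set()
    declared_n = None
    max_label = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "nodes":
                    declared_n = int(parts[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListFormatError(f"line {lineno}: expected two node labels")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise EdgeListFormatError(f"line {lineno}: non-integer label") from exc
            if u == v:
                raise EdgeListFormatError(f"line {lineno}: self-loop at node {u}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise EdgeListFormatError(f"line {lineno}: duplicate edge {key}")
            seen.add(key)
            max_label = max(max_label, u, v)
            edges.append(key)
    n = declared_n if declared_n is not None else max_label + 1
    net = ContactNetwork(n, edges)
    if not net.is_connected():
        msg = f"{path}: graph is not connected"
        if strict:
            raise EdgeListFormatError(msg)
        warnings.warn(msg, stacklevel=2)
    return net
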