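"""Catalogue of the 30 graphlets on 2-5 nodes and their 73 automorphism orbits.

A *graphlet* is a small connected induced subgraph of a larger network.  Two
nodes of a graphlet belong to the same *automorphism orbit* when some
automorphism of the graphlet maps one onto the other; across the 30
non-isomorphic graphlets on 2-5 nodes there are exactly 73 such orbits,
numbered 0-72.  The per-node orbit-count vector over these 73 orbits is the
*graphlet signature* (graphlet degree vector) used by the topology-based
disease similarity measure.

The catalogue below is frozen data: for each graphlet, an edge list on nodes
``0..n-1`` and the orbit number of every node.  Graphlets are ordered by node
count, then edge count, then the canonical published within-class order;
orbit numbers within a graphlet increase with (node degree, sorted
neighbour-degree multiset).  The test-suite re-validates the whole table by
explicit automorphism-group computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

N_ORBITS = 73
N_GRAPHLETS = 30


@dataclass(frozen=True)
class Graphlet:
    """One catalogue entry: a small graph plus the orbit label of each node."""

    index: int
    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    orbits: tuple[int, ...]  # orbit number of node i, length n_nodes

    @property
    def adjacency(self) -> tuple[frozenset[int], ...]:
        return _adjacency(self.edges, self.n_nodes)


def _adjacency(edges, n) -> tuple[frozenset[int], ...]:
    adj = [set() for _ in range(n)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return tuple(frozenset(a) for a in adj)


def _k5_minus(missing):
    return tuple(
        (i, j)
        for i in range(5)
        for j in range(i + 1, 5)
        if (i, j) not in missing and (j, i) not in missing
    )


#: The 30 graphlets G0..G29.  Comments give the common name of each graph.
GRAPHLETS: tuple[Graphlet, ...] = (
    # --- 2 nodes ---
    Graphlet(0, 2, ((0, 1),), (0, 0)),  # edge
    # --- 3 nodes ---
    Graphlet(1, 3, ((0, 1), (1, 2)), (1, 2, 1)),  # path P3
    Graphlet(2, 3, ((0, 1), (0, 2), (1, 2)), (3, 3, 3)),  # triangle
    # --- 4 nodes ---
    Graphlet(3, 4, ((0, 1), (1, 2), (2, 3)), (4, 5, 5, 4)),  # path P4
    Graphlet(4, 4, ((0, 3), (1, 3), (2, 3)), (6, 6, 6, 7)),  # claw / 3-star
    Graphlet(5, 4, ((0, 1), (1, 2), (2, 3), (0, 3)), (8, 8, 8, 8)),  # cycle C4
    Graphlet(6, 4, ((0, 3), (1, 2), (1, 3), (2, 3)), (9, 10, 10, 11)),  # paw
    Graphlet(7, 4, ((0, 2), (0, 3), (1, 2), (1, 3), (2, 3)), (12, 12, 13, 13)),  # diamond
    Graphlet(8, 4, ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)), (14, 14, 14, 14)),  # K4
    # --- 5 nodes, 4 edges (trees) ---
    Graphlet(9, 5, ((0, 1), (1, 2), (2, 3), (3, 4)), (15, 16, 17, 16, 15)),  # path P5
    Graphlet(10, 5, ((0, 1), (1, 2), (2, 3), (2, 4)), (18, 20, 21, 19, 19)),  # fork
    Graphlet(11, 5, ((0, 4), (1, 4), (2, 4), (3, 4)), (22, 22, 22, 22, 23)),  # star S4
    # --- 5 nodes, 5 edges ---
    Graphlet(12, 5, ((0, 2), (1, 2), (2, 3), (2, 4), (3, 4)), (24, 24, 26, 25, 25)),  # cricket
    Graphlet(13, 5, ((0, 1), (1, 2), (2, 3), (2, 4), (3, 4)), (27, 28, 30, 29, 29)),  # tadpole
    Graphlet(14, 5, ((0, 2), (1, 3), (2, 3), (2, 4), (3, 4)), (31, 31, 33, 33, 32)),  # bull
    Graphlet(15, 5, ((0, 1), (1, 2), (2, 3), (3, 4), (0, 4)), (34, 34, 34, 34, 34)),  # cycle C5
    Graphlet(16, 5, ((0, 1), (1, 2), (2, 3), (3, 4), (1, 4)), (35, 38, 37, 36, 37)),  # C4 + pendant
    # --- 5 nodes, 6 edges ---
    Graphlet(17, 5, ((0, 4), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)), (39, 40, 40, 41, 42)),  # diamond + pendant at degree-3 node
    Graphlet(18, 5, ((0, 1), (0, 4), (1, 4), (2, 3), (2, 4), (3, 4)), (43, 43, 43, 43, 44)),  # bowtie
    Graphlet(19, 5, ((0, 1), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)), (45, 47, 46, 48, 48)),  # diamond + pendant at degree-2 node
    Graphlet(20, 5, ((0, 3), (0, 4), (1, 3), (1, 4), (2, 3), (2, 4)), (49, 49, 49, 50, 50)),  # K2,3
    Graphlet(21, 5, ((0, 1), (0, 2), (1, 3), (2, 3), (2, 4), (3, 4)), (51, 51, 53, 53, 52)),  # house
    # --- 5 nodes, 7 edges ---
    Graphlet(
        22,
        5,
        ((3, 4), (0, 3), (0, 4), (1, 3), (1, 4), (2, 3), (2, 4)),
        (54, 54, 54, 55, 55),
    ),  # complete split: K2 joined to 3 independent nodes
    Graphlet(
        23,
        5,
        ((0, 1), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)),
        (56, 58, 57, 57, 57),
    ),  # K4 + pendant
    Graphlet(24, 5, _k5_minus({(0, 1), (0, 2), (1, 3)}), (59, 59, 60, 60, 61)),  # K5 minus P4
    Graphlet(25, 5, _k5_minus({(0, 3), (0, 4), (1, 2)}), (62, 63, 63, 64, 64)),  # K5 minus (P3 + K2)
    # --- 5 nodes, 8 edges ---
    Graphlet(26, 5, _k5_minus({(0, 1), (0, 2)}), (65, 66, 66, 67, 67)),  # K5 minus P3
    Graphlet(
        27,
        5,
        ((0, 1), (1, 2), (2, 3), (0, 3), (0, 4), (1, 4), (2, 4), (3, 4)),
        (68, 68, 68, 68, 69),
    ),  # wheel W4
    # --- 5 nodes, 9-10 edges ---
    Graphlet(28, 5, _k5_minus({(0, 1)}), (70, 70, 71, 71, 71)),  # K5 minus an edge
    Graphlet(29, 5, _k5_minus(set()), (72, 72, 72, 72, 72)),  # K5
)


def graphlet_of_orbit(orbit: int) -> Graphlet:
    """Return the catalogue graphlet containing the given orbit number."""
    for g in GRAPHLETS:
        if orbit in g.orbits:
            return g
    raise ValueError(f"orbit {orbit} is not in 0..{N_ORBITS - 1}")


# ---------------------------------------------------------------------------
# Automorphisms and isomorphism on <=5 nodes (explicit permutation search).
# These are the reference routines the catalogue is validated against and the
# brute-force signature oracle classifies with.
# ---------------------------------------------------------------------------


def edge_set(edges) -> frozenset[frozenset[int]]:
    return frozenset(frozenset(e) for e in edges)


def automorphisms(n: int, edges) -> list[tuple[int, ...]]:
    """All node permutations of ``0..n-1`` preserving the edge set."""
    es = edge_set(edges)
    autos = []
    for perm in permutations(range(n)):
        mapped = frozenset(frozenset((perm[u], perm[v])) for u, v in edges)
        if mapped == es:
            autos.append(perm)
    return autos


def automorphism_orbits(n: int, edges) -> list[frozenset[int]]:
    """Partition of the nodes into automorphism orbits, as frozensets."""
    autos = automorphisms(n, edges)
    seen: set[int] = set()
    orbits = []
    for v in range(n):
        if v in seen:
            continue
        orbit = frozenset(perm[v] for perm in autos)
        orbits.append(orbit)
        seen |= orbit
    return orbits


def find_isomorphism(n: int, edges, graphlet: Graphlet):
    """A permutation mapping graphlet node i -> subject node perm[i], or None."""
    if n != graphlet.n_nodes or len(edge_set(edges)) != len(edge_set(graphlet.edges)):
        return None
    target = edge_set(edges)
    for perm in permutations(range(n)):
        mapped = frozenset(frozenset((perm[u], perm[v])) for u, v in graphlet.edges)
        if mapped == target:
            return perm
    return None


def classify_subgraph(n: int, edges) -> tuple[Graphlet, tuple[int, ...]]:
    """Identify a connected graph on 2-5 nodes in the catalogue.

    Returns the matching catalogue graphlet and the orbit number of each
    subject node ``0..n-1``.
    """
    for g in GRAPHLETS:
        perm = find_isomorphism(n, edges, g)
        if perm is not None:
            node_orbit = [0] * n
            for gnode, subject in enumerate(perm):
                node_orbit[subject] = g.orbits[gnode]
            return g, tuple(node_orbit)
    raise ValueError("graph is not a connected graphlet on 2-5 nodes")


# ---------------------------------------------------------------------------
# Orbit dependency counts and weights
# ---------------------------------------------------------------------------


def _orbits_touched_within(g: Graphlet, node: int) -> set[int]:
    """Orbits touched by ``node`` across all connected induced subgraphs of g."""
    from itertools import combinations

    adj = g.adjacency
    touched: set[int] = set()
    others = [v for v in range(g.n_nodes) if v != node]
    for k in range(1, min(4, g.n_nodes - 1) + 1):
        for extra in combinations(others, k):
            nodes = (node, *extra)
            idx = {v: i for i, v in enumerate(nodes)}
            sub_edges = [
                (idx[u], idx[v])
                for u, v in g.edges
                if u in idx and v in idx
            ]
            if not _connected(len(nodes), sub_edges):
                continue
            _, node_orbits = classify_subgraph(len(nodes), sub_edges)
            touched.add(node_orbits[0])
    return touched


def _connected(n: int, edges) -> bool:
    if n == 1:
        return True
    adj = _adjacency(edges, n)
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


@lru_cache(maxsize=1)
def orbit_dependency_counts() -> tuple[int, ...]:
    """Dependency count o_i for every orbit i = 0..72.

    o_i is the number of distinct orbits that a node occupying orbit i
    necessarily touches within its own graphlet (orbit i itself included);
    e.g. a triangle node (orbit 3) also touches orbit 0 twice, so o_3 = 2,
    while o_0 = 1.  These counts grade how much of a signature component is
    already implied by other components.
    """
    counts = [0] * N_ORBITS
    for g in GRAPHLETS:
        done: set[int] = set()
        for node, orb in enumerate(g.orbits):
            if orb in done:
                continue
            done.add(orb)
            counts[orb] = len(_orbits_touched_within(g, node))
    return tuple(counts)


@lru_cache(maxsize=1)
def orbit_weights() -> np.ndarray:
    """Orbit weights ``w_i = 1 - log(o_i) / log(73)``, a 73-vector in (0, 1].

    Orbits whose counts are largely determined by other orbits (high o_i)
    are down-weighted when comparing signatures; orbit 0 (degree), the only
    fully independent orbit, has weight exactly 1.
    """
    o = np.asarray(orbit_dependency_counts(), dtype=float)
    return 1.0 - np.log(o) / math.log(N_ORBITS)
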